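import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

from twinewas.data_model import CELL_TYPES, BetaMatrix, CellCounts, SampleSheet
from twinewas.simulate import PRESETS, simulate_cohort


@pytest.fixture(scope="session")
def demo_cohort():
    """Small cohort (20 pairs x 500 probes) shared by read-only tests."""
    return simulate_cohort(PRESETS["demo"])


def make_sample_sheet(n_pairs: int, seed: int = 0, incomplete: int = 0) -> SampleSheet:
    """Hand-sized sample sheet: pairs P0000A/B..., alternating sex."""
    rng = np.random.default_rng(seed)
    rows = []
    for j in range(n_pairs):
        pid = f"P{j:04d}"
        members = ["A"] if j < incomplete else ["A", "B"]
        age = float(55 + rng.integers(0, 25))
        for m in members:
            rows.append(
                {
                    "sample_id": f"{pid}{m}",
                    "pair_id": pid,
                    "sex": "female" if j % 2 == 0 else "male",
                    "age_followup": age,
                    "chip_side": "Left" if j % 2 == 0 else "Right",
                    "chip_row": j % 6 + 1,
                }
            )
    return SampleSheet(pd.DataFrame(rows))


def make_cell_counts(sample_ids, seed: int = 0) -> CellCounts:
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        rng.lognormal(0.0, 0.3, size=(len(sample_ids), 5)), columns=CELL_TYPES
    )
    frame.insert(0, "sample_id", list(sample_ids))
    return CellCounts(frame)


def make_beta(n_probes: int, sample_ids, seed: int = 0) -> BetaMatrix:
    rng = np.random.default_rng(seed)
    values = rng.beta(2, 2, size=(n_probes, len(sample_ids)))
    return BetaMatrix(
        pd.DataFrame(values, index=[f"cg{i:06d}" for i in range(n_probes)], columns=list(sample_ids))
    )
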