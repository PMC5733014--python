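"""Shared data containers and TSV/GMT readers and writers.

All tabular formats use a single dialect: tab-delimited, one header line,
the literal string ``NA`` for missing values. Coordinates are 1-based,
450K-manifest style; a negative distance means the probe lies upstream of
its nearest gene and a missing distance means the probe falls inside it.
Sample and pair identifiers are opaque strings; wherever a deterministic
order is required it is lexicographic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NA_TOKEN = "NA"

CELL_TYPES = ["monocytes", "lymphocytes", "basophils", "neutrophils", "eosinophils"]

GENE_REGIONS = ["TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR", "IGR"]
CGI_CONTEXTS = ["island", "shore", "shelf", "open sea"]
CGI_FEATURES = {f"{r}-{c}" for r in GENE_REGIONS for c in CGI_CONTEXTS}

SAMPLE_SHEET_COLUMNS = ["sample_id", "pair_id", "sex", "age_followup", "chip_side", "chip_row"]
ANNOTATION_COLUMNS = ["probe_id", "chromosome", "position", "gene_symbol", "distance_bp", "cgi_feature"]


class ParseError(ValueError):
    """A file could not be parsed into the declared tabular layout."""


class ValidationError(ValueError):
    """Parsed data violates a type invariant."""


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False, **kwargs)


def _write_tsv(frame: pd.DataFrame, path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", na_rep=NA_TOKEN, index=index)


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dupes = ids[ids.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")


# ---------------------------------------------------------------------------
# methylation matrices


@dataclass
class BetaMatrix:
    """Probes × samples matrix of methylation fractions in [0, 1].

    ``data`` is indexed by probe id with sample ids as columns; NaN encodes
    a missing (or QC-masked) measurement.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "probe ids")
        _check_unique(self.data.columns, "sample ids")
        values = self.data.to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            bad = (values < 0) | (values > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value {values[i, j]!r} outside [0, 1] at probe "
                f"{self.data.index[i]!r}, sample {self.data.columns[j]!r}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class ProbeQCMetrics:
    """Per-measurement QC companions to a BetaMatrix (same probes × samples)."""

    bead_count: pd.DataFrame
    detection_p: pd.DataFrame
    signal_zero: pd.DataFrame

    def __post_init__(self) -> None:
        ref = self.bead_count
        for name in ("detection_p", "signal_zero"):
            frame = getattr(self, name)
            if not (frame.index.equals(ref.index) and frame.columns.equals(ref.columns)):
                raise ValidationError(f"{name} dimensions do not match bead_count")
        if (self.bead_count.to_numpy() < 0).any():
            raise ValidationError("negative bead count")
        dp = self.detection_p.to_numpy(dtype=float)
        if np.nanmin(dp) < 0 or np.nanmax(dp) > 1:
            raise ValidationError("detection p-value outside [0, 1]")

    def congruent_with(self, beta: BetaMatrix) -> bool:
        return self.bead_count.index.equals(beta.probe_ids) and self.bead_count.columns.equals(
            beta.sample_ids
        )


def read_beta_matrix(path) -> BetaMatrix:
    """Read a probes × samples beta-value TSV (header row of sample ids)."""
    raw = _read_tsv(path, index_col=0, dtype=str)
    numeric = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            probe = raw.index[bad.argmax()]
            raise ParseError(
                f"non-numeric cell {raw.loc[probe, col]!r} at probe {probe!r}, sample {col!r}"
            )
        numeric[col] = converted
    return BetaMatrix(numeric)


def write_beta_matrix(beta: BetaMatrix, path) -> None:
    frame = beta.data.copy()
    frame.index.name = "probe_id"
    _write_tsv(frame, path, index=True)


def read_qc_metrics(bead_path, detection_path, signal_zero_path) -> ProbeQCMetrics:
    bead = _read_tsv(bead_path, index_col=0).astype(float)
    det = _read_tsv(detection_path, index_col=0).astype(float)
    zero = _read_tsv(signal_zero_path, index_col=0).astype(bool)
    return ProbeQCMetrics(bead, det, zero)


def write_qc_metrics(qc: ProbeQCMetrics, bead_path, detection_path, signal_zero_path) -> None:
    for frame, path in (
        (qc.bead_count, bead_path),
        (qc.detection_p, detection_path),
        (qc.signal_zero.astype(int), signal_zero_path),
    ):
        out = frame.copy()
        out.index.name = "probe_id"
        _write_tsv(out, path, index=True)


# ---------------------------------------------------------------------------
# sample sheet


@dataclass
class SampleSheet:
    """One row per sample: pair membership, sex, age at follow-up, chip position.

    MZ pairs must agree on sex and age; a pair may have one or two members
    (singletons are flagged ``incomplete`` rather than rejected — the
    individual-level scan can still use them).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        _check_unique(self.data["sample_id"], "sample ids")
        df = self.data
        bad_sex = ~df["sex"].isin(["female", "male"])
        if bad_sex.any():
            raise ValidationError(f"unknown sex value {df.loc[bad_sex, 'sex'].iloc[0]!r}")
        if not df["chip_side"].isin(["Left", "Right"]).all():
            raise ValidationError("chip_side must be Left or Right")
        rows = pd.to_numeric(df["chip_row"], errors="coerce")
        if rows.isna().any() or not rows.isin(range(1, 7)).all():
            raise ValidationError("chip_row must be an integer in 1..6")
        if df[["pair_id", "chip_side", "chip_row"]].isna().any().any():
            raise ValidationError("pair/chip fields must be non-missing")
        for pair_id, grp in df.groupby("pair_id"):
            if len(grp) > 2:
                raise ValidationError(f"pair {pair_id!r} has {len(grp)} members")
            if grp["sex"].nunique() > 1:
                raise ValidationError(f"pair {pair_id!r} has discordant sex (MZ pairs are same-sex)")
            if grp["age_followup"].nunique() > 1:
                raise ValidationError(f"pair {pair_id!r} has discordant age at follow-up")
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.data["sample_id"])

    def complete_pairs(self) -> dict[str, tuple[str, str]]:
        """pair_id → (minuend, subtrahend) for pairs with two members,
        ordered lexicographically by sample id."""
        out = {}
        for pair_id, grp in self.data.groupby("pair_id"):
            if len(grp) == 2:
                a, b = sorted(grp["sample_id"])
                out[pair_id] = (a, b)
        return out

    def incomplete_pair_ids(self) -> list[str]:
        sizes = self.data.groupby("pair_id").size()
        return sorted(sizes.index[sizes == 1])


def read_sample_sheet(path) -> SampleSheet:
    df = _read_tsv(path, dtype={"sample_id": str, "pair_id": str, "sex": str, "chip_side": str})
    if "chip_row" in df.columns:
        df["chip_row"] = pd.to_numeric(df["chip_row"], errors="coerce").astype("Int64")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    _write_tsv(sheet.data[SAMPLE_SHEET_COLUMNS], path)


# ---------------------------------------------------------------------------
# cell counts


@dataclass
class CellCounts:
    """Leukocyte subtype counts per sample (five subtypes; missing allowed)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["sample_id", *CELL_TYPES]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValidationError(f"cell counts missing columns: {missing}")
        _check_unique(self.data["sample_id"], "sample ids")
        if "imputed" not in self.data.columns:
            self.data = self.data.assign(imputed=False)
        self.data["imputed"] = self.data["imputed"].astype(bool)
        counts = self.data[CELL_TYPES].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            if (counts < 0).any():
                raise ValidationError("negative cell count")
        self.data = self.data.reset_index(drop=True)

    def complete_mask(self) -> pd.Series:
        return self.data[CELL_TYPES].notna().all(axis=1).set_axis(self.data["sample_id"])

    def counts_by_sample(self) -> pd.DataFrame:
        return self.data.set_index("sample_id")[CELL_TYPES]


def read_cell_counts(path) -> CellCounts:
    df = _read_tsv(path, dtype={"sample_id": str})
    if "imputed" in df.columns:
        df["imputed"] = df["imputed"].astype(int).astype(bool)
    return CellCounts(df)


def write_cell_counts(counts: CellCounts, path) -> None:
    out = counts.data.copy()
    out["imputed"] = out["imputed"].astype(int)
    _write_tsv(out, path)


# ---------------------------------------------------------------------------
# probe annotation


@dataclass
class Annotation:
    """450K-manifest-like probe annotation (nearest gene, CGI context)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"annotation missing columns: {missing}")
        _check_unique(self.data["probe_id"], "probe ids")
        if (self.data["position"].dropna() < 1).any():
            raise ValidationError("positions are 1-based and must be >= 1")
        bad = ~self.data["cgi_feature"].dropna().isin(CGI_FEATURES)
        if bad.any():
            value = self.data["cgi_feature"].dropna()[bad].iloc[0]
            raise ValidationError(f"unknown CGI feature {value!r}")
        self.data = self.data.reset_index(drop=True)

    def by_probe(self) -> pd.DataFrame:
        return self.data.set_index("probe_id")

    def gene_universe(self) -> set[str]:
        return set(self.data["gene_symbol"].dropna())


def read_annotation(path) -> Annotation:
    df = _read_tsv(
        path,
        dtype={"probe_id": str, "chromosome": str, "gene_symbol": str, "cgi_feature": str},
    )
    df["position"] = pd.to_numeric(df["position"], errors="coerce").astype("Int64")
    df["distance_bp"] = pd.to_numeric(df["distance_bp"], errors="coerce").astype("Int64")
    return Annotation(df)


def write_annotation(annotation: Annotation, path) -> None:
    _write_tsv(annotation.data[ANNOTATION_COLUMNS], path)


# ---------------------------------------------------------------------------
# gene sets


@dataclass
class GeneSetCollection:
    """Named gene-symbol sets (e.g. one pathway database)."""

    sets: dict[str, set[str]]
    source: str = field(default="unknown")

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path, source: str | None = None) -> GeneSetCollection:
    """Read a standard GMT file: name, description, then tab-separated symbols."""
    sets: dict[str, set[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"GMT line {lineno} has {len(fields)} fields (need >= 3)")
            name = fields[0]
            if name in sets:
                raise ParseError(f"duplicate gene-set name {name!r} at line {lineno}")
            sets[name] = {g for g in fields[2:] if g}
    if not sets:
        logger.warning("GMT file %s contains no gene sets", path)
    return GeneSetCollection(sets, source=source or str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as handle:
        for name in sorted(collection.sets):
            members = sorted(collection.sets[name])
            handle.write("\t".join([name, collection.source, *members]) + "\n")
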