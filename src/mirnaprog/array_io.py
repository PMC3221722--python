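"""Readers, writers and validated containers for probe-level array data.

Three tab-delimited interchange formats are supported:

* **probe annotation** — columns ``probe_id``, ``probeset_id``, ``species``
  (``human``/``other``) and ``role`` (``measurement``/``background``);
* **intensity table** — first column ``probe_id``, remaining columns one per
  array, strictly positive linear-scale intensities;
* **sample sheet** — one row per array with the analytical covariates
  (RNA input, ATP-mix dilution, chip lot, extraction and labeling kit) and
  optional clinical outcome (recurrence status, follow-up time, event flag).

Everything downstream consumes the typed containers defined here; no other
module touches files directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

EXTRACTION_KITS = ("HP", "RA")
LABELING_KITS = ("F", "FH")
SPECIES_LEVELS = ("human", "other")
ROLE_LEVELS = ("measurement", "background")

SAMPLE_SHEET_COLUMNS = (
    "array_id",
    "sample_id",
    "rna_input_ng",
    "atp_dilution",
    "lot_id",
    "extraction_kit",
    "labeling_kit",
    "recurrence",
    "time_months",
    "event",
)


class ArrayIOError(ValueError):
    """Raised on malformed or inconsistent input tables."""


@dataclass(frozen=True)
class ProbeAnnotation:
    """Maps probes to probe sets and flags species and probe role.

    Background probes stand alone: their ``probeset_id`` equals their own
    ``probe_id``. Probe sets are unordered bags of probes.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"probe_id", "probeset_id", "species", "role"}
        missing = required - set(t.columns)
        if missing:
            raise ArrayIOError(f"annotation missing columns: {sorted(missing)}")
        if t["probe_id"].duplicated().any():
            dup = t.loc[t["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ArrayIOError(f"duplicate probe_id in annotation: {dup!r}")
        bad_species = set(t["species"]) - set(SPECIES_LEVELS)
        if bad_species:
            raise ArrayIOError(
                f"unknown species {sorted(bad_species)}; allowed {SPECIES_LEVELS}"
            )
        bad_role = set(t["role"]) - set(ROLE_LEVELS)
        if bad_role:
            raise ArrayIOError(
                f"unknown role {sorted(bad_role)}; allowed {ROLE_LEVELS}"
            )
        bg = t[t["role"] == "background"]
        if not (bg["probe_id"] == bg["probeset_id"]).all():
            raise ArrayIOError(
                "background probes must have probeset_id equal to probe_id"
            )
        object.__setattr__(self, "table", t.reset_index(drop=True))

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.table["probe_id"])

    @property
    def measurement_mask(self) -> np.ndarray:
        return (self.table["role"] == "measurement").to_numpy()

    @property
    def background_mask(self) -> np.ndarray:
        return (self.table["role"] == "background").to_numpy()

    @property
    def human_mask(self) -> np.ndarray:
        return (self.table["species"] == "human").to_numpy()

    def measurement_probesets(self, human_only: bool = False) -> pd.Index:
        t = self.table
        sel = t["role"] == "measurement"
        if human_only:
            sel &= t["species"] == "human"
        return pd.Index(pd.unique(t.loc[sel, "probeset_id"]))

    def probeset_of(self) -> pd.Series:
        """probe_id -> probeset_id for measurement probes."""
        t = self.table[self.table["role"] == "measurement"]
        return pd.Series(t["probeset_id"].to_numpy(), index=t["probe_id"].to_numpy())


@dataclass(frozen=True)
class IntensityMatrix:
    """Probe × array matrix of strictly positive linear-scale intensities."""

    values: pd.DataFrame  # index = probe ids, columns = array ids

    def __post_init__(self) -> None:
        v = self.values
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise ArrayIOError(f"duplicate array id: {dup!r}")
        arr = v.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            probe, col = _first_bad(v, ~np.isfinite(arr))
            raise ArrayIOError(f"non-finite intensity at probe {probe!r}, array {col!r}")
        if (arr <= 0).any():
            probe, col = _first_bad(v, arr <= 0)
            raise ArrayIOError(
                f"non-positive intensity at probe {probe!r}, array {col!r}"
            )

    @property
    def array_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_arrays(self, array_ids: Sequence[str]) -> "IntensityMatrix":
        missing = [a for a in array_ids if a not in self.values.columns]
        if missing:
            raise ArrayIOError(f"unknown array ids: {missing}")
        return IntensityMatrix(self.values.loc[:, list(array_ids)])


def _first_bad(df: pd.DataFrame, mask: np.ndarray):
    i, j = np.argwhere(mask)[0]
    return df.index[i], df.columns[j]


@dataclass(frozen=True)
class SampleSheet:
    """Per-array analytical covariates plus optional clinical outcome."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = set(SAMPLE_SHEET_COLUMNS) - set(t.columns)
        if missing:
            raise ArrayIOError(f"sample sheet missing columns: {sorted(missing)}")
        if t["array_id"].duplicated().any():
            dup = t.loc[t["array_id"].duplicated(), "array_id"].iloc[0]
            raise ArrayIOError(f"duplicate array_id: {dup!r}")
        for col, levels in (("extraction_kit", EXTRACTION_KITS), ("labeling_kit", LABELING_KITS)):
            bad = set(t[col].dropna()) - set(levels)
            if bad:
                raise ArrayIOError(
                    f"unknown {col} level(s) {sorted(bad)}; allowed levels are "
                    f"{{{', '.join(levels)}}}"
                )
        for col in ("recurrence", "event"):
            vals = t[col].dropna()
            bad = set(vals) - {0, 1, 0.0, 1.0}
            if bad:
                raise ArrayIOError(f"{col} must be 0/1/NA, got {sorted(bad)}")
        tm = t["time_months"]
        if (tm.dropna() < 0).any():
            raise ArrayIOError("time_months must be >= 0")
        ev1 = t["event"] == 1
        if (ev1 & tm.isna()).any():
            aid = t.loc[ev1 & tm.isna(), "array_id"].iloc[0]
            raise ArrayIOError(f"event=1 without time_months for array {aid!r}")
        object.__setattr__(self, "table", t.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.table)

    @property
    def array_ids(self) -> list[str]:
        return list(self.table["array_id"])

    def row(self, array_id: str) -> pd.Series:
        sel = self.table[self.table["array_id"] == array_id]
        if sel.empty:
            raise ArrayIOError(f"unknown array_id: {array_id!r}")
        return sel.iloc[0]

    def subset(self, array_ids: Sequence[str]) -> "SampleSheet":
        idx = self.table["array_id"].isin(array_ids)
        return SampleSheet(self.table[idx])


@dataclass(frozen=True)
class ExpressionMatrix:
    """Probe-set × array expression with its summarization mode attached.

    ``mode`` is either ``avg_diff_raw`` (linear-scale mean of perfect-match
    probes, no background correction) or ``rma_log2`` (quantile-normalized,
    median-polished log2 indexes). ``feature_subset`` records which probe
    sets were kept (``human`` or ``all``).
    """

    values: pd.DataFrame  # index = probeset ids, columns = array ids
    mode: str
    feature_subset: str = "all"

    def __post_init__(self) -> None:
        if self.mode not in ("avg_diff_raw", "rma_log2"):
            raise ArrayIOError(f"unknown expression mode: {self.mode!r}")
        if self.values.index.duplicated().any():
            raise ArrayIOError("duplicate probeset ids in expression matrix")

    @property
    def array_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)


# ---------------------------------------------------------------------------
# Readers / writers (TSV, UTF-8, '.' decimal; "NA" or empty cell = missing)
# ---------------------------------------------------------------------------

_NA_TOKENS = ["NA", ""]


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    t = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return ProbeAnnotation(t)


def write_probe_annotation(annotation: ProbeAnnotation, path: str | Path) -> None:
    annotation.table.to_csv(path, sep="\t", index=False)


def read_intensity_table(path: str | Path, annotation: ProbeAnnotation) -> IntensityMatrix:
    """Read a probe × array TSV and normalize probe order to the annotation.

    Every annotation probe must be present exactly once; extra or missing
    probes, duplicates, and non-numeric or non-positive cells are rejected
    with the offending probe/array named.
    """
    t = pd.read_csv(path, sep="\t", index_col=0)
    if t.index.duplicated().any():
        dup = t.index[t.index.duplicated()][0]
        raise ArrayIOError(f"duplicate probe_id in intensity table: {dup!r}")
    want = annotation.probe_ids
    extra = t.index.difference(want)
    if len(extra):
        raise ArrayIOError(f"probe {extra[0]!r} not present in annotation")
    missing = want.difference(t.index)
    if len(missing):
        raise ArrayIOError(f"probe {missing[0]!r} missing from intensity table")
    t = t.reindex(want)
    for col in t.columns:
        if not pd.api.types.is_numeric_dtype(t[col]):
            bad = t.index[pd.to_numeric(t[col], errors="coerce").isna()][0]
            raise ArrayIOError(f"non-numeric intensity at probe {bad!r}, array {col!r}")
    arr = t.to_numpy(dtype=float)
    if (arr <= 0).any() or not np.isfinite(arr).all():
        probe, col = _first_bad(t, (arr <= 0) | ~np.isfinite(arr))
        raise ArrayIOError(f"non-positive intensity at probe {probe!r}, array {col!r}")
    return IntensityMatrix(t)


def write_intensity_table(matrix: IntensityMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    t = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=_NA_TOKENS
    )
    missing = set(SAMPLE_SHEET_COLUMNS) - set(t.columns)
    if missing:
        raise ArrayIOError(f"sample sheet missing columns: {sorted(missing)}")
    for col in ("rna_input_ng", "time_months", "recurrence", "event"):
        t[col] = pd.to_numeric(t[col], errors="raise").astype(float)
    return SampleSheet(t)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_expression(expression: ExpressionMatrix, path: str | Path) -> None:
    out = expression.values.copy()
    out.index.name = f"probeset_id[{expression.mode}:{expression.feature_subset}]"
    out.to_csv(path, sep="\t", float_format="%.10g")
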