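"""Probe-set summarization in the two modes the workflow uses.

``avg_diff_raw`` is the classifier's default input: the arithmetic mean of
each probe set's perfect-match probe intensities on the linear scale, with
no background correction and no cross-array normalization (this array has
no mismatch probes, so "average difference" reduces to the mean of the
perfect-match probes). ``rma_like`` is the correlation/PCA default: log2 →
probe-level quantile normalization across arrays → per-probe-set
median-polish summarization, yielding log2 expression indexes. The RMA
convolution background step is intentionally omitted; the pipeline runs
background-free throughout.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .array_io import ExpressionMatrix, IntensityMatrix, ProbeAnnotation

MEDIAN_POLISH_TOL = 1e-6
MEDIAN_POLISH_MAX_ITER = 20


class NormalizationError(ValueError):
    pass


def _grouped(intensities: IntensityMatrix, annotation: ProbeAnnotation, human_only: bool):
    t = annotation.table
    sel = (t["role"] == "measurement").to_numpy()
    if human_only:
        sel &= (t["species"] == "human").to_numpy()
    probes = t.loc[sel, "probe_id"].to_numpy()
    sets = t.loc[sel, "probeset_id"].to_numpy()
    values = intensities.values.loc[probes]
    set_order = pd.Index(pd.unique(sets))
    for sid in set_order:
        if (sets == sid).sum() == 0:  # pragma: no cover - unreachable by construction
            raise NormalizationError(f"empty probe set: {sid!r}")
    return values, sets, set_order


def avg_diff_raw(
    intensities: IntensityMatrix,
    annotation: ProbeAnnotation,
    human_only: bool = True,
) -> ExpressionMatrix:
    """Linear-scale mean of each probe set's measurement probes, per array."""
    values, sets, set_order = _grouped(intensities, annotation, human_only)
    summarized = values.groupby(sets, sort=False).mean().loc[set_order]
    return ExpressionMatrix(
        summarized, mode="avg_diff_raw", feature_subset="human" if human_only else "all"
    )


def quantile_normalize(log2_values: np.ndarray) -> np.ndarray:
    """Classic quantile normalization across columns (arrays).

    Every array is mapped onto the mean sorted profile; tied values within
    an array receive the mean of the reference quantiles they span.
    """
    n_probes, n_arrays = log2_values.shape
    order = np.argsort(log2_values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(log2_values, order, axis=0)
    reference = sorted_vals.mean(axis=1)
    out = np.empty_like(log2_values)
    for j in range(n_arrays):
        xs = sorted_vals[:, j]
        mapped = reference.copy()
        bounds = np.flatnonzero(np.diff(xs) != 0) + 1
        starts = np.concatenate([[0], bounds])
        ends = np.concatenate([bounds, [n_probes]])
        for gi in np.flatnonzero(ends - starts > 1):
            s, e = starts[gi], ends[gi]
            mapped[s:e] = reference[s:e].mean()
        out[order[:, j], j] = mapped
    return out


def median_polish(matrix: np.ndarray) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Additive decomposition overall + row + column + residual.

    Alternating row/column median sweeps until residual medians fall below
    ``MEDIAN_POLISH_TOL`` or ``MEDIAN_POLISH_MAX_ITER`` iterations.
    Returns (overall, row_effects, col_effects, residuals).
    """
    resid = np.asarray(matrix, dtype=float).copy()
    nrow, ncol = resid.shape
    overall = 0.0
    row_eff = np.zeros(nrow)
    col_eff = np.zeros(ncol)
    for _ in range(MEDIAN_POLISH_MAX_ITER):
        rmed = np.median(resid, axis=1)
        resid -= rmed[:, None]
        row_eff += rmed
        cmed_of_rows = np.median(row_eff)
        row_eff -= cmed_of_rows
        overall += cmed_of_rows

        cmed = np.median(resid, axis=0)
        resid -= cmed[None, :]
        col_eff += cmed
        rmed_of_cols = np.median(col_eff)
        col_eff -= rmed_of_cols
        overall += rmed_of_cols
        if (
            np.abs(np.median(resid, axis=1)).max() <= MEDIAN_POLISH_TOL
            and np.abs(np.median(resid, axis=0)).max() <= MEDIAN_POLISH_TOL
        ):
            break
    return overall, row_eff, col_eff, resid


def rma_like(
    intensities: IntensityMatrix,
    annotation: ProbeAnnotation,
    human_only: bool = True,
) -> ExpressionMatrix:
    """Quantile-normalized, median-polished log2 expression indexes.

    The expression index of array *j* for a probe set is the fitted overall
    effect plus that array's column effect. A single array (quantile step
    undefined) falls back to log2 + median polish with a warning.
    """
    values, sets, set_order = _grouped(intensities, annotation, human_only)
    arr = np.log2(values.to_numpy(dtype=float))
    if arr.shape[1] >= 2:
        arr = quantile_normalize(arr)
    else:
        warnings.warn(
            "single array: quantile normalization undefined, using log2 + median polish",
            stacklevel=2,
        )
    out = np.empty((len(set_order), arr.shape[1]))
    set_pos = {sid: i for i, sid in enumerate(set_order)}
    for sid, block in pd.Series(np.arange(len(sets))).groupby(sets, sort=False):
        rows = arr[block.to_numpy(), :]
        overall, _row_eff, col_eff, _resid = median_polish(rows)
        out[set_pos[sid], :] = overall + col_eff
    summarized = pd.DataFrame(out, index=set_order, columns=values.columns)
    return ExpressionMatrix(
        summarized, mode="rma_log2", feature_subset="human" if human_only else "all"
    )
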