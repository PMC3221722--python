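"""Per-array QC summaries, detection calls, self-self correlations and the
regression/ANOVA machinery used to compare analytical conditions.

Detection dialect: a probe is "detected" when its one-sided empirical p
against the array's background-probe distribution, p = (1 + #{background >=
probe}) / (1 + #background), is <= alpha; a probe set is detected when a
one-sided Wilcoxon rank-sum of its probes against the background probes
gives p <= alpha. The default alpha of 0.06 follows the conventional
default of the vendor QC tooling for this array family.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .array_io import ArrayIOError, IntensityMatrix, ProbeAnnotation, SampleSheet

DEFAULT_ALPHA = 0.06


class QCError(ValueError):
    pass


@dataclass(frozen=True)
class QCReport:
    """One row per array: linear-scale intensity means and detection counts."""

    table: pd.DataFrame  # columns: array_id, mean_intensity, mean_background,
    #          n_detected_probes, n_detected_probesets
    detection_alpha: float


@dataclass(frozen=True)
class RegressionResult:
    """Ordinary least-squares slope with its inference summary."""

    slope: float
    se: float
    t_stat: float
    p_value: float
    r_squared: float
    n: int
    intercept: float = float("nan")

    def ci95(self) -> tuple[float, float]:
        tcrit = stats.t.ppf(0.975, self.n - 2)
        return self.slope - tcrit * self.se, self.slope + tcrit * self.se


@dataclass(frozen=True)
class GroupTestResult:
    statistic: float
    df: tuple
    p_value: float
    group_means: dict
    group_ses: dict
    kind: str  # "t" or "anova"


@dataclass(frozen=True)
class CorrelationTable:
    """Symmetric array × array Pearson r on log2 probe intensities."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.table.to_numpy()
        if not np.allclose(v, v.T, equal_nan=True):
            raise QCError("correlation table must be symmetric")

    def pair(self, a: str, b: str) -> float:
        return float(self.table.loc[a, b])


def _detection_pvalues_probes(meas: np.ndarray, background: np.ndarray) -> np.ndarray:
    """One-sided empirical p per probe vs the background distribution."""
    bg_sorted = np.sort(background)
    # #{background >= x} via position of x in the sorted background
    n_ge = len(bg_sorted) - np.searchsorted(bg_sorted, meas, side="left")
    return (1.0 + n_ge) / (1.0 + len(bg_sorted))


def _detection_pvalues_sets(
    meas: np.ndarray, set_index: np.ndarray, n_sets: int, background: np.ndarray
) -> np.ndarray:
    """One-sided Wilcoxon rank-sum p per probe set vs the background probes.

    Exact enumeration when the combined sample is small and tie-free;
    mid-rank normal approximation with tie correction otherwise.
    """
    sizes = np.bincount(set_index, minlength=n_sets)
    pvals = np.empty(n_sets)
    # group probes by set size so each homogeneous block is one vectorized call
    for size in np.unique(sizes):
        sel_sets = np.flatnonzero(sizes == size)
        rows = meas[np.isin(set_index, sel_sets)].reshape(len(sel_sets), size)
        small = size + len(background) <= 20
        tie_free = len(np.unique(np.concatenate([rows.ravel(), background]))) == (
            rows.size + len(background)
        )
        method = "exact" if small and tie_free else "asymptotic"
        bg = np.broadcast_to(background, (len(sel_sets), len(background)))
        res = stats.mannwhitneyu(rows, bg, alternative="greater", method=method, axis=-1)
        pvals[sel_sets] = np.atleast_1d(res.pvalue)
    return pvals


def qc_report(
    intensities: IntensityMatrix,
    annotation: ProbeAnnotation,
    alpha: float = DEFAULT_ALPHA,
) -> QCReport:
    """Compute the four per-array QC metrics.

    Means are arithmetic means on the linear scale over measurement and
    background probes respectively; detection follows the module-level
    dialect. Counts are monotone non-increasing as ``alpha`` decreases, and
    at alpha = 1 every probe is detected.
    """
    if not 0 < alpha <= 1:
        raise QCError(f"alpha must be in (0, 1], got {alpha}")
    meas_mask = annotation.measurement_mask
    bg_mask = annotation.background_mask
    if not bg_mask.any():
        raise QCError("no background probes in annotation: detection unavailable")
    set_ids = annotation.table.loc[meas_mask, "probeset_id"].to_numpy()
    uniq_sets, set_index = np.unique(set_ids, return_inverse=True)

    rows = []
    for array_id in intensities.array_ids:
        col = intensities.values[array_id].to_numpy(dtype=float)
        meas = col[meas_mask]
        bg = col[bg_mask]
        p_probe = _detection_pvalues_probes(meas, bg)
        p_set = _detection_pvalues_sets(meas, set_index, len(uniq_sets), bg)
        rows.append(
            {
                "array_id": array_id,
                "mean_intensity": float(meas.mean()),
                "mean_background": float(bg.mean()),
                "n_detected_probes": int((p_probe <= alpha).sum()),
                "n_detected_probesets": int((p_set <= alpha).sum()),
            }
        )
    return QCReport(pd.DataFrame(rows), alpha)


def self_self_correlation(
    intensities: IntensityMatrix,
    annotation: ProbeAnnotation,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> CorrelationTable:
    """Pearson r over log2 intensities of all measurement probes.

    With ``pairs=None`` every pairwise combination is filled in; otherwise
    only the requested pairs (plus the unit diagonal) are computed and the
    rest left as NaN.
    """
    ids = intensities.array_ids
    if len(ids) < 2:
        raise QCError("need at least 2 arrays for self-self correlations")
    meas = annotation.measurement_mask
    log2 = np.log2(intensities.values.to_numpy(dtype=float)[meas, :])
    spans = np.ptp(log2, axis=0)
    if (spans == 0).any():
        bad = ids[int(np.flatnonzero(spans == 0)[0])]
        raise QCError(f"array {bad!r} has constant log2 intensities; correlation undefined")
    out = pd.DataFrame(np.nan, index=ids, columns=ids)
    np.fill_diagonal(out.values, 1.0)
    if pairs is None:
        pairs = list(combinations(ids, 2))
    col = {a: i for i, a in enumerate(ids)}
    for a, b in pairs:
        r = float(np.corrcoef(log2[:, col[a]], log2[:, col[b]])[0, 1])
        out.loc[a, b] = r
        out.loc[b, a] = r
    return CorrelationTable(out)


def regress(response: Sequence[float], covariate: Sequence[float]) -> RegressionResult:
    """Simple OLS of response on covariate with t inference (df = n − 2)."""
    y = np.asarray(response, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise QCError("response and covariate must be equal-length vectors")
    n = len(y)
    if n < 3:
        raise QCError(f"need n >= 3 observations, got {n}")
    if np.ptp(x) == 0:
        raise QCError("constant covariate: slope undefined")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        se=float(res.stderr),
        t_stat=float(res.slope / res.stderr) if res.stderr > 0 else float("inf"),
        p_value=float(res.pvalue),
        r_squared=float(res.rvalue**2),
        n=n,
        intercept=float(res.intercept),
    )


def compare_groups(
    values: Sequence[float],
    groups: Sequence,
    equal_var: bool = True,
) -> GroupTestResult:
    """Two groups → pooled-variance t-test; more → one-way fixed-effects ANOVA.

    ``equal_var=False`` switches the two-group case to the Welch variant.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    levels = pd.unique(g)
    if len(levels) < 2:
        raise QCError("need at least 2 groups")
    split = [y[g == lv] for lv in levels]
    for lv, arr in zip(levels, split):
        if len(arr) < 2:
            raise QCError(f"group {lv!r} has n < 2")
    means = {lv: float(arr.mean()) for lv, arr in zip(levels, split)}
    ses = {lv: float(arr.std(ddof=1) / np.sqrt(len(arr))) for lv, arr in zip(levels, split)}
    if len(levels) == 2:
        t, p = stats.ttest_ind(split[0], split[1], equal_var=equal_var)
        if equal_var:
            df: tuple = (len(y) - 2,)
        else:
            df = (_welch_df(split[0], split[1]),)
        # degenerate all-equal data: report the null outcome rather than nan
        if np.isnan(t):
            t, p = 0.0, 1.0
        return GroupTestResult(float(t), df, float(p), means, ses, "t")
    f, p = stats.f_oneway(*split)
    if np.isnan(f):
        f, p = 0.0, 1.0
    df = (len(levels) - 1, len(y) - len(levels))
    return GroupTestResult(float(f), df, float(p), means, ses, "anova")


def _welch_df(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    return float((va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1)))


def _parse_dilution(s: str) -> float:
    num, den = str(s).split(":")
    return float(den) / float(num)


def correlation_vs_input_deviation(
    intensities: IntensityMatrix,
    samples: SampleSheet,
    annotation: ProbeAnnotation,
    covariate: str = "rna_input_ng",
    deviation: str = "log-ratio",
) -> RegressionResult:
    """Regress pairwise self-self correlation on the pair's covariate deviation.

    All arrays passed in are treated as replicates of one sample. For
    ``covariate="rna_input_ng"`` the deviation is |log2(input_A/input_B)|
    (``deviation="log-ratio"``, the default: halving and doubling are
    equivalent perturbations) or |input_A − input_B| in ng
    (``deviation="abs-ng"``). ``covariate="atp_dilution"`` uses the log2
    ratio of dilution factors; a numeric covariate column works the same
    way. A significantly negative slope reproduces the input-ratio decay of
    self-self correlations; null conditions give a slope whose CI covers 0.
    """
    if deviation not in ("log-ratio", "abs-ng"):
        raise QCError(f"unknown deviation measure: {deviation!r}")
    ids = intensities.array_ids
    sheet = samples.table.set_index("array_id").loc[ids]
    categorical = False
    if covariate == "atp_dilution":
        xvals = sheet["atp_dilution"].map(_parse_dilution).to_numpy(dtype=float)
    elif covariate == "lot_id":
        # categorical condition: deviation is a same/different-lot indicator
        categorical = True
        xvals = sheet["lot_id"].to_numpy()
    else:
        xvals = pd.to_numeric(sheet[covariate]).to_numpy(dtype=float)
    if len(pd.unique(xvals)) < 2:
        raise QCError(f"covariate {covariate!r} is constant across arrays")
    corr = self_self_correlation(intensities, annotation)
    rs, devs = [], []
    for (i, a), (j, b) in combinations(enumerate(ids), 2):
        rs.append(corr.pair(a, b))
        if categorical:
            devs.append(0.0 if xvals[i] == xvals[j] else 1.0)
        elif deviation == "log-ratio":
            devs.append(abs(np.log2(xvals[i] / xvals[j])))
        else:
            devs.append(abs(xvals[i] - xvals[j]))
    if len(rs) < 3:
        raise QCError("need at least 3 array pairs")
    return regress(rs, devs)
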