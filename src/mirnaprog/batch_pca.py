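"""Principal component analysis over samples and between-kit variance.

Used to quantify how much of the leading-component variance an analytical
grouping (extraction kit, labeling kit, lot ...) explains — the numeric
counterpart of the kit-separation score plots. Features are centered across
samples (no unit-variance scaling by default) and decomposed by SVD with a
deterministic sign convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .array_io import ExpressionMatrix, SampleSheet


class PCAError(ValueError):
    pass


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame        # samples × components
    loadings: pd.DataFrame      # features × components
    variance_explained: np.ndarray
    feature_subset: str


@dataclass(frozen=True)
class GroupVarianceResult:
    component: int
    eta_squared: float
    grouping: str


def pca(
    expression: ExpressionMatrix,
    features: Sequence[str] | None = None,
    n_components: int | None = None,
    scale: bool = False,
) -> PCAResult:
    """Centered (optionally scaled) PCA of arrays over the chosen features.

    Sign convention: for each component the loading entry of largest
    magnitude is made positive, so results are reproducible across runs.
    """
    vals = expression.values
    if features is not None:
        missing = [f for f in features if f not in vals.index]
        if missing:
            raise PCAError(f"features not in expression matrix: {missing[:5]}")
        vals = vals.loc[list(features)]
    X = vals.to_numpy(dtype=float).T  # samples × features
    n_samples, n_features = X.shape
    if n_samples < 3:
        raise PCAError(f"need at least 3 samples, got {n_samples}")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_samples, n_features) if n_components is None else n_components
    k = min(k, len(S))
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    # deterministic sign: largest-|loading| entry positive per component
    for c in range(k):
        pivot = np.argmax(np.abs(Vt[c]))
        if Vt[c, pivot] < 0:
            Vt[c] *= -1.0
            U[:, c] *= -1.0
    scores = U * S
    total_ss = (Xc**2).sum()
    var_exp = (S**2) / total_ss if total_ss > 0 else np.zeros(k)
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=vals.columns, columns=comp_names),
        loadings=pd.DataFrame(Vt.T, index=vals.index, columns=comp_names),
        variance_explained=var_exp,
        feature_subset=expression.feature_subset,
    )


def between_group_variance(
    pca_result: PCAResult,
    grouping: Sequence,
    component: int = 1,
    grouping_name: str = "group",
) -> GroupVarianceResult:
    """eta² = between-group / total sum of squares of one component's scores."""
    scores = pca_result.scores[f"PC{component}"].to_numpy()
    g = np.asarray(grouping)
    if len(g) != len(scores):
        raise PCAError("grouping length must match number of samples")
    levels = pd.unique(g)
    if len(levels) < 2:
        raise PCAError("need at least 2 groups")
    grand = scores.mean()
    ss_total = ((scores - grand) ** 2).sum()
    ss_between = sum(
        (g == lv).sum() * (scores[g == lv].mean() - grand) ** 2 for lv in levels
    )
    eta2 = float(ss_between / ss_total) if ss_total > 0 else 0.0
    return GroupVarianceResult(component, eta2, grouping_name)


def paired_kit_analysis(
    expression: ExpressionMatrix,
    samples: SampleSheet,
    kit_field: str,
    n_components: int = 2,
) -> dict:
    """Within-sample/between-kit vs between-sample/within-kit distance.

    Every sample must be measured under both kit levels. Distances are
    Euclidean in the leading-component score space. A ratio above 1 means a
    sample re-processed with the other kit lands farther from itself than
    two different samples processed alike — the signature of a dominating
    batch effect.
    """
    t = samples.table
    if kit_field not in t.columns:
        raise PCAError(f"unknown kit field: {kit_field!r}")
    levels = pd.unique(t[kit_field])
    if len(levels) != 2:
        raise PCAError(f"kit field {kit_field!r} must have exactly 2 levels")
    by_sample = t.groupby("sample_id")[kit_field].nunique()
    unpaired = by_sample[by_sample < 2]
    if len(unpaired):
        raise PCAError(f"samples not present under both kits: {list(unpaired.index)}")

    res = pca(expression, n_components=n_components)
    scores = res.scores.loc[t["array_id"]].to_numpy()
    sample_ids = t["sample_id"].to_numpy()
    kits = t[kit_field].to_numpy()

    within_sample = []
    for sid in pd.unique(sample_ids):
        idx = np.flatnonzero(sample_ids == sid)
        for i, j in combinations(idx, 2):
            if kits[i] != kits[j]:
                within_sample.append(np.linalg.norm(scores[i] - scores[j]))
    between_sample = []
    for lv in levels:
        idx = np.flatnonzero(kits == lv)
        for i, j in combinations(idx, 2):
            if sample_ids[i] != sample_ids[j]:
                between_sample.append(np.linalg.norm(scores[i] - scores[j]))
    mean_within = float(np.mean(within_sample))
    mean_between = float(np.mean(between_sample))
    if mean_within < 1e-12:  # identical duplicate arrays across "kits"
        mean_within, ratio = 0.0, 0.0
    elif mean_between > 0:
        ratio = mean_within / mean_between
    else:
        ratio = float("inf")
    return {
        "kit_field": kit_field,
        "mean_within_sample_between_kit": mean_within,
        "mean_between_sample_within_kit": mean_between,
        "ratio": float(ratio),
        "pca": res,
    }
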