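"""t-statistic feature ranking + linear SVM prognosticator with two
cross-validation schemes.

The classifier predicts recurrence (call 1) vs no recurrence (call 0) from
probe-set expression. Features are ranked by the pooled-variance two-sample
t statistic between outcome classes; a linear-kernel SVM (default C = 1) is
trained on the top-ranked features after z-scoring each feature with the
*training* mean and standard deviation. Two evaluation schemes are
provided:

* **Monte-Carlo**: repeatedly hold out a random third of the cohort, run a
  leave-one-out loop on the remaining two-thirds recording each fold's
  top-k features, train the SVM on the k most *frequent* features (the
  feature-frequency consensus), and score the held-out third. The spread
  of replicate accuracies gives a normal-approximation 95% CI on the mean.
* **Nested LOOCV**: an outer leave-one-out loop holds out the test sample;
  an inner leave-one-out loop on the remaining N−1 samples measures
  accuracy for every candidate signature size k, and the best (smallest on
  ties) k classifies the outer sample. The modal k across outer folds is
  the final signature size, refit on all samples.

Both schemes keep every ranking and every standardization strictly inside
the fold's training portion, so accuracy estimates carry no selection bias
— under permuted labels they sit at chance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from .array_io import ExpressionMatrix

DEFAULT_K_GRID = (5, 10, 15, 20, 25, 30, 40, 50)
DEFAULT_C = 1.0
MODEL_SCHEMA_VERSION = 1


class ClassifierError(ValueError):
    pass


# ---------------------------------------------------------------------------
# t ranking
# ---------------------------------------------------------------------------

def _t_stats(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per feature (class 0 minus class 1).

    Tolerates single-member classes (their sum of squares is zero; the
    pooled df shrinks accordingly) so it stays total inside tiny
    cross-validation folds; an *empty* class is degenerate and rejected.
    Zero pooled variance — including the df = 0 case of a 1-vs-1 fold — is
    resolved as |t| = +inf when the class means differ, 0 when equal.
    """
    m0 = y == 0
    m1 = y == 1
    n0, n1 = int(m0.sum()), int(m1.sum())
    if n0 < 1 or n1 < 1:
        raise ClassifierError(f"class degenerate: sizes {n0} and {n1}")
    X0, X1 = X[m0], X[m1]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    ss0 = ((X0 - mu0) ** 2).sum(axis=0)
    ss1 = ((X1 - mu1) ** 2).sum(axis=0)
    df = n0 + n1 - 2
    pooled = (ss0 + ss1) / df if df > 0 else np.zeros_like(ss0)
    se = np.sqrt(pooled * (1.0 / n0 + 1.0 / n1))
    diff = mu0 - mu1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    zero = se == 0
    if zero.any():
        dz = diff[zero]
        t[zero] = np.where(dz != 0, np.where(dz > 0, np.inf, -np.inf), 0.0)
    return t


def _rank_order(t: np.ndarray) -> np.ndarray:
    """Indices ordered by decreasing |t|, ties broken by feature position
    (feature ids are kept in a fixed order, so position order == id order)."""
    return np.lexsort((np.arange(len(t)), -np.abs(t)))


def t_rank(expression: ExpressionMatrix, labels: Sequence[int]) -> pd.DataFrame:
    """Rank all features by |t| between the two outcome classes.

    Returns a DataFrame (feature_id, t) in ranking order.
    """
    y = np.asarray(labels, dtype=int)
    X = expression.values.to_numpy(dtype=float).T
    if len(y) != X.shape[0]:
        raise ClassifierError("labels length must match number of arrays")
    if min(int((y == 0).sum()), int((y == 1).sum())) < 2:
        raise ClassifierError("both classes need n >= 2 for ranking")
    t = _t_stats(X, y)
    order = _rank_order(t)
    ids = np.asarray(expression.feature_ids)
    return pd.DataFrame({"feature_id": ids[order], "t": t[order]})


# ---------------------------------------------------------------------------
# SVM model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrognosticModel:
    """A frozen, self-contained linear decision rule.

    Prediction is sign(w·z + b) with z the feature vector standardized by
    the stored training means/sds; a sample exactly on the boundary is
    called 0 ("no recurrence").
    """

    features: tuple
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    bias: float
    C: float
    mode: str
    training_accuracy: float

    def decision_values(self, expression: ExpressionMatrix) -> np.ndarray:
        vals = expression.values
        missing = [f for f in self.features if f not in vals.index]
        if missing:
            raise ClassifierError(f"model features missing from expression: {missing}")
        X = vals.loc[list(self.features)].to_numpy(dtype=float).T
        Z = (X - self.means) / self.sds
        return Z @ self.weights + self.bias

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "schema_version": MODEL_SCHEMA_VERSION,
            "features": list(self.features),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "C": self.C,
            "mode": self.mode,
            "training_accuracy": self.training_accuracy,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PrognosticModel":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        if d.get("schema_version") != MODEL_SCHEMA_VERSION:
            raise ClassifierError(
                f"unsupported model schema version: {d.get('schema_version')}"
            )
        return cls(
            features=tuple(d["features"]),
            means=np.asarray(d["means"], dtype=float),
            sds=np.asarray(d["sds"], dtype=float),
            weights=np.asarray(d["weights"], dtype=float),
            bias=float(d["bias"]),
            C=float(d["C"]),
            mode=d["mode"],
            training_accuracy=float(d["training_accuracy"]),
        )


try:  # low-level libsvm entry point: same solver as SVC without the
    # per-call validation overhead (the CV loops fit tens of thousands of
    # tiny models); equivalence with SVC is asserted in the test suite
    from sklearn.svm import _libsvm

    _libsvm.set_verbosity_wrap(0)
except ImportError:  # pragma: no cover
    _libsvm = None


def _fit_linear_svm(Z: np.ndarray, y: np.ndarray, C: float) -> tuple[np.ndarray, float]:
    """Fit a binary linear-kernel C-SVM; returns (weights, bias) with the
    sklearn convention that positive decision values mean class 1."""
    if _libsvm is not None:
        Z64 = np.ascontiguousarray(Z, dtype=np.float64)
        y64 = np.asarray(y, dtype=np.float64)
        out = _libsvm.fit(Z64, y64, svm_type=0, kernel="linear", C=float(C))
        sv, sv_coef, intercept = out[1], out[3], out[4]
        return -(sv_coef @ sv).ravel(), -float(intercept[0])
    svc = SVC(kernel="linear", C=C)  # pragma: no cover - fallback path
    svc.fit(Z, y)
    return svc.coef_[0].copy(), float(svc.intercept_[0])


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if (sds == 0).any():
        raise ClassifierError(
            f"feature with zero training variance at column {int(np.flatnonzero(sds == 0)[0])}"
        )
    return means, sds


def train(
    expression: ExpressionMatrix,
    labels: Sequence[int],
    features: Sequence[str],
    C: float = DEFAULT_C,
) -> PrognosticModel:
    """Z-score the chosen features on the training data and fit the SVM."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ClassifierError("training labels contain a single class")
    vals = expression.values
    missing = [f for f in features if f not in vals.index]
    if missing:
        raise ClassifierError(f"features not in expression matrix: {missing}")
    X = vals.loc[list(features)].to_numpy(dtype=float).T
    means, sds = _standardize_fit(X)
    Z = (X - means) / sds
    w, b = _fit_linear_svm(Z, y, C)
    calls = (Z @ w + b > 0).astype(int)
    model = PrognosticModel(
        features=tuple(features),
        means=means,
        sds=sds,
        weights=w,
        bias=b,
        C=C,
        mode=expression.mode,
        training_accuracy=float((calls == y).mean()),
    )
    return model


def predict(model: PrognosticModel, expression: ExpressionMatrix) -> np.ndarray:
    """Deterministic 0/1 calls; decision value > 0 → 1 (boundary → 0)."""
    return (model.decision_values(expression) > 0).astype(int)


# ---------------------------------------------------------------------------
# Feature-frequency consensus (inner LOOCV of the Monte-Carlo scheme)
# ---------------------------------------------------------------------------

def _consensus_from_array(
    X: np.ndarray, y: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(frequency, mean |t| when chosen, consensus indices) for top-k ranking
    repeated across leave-one-out folds."""
    n, f = X.shape
    if n < 3:
        raise ClassifierError(f"need n >= 3 samples for the LOOCV loop, got {n}")
    if not 1 <= k <= f:
        raise ClassifierError(f"k must be in [1, {f}], got {k}")
    freq = np.zeros(f, dtype=int)
    abs_t_sum = np.zeros(f)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        t = _t_stats(X[mask], y[mask])
        top = _rank_order(t)[:k]
        freq[top] += 1
        abs_t_sum[top] += np.abs(t[top])
        mask[i] = True
    with np.errstate(invalid="ignore"):
        mean_abs_t = np.where(freq > 0, abs_t_sum / np.maximum(freq, 1), 0.0)
    inf_chosen = np.isinf(abs_t_sum) & (freq > 0)
    mean_abs_t[inf_chosen] = np.inf
    # consensus: most frequent; ties by higher mean |t|, then feature order
    order = np.lexsort((np.arange(f), -np.nan_to_num(mean_abs_t, posinf=np.finfo(float).max), -freq))
    return freq, mean_abs_t, order[:k]


def inner_loocv_consensus(
    expression: ExpressionMatrix, labels: Sequence[int], k: int
) -> tuple[pd.DataFrame, list[str]]:
    """Feature-frequency table across leave-one-out folds and the top-k
    consensus features."""
    y = np.asarray(labels, dtype=int)
    X = expression.values.to_numpy(dtype=float).T
    freq, mean_abs_t, consensus = _consensus_from_array(X, y, k)
    ids = np.asarray(expression.feature_ids)
    table = pd.DataFrame(
        {"feature_id": ids, "frequency": freq, "mean_abs_t": mean_abs_t}
    )
    table = table.sort_values(
        ["frequency", "mean_abs_t", "feature_id"], ascending=[False, False, True]
    ).reset_index(drop=True)
    return table, [str(s) for s in ids[consensus]]


# ---------------------------------------------------------------------------
# Monte-Carlo two-thirds / one-third evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonteCarloResult:
    R: int
    accuracies: np.ndarray
    mean_accuracy: float
    ci_low: float
    ci_high: float
    k_fixed: int
    seed: int
    n_resampled_splits: int = 0

    def to_dict(self) -> dict:
        return {
            "R": self.R,
            "mean_accuracy": self.mean_accuracy,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "k_fixed": self.k_fixed,
            "seed": self.seed,
            "n_resampled_splits": self.n_resampled_splits,
            "accuracies": self.accuracies.tolist(),
        }


def monte_carlo_evaluate(
    expression: ExpressionMatrix,
    labels: Sequence[int],
    R: int = 1000,
    k: int = 30,
    seed: int = 0,
    C: float = DEFAULT_C,
    stratified: bool = False,
) -> MonteCarloResult:
    """Repeated random 2/3-train / 1/3-test evaluation with consensus features.

    Each replicate draws a uniform random two-thirds training split (a split
    leaving a class unrepresented in training is redrawn and counted),
    selects the k feature-frequency-consensus features from a leave-one-out
    loop inside the training set, trains the SVM on those, and scores the
    held-out third. The 95% CI is mean ± 1.96·sd/√R over replicates.
    """
    if R < 2:
        raise ClassifierError(f"R must be >= 2, got {R}")
    y = np.asarray(labels, dtype=int)
    X = expression.values.to_numpy(dtype=float).T
    n = len(y)
    if n < 9:
        raise ClassifierError(f"need n >= 9 samples, got {n}")
    n_train = int(np.ceil(2 * n / 3))
    rng = np.random.default_rng(seed)
    accs = np.empty(R)
    n_resampled = 0
    for r in range(R):
        while True:
            if stratified:
                tr = []
                for cls in (0, 1):
                    idx = np.flatnonzero(y == cls)
                    take = int(np.ceil(2 * len(idx) / 3))
                    tr.append(rng.permutation(idx)[:take])
                train_idx = np.sort(np.concatenate(tr))
            else:
                train_idx = np.sort(rng.permutation(n)[:n_train])
            y_tr = y[train_idx]
            if len(np.unique(y_tr)) == 2 and np.bincount(y_tr, minlength=2).min() >= 2:
                break
            n_resampled += 1
        test_idx = np.setdiff1d(np.arange(n), train_idx)
        X_tr = X[train_idx]
        _, _, consensus = _consensus_from_array(X_tr, y_tr, k)
        means, sds = _standardize_fit(X_tr[:, consensus])
        Z_tr = (X_tr[:, consensus] - means) / sds
        w, b = _fit_linear_svm(Z_tr, y_tr, C)
        Z_te = (X[test_idx][:, consensus] - means) / sds
        calls = (Z_te @ w + b > 0).astype(int)
        accs[r] = (calls == y[test_idx]).mean()
    mean = float(accs.mean())
    half = 1.96 * float(accs.std(ddof=1)) / np.sqrt(R)
    return MonteCarloResult(
        R=R,
        accuracies=accs,
        mean_accuracy=mean,
        ci_low=mean - half,
        ci_high=mean + half,
        k_fixed=k,
        seed=seed,
        n_resampled_splits=n_resampled,
    )


def compare_assays(result_a: MonteCarloResult, result_b: MonteCarloResult) -> float:
    """Welch t-test p-value for equal mean accuracy of two evaluations."""
    a, b = result_a.accuracies, result_b.accuracies
    if len(a) < 2 or len(b) < 2:
        raise ClassifierError("both results need R >= 2 replicates")
    if np.array_equal(a, b):
        # t = 0 by symmetry; also covers zero shared variance, where scipy
        # would return nan
        return 1.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    if np.isnan(p):
        return 1.0
    return float(p)


# ---------------------------------------------------------------------------
# Nested LOOCV with data-driven signature size
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NestedCVResult:
    folds: pd.DataFrame  # held_out_id, k_star, call, truth, correct
    loocv_accuracy: float
    k_final: int
    final_features: tuple
    k_grid: tuple
    n_skipped_inner_folds: int = 0

    def to_dict(self) -> dict:
        return {
            "loocv_accuracy": self.loocv_accuracy,
            "k_final": self.k_final,
            "final_features": list(self.final_features),
            "k_grid": list(self.k_grid),
            "n_skipped_inner_folds": self.n_skipped_inner_folds,
            "folds": self.folds.to_dict(orient="records"),
        }


def nested_loocv(
    expression: ExpressionMatrix,
    labels: Sequence[int],
    k_grid: Sequence[int] = DEFAULT_K_GRID,
    C: float = DEFAULT_C,
) -> NestedCVResult:
    """Outer LOOCV with an inner LOOCV choosing the signature size.

    For each outer held-out sample, the inner loop computes for every k in
    ``k_grid`` the leave-one-out accuracy on the remaining N−1 samples
    (ranking on N−2 each time); k* is the accuracy-maximizing k (ties →
    smallest), and the outer sample is classified with the top-k* features
    ranked on all N−1. The final signature size is the modal k* (ties →
    smallest), refit on the full cohort. The procedure is deterministic.

    Inner folds whose training portion degenerates to one class are skipped
    and counted; more than 20% skipped folds aborts.
    """
    y = np.asarray(labels, dtype=int)
    X = expression.values.to_numpy(dtype=float).T
    n, f = X.shape
    if n < 4:
        raise ClassifierError(f"need n >= 4 samples, got {n}")
    k_grid = tuple(sorted(set(int(k) for k in k_grid)))
    if not k_grid or k_grid[0] < 1 or k_grid[-1] > f:
        raise ClassifierError(f"k_grid must lie within [1, {f}], got {k_grid}")
    ids = np.asarray(expression.feature_ids)
    array_ids = expression.array_ids
    kmax = k_grid[-1]

    n_skipped_total = 0
    records = []
    outer_mask = np.ones(n, dtype=bool)
    for i in range(n):
        outer_mask[i] = False
        Xo, yo = X[outer_mask], y[outer_mask]
        m = len(yo)
        correct = np.zeros(len(k_grid), dtype=int)
        counted = 0
        skipped = 0
        inner_mask = np.ones(m, dtype=bool)
        for j in range(m):
            inner_mask[j] = False
            y_tr = yo[inner_mask]
            if np.bincount(y_tr, minlength=2).min() < 1:
                skipped += 1
                inner_mask[j] = True
                continue
            X_tr = Xo[inner_mask]
            order = _rank_order(_t_stats(X_tr, y_tr))[:kmax]
            X_top = X_tr[:, order]
            means, sds = _standardize_fit(X_top)
            Z_tr = (X_top - means) / sds
            z_te = (Xo[j, order] - means) / sds
            for ki, k in enumerate(k_grid):
                w, b = _fit_linear_svm(Z_tr[:, :k], y_tr, C)
                call = int(z_te[:k] @ w + b > 0)
                correct[ki] += int(call == yo[j])
            counted += 1
            inner_mask[j] = True
        n_skipped_total += skipped
        if counted == 0 or skipped > 0.2 * m:
            raise ClassifierError(
                f"outer fold {i}: {skipped}/{m} inner folds degenerate (> 20%)"
            )
        k_star = k_grid[int(np.argmax(correct))]  # argmax returns smallest on ties

        order = _rank_order(_t_stats(Xo, yo))[:k_star]
        means, sds = _standardize_fit(Xo[:, order])
        Z = (Xo[:, order] - means) / sds
        w, b = _fit_linear_svm(Z, yo, C)
        z_te = (X[i, order] - means) / sds
        call = int(z_te @ w + b > 0)
        records.append(
            {
                "held_out_id": array_ids[i],
                "k_star": k_star,
                "call": call,
                "truth": int(y[i]),
                "correct": int(call == y[i]),
            }
        )
        outer_mask[i] = True

    folds = pd.DataFrame(records)
    k_counts = folds["k_star"].value_counts()
    top_count = k_counts.max()
    k_final = int(min(k for k, c in k_counts.items() if c == top_count))
    final_order = _rank_order(_t_stats(X, y))[:k_final]
    return NestedCVResult(
        folds=folds,
        loocv_accuracy=float(folds["correct"].mean()),
        k_final=k_final,
        final_features=tuple(str(s) for s in ids[final_order]),
        k_grid=k_grid,
        n_skipped_inner_folds=n_skipped_total,
    )


def fit_prognosticator(
    expression: ExpressionMatrix,
    labels: Sequence[int],
    k: int,
    C: float = DEFAULT_C,
) -> PrognosticModel:
    """Convenience: rank on the full training cohort, keep the top k, train."""
    ranking = t_rank(expression, labels)
    features = ranking["feature_id"].head(k).tolist()
    return train(expression, labels, features, C=C)
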