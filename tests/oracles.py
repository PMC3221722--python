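"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (normal equations, textbook sums of
squares, exhaustive enumeration, triple loops) and shares no code with the
package paths it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats
from sklearn.svm import SVC


def ols_normal_equations(x: np.ndarray, y: np.ndarray) -> dict:
    """Simple linear regression via the normal equations."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    n = len(y)
    s2 = resid @ resid / (n - 2)
    cov = s2 * np.linalg.inv(X.T @ X)
    se_b = np.sqrt(cov[1, 1])
    t = beta[1] / se_b
    p = 2 * stats.t.sf(abs(t), n - 2)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1 - resid @ resid / ss_tot
    return {"slope": beta[1], "intercept": beta[0], "se": se_b, "t": t, "p": p, "r2": r2}


def pooled_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Equal-variance two-sample t by the textbook formula."""
    na, nb = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), na + nb - 2)
    return t, p


def anova_oneway(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA from sums of squares."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    F = (ss_between / df_b) / (ss_within / df_w)
    p = stats.f.sf(F, df_b, df_w)
    return F, p


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    ac, bc = a - a.mean(), b - b.mean()
    return float((ac @ bc) / np.sqrt((ac @ ac) * (bc @ bc)))


def ranksum_exact_p_greater(x: np.ndarray, y: np.ndarray) -> float:
    """Exact one-sided (x stochastically greater) rank-sum p by enumeration
    of every assignment of ranks to the x-sample."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # mid-ranks for ties
    nx = len(x)
    observed = ranks[:nx].sum()
    count = 0
    total = 0
    for comb in combinations(range(len(pooled)), nx):
        total += 1
        if ranks[list(comb)].sum() >= observed - 1e-12:
            count += 1
    return count / total


def pca_eigh(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """PCA via eigendecomposition of the covariance matrix.

    Returns (variance fractions, scores) with components ordered by
    decreasing eigenvalue; the sign convention is unspecified.
    """
    Xc = X - X.mean(axis=0)
    C = Xc.T @ Xc
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals = np.clip(vals, 0, None)
    return vals / vals.sum(), Xc @ vecs


def km_by_hand(times: np.ndarray, events: np.ndarray) -> dict[float, float]:
    """Product-limit estimate as a time -> S(t) table, events before
    censorings at ties."""
    s = 1.0
    out = {}
    for u in np.unique(times):
        n_risk = (times >= u).sum()
        d = ((times == u) & (events == 1)).sum()
        if d > 0:
            s *= 1 - d / n_risk
        out[float(u)] = s
    return out


def logrank_by_hand(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank from the O/E/V table."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    lv = np.unique(groups)
    in1 = groups == lv[1]
    O = E = V = 0.0
    for u in np.unique(times[events == 1]):
        at = times >= u
        n, n1 = at.sum(), (at & in1).sum()
        d = ((times == u) & (events == 1)).sum()
        d1 = ((times == u) & (events == 1) & in1).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = (O - E) ** 2 / V
    return chi2, float(stats.chi2.sf(chi2, 1))


def nested_loocv_naive(X: np.ndarray, y: np.ndarray, k_grid, C: float = 1.0) -> dict:
    """Literal triple-loop nested LOOCV sharing no code with the package.

    Ranking by |pooled t| (scipy), z-scoring by training stats, sklearn SVC
    with a linear kernel, ties broken toward smaller k and lower feature
    index.
    """

    def rank(Xtr, ytr):
        ts = []
        for col in range(Xtr.shape[1]):
            a, b = Xtr[ytr == 0, col], Xtr[ytr == 1, col]
            sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (
                len(a) + len(b) - 2
            )
            if sp2 == 0:
                ts.append(np.inf if a.mean() != b.mean() else 0.0)
            else:
                ts.append(abs((a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))))
        return sorted(range(Xtr.shape[1]), key=lambda c: (-ts[c], c))

    def svm_call(Xtr, ytr, xte):
        mu, sd = Xtr.mean(0), Xtr.std(0, ddof=1)
        svc = SVC(kernel="linear", C=C).fit((Xtr - mu) / sd, ytr)
        return int(svc.decision_function(((xte - mu) / sd).reshape(1, -1))[0] > 0)

    n = len(y)
    k_stars, calls = [], []
    for i in range(n):
        keep = [a for a in range(n) if a != i]
        Xo, yo = X[keep], y[keep]
        accs = []
        for k in k_grid:
            hits = 0
            for j in range(len(keep)):
                inner = [a for a in range(len(keep)) if a != j]
                feats = rank(Xo[inner], yo[inner])[:k]
                hits += int(svm_call(Xo[inner][:, feats], yo[inner], Xo[j, feats]) == yo[j])
            accs.append(hits)
        k_star = k_grid[int(np.argmax(accs))]
        feats = rank(Xo, yo)[:k_star]
        calls.append(svm_call(Xo[:, feats], yo, X[i, feats]))
        k_stars.append(k_star)
    acc = float(np.mean([c == t for c, t in zip(calls, y)]))
    vals, counts = np.unique(k_stars, return_counts=True)
    k_final = int(min(vals[counts == counts.max()]))
    return {"k_stars": k_stars, "calls": calls, "accuracy": acc, "k_final": k_final}
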