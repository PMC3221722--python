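"""Prognosticator-call robustness under analytical perturbations, and
survival separation of the predicted groups.

Robustness is measured as *concordance*: the fraction of condition-varied
replicate arrays of a sample whose prognosticator call matches the call on
that sample's default-condition reference array (most technical replicates
carry no ground-truth outcome, so accuracy is not defined for them).

Survival uses the product-limit (Kaplan–Meier) estimator and the unweighted
Mantel–Haenszel log-rank test on the predicted "recurrence" vs "no
recurrence" groups. At tied times, events are processed before censorings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .array_io import IntensityMatrix, ProbeAnnotation, SampleSheet
from .normalization import avg_diff_raw, rma_like
from .prognostic_classifier import PrognosticModel, predict

_CONDITION_FIELDS = (
    "rna_input_ng",
    "atp_dilution",
    "lot_id",
    "extraction_kit",
    "labeling_kit",
)
_CONDITION_NAMES = {
    "rna_input_ng": "input",
    "atp_dilution": "atp",
    "lot_id": "lot",
    "extraction_kit": "extraction",
    "labeling_kit": "labeling",
}


class RobustnessError(ValueError):
    pass


class SurvivalError(ValueError):
    pass


@dataclass(frozen=True)
class RobustnessReport:
    """Per-condition replicate calls and concordance with the reference."""

    table: pd.DataFrame  # condition, array_id, sample_id, call, reference_call, concordant
    concordance: dict    # condition -> fraction of replicates matching reference


def _summarize(intensities, annotation, mode: str, human_only: bool):
    if mode == "avg_diff_raw":
        return avg_diff_raw(intensities, annotation, human_only=human_only)
    if mode == "rma_log2":
        return rma_like(intensities, annotation, human_only=human_only)
    raise RobustnessError(f"unknown summarization mode: {mode!r}")


def _varied_condition(row: pd.Series, reference: dict) -> str | None:
    varied = [
        f for f in _CONDITION_FIELDS
        if not _levels_equal(row[f], reference[f], f)
    ]
    if len(varied) > 1:
        raise RobustnessError(
            f"replicate {row['array_id']!r} varies more than one covariate: {varied}"
        )
    return varied[0] if varied else None


def _levels_equal(a, b, fld: str) -> bool:
    if fld == "rna_input_ng":
        return float(a) == float(b)
    return str(a) == str(b)


DEFAULT_REFERENCE = {
    "rna_input_ng": 600.0,
    "atp_dilution": "1:50",
    "lot_id": "L1",
    "extraction_kit": "RA",
    "labeling_kit": "FH",
}


def robustness_calls(
    model: PrognosticModel,
    replicates: IntensityMatrix,
    replicate_sheet: SampleSheet,
    reference: IntensityMatrix,
    reference_sheet: SampleSheet,
    annotation: ProbeAnnotation,
    human_only: bool = True,
) -> RobustnessReport:
    """Predict every replicate and compare with its sample's reference call.

    Replicates are summarized with the same mode the model was trained on.
    Each replicate array must vary exactly one analytical covariate from
    the default condition; the varied covariate labels the condition group
    (a replicate at the default condition itself counts toward every
    group's denominator is *not* done — it forms its own "reference"
    group).
    """
    ref_expr = _summarize(reference, annotation, model.mode, human_only)
    ref_calls = dict(
        zip(
            reference_sheet.table["sample_id"],
            predict(model, ref_expr)[
                [ref_expr.array_ids.index(a) for a in reference_sheet.table["array_id"]]
            ],
        )
    )
    rep_expr = _summarize(replicates, annotation, model.mode, human_only)
    rep_calls = predict(model, rep_expr)
    call_of = dict(zip(rep_expr.array_ids, rep_calls))

    rows = []
    for _, row in replicate_sheet.table.iterrows():
        sid = row["sample_id"]
        if sid not in ref_calls:
            raise RobustnessError(f"no reference array for sample {sid!r}")
        varied = _varied_condition(row, DEFAULT_REFERENCE)
        condition = _CONDITION_NAMES[varied] if varied else "reference"
        call = int(call_of[row["array_id"]])
        ref = int(ref_calls[sid])
        rows.append(
            {
                "condition": condition,
                "array_id": row["array_id"],
                "sample_id": sid,
                "call": call,
                "reference_call": ref,
                "concordant": int(call == ref),
            }
        )
    table = pd.DataFrame(rows)
    concordance = {
        cond: float(sub["concordant"].mean())
        for cond, sub in table.groupby("condition")
    }
    return RobustnessReport(table, concordance)


# ---------------------------------------------------------------------------
# Kaplan–Meier and log-rank
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KMCurve:
    group: str
    times: np.ndarray       # distinct times where anything happens
    survival: np.ndarray    # S(t) just after each time
    at_risk: np.ndarray     # number at risk just before each time
    events: np.ndarray      # events at each time

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class LogRankResult:
    chi_squared: float
    df: int
    p_value: float


def km_estimate(
    time: Sequence[float],
    event: Sequence[int],
    group: Sequence | None = None,
) -> dict[str, KMCurve]:
    """Product-limit survival estimate per group.

    Censorings decrement the at-risk count without dropping the curve; with
    no censoring the estimate equals the empirical survival function.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if (t < 0).any():
        raise SurvivalError("negative time")
    if group is None:
        group = np.zeros(len(t), dtype=int)
    g = np.asarray(group)
    if len(t) != len(e) or len(t) != len(g):
        raise SurvivalError("time, event and group must have equal length")
    curves = {}
    for lv in pd.unique(g):
        sel = g == lv
        ts, es = t[sel], e[sel]
        if len(ts) == 0:
            raise SurvivalError(f"empty group {lv!r}")
        uniq = np.unique(ts)
        at_risk = np.empty(len(uniq))
        events = np.empty(len(uniq))
        surv = np.empty(len(uniq))
        s = 1.0
        for i, u in enumerate(uniq):
            # events at a tied time are processed before censorings, so the
            # at-risk set at time u includes everyone with t >= u
            n_at_risk = int((ts >= u).sum())
            d = int(((ts == u) & (es == 1)).sum())
            at_risk[i] = n_at_risk
            events[i] = d
            if n_at_risk > 0 and d > 0:
                s *= 1.0 - d / n_at_risk
            surv[i] = s
        curves[str(lv)] = KMCurve(str(lv), uniq, surv, at_risk, events)
    return curves


def logrank(
    time: Sequence[float],
    event: Sequence[int],
    group: Sequence,
) -> LogRankResult:
    """Unweighted (Mantel–Haenszel) log-rank test for two groups.

    At each distinct event time, the observed events in group 1 are
    compared with their hypergeometric expectation given the margins;
    chi² = (ΣO − ΣE)² / ΣV with 1 df. Invariant to swapping group labels.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    g = np.asarray(group)
    levels = pd.unique(g)
    if len(levels) != 2:
        raise SurvivalError(f"log-rank needs exactly 2 groups, got {len(levels)}")
    if e.sum() == 0:
        raise SurvivalError("no events: log-rank undefined")
    in1 = g == levels[1]
    event_times = np.unique(t[e == 1])
    O = E = V = 0.0
    for u in event_times:
        at_risk = t >= u
        n = int(at_risk.sum())
        n1 = int((at_risk & in1).sum())
        d = int(((t == u) & (e == 1)).sum())
        d1 = int(((t == u) & (e == 1) & in1).sum())
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if V == 0:
        return LogRankResult(0.0, 1, 1.0)
    chi2 = (O - E) ** 2 / V
    p = float(stats.chi2.sf(chi2, 1))
    return LogRankResult(float(chi2), 1, max(p, np.finfo(float).tiny))
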