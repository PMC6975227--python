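"""Survival stratification of modules and single genes.

Each unit (a module or a gene) yields one score per tumor sample: the mean of
the unit's per-molecule z-scored expression (z-scoring makes miRNA, lncRNA and
mRNA scales commensurable before averaging; a raw-average mode exists).
Samples are split into two groups by 1-D k-means (k = 2), the groups'
Kaplan-Meier curves are compared with a two-sided log-rank test, and units
with p below alpha are flagged. Direction reports which group (high or low
score) has the worse survival.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test


from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)


def module_score(
    module_ids, expr: ExpressionMatrix, standardize: bool = True
) -> pd.Series:
    """Per-sample mean of the module molecules' (z-scored) expression."""
    ids = list(module_ids)
    missing = [m for m in ids if m not in expr.molecules]
    if missing:
        raise KeyError(f"module molecules missing from expression: {missing}")
    v = expr.values.loc[ids].to_numpy(float)
    if standardize:
        sd = v.std(axis=1, ddof=0)
        sd[sd == 0] = 1.0
        v = (v - v.mean(axis=1, keepdims=True)) / sd[:, None]
    return pd.Series(v.mean(axis=0), index=expr.samples, name="score")


def kmeans_two_groups(scores, seed: int = 0) -> np.ndarray:
    """Two-class 1-D k-means labels, oriented so group 1 has the higher mean.

    In one dimension the k-means optimum is a threshold split of the sorted
    values, so the global optimum is found exactly by scanning every cutpoint
    with prefix sums. Deterministic; ``seed`` is accepted for interface
    stability but the solution does not depend on it.
    """
    s = np.asarray(scores, float)
    if np.unique(s).size < 2:
        raise ValueError("k-means needs at least two distinct score values")
    order = np.argsort(s, kind="stable")
    ss = s[order]
    n = len(ss)
    c1 = np.cumsum(ss)
    c2 = np.cumsum(ss**2)
    i = np.arange(1, n)
    left = c2[:-1] - c1[:-1] ** 2 / i
    right = (c2[-1] - c2[:-1]) - (c1[-1] - c1[:-1]) ** 2 / (n - i)
    cut = int(np.argmin(left + right)) + 1
    labels = np.zeros(n, dtype=int)
    labels[order[cut:]] = 1  # group 1 = higher scores
    return labels


def km_curve(time, event) -> pd.DataFrame:
    """Kaplan-Meier product-limit curve: time, survival, at-risk counts."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if len(time) == 0:
        raise ValueError("need at least one record")
    if (time < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    surv = kmf.survival_function_["KM_estimate"]
    at_risk = kmf.event_table["at_risk"].reindex(surv.index)
    return pd.DataFrame(
        {"time": surv.index.values, "survival": surv.values, "at_risk": at_risk.values}
    )


def logrank(time_a, event_a, time_b, event_b) -> tuple[float, float]:
    """Two-group log-rank test -> (chi-square, two-sided p)."""
    ta, ea = np.asarray(time_a, float), np.asarray(event_a, int)
    tb, eb = np.asarray(time_b, float), np.asarray(event_b, int)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be nonempty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank requires at least one event")
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class SurvivalResult:
    unit_id: str
    n_high: int
    n_low: int
    chi_square: float
    p_value: float
    significant: bool
    direction: str  # which score group has worse survival: "high" or "low"
    labels: pd.Series | None = field(default=None, repr=False)
    error: str | None = None


def survival_screen(
    units: dict,
    expr: ExpressionMatrix,
    clinical: pd.DataFrame,
    alpha: float = 0.05,
    seed: int = 0,
    standardize: bool = True,
    min_samples: int = 10,
) -> list[SurvivalResult]:
    """Screen modules/genes for association with overall survival.

    ``units`` maps unit id -> iterable of molecule ids (a single-gene unit is
    a one-element list). Only tumor samples with clinical records enter;
    samples lacking clinical data are dropped with a logged count. Units with
    degenerate (constant) scores are reported with an ``error`` field while
    the remaining units still run.
    """
    clin = clinical.set_index("sample_id")
    tumor = [s for s in expr.tumor_samples if s in clin.index]
    dropped = len(expr.tumor_samples) - len(tumor)
    if dropped:
        log.info("dropped %d tumor samples without clinical records", dropped)
    if len(tumor) < min_samples:
        raise ValueError(
            f"survival screen needs >= {min_samples} tumor samples with "
            f"clinical data, got {len(tumor)}"
        )
    sub = expr.subset_samples(tumor)
    time = clin.loc[tumor, "time_days"].to_numpy(float)
    event = clin.loc[tumor, "event"].to_numpy(int)

    results = []
    for unit_id, ids in units.items():
        try:
            score = module_score(ids, sub, standardize=standardize)
            labels = kmeans_two_groups(score.values, seed=seed)
            hi, lo = labels == 1, labels == 0
            chi2, p = logrank(time[hi], event[hi], time[lo], event[lo])
        except (ValueError, KeyError) as exc:
            results.append(
                SurvivalResult(str(unit_id), 0, 0, float("nan"), float("nan"),
                               False, "", error=str(exc))
            )
            continue
        # worse survival = higher event-weighted hazard; compare KM at horizon
        km_hi = km_curve(time[hi], event[hi])
        km_lo = km_curve(time[lo], event[lo])
        direction = "high" if km_hi["survival"].iloc[-1] < km_lo["survival"].iloc[-1] else "low"
        results.append(
            SurvivalResult(
                unit_id=str(unit_id),
                n_high=int(hi.sum()),
                n_low=int(lo.sum()),
                chi_square=chi2,
                p_value=p,
                significant=bool(p < alpha),
                direction=direction,
                labels=pd.Series(labels, index=tumor, name=str(unit_id)),
            )
        )
    return results


def results_table(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "unit_id": r.unit_id,
                "n_high": r.n_high,
                "n_low": r.n_low,
                "chi_square": r.chi_square,
                "p_value": r.p_value,
                "significant": r.significant,
                "direction": r.direction,
                "error": r.error or "",
            }
            for r in results
        ]
    )
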