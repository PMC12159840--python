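"""Therapy-endpoint statistics: survival analysis and group comparisons.

Kaplan-Meier product-limit curves with median survival, the log-rank
(Mantel-Cox) test, exact/midrank Mann-Whitney U, the two-stage
Benjamini-Krieger-Yekutieli (BKY) adaptive FDR step-up, and fold-change
summaries for bioluminescence / tumor-volume trajectories.

Euthanasia at a humane endpoint is coded as an event (death); censoring is
reserved for subjects alive at study termination.  Median survival is the
smallest time at which the survival function falls to <= 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy.stats import mannwhitneyu

from .errors import UndefinedStatisticError, ValidationError


@dataclass(frozen=True)
class SurvivalRecord:
    subject_id: str
    group: str
    time_d: float
    event: bool  # True = event (death/euthanasia), False = censored

    def __post_init__(self) -> None:
        if not math.isfinite(self.time_d) or self.time_d <= 0:
            raise ValidationError(f"time_d must be finite and > 0, got {self.time_d}")


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve: step function S(t) with S(0) = 1."""

    times: tuple[float, ...]  # distinct event times, ascending
    survival: tuple[float, ...]  # S(t) just after each event time
    n_at_risk: tuple[int, ...]
    median_d: float | None  # smallest t with S(t) <= 0.5; None if not reached

    def survival_at(self, t: float) -> float:
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_per_group: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p_value out of [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class FdrDecision:
    p_values: tuple[float, ...]
    q: float
    rejected: tuple[bool, ...]
    r1: int  # stage-1 rejection count

    @property
    def n_rejected(self) -> int:
        return sum(self.rejected)


def _to_arrays(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    t = np.array([r.time_d for r in records], float)
    e = np.array([r.event for r in records], bool)
    return t, e


def km_fit(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier product-limit estimate of the survival function.

    Ties at a time are processed together; subjects censored at an event time
    are removed from the risk set only after that event.  All-censored input
    yields a flat curve with median absent.
    """
    if not records:
        raise ValidationError("records must be non-empty")
    t, e = _to_arrays(records)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)

    event_times = np.unique(t[e])
    surv = [float(kmf.survival_function_at_times(ti).iloc[0]) for ti in event_times]
    n_at_risk = [int(np.sum(t >= ti)) for ti in event_times]
    # smallest event time with S(t) <= 0.5; the tolerance admits survival
    # probabilities that are exactly one half up to float rounding
    median_d = next(
        (float(ti) for ti, si in zip(event_times, surv) if si <= 0.5 + 1e-9), None
    )
    return KMCurve(
        times=tuple(float(ti) for ti in event_times),
        survival=tuple(surv),
        n_at_risk=tuple(n_at_risk),
        median_d=median_d,
    )


def logrank_test(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> TestResult:
    """Log-rank (Mantel-Cox) comparison of two survival curves.

    Chi-square statistic (O - E)^2 / V summed over event times with the
    hypergeometric variance and tie correction; two-sided p from chi2(1).
    """
    if not group_a or not group_b:
        raise ValidationError("both groups must be non-empty")
    ta, ea = _to_arrays(group_a)
    tb, eb = _to_arrays(group_b)
    if not (ea.any() or eb.any()):
        raise UndefinedStatisticError("log-rank undefined: no events in either group")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return TestResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        method="log-rank (Mantel-Cox)",
        n_per_group=(len(group_a), len(group_b)),
    )


def mann_whitney_exact(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U via midranks.

    Exact enumeration when n_x + n_y <= 12 and the pooled sample is tie-free;
    otherwise the tie-corrected normal (midrank) approximation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 12 and no_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=f"Mann-Whitney U ({method})",
        n_per_group=(int(x.size), int(y.size)),
    )


def _step_up(p_sorted: np.ndarray, level: float) -> int:
    """Number of rejections of the linear (BH-type) step-up at `level`."""
    m = p_sorted.size
    thresholds = level * np.arange(1, m + 1) / m
    passing = np.nonzero(p_sorted <= thresholds)[0]
    return int(passing[-1] + 1) if passing.size else 0


def bky_two_stage(p_values: Sequence[float], q: float = 0.05) -> FdrDecision:
    """Two-stage Benjamini-Krieger-Yekutieli adaptive FDR step-up (2006).

    Stage 1: linear step-up at q' = q/(1+q), giving r1 rejections.  If r1 is
    0 (nothing) or m (everything), stop.  Otherwise stage 2 re-tests with the
    step-up at q' * m/(m - r1); the rejected set is the stage-2 prefix of the
    ascending p-value order.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return FdrDecision(p_values=(), q=q, rejected=(), r1=0)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    q1 = q / (1.0 + q)
    r1 = _step_up(p_sorted, q1)
    if r1 == 0 or r1 == m:
        k = r1
    else:
        k = _step_up(p_sorted, q1 * m / (m - r1))
    rejected = np.zeros(m, bool)
    rejected[order[:k]] = True
    return FdrDecision(
        p_values=tuple(float(v) for v in p), q=q, rejected=tuple(bool(b) for b in rejected), r1=r1
    )


def fold_change(baseline: float, later: float) -> float:
    """Fold decrease from baseline to a later measurement: baseline / later."""
    if baseline <= 0 or later <= 0:
        raise ValidationError("baseline and later must both be > 0")
    return baseline / later


def records_from_frame(df: pd.DataFrame) -> list[SurvivalRecord]:
    """Build survival records from a frame with columns subject_id, group,
    time_d, event (0/1)."""
    return [
        SurvivalRecord(
            subject_id=str(r.subject_id),
            group=str(r.group),
            time_d=float(r.time_d),
            event=bool(int(r.event)),
        )
        for r in df.itertuples(index=False)
    ]


def read_survival(path, *, sep: str = ",") -> list[SurvivalRecord]:
    """Read the survival CSV schema: subject_id, group, time_d, event(0/1)."""
    return records_from_frame(pd.read_csv(path, sep=sep))
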