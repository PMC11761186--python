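"""Survival and discrimination statistics, implemented from first principles.

Kaplan-Meier product-limit curves, the two-group log-rank test with
hypergeometric variance, AUROC via the rank (Mann-Whitney) formulation,
step-wise log-rank cutoff search, the Mantel-Haenszel hazard ratio with a
log-scale normal-approximation interval, and the 2x2 Pearson chi-square
test. Only chi-square/t tail probabilities come from scipy.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class ValidationError(ValueError):
    pass


@dataclass
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    chi2: float
    p: float
    df: int = 1


@dataclass
class CutoffResult:
    cutoff: float
    p: float
    chi2: float
    n_high: int
    n_low: int


@dataclass
class HazardRatioResult:
    hr: float
    ci_low: float
    ci_high: float
    flagged: bool = False


def _check_surv(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValidationError("empty survival data")
    if np.any(times < 0) or np.any(~np.isfinite(times)):
        raise ValidationError("times must be finite and nonnegative")
    if not np.isin(events, (0, 1)).all():
        raise ValidationError("event flags must be 0 or 1")
    return times, events.astype(int)


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier estimator; censored observations leave the risk set
    without stepping the curve down."""
    times, events = _check_surv(times, events)
    event_times = np.unique(times[events == 1])
    surv = np.empty(event_times.size)
    risk = np.empty(event_times.size, dtype=int)
    s = 1.0
    for i, t in enumerate(event_times):
        n_at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d / n_at_risk
        surv[i] = s
        risk[i] = n_at_risk
    return KMCurve(event_times, surv, risk)


def _logrank_tables(times, events, group):
    """Per-event-time observed events in group 1, expected events and
    hypergeometric variance."""
    event_times = np.unique(times[events == 1])
    o1 = e1 = v = 0.0
    o2 = e2 = 0.0
    for t in event_times:
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & (group == 1)).sum())
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & (group == 1)).sum())
        o1 += d1
        o2 += d - d1
        e1 += d * n1 / n
        e2 += d * (n - n1) / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o1, e1, o2, e2, v


def logrank_test(times, events, group) -> LogRankResult:
    """Two-group log-rank test: chi2 = (sum O1 - sum E1)^2 / sum V, 1 df."""
    times, events = _check_surv(times, events)
    group = np.asarray(group).astype(int)
    if not np.isin(group, (0, 1)).all():
        raise ValidationError("group labels must be 0 or 1")
    if (group == 0).sum() == 0 or (group == 1).sum() == 0:
        raise ValidationError("both groups must be nonempty")
    o1, e1, _, _, v = _logrank_tables(times, events, group)
    if v <= 0:
        return LogRankResult(0.0, 1.0)
    chi2 = (o1 - e1) ** 2 / v
    return LogRankResult(float(chi2), float(stats.chi2.sf(chi2, 1)))


def auroc(scores, labels) -> float:
    """P(score+ > score-) + 0.5 P(score+ = score-) via mid-ranks."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if not np.isin(labels, (0, 1)).all():
        raise ValidationError("labels must be binary")
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValidationError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def best_cutoff(scores, times, events, min_group_frac: float = 0.1) -> CutoffResult:
    """Step-wise search for the score cutoff minimising the log-rank p.

    Every midpoint between consecutive distinct sorted scores is a
    candidate; candidates leaving either group below ``min_group_frac`` of
    the samples are inadmissible. Ties in p resolve to the lower cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    times, events = _check_surv(times, events)
    distinct = np.unique(scores)
    if distinct.size < 2:
        raise ValidationError("need at least 2 distinct scores")
    n = scores.size
    min_n = min_group_frac * n
    best: CutoffResult | None = None
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        cut = 0.5 * (lo + hi)
        high = (scores > cut).astype(int)
        n_high = int(high.sum())
        n_low = n - n_high
        if n_high < min_n or n_low < min_n:
            continue
        res = logrank_test(times, events, high)
        if best is None or res.p < best.p:
            best = CutoffResult(cut, res.p, res.chi2, n_high, n_low)
    if best is None:
        raise ValidationError(
            "no admissible cutoff satisfies the minimum group size")
    return best


def hazard_ratio(times, events, group) -> HazardRatioResult:
    """Mantel-Haenszel hazard ratio (O1/E1)/(O2/E2) of group 1 vs group 0
    with a log-scale normal 95% interval, SE = sqrt(1/E1 + 1/E2)."""
    times, events = _check_surv(times, events)
    group = np.asarray(group).astype(int)
    if (group == 0).sum() == 0 or (group == 1).sum() == 0:
        raise ValidationError("both groups must be nonempty")
    if events.sum() == 0:
        raise ValidationError("no events observed")
    o1, e1, o2, e2, _ = _logrank_tables(times, events, group)
    if o1 == 0 or o2 == 0 or e1 == 0 or e2 == 0:
        hr = np.inf if o2 == 0 and o1 > 0 else 0.0
        return HazardRatioResult(float(hr), np.nan, np.nan, flagged=True)
    hr = (o1 / e1) / (o2 / e2)
    se = np.sqrt(1.0 / e1 + 1.0 / e2)
    z = stats.norm.ppf(0.975)
    return HazardRatioResult(float(hr), float(hr * np.exp(-z * se)),
                             float(hr * np.exp(z * se)), flagged=False)


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction, 1 df."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValidationError("table must be 2x2")
    if np.any(t < 0):
        raise ValidationError("counts must be nonnegative")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValidationError("all margins must be positive")
    expected = np.outer(row, col) / t.sum()
    stat = float(((t - expected) ** 2 / expected).sum())
    return stat, float(stats.chi2.sf(stat, 1))
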