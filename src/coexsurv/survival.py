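"""Kaplan-Meier estimation and two-group log-rank comparison.

Kaplan-Meier curves come from lifelines' product-limit fitter; the
two-group log-rank (Mantel-Cox) statistic is computed here from the pooled
event-time 2x2 tables,

    O1 = sum d1_i,   E1 = sum d_i * n1_i / n_i,
    V  = sum d_i * (n1_i/n_i) * (1 - n1_i/n_i) * (n_i - d_i) / (n_i - 1),
    X^2 = (O1 - E1)^2 / V,   p from chi-square with 1 df,

with the degenerate case V = 0 (no between-group information) reported as
statistic 0, p = 1.  Ties between an event and a censoring at the same time
follow the standard convention: the event precedes the censoring, so the
censored subject is still at risk at that time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from scipy.stats import chi2

from .coexpression import GeneProfile
from .errors import CoexsurvError, ValidationError
from .readwrite import SurvivalTable

__all__ = [
    "KMCurve",
    "LogRankResult",
    "km_estimate",
    "log_rank",
    "split_by_expression",
    "compare_partition_survival",
]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate evaluated at the distinct event times."""

    event_times: np.ndarray   # ascending, times with >= 1 event
    survival: np.ndarray      # S(t) just after each event time, non-increasing
    at_risk: np.ndarray       # n_i at each event time
    n_events: np.ndarray      # d_i at each event time
    n_total: int = 0

    def __post_init__(self):
        s = np.asarray(self.survival, dtype=float)
        if len(s) and (np.diff(s) > 1e-12).any():
            raise ValidationError("survival curve must be non-increasing")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.n_events,
            }
        )


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    p_value: float
    n_per_group: tuple
    events_per_group: tuple
    df: int = 1


def km_estimate(s: SurvivalTable) -> KMCurve:
    """Kaplan-Meier product-limit estimate of the survival function.

    Censored times reduce the risk set only; with no events the curve is the
    constant 1 and the event-time vector is empty.
    """
    if len(s) == 0:
        raise ValidationError("empty survival table")
    kmf = KaplanMeierFitter()
    kmf.fit(s.times, event_observed=s.events)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[times, kmf.survival_function_.columns[0]].to_numpy()
    return KMCurve(
        event_times=times,
        survival=surv,
        at_risk=ev["at_risk"].to_numpy(dtype=int),
        n_events=ev["observed"].to_numpy(dtype=int),
        n_total=len(s),
    )


def _pooled_logrank(times_a, events_a, times_b, events_b):
    """O1, E1, V over the pooled distinct event times (vectorized)."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    # risk sets: subjects with time >= t (event-before-censoring tie rule
    # keeps same-time censored subjects at risk)
    n1 = (ta[None, :] >= event_times[:, None]).sum(axis=1)
    n2 = (tb[None, :] >= event_times[:, None]).sum(axis=1)
    d1 = ((ta[None, :] == event_times[:, None]) & (ea[None, :] == 1)).sum(axis=1)
    d2 = ((tb[None, :] == event_times[:, None]) & (eb[None, :] == 1)).sum(axis=1)
    n = n1 + n2
    d = d1 + d2
    with np.errstate(invalid="ignore", divide="ignore"):
        e1 = d * n1 / n
        v = d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    v = np.where(n > 1, v, 0.0)
    return float(d1.sum()), float(e1.sum()), float(np.nansum(v))


def log_rank(a: SurvivalTable, b: SurvivalTable) -> LogRankResult:
    """Two-sided two-group log-rank (Mantel-Cox) test."""
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("each group needs at least one record")
    events_total = int(a.events.sum() + b.events.sum())
    if events_total == 0:
        raise CoexsurvError("no events in either group; log-rank undefined")
    o1, e1, v = _pooled_logrank(a.times, a.events, b.times, b.events)
    if v == 0.0:
        statistic, p = 0.0, 1.0
    else:
        statistic = (o1 - e1) ** 2 / v
        p = float(chi2.sf(statistic, df=1))
    return LogRankResult(
        statistic=float(statistic),
        p_value=p,
        n_per_group=(len(a), len(b)),
        events_per_group=(int(a.events.sum()), int(b.events.sum())),
    )


def split_by_expression(
    profile: GeneProfile, s: SurvivalTable, cutoff: float = 0.5
):
    """Split the survival table by a gene's expression quantile.

    Samples with expression strictly above the cutoff quantile form the
    "high" group, the rest the "low" group; default cutoff is the median.
    Returns (low, high).
    """
    if not 0.0 < cutoff < 1.0:
        raise ValidationError("cutoff quantile must be in (0, 1)")
    shared = [sid for sid in profile.sample_ids if sid in set(s.sample_ids)]
    if len(shared) < 4:
        raise CoexsurvError(
            f"need at least 4 shared samples for an expression split (got {len(shared)})"
        )
    prof = profile.restrict(shared)
    threshold = float(np.quantile(prof.values, cutoff))
    high_ids = [sid for sid, v in zip(prof.sample_ids, prof.values) if v > threshold]
    low_ids = [sid for sid, v in zip(prof.sample_ids, prof.values) if v <= threshold]
    if not high_ids or not low_ids:
        raise CoexsurvError(
            f"cutoff quantile {cutoff} leaves an empty group "
            "(try a different cutoff; expression may be heavily tied)"
        )
    return s.subset(low_ids), s.subset(high_ids)


def compare_partition_survival(partition, s: SurvivalTable) -> LogRankResult:
    """Log-rank comparison of the greedy split's two cohorts."""
    if len(partition.cohort2) == 0:
        raise CoexsurvError("no second cohort; survival comparison undefined")
    surv_ids = set(s.sample_ids)
    c1 = [sid for sid in partition.cohort1 if sid in surv_ids]
    c2 = [sid for sid in partition.cohort2 if sid in surv_ids]
    if len(c1) < 2 or len(c2) < 2:
        raise CoexsurvError(
            f"cohorts intersect the survival table with {len(c1)} and {len(c2)} "
            "samples; need >= 2 each"
        )
    return log_rank(s.subset(c1), s.subset(c2))
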