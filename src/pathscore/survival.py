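"""Kaplan-Meier curves, weighted log-rank tests, outlier stratification,
and Spearman correlation with ordinal stage.

The product-limit estimator and the two-group tests are implemented from
their counting-process formulas. Weights: 1 at every event time gives the
Mantel-Cox (log-rank) test; the number at risk gives the Gehan-Breslow
test, which is sensitive to early differences.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression_io import TUMOUR, SampleAnnotation
from .scoring import OutlierCall

logger = logging.getLogger(__name__)

MANTEL_COX = "mantel_cox"
GEHAN_BRESLOW = "gehan_breslow"


@dataclass
class SurvivalDataset:
    """Per-sample time (months), event flag, and stratum label."""

    sample_ids: tuple[str, ...]
    times: np.ndarray
    events: np.ndarray
    strata: tuple[str, ...]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=bool)
        if (self.times < 0).any():
            raise ValueError("survival times must be non-negative")
        if not (len(self.sample_ids) == len(self.times) == len(self.events) == len(self.strata)):
            raise ValueError("inconsistent survival dataset lengths")

    def truncate(self, horizon: float) -> "SurvivalDataset":
        """Administrative censoring at ``horizon`` (e.g. 60 months)."""
        times = np.minimum(self.times, horizon)
        events = self.events & (self.times <= horizon)
        return SurvivalDataset(self.sample_ids, times, events, self.strata)

    def stratum_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.strata:
            seen.setdefault(s, None)
        return list(seen)


@dataclass
class KMCurve:
    """Stepwise product-limit estimate for one stratum."""

    stratum: str
    event_times: np.ndarray       # distinct times with >= 1 event
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray          # S(t) just after each event time
    censor_times: np.ndarray

    def survival_at(self, t: float) -> float:
        s = 1.0
        for et, sv in zip(self.event_times, self.survival):
            if et <= t:
                s = sv
            else:
                break
        return s

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.event_times,
            "at_risk": self.at_risk.astype(int),
            "events": self.n_events.astype(int),
            "survival": self.survival,
        })


def km_estimate(data: SurvivalDataset) -> dict[str, KMCurve]:
    """Product-limit estimator per stratum.

    S(t) = prod over event times t_i <= t of (1 - d_i / n_i); subjects
    censored at an event time count as at risk at that time (events
    precede censoring on ties).
    """
    curves: dict[str, KMCurve] = {}
    for label in data.stratum_labels():
        mask = np.array([s == label for s in data.strata])
        times = data.times[mask]
        events = data.events[mask]
        if len(times) == 0:
            raise ValueError(f"stratum {label!r} has no subjects")
        if not events.any():
            logger.warning("stratum %r has no events; curve is flat at 1", label)
        order = np.argsort(times, kind="stable")
        times, events = times[order], events[order]
        distinct = np.unique(times[events])
        at_risk = np.array([(times >= t).sum() for t in distinct], dtype=float)
        n_events = np.array([((times == t) & events).sum() for t in distinct], dtype=float)
        surv = np.cumprod(1.0 - n_events / at_risk) if len(distinct) else np.array([])
        curves[label] = KMCurve(
            stratum=label,
            event_times=distinct,
            at_risk=at_risk,
            n_events=n_events,
            survival=surv,
            censor_times=np.sort(times[~events]),
        )
    return curves


@dataclass(frozen=True)
class TwoGroupTestResult:
    test: Literal["mantel_cox", "gehan_breslow"]
    statistic: float
    p_value: float
    df: int = 1

    def __post_init__(self) -> None:
        if self.statistic < 0:
            raise ValueError("chi-square statistic must be >= 0")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def logrank_statistic(
    times: np.ndarray, events: np.ndarray, group1: np.ndarray,
    weights: Literal["mantel_cox", "gehan_breslow"] = MANTEL_COX,
) -> float:
    """Weighted log-rank chi-square for group1 (bool mask) vs the rest."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    group1 = np.asarray(group1, dtype=bool)
    distinct = np.unique(times[events])
    num = 0.0
    var = 0.0
    for t in distinct:
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & group1).sum()
        d = ((times == t) & events).sum()
        d1 = ((times == t) & events & group1).sum()
        if n < 2:
            continue
        expected = d * n1 / n
        v = d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1) if n > 1 else 0.0
        w = float(n) if weights == GEHAN_BRESLOW else 1.0
        num += w * (d1 - expected)
        var += w * w * v
    if var <= 0:
        return 0.0
    return num * num / var


def logrank_test(
    data: SurvivalDataset,
    weights: Literal["mantel_cox", "gehan_breslow"] = MANTEL_COX,
) -> TwoGroupTestResult:
    """Two-group weighted log-rank test; p from chi-square with 1 df."""
    labels = data.stratum_labels()
    if len(labels) != 2:
        raise ValueError(f"two-group test requires exactly 2 strata, got {labels}")
    if not data.events.any():
        raise ValueError("no events observed; test undefined")
    for lab in labels:
        if not any(s == lab for s in data.strata):
            raise ValueError(f"stratum {lab!r} has no subjects")
    group1 = np.array([s == labels[0] for s in data.strata])
    chi2 = logrank_statistic(data.times, data.events, group1, weights)
    p = float(stats.chi2.sf(chi2, df=1))
    return TwoGroupTestResult(test=weights, statistic=float(chi2), p_value=p)


def permutation_logrank_p(
    data: SurvivalDataset,
    weights: Literal["mantel_cox", "gehan_breslow"] = MANTEL_COX,
) -> float:
    """Exact permutation p: all relabelings preserving stratum sizes."""
    labels = data.stratum_labels()
    if len(labels) != 2:
        raise ValueError("two strata required")
    n = len(data.times)
    n1 = sum(s == labels[0] for s in data.strata)
    observed = logrank_statistic(
        data.times, data.events, np.array([s == labels[0] for s in data.strata]), weights
    )
    count = total = 0
    for idx in itertools.combinations(range(n), n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        total += 1
        if logrank_statistic(data.times, data.events, mask, weights) >= observed - 1e-12:
            count += 1
    return count / total


def stratify_by_outlier(
    outliers: Sequence[OutlierCall],
    pathway: str,
    direction: Literal["up", "down"],
    annotations: Sequence[SampleAnnotation],
) -> SurvivalDataset:
    """Outlier tumours (matching direction) vs all other tumours.

    Requires time/event annotations for every tumour sample with an
    outlier call; errors if either stratum would be empty.
    """
    calls = {c.sample_id: c for c in outliers if c.pathway == pathway}
    if not calls:
        raise ValueError(f"no outlier calls for pathway {pathway!r}")
    ann = {a.sample_id: a for a in annotations}
    ids, times, events, strata = [], [], [], []
    for sid, call in calls.items():
        a = ann.get(sid)
        if a is None or a.group != TUMOUR:
            continue
        if a.time_to_event is None or a.event is None:
            raise ValueError(f"tumour sample {sid!r} lacks survival fields")
        ids.append(sid)
        times.append(a.time_to_event)
        events.append(a.event)
        strata.append("outlier" if call.direction == direction else "rest")
    if "outlier" not in strata or "rest" not in strata:
        raise ValueError(
            f"outlier stratification for {pathway!r} ({direction}) leaves an "
            "empty stratum; test undefined"
        )
    return SurvivalDataset(tuple(ids), np.array(times), np.array(events), tuple(strata))


def stratify_by_score_split(
    scores: pd.Series,
    annotations: Sequence[SampleAnnotation],
    split: Literal["median", "tertile"] = "median",
) -> SurvivalDataset:
    """Alternative stratification: high vs low pathway score halves, or the
    top vs bottom tertile (middle tertile dropped)."""
    ann = {a.sample_id: a for a in annotations}
    sub = scores[[s for s in scores.index if s in ann and ann[s].group == TUMOUR]]
    if split == "median":
        cutoff = sub.median()
        high = sub.index[sub > cutoff]
        low = sub.index[sub <= cutoff]
    elif split == "tertile":
        lo_q, hi_q = sub.quantile([1 / 3, 2 / 3])
        high = sub.index[sub > hi_q]
        low = sub.index[sub < lo_q]
    else:
        raise ValueError(f"unknown split {split!r}")
    ids, times, events, strata = [], [], [], []
    for sid in list(high) + list(low):
        a = ann[sid]
        if a.time_to_event is None or a.event is None:
            raise ValueError(f"tumour sample {sid!r} lacks survival fields")
        ids.append(sid)
        times.append(a.time_to_event)
        events.append(a.event)
        strata.append("high" if sid in set(high) else "low")
    if "high" not in strata or "low" not in strata:
        raise ValueError("score split leaves an empty stratum")
    return SurvivalDataset(tuple(ids), np.array(times), np.array(events), tuple(strata))


def spearman(scores: Sequence[float], ordinal: Sequence[int]) -> tuple[float, float]:
    """Tie-corrected Spearman rho; exact p for n <= 8, t-approx otherwise.

    rho is the Pearson correlation of midranks. The exact p enumerates all
    permutations of one vector (two-sided on |rho|).
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(ordinal, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("spearman requires >= 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman undefined for a constant vector")
    rx, ry = stats.rankdata(x), stats.rankdata(y)

    def _pearson(a: np.ndarray, b: np.ndarray) -> float:
        a = a - a.mean()
        b = b - b.mean()
        return float((a @ b) / math.sqrt((a @ a) * (b @ b)))

    rho = _pearson(rx, ry)
    n = len(x)
    if n <= 8:
        count = total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if abs(_pearson(rx, ry[list(perm)])) >= abs(rho) - 1e-12:
                count += 1
        return rho, count / total
    t = rho * math.sqrt((n - 2) / max(1e-300, 1 - rho ** 2))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)
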