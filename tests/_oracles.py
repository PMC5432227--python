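"""Independent brute-force oracles used to verify the implementation.

Everything here is deliberately written from first principles (enumeration
or direct formulas over cluster members), sharing no code with the package
paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def ranksum_permutation_p(x, y) -> float:
    """Two-sided rank-sum p by enumerating every relabeling.

    Statistic: the Mann-Whitney U count of (x_i > y_j) pairs plus half the
    ties — a different formulation from the rank-sum the implementation
    uses, but an equivalent ordering, so the permutation p must match.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    n1, n = len(x), len(x) + len(y)

    def u_stat(group1):
        rest = [pooled[i] for i in range(n) if i not in group1]
        vals = [pooled[i] for i in group1]
        u = 0.0
        for a in vals:
            for b in rest:
                if a > b:
                    u += 1.0
                elif a == b:
                    u += 0.5
        return u

    center = n1 * (n - n1) / 2.0
    observed = abs(u_stat(set(range(n1))) - center)
    count = total = 0
    for combo in itertools.combinations(range(n), n1):
        total += 1
        if abs(u_stat(set(combo)) - center) >= observed - 1e-9:
            count += 1
    return count / total


def logrank_chi2(times, events, group1_mask, weights="mantel_cox") -> float:
    """Weighted log-rank chi-square computed from explicit 2x2 tables."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    g1 = np.asarray(group1_mask, bool)
    num = var = 0.0
    for t in sorted(set(times[events])):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & g1).sum())
        d = int(((times == t) & events).sum())
        d1 = int(((times == t) & events & g1).sum())
        if n < 2:
            continue
        e = d * n1 / n
        v = d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        w = n if weights == "gehan_breslow" else 1.0
        num += w * (d1 - e)
        var += w * w * v
    return 0.0 if var <= 0 else num * num / var


def logrank_permutation_p(times, events, group1_mask, weights="mantel_cox") -> float:
    """Exact permutation p over all label assignments of the group sizes."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    g1 = np.asarray(group1_mask, bool)
    n, n1 = len(times), int(g1.sum())
    observed = logrank_chi2(times, events, g1, weights)
    count = total = 0
    for combo in itertools.combinations(range(n), n1):
        mask = np.zeros(n, bool)
        mask[list(combo)] = True
        total += 1
        if logrank_chi2(times, events, mask, weights) >= observed - 1e-12:
            count += 1
    return count / total


def ward_agglomeration_heights(points: np.ndarray) -> list[float]:
    """Exhaustive Ward agglomeration straight from cluster members.

    At each step evaluates every cluster pair's Ward distance
    sqrt(2 |A||B| / (|A|+|B|)) * ||centroid_A - centroid_B|| and merges the
    minimum. Returns the sequence of merge heights.
    """
    clusters = [[i] for i in range(len(points))]
    heights: list[float] = []

    def ward_d(a, b):
        ca = points[a].mean(axis=0)
        cb = points[b].mean(axis=0)
        return math.sqrt(2.0 * len(a) * len(b) / (len(a) + len(b))) * float(
            np.linalg.norm(ca - cb)
        )

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = ward_d(clusters[i], clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return heights


def km_survival_brute(times, events) -> dict[float, float]:
    """Product-limit values computed independently by direct counting."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    s = 1.0
    out: dict[float, float] = {}
    for t in sorted(set(times[events])):
        n_at_risk = int((times >= t).sum())
        d = int(((times == t) & events).sum())
        s *= 1.0 - d / n_at_risk
        out[float(t)] = s
    return out


def spearman_rho_brute(x, y) -> float:
    """Spearman rho from explicitly constructed midranks."""

    def midranks(v):
        v = list(map(float, v))
        out = []
        for a in v:
            less = sum(1 for b in v if b < a)
            equal = sum(1 for b in v if b == a)
            out.append(less + (equal + 1) / 2.0)
        return out

    rx, ry = midranks(x), midranks(y)
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den
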