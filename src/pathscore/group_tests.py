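"""Tumour-vs-benign pathway tests and heterogeneity summaries.

Two analyses: a two-sample Wilcoxon rank-sum test on per-sample pathway
scores (pathways below the gene-count floor are reported "not tested"),
and a Welch t-test on per-sample mean log2 expression of each pathway's
genes. The rank-sum p-value is exact (full enumeration) for small totals
and a tie/continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression_io import BENIGN, TUMOUR, ExpressionMatrix, SampleAnnotation
from .pathway_catalog import PathwayCatalog, intersect_with_matrix, testable
from .scoring import PathwayScoreMatrix, restandardize

EXACT_MAX_TOTAL = 12  # enumerate all C(N, n1) label assignments up to this N

UPREGULATED = "upregulated"
DOWNREGULATED = "downregulated"
NS = "ns"
NOT_TESTED = "not tested"


@dataclass(frozen=True)
class PathwayTestResult:
    pathway: str
    test: Literal["wilcoxon", "t"]
    statistic: Optional[float]
    p_value: Optional[float]
    direction: str
    n_genes: int
    n_tumour: int
    n_benign: int

    def __post_init__(self) -> None:
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum test of x vs y.

    Returns (W, two-sided p) where W is the rank sum of ``x`` in the
    pooled midrank ranking. Exact enumeration of all label assignments
    when len(x)+len(y) <= EXACT_MAX_TOTAL; otherwise a normal
    approximation with tie correction and a 0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n1].sum())
    n = n1 + n2
    expected = n1 * (n + 1) / 2.0
    if n <= EXACT_MAX_TOTAL:
        dev = abs(w - expected)
        count = 0
        total = 0
        for idx in itertools.combinations(range(n), n1):
            total += 1
            if abs(ranks[list(idx)].sum() - expected) >= dev - 1e-9:
                count += 1
        return w, count / total
    # tie-corrected variance of the rank sum
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return w, 1.0
    z = (abs(w - expected) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return w, float(2.0 * stats.norm.sf(z))


def _split_scores(
    scores: pd.Series, annotations: Sequence[SampleAnnotation]
) -> tuple[np.ndarray, np.ndarray]:
    ann = {a.sample_id: a for a in annotations}
    tumour = scores[[s for s in scores.index if s in ann and ann[s].group == TUMOUR]]
    benign = scores[[s for s in scores.index if s in ann and ann[s].group == BENIGN]]
    return tumour.to_numpy(dtype=float), benign.to_numpy(dtype=float)


def wilcoxon_pathway_test(
    scores: PathwayScoreMatrix,
    annotations: Sequence[SampleAnnotation],
    alpha: float = 0.05,
    min_genes: Optional[int] = None,
    adjust: Optional[Literal["bh"]] = None,
) -> list[PathwayTestResult]:
    """Rank-sum test of tumour vs benign pathway scores, per pathway.

    Pathways with fewer measured genes than the floor (default 6) are
    returned with a "not tested" marker. Direction is assigned by the sign
    of (median tumour - median benign) only when p < alpha. ``adjust="bh"``
    applies Benjamini-Hochberg across the tested pathways (off by default).
    """
    floor = min_genes if min_genes is not None else 6
    results: list[PathwayTestResult] = []
    for pathway in scores.pathways:
        t_vals, b_vals = _split_scores(scores.values[pathway], annotations)
        if len(t_vals) == 0 or len(b_vals) == 0:
            raise ValueError("both tumour and benign groups must be non-empty")
        n_genes = scores.gene_counts[pathway]
        if n_genes < floor:
            results.append(PathwayTestResult(
                pathway=pathway, test="wilcoxon", statistic=None, p_value=None,
                direction=NOT_TESTED, n_genes=n_genes,
                n_tumour=len(t_vals), n_benign=len(b_vals)))
            continue
        w, p = rank_sum_test(t_vals, b_vals)
        results.append(PathwayTestResult(
            pathway=pathway, test="wilcoxon", statistic=w, p_value=p,
            direction=NS, n_genes=n_genes, n_tumour=len(t_vals), n_benign=len(b_vals)))
    if adjust == "bh":
        results = _bh_adjust(results)
    out = []
    for r in results:
        if r.p_value is not None and r.p_value < alpha:
            t_vals, b_vals = _split_scores(scores.values[r.pathway], annotations)
            diff = float(np.median(t_vals) - np.median(b_vals))
            direction = UPREGULATED if diff > 0 else (DOWNREGULATED if diff < 0 else NS)
            r = PathwayTestResult(pathway=r.pathway, test=r.test, statistic=r.statistic,
                                  p_value=r.p_value, direction=direction, n_genes=r.n_genes,
                                  n_tumour=r.n_tumour, n_benign=r.n_benign)
        out.append(r)
    return out


def _bh_adjust(results: list[PathwayTestResult]) -> list[PathwayTestResult]:
    tested = [r for r in results if r.p_value is not None]
    m = len(tested)
    order = np.argsort([r.p_value for r in tested])
    adjusted = np.empty(m)
    prev = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        val = min(prev, tested[i].p_value * m / (rank_idx + 1))
        adjusted[i] = val
        prev = val
    out = []
    j = 0
    for r in results:
        if r.p_value is None:
            out.append(r)
        else:
            out.append(PathwayTestResult(
                pathway=r.pathway, test=r.test, statistic=r.statistic,
                p_value=float(adjusted[j]), direction=r.direction, n_genes=r.n_genes,
                n_tumour=r.n_tumour, n_benign=r.n_benign))
            j += 1
    return out


def ttest_pathway(
    matrix: ExpressionMatrix,
    catalog: PathwayCatalog,
    annotations: Sequence[SampleAnnotation],
    alpha: float = 0.05,
) -> list[PathwayTestResult]:
    """Welch t-test on per-sample mean log2 expression of each pathway.

    ``matrix`` is expected on the log2 scale already. Each sample is
    reduced to its mean expression over the pathway's measured genes;
    tumour and benign means are compared by a two-sided Welch test.
    """
    cat = intersect_with_matrix(catalog, matrix.genes)
    ann = {a.sample_id: a for a in annotations}
    t_ids = [s for s in matrix.samples if s in ann and ann[s].group == TUMOUR]
    b_ids = [s for s in matrix.samples if s in ann and ann[s].group == BENIGN]
    if len(t_ids) < 2 or len(b_ids) < 2:
        raise ValueError("t-test requires >= 2 samples in each group")
    results: list[PathwayTestResult] = []
    for p in cat:
        if p.n_genes == 0:
            continue
        per_sample = matrix.values.loc[list(p.genes)].mean(axis=0)
        t_vals = per_sample[t_ids].to_numpy(dtype=float)
        b_vals = per_sample[b_ids].to_numpy(dtype=float)
        if np.var(t_vals) == 0 and np.var(b_vals) == 0:
            if np.isclose(t_vals.mean(), b_vals.mean()):
                stat, pval = 0.0, 1.0
            else:
                raise ValueError(
                    f"pathway {p.name!r}: zero variance in both groups with "
                    "unequal means; t-test undefined")
        else:
            stat, pval = stats.ttest_ind(t_vals, b_vals, equal_var=False)
            stat, pval = float(stat), float(pval)
        diff = float(t_vals.mean() - b_vals.mean())
        if pval < alpha:
            direction = UPREGULATED if diff > 0 else DOWNREGULATED
        else:
            direction = NS
        results.append(PathwayTestResult(
            pathway=p.name, test="t", statistic=stat, p_value=pval,
            direction=direction, n_genes=p.n_genes,
            n_tumour=len(t_vals), n_benign=len(b_vals)))
    return results


def heterogeneity_summary(
    scores: PathwayScoreMatrix, annotations: Sequence[SampleAnnotation]
) -> pd.DataFrame:
    """Per-pathway dispersion of tumour scores, sorted by SD descending.

    Columns: sd, iqr, range, frac_above_1sd (fraction of tumours whose
    re-standardized score exceeds 1 in absolute value).
    """
    ann = {a.sample_id: a for a in annotations}
    t_ids = [s for s in scores.samples if s in ann and ann[s].group == TUMOUR]
    if len(t_ids) < 2:
        raise ValueError("heterogeneity summary requires >= 2 tumour samples")
    tumour = scores.values.loc[t_ids]
    restd = restandardize(scores).loc[t_ids]
    q75, q25 = tumour.quantile(0.75), tumour.quantile(0.25)
    df = pd.DataFrame({
        "sd": tumour.std(ddof=1),
        "iqr": q75 - q25,
        "range": tumour.max() - tumour.min(),
        "frac_above_1sd": (restd.abs() > 1).mean(),
    })
    df.index.name = "pathway"
    return df.sort_values("sd", ascending=False)


def results_frame(results: Sequence[PathwayTestResult]) -> pd.DataFrame:
    """Flatten test results into the p + direction table shape."""
    return pd.DataFrame([{
        "pathway": r.pathway, "test": r.test,
        "statistic": r.statistic, "p_value": r.p_value,
        "direction": r.direction, "n_genes": r.n_genes,
        "n_tumour": r.n_tumour, "n_benign": r.n_benign,
    } for r in results])
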