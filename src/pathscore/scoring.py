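"""Reference-anchored z-scores, averaged pathway scores, and outlier calls.

The core statistic: each gene is standardized against the mean/SD of a
reference population (all tumours of a cohort, or the benign samples), and
a sample's pathway score is the arithmetic mean of its z-scores over the
pathway's measured genes. Tumours whose (re-standardized) pathway score
exceeds a +/- SD threshold are flagged as outliers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .expression_io import BENIGN, TUMOUR, ExpressionMatrix, SampleAnnotation
from .pathway_catalog import PathwayCatalog, intersect_with_matrix

logger = logging.getLogger(__name__)

MODE_COHORT = "cohort"
MODE_BENIGN = "benign"

SCALE_REFERENCE = "reference"  # re-standardize scores by the reference samples' score mean/SD
SCALE_RAW = "raw"              # threshold raw averaged-z scores directly


@dataclass(frozen=True)
class ReferenceScheme:
    """Which samples anchor the per-gene mean/SD."""

    mode: Literal["cohort", "benign"]
    reference_sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.mode not in (MODE_COHORT, MODE_BENIGN):
            raise ValueError(f"unknown reference mode {self.mode!r}")
        if len(self.reference_sample_ids) < 2:
            raise ValueError("reference scheme needs at least 2 reference samples")


@dataclass
class ZScoreMatrix:
    """Genes x samples z-values plus the scheme that produced them."""

    values: pd.DataFrame
    scheme: ReferenceScheme
    dropped_genes: tuple[str, ...] = ()

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class PathwayScoreMatrix:
    """Samples x pathways score matrix (mean z over each pathway's genes)."""

    values: pd.DataFrame
    scheme: ReferenceScheme
    gene_counts: Mapping[str, int]

    @property
    def pathways(self) -> list[str]:
        return list(self.values.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)


@dataclass(frozen=True)
class OutlierCall:
    sample_id: str
    pathway: str
    direction: Literal["up", "down", "none"]
    threshold_sd: float
    score: float


def _reference_ids(
    annotations: Sequence[SampleAnnotation],
    samples: Sequence[str],
    mode: str,
    cohort: Optional[str] = None,
) -> tuple[str, ...]:
    ann = {a.sample_id: a for a in annotations}
    present = [s for s in samples if s in ann]
    if mode == MODE_COHORT:
        ref = [s for s in present if ann[s].group == TUMOUR
               and (cohort is None or ann[s].cohort == cohort)]
    elif mode == MODE_BENIGN:
        ref = [s for s in present if ann[s].group == BENIGN]
    else:
        raise ValueError(f"unknown reference mode {mode!r}")
    return tuple(ref)


def zscore(
    matrix: ExpressionMatrix,
    annotations: Sequence[SampleAnnotation],
    mode: Literal["cohort", "benign"],
    cohort: Optional[str] = None,
) -> ZScoreMatrix:
    """Per-gene z-scores against the reference population's mean/SD.

    SD uses the n-1 denominator. Genes with zero reference SD are dropped
    (logged), never emitted as NaN/inf.
    """
    ref_ids = _reference_ids(annotations, matrix.samples, mode, cohort)
    if len(ref_ids) < 2:
        raise ValueError(
            f"reference mode {mode!r} resolved to {len(ref_ids)} samples; need >= 2"
        )
    scheme = ReferenceScheme(mode=mode, reference_sample_ids=ref_ids)
    ref = matrix.values[list(ref_ids)]
    mu = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=1)
    keep = sd > 0
    dropped = tuple(matrix.values.index[~keep])
    if dropped:
        logger.warning("zscore: dropping %d constant-reference genes: %s",
                       len(dropped), list(dropped)[:10])
    z = matrix.values.loc[keep].sub(mu[keep], axis=0).div(sd[keep], axis=0)
    return ZScoreMatrix(values=z, scheme=scheme, dropped_genes=dropped)


def pathway_scores(z: ZScoreMatrix, catalog: PathwayCatalog) -> PathwayScoreMatrix:
    """Average z over each pathway's measured genes, per sample.

    The catalog is intersected with the z-matrix's genes first; pathways
    with no measured genes are excluded from the output.
    """
    cat = intersect_with_matrix(catalog, z.genes)
    cols: dict[str, pd.Series] = {}
    gene_counts: dict[str, int] = {}
    for p in cat:
        if p.n_genes == 0:
            logger.warning("pathway_scores: excluding %r (no measured genes)", p.name)
            continue
        cols[p.name] = z.values.loc[list(p.genes)].mean(axis=0)
        gene_counts[p.name] = p.n_genes
    if not cols:
        raise ValueError("no pathway has measured genes")
    values = pd.DataFrame(cols)
    return PathwayScoreMatrix(values=values, scheme=z.scheme, gene_counts=gene_counts)


def restandardize(scores: PathwayScoreMatrix) -> pd.DataFrame:
    """Pathway scores re-expressed in units of the reference samples' score SD.

    Averaged z-scores have SD < 1 under the reference distribution (genes
    are averaged), so SD-threshold rules are applied on this scale: each
    pathway column is centred/scaled by the mean/SD (n-1) of the reference
    samples' scores for that pathway.
    """
    ref = scores.values.loc[list(scores.scheme.reference_sample_ids)]
    mu = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=1)
    if (sd <= 0).any():
        bad = list(sd.index[sd <= 0])
        raise ValueError(f"zero reference-score SD for pathways: {bad}")
    return (scores.values - mu) / sd


def flag_outliers(
    scores: PathwayScoreMatrix,
    annotations: Sequence[SampleAnnotation],
    threshold_sd: float = 2.0,
    scale: Literal["reference", "raw"] = SCALE_REFERENCE,
) -> list[OutlierCall]:
    """Call per-tumour, per-pathway outliers at a strict +/- SD threshold.

    ``scale="reference"`` (default) thresholds scores re-standardized by
    the reference samples' pathway-score mean/SD; ``scale="raw"``
    thresholds the raw averaged-z scores. Comparisons are strict, so a
    score exactly at the threshold is not an outlier.
    """
    if threshold_sd <= 0:
        raise ValueError("threshold_sd must be positive")
    values = restandardize(scores) if scale == SCALE_REFERENCE else scores.values
    ann = {a.sample_id: a for a in annotations}
    calls: list[OutlierCall] = []
    for sample in scores.samples:
        if ann.get(sample) is None or ann[sample].group != TUMOUR:
            continue
        for pathway in scores.pathways:
            s = float(values.loc[sample, pathway])
            if s > threshold_sd:
                direction = "up"
            elif s < -threshold_sd:
                direction = "down"
            else:
                direction = "none"
            calls.append(OutlierCall(sample_id=sample, pathway=pathway,
                                     direction=direction, threshold_sd=threshold_sd,
                                     score=s))
    return calls


def outlier_frame(calls: Sequence[OutlierCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"sample_id": c.sample_id, "pathway": c.pathway, "direction": c.direction,
          "threshold_sd": c.threshold_sd, "score": c.score} for c in calls]
    )
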