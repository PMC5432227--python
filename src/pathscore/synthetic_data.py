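"""Synthetic tumour/benign cohorts with planted pathway structure.

Generates gene-by-sample matrices with per-gene baselines plus noise,
pathway-coherent shifts injected into (subgroups of) tumours, matched
pairs sharing a latent profile, and survival times whose hazard depends on
a designated pathway's planted outlier status. Everything is seeded and a
truth record makes every injected effect recoverable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .expression_io import (
    BENIGN,
    PLATFORM_CONTINUOUS,
    PLATFORM_COUNTS,
    TUMOUR,
    ExpressionMatrix,
    SampleAnnotation,
)
from .pathway_catalog import PathwayCatalog, PathwayDefinition


@dataclass(frozen=True)
class PathwayEffect:
    """A planted shift: ``delta`` in benign-SD units on the log scale,
    applied to a ``subgroup_fraction`` of tumours (1.0 = all)."""

    delta: float
    subgroup_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.subgroup_fraction <= 1.0:
            raise ValueError("subgroup_fraction must be in (0, 1]")


@dataclass
class SyntheticConfig:
    n_benign: int
    n_tumour: int
    catalog: PathwayCatalog
    n_genes: int
    seed: int
    effects: Mapping[str, PathwayEffect] = field(default_factory=dict)
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    noise_sd: float = 1.0
    cohort: str = "SYN"
    platform: str = PLATFORM_CONTINUOUS
    # matched pairs
    n_pairs: int = 0
    pair_correlation: Optional[float] = None
    # survival
    survival_pathway: Optional[str] = None
    hazard_baseline: float = 0.02
    hazard_ratio: float = 1.0
    censoring_rate: float = 0.3

    def __post_init__(self) -> None:
        if min(self.n_benign, self.n_tumour, self.n_genes) < 1:
            raise ValueError("counts must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must be in [0, 1)")
        catalog_genes = {g for p in self.catalog for g in p.genes}
        if len(catalog_genes) > self.n_genes:
            raise ValueError("n_genes smaller than the catalog's gene universe")
        for name in self.effects:
            if name not in self.catalog.names():
                raise ValueError(f"effect on unknown pathway {name!r}")


@dataclass
class TruthRecord:
    """What was planted: per pathway, the shift and the affected tumours."""

    effects: dict[str, PathwayEffect]
    affected: dict[str, tuple[str, ...]]
    outlier_samples: tuple[str, ...] = ()

    def to_json(self, path: str | Path) -> None:
        payload = {
            "effects": {k: {"delta": v.delta, "subgroup_fraction": v.subgroup_fraction}
                        for k, v in self.effects.items()},
            "affected": {k: list(v) for k, v in self.affected.items()},
            "outlier_samples": list(self.outlier_samples),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        payload = json.loads(Path(path).read_text())
        return cls(
            effects={k: PathwayEffect(**v) for k, v in payload["effects"].items()},
            affected={k: tuple(v) for k, v in payload["affected"].items()},
            outlier_samples=tuple(payload["outlier_samples"]),
        )


def _gene_universe(catalog: PathwayCatalog, n_genes: int) -> list[str]:
    """Catalog genes in first-appearance order, padded with background ids."""
    genes: list[str] = []
    seen: set[str] = set()
    for p in catalog:
        for g in p.genes:
            if g not in seen:
                seen.add(g)
                genes.append(g)
    i = 0
    while len(genes) < n_genes:
        i += 1
        cand = f"g{i:04d}"
        if cand not in seen:
            seen.add(cand)
            genes.append(cand)
    return genes


def synthetic_catalog(
    n_pathways: int = 3, genes_per_pathway: int = 10, min_testable_genes: int = 6
) -> PathwayCatalog:
    """A disjoint-block catalog over synthetic gene ids g0001, g0002, ..."""
    pathways = []
    g = 0
    for i in range(n_pathways):
        genes = tuple(f"g{g + j + 1:04d}" for j in range(genes_per_pathway))
        g += genes_per_pathway
        pathways.append(PathwayDefinition(name=f"pathway_{i + 1:02d}", genes=genes,
                                          description="synthetic block"))
    return PathwayCatalog(pathways=tuple(pathways), min_testable_genes=min_testable_genes)


def simulate_cohort(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, list[SampleAnnotation], TruthRecord]:
    """Benign baseline + noise; tumours additionally carry planted pathway
    shifts (delta x noise SD added to every gene of the pathway, for the
    affected tumour subgroup)."""
    rng = np.random.default_rng(config.seed)
    genes = _gene_universe(config.catalog, config.n_genes)
    benign_ids = [f"B{i + 1:03d}" for i in range(config.n_benign)]
    tumour_ids = [f"T{i + 1:03d}" for i in range(config.n_tumour)]
    samples = benign_ids + tumour_ids

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    signal = baseline[:, None] + rng.normal(
        0.0, config.noise_sd, size=(config.n_genes, len(samples))
    )

    gene_index = {g: i for i, g in enumerate(genes)}
    affected: dict[str, tuple[str, ...]] = {}
    for name, eff in config.effects.items():
        pathway = config.catalog[name]
        n_aff = max(1, int(round(eff.subgroup_fraction * config.n_tumour)))
        chosen = sorted(rng.choice(config.n_tumour, size=n_aff, replace=False))
        aff_ids = tuple(tumour_ids[i] for i in chosen)
        affected[name] = aff_ids
        rows = [gene_index[g] for g in pathway.genes]
        cols = [config.n_benign + i for i in chosen]
        signal[np.ix_(rows, cols)] += eff.delta * config.noise_sd

    values = pd.DataFrame(signal, index=genes, columns=samples)
    if config.platform == PLATFORM_COUNTS:
        depth = rng.lognormal(mean=0.0, sigma=0.25, size=len(samples))
        lam = depth[None, :] * np.exp2(values.to_numpy())
        values = pd.DataFrame(rng.poisson(lam).astype(float), index=genes, columns=samples)
        matrix = ExpressionMatrix(values=values, platform=PLATFORM_COUNTS)
    elif config.platform == PLATFORM_CONTINUOUS:
        matrix = ExpressionMatrix(values=values, platform=PLATFORM_CONTINUOUS)
    else:
        raise ValueError(f"unknown platform {config.platform!r}")

    annotations = [
        SampleAnnotation(sample_id=s, group=BENIGN, cohort=config.cohort) for s in benign_ids
    ] + [
        SampleAnnotation(sample_id=s, group=TUMOUR, cohort=config.cohort) for s in tumour_ids
    ]
    truth = TruthRecord(effects=dict(config.effects), affected=affected)
    if config.survival_pathway is not None:
        truth.outlier_samples = affected.get(config.survival_pathway, ())
    return matrix, annotations, truth


def simulate_pairs(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, list[SampleAnnotation], TruthRecord]:
    """Cohort whose first 2*n_pairs tumours form matched pairs.

    Pair members mix a shared latent profile with independent noise so the
    expected within-pair correlation of their (gene-standardized) profiles
    equals ``pair_correlation``.
    """
    rho = config.pair_correlation
    if rho is None or not 0.0 <= rho < 1.0:
        raise ValueError("pair_correlation must be in [0, 1)")
    if config.n_pairs < 1:
        raise ValueError("n_pairs must be >= 1 for simulate_pairs")
    if 2 * config.n_pairs > config.n_tumour:
        raise ValueError("n_tumour too small for the requested pairs")

    rng = np.random.default_rng(config.seed)
    genes = _gene_universe(config.catalog, config.n_genes)
    benign_ids = [f"B{i + 1:03d}" for i in range(config.n_benign)]
    tumour_ids = [f"T{i + 1:03d}" for i in range(config.n_tumour)]
    samples = benign_ids + tumour_ids
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)

    deviations = rng.normal(0.0, 1.0, size=(config.n_genes, len(samples)))
    pair_map: dict[str, str] = {}
    col = {s: j for j, s in enumerate(samples)}
    for p in range(config.n_pairs):
        a, b = tumour_ids[2 * p], tumour_ids[2 * p + 1]
        pair_map[a] = pair_map[b] = f"pair{p + 1:02d}"
        latent = rng.normal(0.0, 1.0, size=config.n_genes)
        for sid in (a, b):
            eps = rng.normal(0.0, 1.0, size=config.n_genes)
            deviations[:, col[sid]] = np.sqrt(rho) * latent + np.sqrt(1.0 - rho) * eps
    signal = baseline[:, None] + config.noise_sd * deviations

    gene_index = {g: i for i, g in enumerate(genes)}
    affected: dict[str, tuple[str, ...]] = {}
    for name, eff in config.effects.items():
        pathway = config.catalog[name]
        n_aff = max(1, int(round(eff.subgroup_fraction * config.n_tumour)))
        chosen = sorted(rng.choice(config.n_tumour, size=n_aff, replace=False))
        affected[name] = tuple(tumour_ids[i] for i in chosen)
        rows = [gene_index[g] for g in pathway.genes]
        cols = [config.n_benign + i for i in chosen]
        signal[np.ix_(rows, cols)] += eff.delta * config.noise_sd

    values = pd.DataFrame(signal, index=genes, columns=samples)
    matrix = ExpressionMatrix(values=values, platform=PLATFORM_CONTINUOUS)
    annotations = [
        SampleAnnotation(sample_id=s, group=BENIGN, cohort=config.cohort)
        for s in benign_ids
    ] + [
        SampleAnnotation(sample_id=s, group=TUMOUR, cohort=config.cohort,
                         pair_id=pair_map.get(s))
        for s in tumour_ids
    ]
    truth = TruthRecord(effects=dict(config.effects), affected=affected)
    if config.survival_pathway is not None:
        truth.outlier_samples = affected.get(config.survival_pathway, ())
    return matrix, annotations, truth


def _uniform_censor_bound(hazard: float, rate: float) -> float:
    """Upper bound u of Uniform(0, u) censoring so that a subject with
    exponential hazard ``hazard`` is censored with probability ``rate``."""
    # P(C < T) = (1 - exp(-h u)) / (h u), decreasing from 1 (u->0) to 0
    f = lambda u: (1.0 - np.exp(-hazard * u)) / (hazard * u) - rate
    lo, hi = 1e-9, 1.0
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError("cannot achieve requested censoring rate")
    return float(brentq(f, lo, hi))


def simulate_survival(
    truth: TruthRecord,
    config: SyntheticConfig,
    annotations: list[SampleAnnotation],
) -> list[SampleAnnotation]:
    """Attach exponential survival times to tumour samples.

    Hazard is ``hazard_baseline`` for non-outliers and hazard_baseline x
    hazard_ratio for planted outliers; censoring is independent
    Uniform(0, u) with u tuned to the configured rate under the baseline
    hazard (0 disables censoring).
    """
    rng = np.random.default_rng(config.seed + 2)
    outliers = set(truth.outlier_samples)
    u_bound = (
        _uniform_censor_bound(config.hazard_baseline, config.censoring_rate)
        if config.censoring_rate > 0 else None
    )
    out: list[SampleAnnotation] = []
    for a in annotations:
        if a.group != TUMOUR:
            out.append(a)
            continue
        h = config.hazard_baseline * (config.hazard_ratio if a.sample_id in outliers else 1.0)
        t_event = rng.exponential(1.0 / h)
        if u_bound is None:
            time, event = t_event, True
        else:
            c = rng.uniform(0.0, u_bound)
            time, event = (t_event, True) if t_event <= c else (c, False)
        out.append(SampleAnnotation(
            sample_id=a.sample_id, group=a.group, cohort=a.cohort, pair_id=a.pair_id,
            time_to_event=float(time), event=bool(event), stage=a.stage,
        ))
    return out
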