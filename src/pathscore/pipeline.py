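"""End-to-end run: catalog -> normalize -> score -> test -> cluster -> survive.

A run is driven by a :class:`RunConfig` (loadable from YAML), writes every
stage's output into one directory named by the config hash, and echoes the
config verbatim for auditability.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .clustering import cluster_samples, cut, to_newick
from .expression_io import (
    PLATFORM_CONTINUOUS,
    PLATFORM_COUNTS,
    align,
    read_annotations,
    read_expression,
)
from .group_tests import results_frame, wilcoxon_pathway_test
from .normalization import apply_size_factors, log2_transform, quantile_normalize, size_factors
from .pathway_catalog import default_catalog, intersect_with_matrix, load_gmt, testable
from .scoring import flag_outliers, outlier_frame, pathway_scores, zscore
from .survival import km_estimate, logrank_test, stratify_by_outlier

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    expression: str
    annotations: str
    platform: str = PLATFORM_CONTINUOUS
    catalog: Optional[str] = None           # None -> bundled 23-pathway catalog
    reference: str = "benign"               # cohort | benign
    cohort: Optional[str] = None
    quantile: bool = False                  # quantile-normalize continuous input
    pseudocount: float = 1.0
    outlier_threshold: float = 2.0
    outlier_scale: str = "reference"
    alpha: float = 0.05
    distance: str = "euclidean"
    linkage: str = "average"
    n_clusters: int = 2
    survival_pathways: list[str] = field(default_factory=list)
    survival_direction: str = "up"
    time_horizon: Optional[float] = None
    out_dir: Optional[str] = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def validate_paths(self) -> None:
        for p in [self.expression, self.annotations, self.catalog]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured path does not exist: {p}")


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the run directory.

    Stages that cannot run (e.g. survival without time/event columns) are
    skipped with a logged reason rather than aborting the whole run.
    """
    config.validate_paths()
    run_dir = Path(config.out_dir) if config.out_dir else Path(f"run-{config.digest()}")
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.yaml").write_text(yaml.safe_dump(asdict(config), sort_keys=True))
    summary: dict = {"stages": {}}

    def fail(stage: str, exc: Exception):
        summary["stages"][stage] = f"failed: {exc}"
        (run_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # --- load
    try:
        matrix = read_expression(config.expression, platform=config.platform)
        annotations = read_annotations(config.annotations)
        matrix, annotations = align(matrix, annotations)
        catalog = load_gmt(config.catalog) if config.catalog else default_catalog()
    except Exception as exc:  # noqa: BLE001
        fail("load", exc)
    summary["stages"]["load"] = f"{matrix.shape[0]} genes x {matrix.shape[1]} samples"

    # --- normalize
    try:
        if config.platform == PLATFORM_COUNTS:
            factors = size_factors(matrix)
            matrix = apply_size_factors(matrix, factors)
            matrix = log2_transform(matrix, pseudocount=config.pseudocount)
            summary["stages"]["normalize"] = "size factors + log2"
        elif config.quantile:
            matrix = quantile_normalize(matrix)
            summary["stages"]["normalize"] = "quantile"
        else:
            summary["stages"]["normalize"] = "none (input used as-is)"
    except Exception as exc:  # noqa: BLE001
        fail("normalize", exc)

    # --- score
    try:
        z = zscore(matrix, annotations, mode=config.reference, cohort=config.cohort)
        scores = pathway_scores(z, catalog)
        scores.values.to_csv(run_dir / "pathway_scores.tsv", sep="\t",
                             index_label="sample_id", float_format="%.10g")
        calls = flag_outliers(scores, annotations, threshold_sd=config.outlier_threshold,
                              scale=config.outlier_scale)
        outlier_frame(calls).to_csv(run_dir / "outliers.tsv", sep="\t", index=False,
                                    float_format="%.10g")
    except Exception as exc:  # noqa: BLE001
        fail("score", exc)
    summary["stages"]["score"] = f"{len(scores.pathways)} pathways scored"

    # --- test
    try:
        cat = intersect_with_matrix(catalog, z.genes)
        results = wilcoxon_pathway_test(scores, annotations, alpha=config.alpha,
                                        min_genes=cat.min_testable_genes)
        results_frame(results).to_csv(run_dir / "pathway_tests.tsv", sep="\t",
                                      index=False, float_format="%.6g")
        summary["stages"]["test"] = (
            f"{sum(r.p_value is not None for r in results)} tested, "
            f"{len(results) - sum(r.p_value is not None for r in results)} below gene floor"
        )
        summary["testable_pathways"] = testable(cat)
    except Exception as exc:  # noqa: BLE001
        fail("test", exc)

    # --- cluster
    try:
        dendrogram = cluster_samples(scores, distance=config.distance, linkage=config.linkage)
        (run_dir / "dendrogram.nwk").write_text(to_newick(dendrogram) + "\n")
        labels = cut(dendrogram, config.n_clusters)
        with (run_dir / "clusters.tsv").open("w") as fh:
            fh.write("sample_id\tcluster\n")
            for s in dendrogram.leaf_order:
                fh.write(f"{s}\t{labels[s]}\n")
        (run_dir / "leaf_order.json").write_text(
            json.dumps({"leaf_order": list(dendrogram.leaf_order)}, indent=2))
        summary["stages"]["cluster"] = f"{config.linkage}/{config.distance}, k={config.n_clusters}"
    except Exception as exc:  # noqa: BLE001
        fail("cluster", exc)

    # --- survive
    surv_results = {}
    have_survival = any(a.time_to_event is not None for a in annotations)
    if config.survival_pathways and have_survival:
        try:
            for pathway in config.survival_pathways:
                data = stratify_by_outlier(calls, pathway, config.survival_direction,
                                           annotations)
                if config.time_horizon is not None:
                    data = data.truncate(config.time_horizon)
                curves = km_estimate(data)
                for label, curve in curves.items():
                    curve.frame().to_csv(
                        run_dir / f"km_{_slug(pathway)}_{label}.tsv", sep="\t",
                        index=False, float_format="%.10g")
                surv_results[pathway] = {
                    name: {"chi_square": r.statistic, "p_value": r.p_value}
                    for name, r in (
                        ("mantel_cox", logrank_test(data, "mantel_cox")),
                        ("gehan_breslow", logrank_test(data, "gehan_breslow")),
                    )
                }
            (run_dir / "survival_tests.json").write_text(
                json.dumps(surv_results, indent=2, sort_keys=True))
            summary["stages"]["survive"] = f"{len(surv_results)} pathway(s) tested"
        except Exception as exc:  # noqa: BLE001
            fail("survive", exc)
    else:
        summary["stages"]["survive"] = "skipped (no survival pathways/annotations)"

    summary["config_digest"] = config.digest()
    (run_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return run_dir


def _slug(name: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in name).strip("_")
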