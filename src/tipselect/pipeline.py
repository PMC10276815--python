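"""End-to-end prioritization pipeline and the synthetic study bundle.

``run_pipeline`` executes rank-product meta-analysis, marker-specificity
scoring and the GOT-IT cascade in order from one declarative config, writing
the decision table, funnel and run report.  ``generate_bundle`` materializes
a complete synthetic study (rank lists, expression bundle, annotations,
assay and competition tables, truth JSON) so the pipeline can be exercised
without any external data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .gotit import Thresholds, apply_assessment_blocks, phenotype_condition_enrichment, select_candidates
from .markers import cluster_marker_stats
from .rankprod import rank_product_analysis
from .simulate import (
    PAPER_LIKE_ARCHETYPES,
    PAPER_LIKE_CANDIDATES,
    ExpressionConfig,
    RankListConfig,
    paper_like_gene_panel,
    simulate_annotations,
    simulate_assays,
    simulate_competition,
    simulate_expression,
    simulate_ranklists,
)

__all__ = ["PipelineConfig", "run_pipeline", "generate_bundle"]

FLOAT_FORMAT = "%.10g"  # fixed numeric formatting keeps reruns byte-identical


@dataclass
class PipelineConfig:
    """Declarative description of one prioritization run."""

    rank_lists: list[str]
    annotations: str
    mtx: str
    features: str
    barcodes: str
    labels: str
    out_dir: str
    target_cluster: str = "tip"
    disease_condition: str = "tumor"
    seed: int = 0
    n_perm: int = 100_000
    mode: str = "montecarlo"
    pre_ranked: bool = False
    missing_policy: str = "intersect"
    max_cells_per_cluster: int = 1000
    thresholds: Thresholds = field(default_factory=Thresholds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        thr = Thresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thr, **raw)

    def validate(self) -> None:
        for p in [self.annotations, self.mtx, self.features, self.barcodes, self.labels, *self.rank_lists]:
            if not Path(p).exists():
                raise FileNotFoundError(f"input file missing: {p}")


def run_pipeline(config: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    """rankprod -> markers -> cascade; returns (decision table, run report).

    Writes rankprod.tsv, markers.tsv, decisions.tsv, candidates.tsv,
    funnel.json and report.json into the configured output directory.
    Deterministic given the config's seed: reruns produce byte-identical
    decision tables.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _config_dict(config), "stages": {}}

    # stage 1: rank-product congruence meta-analysis
    lists = [tio.read_rank_list(p, pre_ranked=config.pre_ranked) for p in config.rank_lists]
    ranked = rank_product_analysis(
        lists,
        missing=config.missing_policy,
        mode=config.mode,
        n_perm=config.n_perm,
        seed=config.seed,
    )
    ranked.to_csv(out / "rankprod.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)
    report["stages"]["rankprod"] = {
        "datasets": [lst.dataset_id for lst in lists],
        "genes_tested": int(len(ranked)),
        "seed": config.seed,
        "n_perm": config.n_perm,
    }

    # stage 2: marker-specificity scoring on the labeled atlas
    matrix = tio.read_expression_bundle(config.mtx, config.features, config.barcodes, config.labels)
    stats = cluster_marker_stats(
        matrix,
        target_cluster=config.target_cluster,
        max_cells_per_cluster=config.max_cells_per_cluster,
        seed=config.seed,
    )
    stats.reset_index(drop=True).to_csv(
        out / "markers.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT
    )
    if matrix.conditions is not None:
        enrichment = phenotype_condition_enrichment(matrix.cell_labels, matrix.conditions)
    else:
        enrichment = None
    report["stages"]["markers"] = {
        "cells": matrix.n_cells,
        "genes": matrix.n_genes,
        "target_cluster": config.target_cluster,
        "positive_markers_tested": int(stats["p_value"].notna().sum()),
    }

    # stage 3: GOT-IT cascade over the top-N congruent genes
    annotations = tio.read_annotations(config.annotations)
    top_genes = list(ranked.head(config.thresholds.top_n)["gene_id"])
    decisions = apply_assessment_blocks(
        annotations,
        stats,
        enrichment,
        thresholds=config.thresholds,
        phenotype=config.target_cluster,
        disease_condition=config.disease_condition,
        genes=top_genes,
    )
    candidates, funnel = select_candidates(ranked, decisions, thresholds=config.thresholds)
    decisions.reset_index(drop=True).to_csv(
        out / "decisions.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT
    )
    candidates.to_csv(out / "candidates.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)
    with open(out / "funnel.json", "w") as fh:
        json.dump(funnel, fh, indent=2, sort_keys=True)
        fh.write("\n")
    report["stages"]["cascade"] = funnel
    report["manifest"] = sorted(
        p.name for p in out.iterdir() if p.suffix in (".tsv", ".json")
    )
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return decisions, report


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["thresholds"] = asdict(config.thresholds)
    return d


def generate_bundle(
    out_dir: str | Path,
    seed: int = 0,
    n_genes: int = 200,
    panel_size: int = 50,
    concordance_noise: float = 1.0,
    cells_per_cluster: int = 150,
    n_background_genes: int = 2000,
) -> dict:
    """Write a complete synthetic study that mirrors the published cascade.

    The planted top-``panel_size`` panel contains the six true candidates and
    the named failure archetypes; the expression matrix plants strong
    tip-cluster folds for every panel gene except the low-specificity
    archetypes; annotations encode the AB2/AB4 failures.  Returns a manifest
    of the written paths plus the truth dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = paper_like_gene_panel(panel_size)

    lists, rank_truth = simulate_ranklists(
        RankListConfig(
            seed=seed,
            n_genes=n_genes,
            k=3,
            n_planted=panel_size,
            concordance_noise=concordance_noise,
            planted_genes=tuple(panel),
        )
    )
    list_paths = []
    for lst in lists:
        p = out / f"{lst.dataset_id}.tsv"
        tio.write_rank_list(lst, p)
        list_paths.append(str(p))

    folds = {}
    for g in panel:
        if g == "SOX4":
            folds[g] = 1.0  # not tip-specific at all
        elif g == "FAM43A":
            folds[g] = float(np.exp(0.5))  # enriched, but below the logFC>1 bar
        else:
            folds[g] = float(np.exp(1.5))
    all_gene_ids = panel + [f"BG{i:04d}" for i in range(1, n_background_genes + 1)]
    matrix, expr_truth = simulate_expression(
        ExpressionConfig(
            seed=seed + 1,
            gene_ids=all_gene_ids,
            cluster_cells={
                "tip": cells_per_cluster,
                "vein": cells_per_cluster,
                "immune": cells_per_cluster,
                "stromal": cells_per_cluster,
            },
            planted_folds=folds,
        )
    )
    bundle_paths = tio.write_expression_bundle(matrix, out / "expression")

    annotations = simulate_annotations(panel, profile="paper_like", seed=seed + 2)
    ann_path = out / "annotations.tsv"
    tio.write_annotations(annotations, ann_path)

    assays, assay_truth = simulate_assays(seed=seed + 3)
    assay_path = out / "assays.csv"
    assays.to_csv(assay_path, index=False, float_format=FLOAT_FORMAT)

    rows = []
    for cond, p_tip in (("control", 0.5), ("silenced", 0.38)):
        k, n = simulate_competition(n_spheroids=60, p_tip=p_tip, seed=seed + 4)
        rows.append({"condition": cond, "k_silenced_at_tip": k, "n_tips_total": n})
    comp_path = out / "competition.csv"
    pd.DataFrame(rows).to_csv(comp_path, index=False)

    truth = {
        "ranklists": rank_truth,
        "expression": expr_truth,
        "assays": assay_truth,
        "panel": panel,
        "expected_candidates": PAPER_LIKE_CANDIDATES,
        "archetypes": PAPER_LIKE_ARCHETYPES,
    }
    tio.write_truth(truth, out / "truth.json")

    manifest = {
        "rank_lists": list_paths,
        "annotations": str(ann_path),
        "mtx": str(bundle_paths["mtx"]),
        "features": str(bundle_paths["features"]),
        "barcodes": str(bundle_paths["barcodes"]),
        "labels": str(bundle_paths["labels"]),
        "assays": str(assay_path),
        "competition": str(comp_path),
        "truth": str(out / "truth.json"),
    }
    return {"paths": manifest, "truth": truth}
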