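"""Synthetic-data generators that plant known truth into every pipeline input.

Each generator is a pure function of its configuration (same seed, same
output) and records the planted truth alongside the data so downstream
recovery can be scored without external references:

  * K ranked marker lists with a planted congruent gene set and tunable
    rank-jitter noise — emulates per-dataset tip-cell marker rankings;
  * a negative-binomial cell x gene count matrix with a minority "tip"
    cluster carrying planted mean-scale fold-changes — emulates the labeled
    tumor-microenvironment atlas used for specificity scoring;
  * annotation tables with configurable profiles, including one that mirrors
    the archetypes of the published cascade (six passers, a disease-linked
    gene, an already-described gene, over-published genes, a secreted gene,
    low-specificity genes);
  * binomial tip-occupancy counts for the mosaic-spheroid competition assay;
  * Gaussian replicate assay measurements with planted multiplicative
    effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .gotit import FALSE, TRUE, UNKNOWN
from .markers import ExpressionMatrix
from .rankprod import ScoredGeneList

__all__ = [
    "RankListConfig",
    "ExpressionConfig",
    "simulate_ranklists",
    "simulate_expression",
    "simulate_annotations",
    "simulate_marker_stats",
    "simulate_competition",
    "simulate_assays",
    "PAPER_LIKE_CANDIDATES",
    "PAPER_LIKE_ARCHETYPES",
    "paper_like_gene_panel",
]


# ---------------------------------------------------------------------------
# ranked lists


@dataclass(frozen=True)
class RankListConfig:
    """Configuration for the congruent-rank-list generator.

    ``concordance_noise`` is the standard deviation (in rank units) of the
    Gaussian jitter applied independently per dataset to each planted gene's
    target position; 0 puts the planted genes at ranks 1..n_planted in every
    list.
    """

    seed: int
    n_genes: int = 200
    k: int = 3
    n_planted: int = 10
    concordance_noise: float = 5.0
    planted_genes: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_planted >= self.n_genes:
            raise ValueError("n_planted must be smaller than n_genes")
        if self.concordance_noise < 0:
            raise ValueError("concordance_noise must be >= 0")
        if self.k < 2:
            raise ValueError("need at least two datasets")
        if self.planted_genes is not None and len(self.planted_genes) != self.n_planted:
            raise ValueError("planted_genes length must equal n_planted")


def _gene_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def simulate_ranklists(config: RankListConfig) -> tuple[list[ScoredGeneList], dict]:
    """K scored lists in which the planted genes sit near the top of each.

    Planted gene i targets position i, perturbed by Gaussian jitter
    independently per dataset; the non-planted genes fill the remaining
    positions in random (exchangeable) order.  Scores are n - position + 1,
    so ranking by score recovers the latent positions exactly.
    """
    rng = np.random.default_rng(config.seed)
    if config.planted_genes is not None:
        planted = list(config.planted_genes)
        fillers = [g for g in _gene_names(config.n_genes) if g not in set(planted)]
        genes = np.array(planted + fillers[: config.n_genes - len(planted)])
    else:
        genes = np.array(_gene_names(config.n_genes))
    planted_set = list(genes[: config.n_planted])

    lists = []
    for d in range(config.k):
        latent = np.empty(config.n_genes)
        target = np.arange(1, config.n_planted + 1, dtype=float)
        latent[: config.n_planted] = target + config.concordance_noise * rng.standard_normal(
            config.n_planted
        )
        filler = np.arange(config.n_planted + 1, config.n_genes + 1, dtype=float)
        latent[config.n_planted :] = rng.permutation(filler)
        order = np.argsort(latent, kind="stable")  # position 0 = best
        position = np.empty(config.n_genes, dtype=float)
        position[order] = np.arange(1, config.n_genes + 1)
        scores = config.n_genes - position + 1
        lists.append(
            ScoredGeneList(dataset_id=f"dataset_{d + 1}", genes=list(genes), scores=scores)
        )
    truth = {
        "planted_genes": planted_set,
        "n_genes": config.n_genes,
        "k": config.k,
        "concordance_noise": config.concordance_noise,
        "seed": config.seed,
    }
    return lists, truth


# ---------------------------------------------------------------------------
# expression matrix


@dataclass
class ExpressionConfig:
    """Configuration for the negative-binomial count-matrix generator.

    ``cluster_cells`` maps cluster name -> cell count; one cluster is the
    ``tip_cluster``.  ``planted_folds`` maps gene -> mean-scale fold applied
    in the tip cluster only.  ``dispersion`` is the NB shape theta
    (var = mu + mu^2 / theta); smaller theta = noisier counts.
    ``tip_tumor_fraction`` controls the condition labels: tip cells are
    "tumor" with that probability, other clusters 50:50.
    """

    seed: int
    n_genes: int = 1000
    gene_ids: list[str] | None = None  # explicit names override n_genes naming
    cluster_cells: dict[str, int] = field(
        default_factory=lambda: {"tip": 200, "vein": 200, "immune": 200, "stromal": 200}
    )
    tip_cluster: str = "tip"
    # markers must stay a small fraction of the library, else library-size
    # normalization visibly compresses the planted fold (composition effect)
    baseline_mean: float = 1.0
    marker_mean: float = 3.0
    dispersion: float = 2.0
    planted_folds: dict[str, float] = field(default_factory=dict)
    tip_tumor_fraction: float = 0.993

    def __post_init__(self) -> None:
        if self.tip_cluster not in self.cluster_cells:
            raise ValueError(f"tip cluster {self.tip_cluster!r} missing from cluster_cells")
        if len(self.cluster_cells) < 2:
            raise ValueError("need at least two clusters")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        for g, f in self.planted_folds.items():
            if f <= 0:
                raise ValueError(f"fold for {g!r} must be positive, got {f}")


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """Negative binomial with mean ``mean`` and shape theta (var = mu + mu^2/theta)."""
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p)


def simulate_expression(config: ExpressionConfig) -> tuple[ExpressionMatrix, dict]:
    """NB counts with cluster structure and planted tip-cluster fold-changes.

    Genes named in ``planted_folds`` get a raised baseline (``marker_mean``)
    so their fold is measurable above sampling noise; all other genes share
    ``baseline_mean``.  The fold multiplies the mean in the tip cluster only.
    """
    rng = np.random.default_rng(config.seed)
    if config.gene_ids is not None:
        genes = list(config.gene_ids)
        config.n_genes = len(genes)
    else:
        genes = _gene_names(config.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    for g in config.planted_folds:
        if g not in gene_index:
            raise ValueError(f"planted gene {g!r} not among the simulated genes")

    base = np.full(config.n_genes, config.baseline_mean)
    # mild gene-to-gene variability so library sizes are not identical
    base = base * rng.lognormal(mean=0.0, sigma=0.25, size=config.n_genes)
    for g in config.planted_folds:
        base[gene_index[g]] = config.marker_mean

    blocks, barcodes, labels, conditions = [], [], [], []
    cell_no = 0
    for cluster in config.cluster_cells:  # dict order is deterministic
        n_cells = config.cluster_cells[cluster]
        mu = base.copy()
        if cluster == config.tip_cluster:
            for g, f in config.planted_folds.items():
                mu[gene_index[g]] *= f
        counts = _nb_sample(rng, np.tile(mu, (n_cells, 1)), config.dispersion)
        blocks.append(sp.csr_matrix(counts))
        p_tumor = config.tip_tumor_fraction if cluster == config.tip_cluster else 0.5
        cond = np.where(rng.random(n_cells) < p_tumor, "tumor", "normal")
        for i in range(n_cells):
            barcodes.append(f"CELL{cell_no + i:05d}")
        cell_no += n_cells
        labels.extend([cluster] * n_cells)
        conditions.extend(cond.tolist())

    counts = sp.vstack(blocks, format="csr")
    matrix = ExpressionMatrix(
        counts=counts,
        gene_ids=genes,
        barcodes=barcodes,
        cell_labels=pd.Series(labels, index=barcodes),
        conditions=pd.Series(conditions, index=barcodes),
    )
    truth = {
        "planted_folds": dict(config.planted_folds),
        "planted_logfc": {g: float(np.log(f)) for g, f in config.planted_folds.items()},
        "tip_cluster": config.tip_cluster,
        "tip_tumor_fraction": config.tip_tumor_fraction,
        "seed": config.seed,
    }
    return matrix, truth


# ---------------------------------------------------------------------------
# annotations

# the six genes the cascade should keep, and the named failure archetypes
PAPER_LIKE_CANDIDATES = ["CD93", "TCF4", "ADGRL4", "GJA1", "CCDC85B", "MYH9"]
PAPER_LIKE_ARCHETYPES = {
    "SPARC": "ab2",  # disease-linked (central nervous system disorders)
    "SEMA6B": "ab2",  # disease-linked (progressive myoclonic epilepsy)
    "SMAD1": "ab4",  # already described in ECs and tip cells
    "SOX4": "ab5",  # not tip-EC specific
    "FAM43A": "ab5",  # low tip-EC specificity
}


def paper_like_gene_panel(n_genes: int = 50) -> list[str]:
    """A top-N candidate panel containing the named passers and archetypes.

    Filler genes (TIPM01, TIPM02, ...) pad the panel to ``n_genes``.
    """
    named = PAPER_LIKE_CANDIDATES + list(PAPER_LIKE_ARCHETYPES)
    if n_genes < len(named):
        raise ValueError(f"panel needs at least {len(named)} genes")
    fillers = [f"TIPM{i:02d}" for i in range(1, n_genes - len(named) + 1)]
    return named + fillers


def simulate_annotations(
    gene_ids: list[str], profile: str, seed: int
) -> pd.DataFrame:
    """Annotation table for the cascade under a named profile.

    ``all_pass`` makes every gene pass AB2/AB4/AB5 flags; ``all_unknown``
    leaves every three-valued flag unknown (fail-safe exclusion downstream);
    ``paper_like`` plants exactly the six passing genes and the named
    failure archetypes, with filler genes failing AB4 on publication counts.
    """
    rng = np.random.default_rng(seed)
    if profile not in ("paper_like", "all_pass", "all_unknown"):
        raise ValueError(f"unknown profile {profile!r}")

    rows = []
    for g in gene_ids:
        row = {
            "gene_id": g,
            "pub_count_angiogenesis": int(rng.integers(0, 20)),
            "pub_count_tip": int(rng.integers(0, 3)),
            "previously_described_tip": FALSE,
            "secreted": FALSE,
            "disease_link": FALSE,
            "disease_note": "",
            "perturbagen_available": True,
        }
        if profile == "all_unknown":
            row.update(
                previously_described_tip=UNKNOWN,
                secreted=UNKNOWN,
                disease_link=UNKNOWN,
            )
        elif profile == "paper_like":
            if g in PAPER_LIKE_CANDIDATES:
                pass  # passing defaults
            elif g == "SPARC":
                row.update(
                    disease_link=TRUE,
                    disease_note="linked to disorders of the central nervous system",
                )
            elif g == "SEMA6B":
                row.update(
                    disease_link=TRUE,
                    disease_note="associated with progressive myoclonic epilepsy",
                )
            elif g == "SMAD1":
                row.update(
                    previously_described_tip=TRUE,
                    pub_count_tip=int(rng.integers(3, 10)),
                )
            elif g in ("SOX4", "FAM43A"):
                pass  # these fail AB5 via the specificity stats, not annotation
            else:
                # filler genes: too well described for AB4
                failure = rng.integers(0, 3)
                if failure == 0:
                    row["pub_count_angiogenesis"] = int(rng.integers(20, 200))
                elif failure == 1:
                    row["pub_count_tip"] = int(rng.integers(3, 15))
                else:
                    row["previously_described_tip"] = TRUE
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id", drop=False)


def simulate_marker_stats(gene_ids: list[str], profile: str, seed: int) -> pd.DataFrame:
    """Companion specificity table for an annotation profile.

    Under ``paper_like``, SOX4 gets a non-specific profile (logfc well
    below 1) and FAM43A a borderline one (just below 1); every other gene
    clears the logFC > 1 rule.
    """
    rng = np.random.default_rng(seed)
    if profile not in ("paper_like", "all_pass", "all_unknown"):
        raise ValueError(f"unknown profile {profile!r}")
    rows = []
    for g in gene_ids:
        lfc = float(rng.uniform(1.3, 2.5))
        if profile == "paper_like":
            if g == "SOX4":
                lfc = float(rng.uniform(0.0, 0.4))
            elif g == "FAM43A":
                lfc = float(rng.uniform(0.6, 0.95))
        rows.append(
            {
                "gene_id": g,
                "logfc": lfc,
                "pct_in": float(rng.uniform(0.6, 1.0)),
                "pct_out": float(rng.uniform(0.0, 0.3)),
                "p_value": float(rng.uniform(1e-12, 1e-4)),
                "q_value": float(rng.uniform(1e-10, 1e-3)),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id", drop=False)


# ---------------------------------------------------------------------------
# competition + assays


def simulate_competition(n_spheroids: int, p_tip: float, seed: int) -> tuple[int, int]:
    """Mosaic-spheroid tip occupancy: one tip per spheroid, k ~ Binomial(n, p_tip).

    Returns (k_silenced_at_tip, n_tips_total).
    """
    if not (0 <= p_tip <= 1):
        raise ValueError(f"p_tip must lie in [0, 1], got {p_tip}")
    if n_spheroids < 1:
        raise ValueError("need at least one spheroid")
    rng = np.random.default_rng(seed)
    k = int(rng.binomial(n_spheroids, p_tip))
    return k, n_spheroids


def simulate_assays(
    seed: int,
    groups: dict[str, float] | None = None,
    n_replicates: int = 6,
    control_mean: float = 100.0,
    cv: float = 0.15,
) -> tuple[pd.DataFrame, dict]:
    """Gaussian replicate measurements with planted multiplicative effects.

    ``groups`` maps group name -> fractional effect (0.35 means the group
    mean is reduced by 35% versus control); the control group is added
    automatically with effect 0.  Noise sd is cv * group mean.
    """
    if groups is None:
        groups = {"siRNA2": 0.35, "siRNA3": 0.326}
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates per group")
    if cv <= 0:
        raise ValueError("cv must be positive")
    for name, eff in groups.items():
        if not (-1 < eff < 1):
            raise ValueError(f"effect for {name!r} must lie in (-1, 1), got {eff}")
    rng = np.random.default_rng(seed)
    rows = []
    all_groups = {"control": 0.0, **groups}
    for name, eff in all_groups.items():
        mu = control_mean * (1 - eff)
        vals = rng.normal(mu, cv * mu, size=n_replicates)
        for i, v in enumerate(vals, start=1):
            rows.append({"group": name, "replicate_id": i, "value": float(v)})
    truth = {
        "control_mean": control_mean,
        "effects": dict(all_groups),
        "cv": cv,
        "n_replicates": n_replicates,
        "seed": seed,
    }
    return pd.DataFrame(rows), truth
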