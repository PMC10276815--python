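"""Rank-product congruence meta-analysis across K ranked marker-gene lists.

A gene that is a genuine marker of the same phenotype in several independent
datasets should sit near the top of every per-dataset ranking.  The rank
product RP_g = prod_d r_{g,d} summarizes that congruence: small values mean
consistent top ranking.  Significance is assessed against the null model in
which each gene's rank is independently uniform on {1..n_d} in every dataset,
either by exhaustive enumeration (small universes) or Monte-Carlo sampling,
followed by Benjamini-Hochberg correction across the tested genes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ScoredGeneList",
    "RankMatrix",
    "assign_ranks",
    "build_rank_matrix",
    "rank_product",
    "rp_significance",
    "rank_product_analysis",
]

ENUMERATION_BUDGET = 1_000_000

TiePolicy = Literal["average", "min", "ordinal"]


@dataclass
class ScoredGeneList:
    """One dataset's marker list: gene ids with enrichment scores (higher = more enriched)."""

    dataset_id: str
    genes: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) == 0:
            raise ValueError(f"dataset {self.dataset_id!r}: empty gene list")
        if len(self.genes) != len(self.scores):
            raise ValueError(
                f"dataset {self.dataset_id!r}: {len(self.genes)} genes vs "
                f"{len(self.scores)} scores"
            )
        if not np.all(np.isfinite(self.scores)):
            raise ValueError(f"dataset {self.dataset_id!r}: non-finite scores")
        seen: set[str] = set()
        for g in self.genes:
            if g in seen:
                raise ValueError(f"dataset {self.dataset_id!r}: duplicate gene_id {g!r}")
            seen.add(g)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class RankMatrix:
    """Per-gene ranks across K datasets (genes restricted to the shared universe).

    ``ranks`` is a genes x K DataFrame; ``n_per_dataset`` records each list's
    full universe size (ranks were assigned before intersecting, so a gene's
    rank can exceed the number of shared genes).
    """

    ranks: pd.DataFrame
    n_per_dataset: list[int] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.ranks.shape[1]

    @property
    def genes(self) -> list[str]:
        return list(self.ranks.index)


def assign_ranks(gene_list: ScoredGeneList, tie_policy: TiePolicy = "average") -> pd.Series:
    """Rank genes so that rank 1 is the highest score.

    With ``average`` ties the multiset of ranks always sums to n(n+1)/2.
    """
    if tie_policy not in ("average", "min", "ordinal"):
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    r = rankdata(-gene_list.scores, method=tie_policy)
    return pd.Series(r, index=gene_list.genes, name=gene_list.dataset_id)


def build_rank_matrix(
    lists: Sequence[ScoredGeneList],
    tie_policy: TiePolicy = "average",
    missing: Literal["intersect", "worst_rank"] = "intersect",
) -> RankMatrix:
    """Assemble per-dataset ranks into a shared-gene matrix.

    ``intersect`` (default) keeps only genes present in every list.
    ``worst_rank`` keeps the union, imputing rank n_d for genes absent from a
    dataset (an explicitly pessimistic choice, off by default).
    """
    if len(lists) < 2:
        raise ValueError("need at least two datasets for a rank product")
    ids = [lst.dataset_id for lst in lists]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate dataset_id among input lists")
    per_ds = [assign_ranks(lst, tie_policy) for lst in lists]
    n_per_dataset = [len(lst) for lst in lists]

    if missing == "intersect":
        shared = set(per_ds[0].index)
        for s in per_ds[1:]:
            shared &= set(s.index)
        if not shared:
            raise ValueError("no genes shared by all datasets")
        genes = sorted(shared)
        ranks = pd.DataFrame({s.name: s.loc[genes] for s in per_ds}, index=genes)
    elif missing == "worst_rank":
        union: set[str] = set()
        for s in per_ds:
            union |= set(s.index)
        genes = sorted(union)
        cols = {}
        for s, n_d in zip(per_ds, n_per_dataset):
            cols[s.name] = s.reindex(genes).fillna(float(n_d))
        ranks = pd.DataFrame(cols, index=genes)
    else:
        raise ValueError(f"unknown missing policy {missing!r}")
    return RankMatrix(ranks=ranks, n_per_dataset=n_per_dataset)


def rank_product(matrix: RankMatrix) -> pd.DataFrame:
    """Per-gene rank product and its geometric mean, sorted ascending.

    The product is accumulated in log-space so large universes cannot
    overflow; ties in rp break deterministically on gene_id.
    """
    ranks = matrix.ranks
    if ranks.isna().any().any():
        bad = ranks.index[ranks.isna().any(axis=1)][0]
        raise ValueError(f"gene {bad!r} is missing a rank in at least one dataset")
    r = ranks.to_numpy(dtype=float)
    log_rp = np.log(r).sum(axis=1)
    with np.errstate(over="ignore"):
        rp = np.prod(r, axis=1)  # exact for integer-valued ranks
    rp = np.where(np.isfinite(rp), rp, np.exp(log_rp))  # log-space overflow fallback
    out = pd.DataFrame(
        {
            "gene_id": ranks.index,
            "rp": rp,
            "rp_geomean": np.exp(log_rp / matrix.k),
        }
    )
    out = out.sort_values(["rp", "gene_id"], kind="mergesort").reset_index(drop=True)
    return out


def _null_rp_enumerated(n_per_dataset: Sequence[int]) -> np.ndarray:
    """All prod(n_d) rank products under the independent-uniform null, sorted."""
    grids = np.meshgrid(*[np.arange(1, n + 1, dtype=float) for n in n_per_dataset], indexing="ij")
    rp = np.ones_like(grids[0])
    for g in grids:
        rp = rp * g
    return np.sort(rp.ravel())


def _null_rp_montecarlo(n_per_dataset: Sequence[int], n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """B sampled rank products under the null, sorted."""
    rp = np.ones(n_perm)
    for n_d in n_per_dataset:
        rp *= rng.integers(1, n_d + 1, size=n_perm).astype(float)
    return np.sort(rp)


def rp_significance(
    rp_values: np.ndarray | pd.Series,
    n_per_dataset: Sequence[int],
    mode: Literal["enumerate", "montecarlo"] = "montecarlo",
    n_perm: int = 100_000,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation p-values and BH q-values for observed rank products.

    Null model: each gene's rank independently uniform on {1..n_d} per
    dataset; p = P(RP_null <= rp_observed).  Monte-Carlo p-values use the
    add-one correction (b+1)/(B+1) and therefore never reach 0.
    """
    rp = np.asarray(rp_values, dtype=float)
    if mode == "enumerate":
        total = int(np.prod([float(n) for n in n_per_dataset]))
        if total > ENUMERATION_BUDGET:
            raise ValueError(
                f"enumeration over {total} rank tuples exceeds the budget "
                f"({ENUMERATION_BUDGET}); use mode='montecarlo'"
            )
        null = _null_rp_enumerated(n_per_dataset)
        # exact tail probability: count of null products <= observed
        p = np.searchsorted(null, rp, side="right") / null.size
    elif mode == "montecarlo":
        if n_perm < 1000:
            raise ValueError(f"n_perm={n_perm} < 1000: too few permutations")
        if seed is None:
            raise ValueError("montecarlo mode requires an explicit seed")
        rng = np.random.default_rng(seed)
        null = _null_rp_montecarlo(n_per_dataset, n_perm, rng)
        b = np.searchsorted(null, rp, side="right")
        p = (b + 1) / (n_perm + 1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    q = multipletests(p, method="fdr_bh")[1]
    return p, q


def rank_product_analysis(
    lists: Sequence[ScoredGeneList],
    tie_policy: TiePolicy = "average",
    missing: Literal["intersect", "worst_rank"] = "intersect",
    mode: Literal["enumerate", "montecarlo"] = "montecarlo",
    n_perm: int = 100_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Full analysis: ranks -> rank products -> permutation p -> BH q.

    Returns a DataFrame sorted ascending by rp with one column of per-dataset
    ranks per input list.
    """
    matrix = build_rank_matrix(lists, tie_policy=tie_policy, missing=missing)
    result = rank_product(matrix)
    p, q = rp_significance(
        result["rp"].to_numpy(), matrix.n_per_dataset, mode=mode, n_perm=n_perm, seed=seed
    )
    result["p_value"] = p
    result["q_value"] = q
    for col in matrix.ranks.columns:
        result[f"rank_{col}"] = matrix.ranks.loc[result["gene_id"], col].to_numpy()
    return result
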