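"""GOT-IT assessment-block cascade for candidate prioritization.

The Guidelines On Target Assessment for Innovative Therapeutics organize
target triage into assessment blocks.  Four are relevant here (AB3 concerns
microbial targets and is skipped by construction):

  AB1  target-disease linkage — the phenotype must be concentrated in the
       disease condition (tip cells almost exclusively tumor-derived);
  AB2  target-related safety  — exclude genes genetically linked to another
       disease in adults;
  AB4  strategic novelty      — exclude well-described genes (>= 20
       angiogenesis publications, >= 3 tip-cell publications, or already
       described in tip cells);
  AB5  technical feasibility  — exclude secreted products, genes without
       perturbagens, and genes failing the logFC > 1 specificity rule.

Unknown annotation fields are fail-safe: they propagate to an ``unknown``
verdict and the gene is excluded, never silently passed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .markers import specificity_filter

__all__ = [
    "TRUE",
    "FALSE",
    "UNKNOWN",
    "Thresholds",
    "phenotype_condition_enrichment",
    "ab1_verdict",
    "apply_assessment_blocks",
    "select_candidates",
]

# three-valued flags used in annotation tables
TRUE, FALSE, UNKNOWN = "true", "false", "unknown"
_FLAG_VALUES = {TRUE, FALSE, UNKNOWN}


@dataclass(frozen=True)
class Thresholds:
    """Selection thresholds; inequalities are strict where noted."""

    top_n: int = 50
    max_angio_pubs: int = 20  # pass requires pub_count_angiogenesis < 20
    max_tip_pubs: int = 3  # pass requires pub_count_tip < 3
    lfc_min: float = 1.0  # pass requires logfc > 1 (strict)
    ab1_fraction_min: float = 0.9  # disease-condition fraction of the phenotype

    def __post_init__(self) -> None:
        if self.top_n <= 0 or self.max_angio_pubs <= 0 or self.max_tip_pubs <= 0:
            raise ValueError("count thresholds must be positive")
        if self.lfc_min <= 0 or not (0 < self.ab1_fraction_min <= 1):
            raise ValueError("invalid lfc_min or ab1_fraction_min")


def _check_flag(value: str, field: str, row: int) -> str:
    if value not in _FLAG_VALUES:
        raise ValueError(f"annotation row {row}: {field}={value!r} is not true/false/unknown")
    return value


def phenotype_condition_enrichment(
    cell_labels: pd.Series, conditions: pd.Series
) -> pd.DataFrame:
    """Cell counts and row-normalized fractions per (phenotype, condition).

    Rows are phenotypes; for each, the fractions across conditions sum to 1.
    """
    if len(cell_labels) != len(conditions):
        raise ValueError("cell_labels and conditions differ in length")
    if cell_labels.isna().any() or conditions.isna().any():
        raise ValueError("every cell needs both a phenotype and a condition label")
    counts = pd.crosstab(cell_labels, conditions)
    counts.index.name = "phenotype"
    counts.columns.name = "condition"
    fractions = counts.div(counts.sum(axis=1), axis=0)
    return pd.concat({"count": counts, "fraction": fractions}, axis=1)


def ab1_verdict(
    enrichment: pd.DataFrame,
    phenotype: str,
    disease_condition: str,
    thresholds: Thresholds = Thresholds(),
) -> tuple[str, str]:
    """AB1: pass iff the phenotype's disease-condition fraction >= ab1_fraction_min.

    The linkage is a property of the phenotype, so one verdict applies to
    every gene in the evaluated list.
    """
    if phenotype not in enrichment.index:
        return UNKNOWN, f"phenotype {phenotype!r} absent from enrichment table"
    if ("fraction", disease_condition) not in enrichment.columns:
        return UNKNOWN, f"condition {disease_condition!r} absent from enrichment table"
    frac = float(enrichment.loc[phenotype, ("fraction", disease_condition)])
    if pd.isna(frac):
        return UNKNOWN, f"no cells for phenotype {phenotype!r}"
    if frac >= thresholds.ab1_fraction_min:
        return "pass", f"{disease_condition} fraction {frac:.3f} >= {thresholds.ab1_fraction_min:g}"
    return "fail", f"{disease_condition} fraction {frac:.3f} < {thresholds.ab1_fraction_min:g}"


def _ab2(row: pd.Series) -> tuple[str, str]:
    link = row["disease_link"]
    if link == TRUE:
        note = row.get("disease_note", "") or "genetic disease link"
        return "fail", f"disease link: {note}"
    if link == UNKNOWN:
        return UNKNOWN, "disease link not assessed"
    return "pass", "no known disease link"


def _ab4(row: pd.Series, thresholds: Thresholds) -> tuple[str, str]:
    if row["previously_described_tip"] == TRUE:
        return "fail", "already described as expressed in tip cells"
    angio = int(row["pub_count_angiogenesis"])
    tip = int(row["pub_count_tip"])
    if angio >= thresholds.max_angio_pubs:
        return "fail", f"{angio} angiogenesis publications (>= {thresholds.max_angio_pubs})"
    if tip >= thresholds.max_tip_pubs:
        return "fail", f"{tip} tip-cell publications (>= {thresholds.max_tip_pubs})"
    if row["previously_described_tip"] == UNKNOWN:
        return UNKNOWN, "tip-cell novelty not assessed"
    return "pass", f"novel: {angio} angiogenesis / {tip} tip-cell publications"


def _ab5(row: pd.Series, spec_verdict: str, spec_reason: str) -> tuple[str, str]:
    if row["secreted"] == TRUE:
        return "fail", "secreted product"
    if not bool(row["perturbagen_available"]):
        return "fail", "no perturbagen available"
    if spec_verdict == "fail":
        return "fail", f"not cluster-specific ({spec_reason})"
    if row["secreted"] == UNKNOWN:
        return UNKNOWN, "secretion status unknown"
    if spec_verdict == "unknown":
        return UNKNOWN, spec_reason
    return "pass", f"feasible: not secreted, perturbagen available, {spec_reason}"


def apply_assessment_blocks(
    annotations: pd.DataFrame,
    marker_stats: pd.DataFrame,
    enrichment: pd.DataFrame | None,
    thresholds: Thresholds = Thresholds(),
    phenotype: str = "tip",
    disease_condition: str = "tumor",
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene AB1/AB2/AB4/AB5 verdicts with reasons and the final candidate flag.

    ``annotations`` must be indexed (or indexable) by gene_id with the
    documented columns; genes without an annotation row become ``unknown``.
    ``final_candidate`` is true iff every block passes — an unknown anywhere
    excludes the gene (fail-safe policy).
    """
    ann = annotations.copy()
    if ann.index.name != "gene_id":
        ann = ann.set_index("gene_id", drop=False)
    for i, (g, row) in enumerate(ann.iterrows()):
        for fld in ("previously_described_tip", "secreted", "disease_link"):
            _check_flag(str(row[fld]), fld, i)
        for fld in ("pub_count_angiogenesis", "pub_count_tip"):
            if int(row[fld]) < 0:
                raise ValueError(f"annotation row {i}: negative {fld}")

    if genes is None:
        genes = list(ann.index)

    spec = specificity_filter(marker_stats, genes=genes, lfc_min=thresholds.lfc_min)

    if enrichment is None:
        ab1 = (UNKNOWN, "no enrichment table supplied")
    else:
        ab1 = ab1_verdict(enrichment, phenotype, disease_condition, thresholds)

    records = []
    for g in genes:
        if g not in ann.index:
            verdicts: Mapping[str, tuple[str, str]] = {
                b: (UNKNOWN, "no annotation row") for b in ("ab2", "ab4", "ab5")
            }
        else:
            row = ann.loc[g]
            sv = spec.loc[g]
            verdicts = {
                "ab2": _ab2(row),
                "ab4": _ab4(row, thresholds),
                "ab5": _ab5(row, str(sv["verdict"]), str(sv["reason"])),
            }
        all_blocks = {"ab1": ab1, **verdicts}
        final = all(v == "pass" for v, _ in all_blocks.values())
        rec = {"gene_id": g}
        for block, (v, reason) in all_blocks.items():
            rec[f"{block}_verdict"] = v
            rec[f"{block}_reason"] = reason
        rec["final_candidate"] = final
        records.append(rec)
    return pd.DataFrame(records).set_index("gene_id", drop=False)


def select_candidates(
    ranked: pd.DataFrame,
    decisions: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
) -> tuple[pd.DataFrame, dict]:
    """Walk the top-N of the ranked list through the decisions; report the funnel.

    ``ranked`` must be sorted ascending by rp (ties broken on gene_id).
    Returns (candidate table in rank order, funnel dict whose exclusion
    counts sum to top_n).
    """
    rp = ranked["rp"].to_numpy()
    if rp.size > 1 and (rp[:-1] > rp[1:]).any():
        raise ValueError("ranked list is not sorted ascending by rp")
    top = ranked.head(thresholds.top_n).copy()
    top["rank_in_list"] = range(1, len(top) + 1)

    funnel = {
        "top_n": len(top),
        "excluded_ab1": 0,
        "excluded_ab2": 0,
        "excluded_ab4": 0,
        "excluded_ab5": 0,
        "unknown": 0,
        "candidates": 0,
    }
    rows = []
    for _, entry in top.iterrows():
        g = entry["gene_id"]
        if g not in decisions.index:
            funnel["unknown"] += 1
            continue
        d = decisions.loc[g]
        verdicts = [(b, d[f"{b}_verdict"]) for b in ("ab1", "ab2", "ab4", "ab5")]
        first_fail = next((b for b, v in verdicts if v == "fail"), None)
        if first_fail is not None:
            funnel[f"excluded_{first_fail}"] += 1
            continue
        if any(v == UNKNOWN for _, v in verdicts):
            funnel["unknown"] += 1
            continue
        funnel["candidates"] += 1
        rows.append(
            {
                "gene_id": g,
                "rank_in_list": int(entry["rank_in_list"]),
                "rp": float(entry["rp"]),
            }
        )
    candidates = pd.DataFrame(rows, columns=["gene_id", "rank_in_list", "rp"])
    return candidates, funnel
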