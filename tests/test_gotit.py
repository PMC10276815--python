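"""The assessment-block cascade: verdict rules, fail-safe unknowns, funnel."""

import numpy as np
import pandas as pd
import pytest

from tipselect.gotit import (
    FALSE,
    TRUE,
    UNKNOWN,
    Thresholds,
    ab1_verdict,
    apply_assessment_blocks,
    phenotype_condition_enrichment,
    select_candidates,
)
from tipselect.simulate import (
    PAPER_LIKE_ARCHETYPES,
    PAPER_LIKE_CANDIDATES,
    paper_like_gene_panel,
    simulate_annotations,
    simulate_marker_stats,
)


def annotation_row(gene, **overrides):
    row = {
        "gene_id": gene,
        "pub_count_angiogenesis": 1,
        "pub_count_tip": 0,
        "previously_described_tip": FALSE,
        "secreted": FALSE,
        "disease_link": FALSE,
        "disease_note": "",
        "perturbagen_available": True,
    }
    row.update(overrides)
    return row


def make_annotations(rows):
    return pd.DataFrame(rows).set_index("gene_id", drop=False)


def passing_stats(genes, logfc=2.0):
    return pd.DataFrame(
        {"gene_id": genes, "logfc": [logfc] * len(genes)}
    ).set_index("gene_id", drop=False)


class TestEnrichment:
    def test_counts_and_row_normalized_fractions(self):
        labels = pd.Series(["tip"] * 200 + ["vein"] * 100)
        conditions = pd.Series(["tumor"] * 199 + ["normal"] + ["tumor"] * 50 + ["normal"] * 50)
        table = phenotype_condition_enrichment(labels, conditions)
        assert table.loc["tip", ("count", "tumor")] == 199
        assert table.loc["tip", ("fraction", "tumor")] == pytest.approx(0.995)
        assert table.loc["vein", ("fraction", "tumor")] == pytest.approx(0.5)
        # fractions sum to one per phenotype
        assert table["fraction"].sum(axis=1).tolist() == pytest.approx([1.0, 1.0])

    def test_ab1_pass_fail_unknown(self):
        labels = pd.Series(["tip"] * 10 + ["vein"] * 10)
        conditions = pd.Series(["tumor"] * 10 + ["normal"] * 10)
        table = phenotype_condition_enrichment(labels, conditions)
        assert ab1_verdict(table, "tip", "tumor")[0] == "pass"  # fraction 1.0
        assert ab1_verdict(table, "vein", "tumor")[0] == "fail"
        assert ab1_verdict(table, "ghost", "tumor")[0] == UNKNOWN


class TestBlockRules:
    def test_ab2_disease_link_fails_with_note(self):
        ann = make_annotations(
            [
                annotation_row(
                    "SPARC",
                    disease_link=TRUE,
                    disease_note="linked to disorders of the central nervous system",
                ),
                annotation_row("ok"),
            ]
        )
        d = apply_assessment_blocks(ann, passing_stats(["SPARC", "ok"]), None)
        assert d.loc["SPARC", "ab2_verdict"] == "fail"
        assert "central nervous system" in d.loc["SPARC", "ab2_reason"]
        assert d.loc["ok", "ab2_verdict"] == "pass"

    @pytest.mark.parametrize(
        "overrides, expected",
        [
            ({"pub_count_angiogenesis": 20}, "fail"),  # strict "less than 20"
            ({"pub_count_angiogenesis": 19}, "pass"),
            ({"pub_count_tip": 3}, "fail"),  # strict "less than three"
            ({"pub_count_tip": 2}, "pass"),
            ({"previously_described_tip": TRUE}, "fail"),
            ({"previously_described_tip": UNKNOWN}, UNKNOWN),
        ],
    )
    def test_ab4_novelty_boundaries(self, overrides, expected):
        ann = make_annotations([annotation_row("g", **overrides)])
        d = apply_assessment_blocks(ann, passing_stats(["g"]), None)
        assert d.loc["g", "ab4_verdict"] == expected

    @pytest.mark.parametrize(
        "overrides, logfc, expected",
        [
            ({"secreted": TRUE}, 3.0, "fail"),  # secreted fails regardless
            ({"perturbagen_available": False}, 3.0, "fail"),
            ({}, 0.5, "fail"),  # specificity rule
            ({"secreted": UNKNOWN}, 3.0, UNKNOWN),
            ({}, 3.0, "pass"),
        ],
    )
    def test_ab5_feasibility(self, overrides, logfc, expected):
        ann = make_annotations([annotation_row("g", **overrides)])
        d = apply_assessment_blocks(ann, passing_stats(["g"], logfc=logfc), None)
        assert d.loc["g", "ab5_verdict"] == expected

    def test_unknown_never_becomes_candidate(self):
        ann = make_annotations([annotation_row("g", disease_link=UNKNOWN)])
        stats = passing_stats(["g"])
        enr = phenotype_condition_enrichment(
            pd.Series(["tip"] * 5 + ["o"] * 5), pd.Series(["tumor"] * 5 + ["normal"] * 5)
        )
        d = apply_assessment_blocks(ann, stats, enr)
        assert d.loc["g", "ab2_verdict"] == UNKNOWN
        assert not d.loc["g", "final_candidate"]

    def test_missing_annotation_row_is_unknown(self):
        ann = make_annotations([annotation_row("known")])
        d = apply_assessment_blocks(ann, passing_stats(["known", "ghost"]), None, genes=["known", "ghost"])
        assert d.loc["ghost", "ab2_verdict"] == UNKNOWN
        assert not d.loc["ghost", "final_candidate"]

    def test_malformed_flag_rejected_with_row(self):
        ann = make_annotations([annotation_row("g", secreted="maybe")])
        with pytest.raises(ValueError, match="row 0"):
            apply_assessment_blocks(ann, passing_stats(["g"]), None)

    def test_annotation_order_does_not_change_verdicts(self):
        rows = [
            annotation_row("a"),
            annotation_row("b", secreted=TRUE),
            annotation_row("c", pub_count_tip=5),
        ]
        stats = passing_stats(["a", "b", "c"])
        enr = None
        fwd = apply_assessment_blocks(make_annotations(rows), stats, enr, genes=["a", "b", "c"])
        rev = apply_assessment_blocks(make_annotations(rows[::-1]), stats, enr, genes=["a", "b", "c"])
        pd.testing.assert_frame_equal(fwd, rev)


class TestSelectCandidates:
    def ranked(self, genes):
        return pd.DataFrame({"gene_id": genes, "rp": np.arange(1, len(genes) + 1, dtype=float)})

    def test_single_passing_gene_in_toy_fixture(self):
        genes = [f"g{i}" for i in range(10)]
        rows = []
        for i, g in enumerate(genes):
            if i == 4:
                rows.append(annotation_row(g))
            else:
                rows.append(annotation_row(g, pub_count_angiogenesis=50))
        ann = make_annotations(rows)
        enr = phenotype_condition_enrichment(
            pd.Series(["tip"] * 5), pd.Series(["tumor"] * 5)
        )
        d = apply_assessment_blocks(ann, passing_stats(genes), enr)
        cands, funnel = select_candidates(self.ranked(genes), d, Thresholds(top_n=10))
        assert cands["gene_id"].tolist() == ["g4"]
        assert funnel["excluded_ab4"] == 9
        assert funnel["candidates"] == 1

    def test_funnel_counts_sum_to_top_n(self):
        genes = [f"g{i}" for i in range(8)]
        ann = make_annotations([annotation_row(g, disease_link=UNKNOWN) for g in genes[:4]])
        d = apply_assessment_blocks(ann, passing_stats(genes), None, genes=genes)
        cands, funnel = select_candidates(self.ranked(genes), d, Thresholds(top_n=8))
        assert len(cands) == 0  # all-unknown -> fail-safe zero candidates
        total = sum(funnel[k] for k in funnel if k.startswith("excluded")) + funnel["unknown"] + funnel["candidates"]
        assert total == funnel["top_n"] == 8

    def test_tightening_thresholds_never_adds_candidates(self):
        panel = paper_like_gene_panel()
        ann = simulate_annotations(panel, "paper_like", seed=1)
        stats = simulate_marker_stats(panel, "paper_like", seed=1)
        enr = phenotype_condition_enrichment(
            pd.Series(["tip"] * 5), pd.Series(["tumor"] * 5)
        )
        ranked = self.ranked(panel)
        loose = Thresholds()
        tight = Thresholds(max_angio_pubs=5, max_tip_pubs=1, lfc_min=1.8)
        d_loose = apply_assessment_blocks(ann, stats, enr, thresholds=loose)
        d_tight = apply_assessment_blocks(ann, stats, enr, thresholds=tight)
        c_loose, _ = select_candidates(ranked, d_loose, loose)
        c_tight, _ = select_candidates(ranked, d_tight, tight)
        assert set(c_tight["gene_id"]) <= set(c_loose["gene_id"])

    def test_unsorted_ranked_list_rejected(self):
        ranked = pd.DataFrame({"gene_id": ["a", "b"], "rp": [5.0, 2.0]})
        with pytest.raises(ValueError, match="sorted"):
            select_candidates(ranked, pd.DataFrame(index=pd.Index([], name="gene_id")))


class TestPaperLikeFixture:
    """The named archetypes reproduce the published per-gene decisions."""

    @pytest.fixture()
    def decisions(self):
        panel = paper_like_gene_panel()
        ann = simulate_annotations(panel, "paper_like", seed=2)
        stats = simulate_marker_stats(panel, "paper_like", seed=2)
        enr = phenotype_condition_enrichment(
            pd.Series(["tip"] * 199 + ["tip"] + ["vein"] * 100),
            pd.Series(["tumor"] * 199 + ["normal"] + ["tumor"] * 100),
        )
        return apply_assessment_blocks(ann, stats, enr)

    def test_named_failures_fail_their_blocks(self, decisions):
        for gene, block in PAPER_LIKE_ARCHETYPES.items():
            assert decisions.loc[gene, f"{block}_verdict"] == "fail", gene
            assert not decisions.loc[gene, "final_candidate"]

    def test_six_candidates_pass_everything(self, decisions):
        finals = decisions.index[decisions["final_candidate"]].tolist()
        assert sorted(finals) == sorted(PAPER_LIKE_CANDIDATES)

    def test_every_excluded_gene_has_a_reason(self, decisions):
        excluded = decisions[~decisions["final_candidate"]]
        for _, row in excluded.iterrows():
            reasons = [
                row[f"{b}_reason"]
                for b in ("ab1", "ab2", "ab4", "ab5")
                if row[f"{b}_verdict"] in ("fail", UNKNOWN)
            ]
            assert any(reasons)
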