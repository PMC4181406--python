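"""Test-set geometry, masking, confusion metrics, ranking."""

import numpy as np
import pytest

from netphen.errors import ConfigurationError, DataIntegrityError
from netphen.textmine import DocumentAnnotation, DocumentCohort, TermRecord
from netphen.validation import TestCase as PositionalTestCase
from netphen.validation import (GeneOrder, ScoredTestCase, build_test_set,
                                evaluate, mask_associations, rank_auc,
                                rank_causal)


def order_of(n, chrom="chr1"):
    return GeneOrder([(f"g{i}", chrom, i) for i in range(n)])


class TestBuildTestSet:
    def test_interior_position_takes_50_up_49_down(self):
        order = order_of(400)
        case = build_test_set("g200", order)
        assert len(case.candidates) == 100
        idx = case.candidates.index("g200")
        assert idx == 50                      # 50 upstream flanking genes
        assert len(case.candidates) - idx - 1 == 49
        assert case.candidates[0] == "g150"
        assert case.candidates[-1] == "g249"

    def test_telomere_deficit_compensated_downstream(self):
        case = build_test_set("g10", order_of(400))
        assert len(case.candidates) == 100
        assert case.candidates.index("g10") == 10
        assert case.candidates[0] == "g0"
        assert case.candidates[-1] == "g99"

    def test_extreme_telomere_all_downstream(self):
        case = build_test_set("g0", order_of(400))
        assert len(case.candidates) == 100
        assert case.candidates[0] == "g0"
        assert case.candidates[-1] == "g99"

    def test_every_position_yields_exactly_100(self):
        order = order_of(150)
        for i in range(150):
            assert len(build_test_set(f"g{i}", order).candidates) == 100

    def test_full_flanks_variant_gives_101(self):
        case = build_test_set("g200", order_of(400), full_flanks=True)
        assert len(case.candidates) == 101
        assert case.candidates.index("g200") == 50

    def test_short_chromosome_error_names_chromosome(self):
        with pytest.raises(ConfigurationError, match="chrM"):
            build_test_set("g3", order_of(50, chrom="chrM"))

    def test_causal_gene_must_be_known(self):
        with pytest.raises(DataIntegrityError, match="gX"):
            build_test_set("gX", order_of(200))


class TestMaskAssociations:
    @pytest.fixture
    def cohort(self):
        terms = {"t": TermRecord("t", frozenset({"MeSH"}),
                                 "Disease or Syndrome")}
        anns = [DocumentAnnotation("D", {"t": 1}),
                DocumentAnnotation("P", {"t": 2}),
                DocumentAnnotation("Q", {"t": 1})]
        return DocumentCohort(annotations=anns, term_table=terms,
                              gene_links={"g1": {"D", "P"}, "g2": {"Q"}})

    def test_disease_links_removed_abstracts_kept(self, cohort):
        masked = mask_associations(cohort, "g1", {"D"})
        assert masked.gene_links["g1"] == {"P"}
        assert masked.gene_links["g2"] == {"Q"}          # untouched
        assert cohort.gene_links["g1"] == {"D", "P"}     # input unchanged

    def test_gene_without_disease_links_unchanged(self, cohort):
        masked = mask_associations(cohort, "g2", {"D"})
        assert masked.gene_links == cohort.gene_links

    def test_idempotent(self, cohort):
        once = mask_associations(cohort, "g1", {"D"})
        twice = mask_associations(once, "g1", {"D"})
        assert once.gene_links == twice.gene_links


def scored(disease, causal, z):
    candidates = tuple(z.keys())
    return ScoredTestCase(
        case=PositionalTestCase(disease_id=disease, causal_gene=causal,
                      candidates=candidates),
        z=dict(z))


class TestEvaluate:
    def test_perfect_classifier(self):
        cases = [scored("d1", "gA", {"gA": 5.0, "g1": -1.0, "g2": 0.0}),
                 scored("d2", "gB", {"gB": 4.0, "g3": -2.0, "g4": 1.0})]
        sweep = evaluate(cases, discriminators=[2.0])
        r = sweep.results[0]
        assert (r.tp, r.fp, r.tn, r.fn) == (2, 0, 4, 0)
        assert r.recall == r.precision == r.mcc == 1.0

    def test_hand_enumerated_toy_confusion_counts(self):
        # two cases, cut-off 1.0: causal gA above (tp), causal gB below
        # (fn); non-causal above: g4 (fp); below: g1, g2, g3 (tn)
        cases = [scored("d1", "gA", {"gA": 2.0, "g1": 0.5, "g2": -0.5}),
                 scored("d2", "gB", {"gB": 0.0, "g3": 0.9, "g4": 1.5})]
        r = evaluate(cases, discriminators=[1.0]).results[0]
        assert (r.tp, r.fp, r.tn, r.fn) == (1, 1, 3, 1)
        assert r.recall == pytest.approx(0.5)
        assert r.precision == pytest.approx(0.5)
        num = 1 * 3 - 1 * 1
        den = np.sqrt((1 + 1) * (1 + 1) * (3 + 1) * (3 + 1))
        assert r.mcc == pytest.approx(num / den)

    def test_random_scores_give_auc_half(self):
        rng = np.random.default_rng(12)
        cases = []
        for i in range(60):
            z = {f"g{j}": float(rng.standard_normal()) for j in range(40)}
            cases.append(scored(f"d{i}", "g0", z))
        grid = np.quantile(rng.standard_normal(5000),
                           np.linspace(0, 0.999, 300))
        sweep = evaluate(cases, discriminators=grid)
        assert sweep.auc == pytest.approx(0.5, abs=0.08)

    def test_mcc_zero_when_marginal_empty(self):
        cases = [scored("d", "gA", {"gA": 1.0, "g1": 0.5})]
        r = evaluate(cases, discriminators=[-10.0]).results[0]
        assert r.fn == 0 and r.tn == 0 and r.mcc == 0.0

    def test_all_pass_cutoff_gives_recall_one(self):
        cases = [scored("d", "gA", {"gA": -3.0, "g1": 2.0})]
        r = evaluate(cases, discriminators=[-3.0]).results[0]
        assert r.recall == 1.0

    def test_sweep_auc_matches_rank_auc_within_grid_resolution(self):
        rng = np.random.default_rng(5)
        cases = []
        for i in range(40):
            z = {f"g{j}": float(rng.standard_normal()) for j in range(60)}
            z["g0"] += 1.5  # informative but imperfect causal signal
            cases.append(scored(f"d{i}", "g0", z))
        grid = np.quantile(rng.standard_normal(5000),
                           1.0 - np.linspace(0.001, 1.0, 500))
        sweep = evaluate(cases, discriminators=grid)
        assert sweep.auc == pytest.approx(rank_auc(cases), abs=0.02)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ConfigurationError):
            evaluate([], [0.0])
        with pytest.raises(ConfigurationError):
            evaluate([scored("d", "g", {"g": 1.0})], [])


class TestRankCausal:
    def test_strict_top_rank_counts_toward_topk(self):
        cases = [scored("d", "gA", {"gA": 3.0, "g1": 1.0, "g2": 2.0})]
        summary = rank_causal(cases)
        assert summary.ranks[("d", "gA")] == 1
        assert summary.top1_fraction == 1.0
        assert summary.top5_fraction == 1.0

    def test_tie_takes_worst_rank(self):
        z = {"gA": 1.0, **{f"g{i}": 1.0 for i in range(5)},
             "low": -1.0}
        summary = rank_causal([scored("d", "gA", z)])
        assert summary.ranks[("d", "gA")] == 6
        assert summary.top5_fraction == 0.0

    def test_unscorable_causal_counts_as_coverage_loss(self):
        case = PositionalTestCase("d", "gA", ("gA", "g1"))
        sc = ScoredTestCase(case=case, z={"g1": 0.3}, unscorable=("gA",))
        ok = scored("d2", "gB", {"gB": 2.0, "g9": 0.0})
        summary = rank_causal([sc, ok])
        assert summary.ranks[("d", "gA")] is None
        assert summary.coverage == 0.5
        assert summary.top1_fraction == 0.5


class TestTestCaseInvariants:
    def test_causal_must_be_a_candidate(self):
        with pytest.raises(DataIntegrityError):
            PositionalTestCase("d", "gX", ("g1", "g2"))

    def test_duplicate_candidates_rejected(self):
        with pytest.raises(DataIntegrityError):
            PositionalTestCase("d", "g1", ("g1", "g1"))
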