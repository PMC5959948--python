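"""Success tables, baseline median, exact McNemar, Spearman."""

import itertools
import math

import pytest

from phenorank.errors import DomainError, InsufficientDataError
from phenorank.evaluate import (
    CausalRankRecord,
    baseline_median_ranks,
    compare_dichotomized,
    evaluate_all,
    mcnemar_exact,
    spearman_profile_size_effect,
    success_at_n,
)
from phenorank.prioritize import rank_genes

from conftest import g, make_pair, make_term, p, sent
from phenorank.cooccur import build_store
from phenorank.kb_io import Knowledgebase


class TestSuccessAtN:
    def test_counts_and_rounding(self):
        # 563 pairs with 31/90/120/173/308 inside the N thresholds
        ranks = [1] * 31 + [5] * 59 + [10] * 30 + [20] * 53 + [100] * 135
        ranks += [101] * (563 - len(ranks))
        table = success_at_n(ranks)
        assert table.counts == (31, 90, 120, 173, 308)
        assert table.percentages == (5.5, 16.0, 21.3, 30.7, 54.7)

    def test_unresolved_complement(self):
        ranks = [100] * 308 + [101] * 255
        table = success_at_n(ranks)
        assert table.unresolved_at(100) == 255

    def test_all_censored(self):
        table = success_at_n([101, 101, 101])
        assert table.counts == (0, 0, 0, 0, 0)

    def test_monotone_in_threshold(self):
        ranks = [1, 3, 7, 15, 60, 101, 101]
        table = success_at_n(ranks)
        assert list(table.counts) == sorted(table.counts)

    def test_rounding_is_half_up(self):
        # 1/8 = 12.5% exactly; half-up to one decimal of 100*1/16 = 6.25 -> 6.3
        table = success_at_n([1] + [101] * 15)
        assert table.percent_at(1) == 6.3


class TestBaselineMedianRanks:
    def build(self, ranks_by_disease, causal):
        """predictions mapping via planted stores is overkill here; use
        RankedPredictions produced from a tiny constructed store."""
        preds = {}
        for disease, ordered in ranks_by_disease.items():
            sentences = []
            for i, gene in enumerate(ordered):
                for _ in range(len(ordered) - i):
                    sentences.append(
                        sent(f"{disease}-{gene}-{len(sentences)}", g(gene), p("p1"))
                    )
            store = build_store(sentences)
            from phenorank.kb_io import PhenotypeProfile

            profile = PhenotypeProfile((make_term("p1", "one"),), disease)
            preds[disease] = rank_genes(store, profile, k=100)
        return baseline_median_ranks(preds, causal, k=100)

    def test_odd_count_median(self):
        # gX ranks 3, 5, 7 in the three diseases it does not cause
        ranks = {
            "D1": ["a", "b", "gX", "c", "d"],          # rank 3
            "D2": ["a", "b", "c", "d", "gX", "e"],     # rank 5
            "D3": ["a", "b", "c", "d", "e", "f", "gX"],  # rank 7
            "D4": ["gX"],
        }
        causal = {"D1": "z", "D2": "z", "D3": "z", "D4": "gX"}
        assert self.build(ranks, causal)["gX"] == 5.0

    def test_even_count_with_censored_sentinel(self):
        ranks = {
            "D1": ["a", "gX", "b"],  # rank 2
            "D2": ["a", "b", "c"],   # absent -> sentinel 101
            "D3": ["gX"],
        }
        causal = {"D1": "z", "D2": "z", "D3": "gX"}
        assert self.build(ranks, causal)["gX"] == pytest.approx(51.5)

    def test_gene_causal_for_only_disease_has_no_baseline(self):
        ranks = {"D1": ["gX"]}
        assert self.build(ranks, {"D1": "gX"})["gX"] is None


class TestMcnemarExact:
    def test_one_sided_discordance(self):
        assert mcnemar_exact(3, 0) == pytest.approx(0.25)

    def test_no_discordance_is_one(self):
        assert mcnemar_exact(0, 0) == 1.0

    def test_printed_value_with_bonferroni(self):
        p_val = mcnemar_exact(19, 2)
        assert p_val == pytest.approx(0.000221252, abs=1e-8)
        assert round(min(1.0, 5 * p_val), 4) == 0.0011

    @pytest.mark.parametrize("b,c", [(3, 1), (7, 7), (0, 5), (12, 2)])
    def test_symmetric(self, b, c):
        assert mcnemar_exact(b, c) == mcnemar_exact(c, b)

    def test_equals_enumeration_for_small_n(self):
        # oracle: enumerate all 2^n equally likely discordance patterns and
        # sum the probability of outcomes at least as extreme (two-sided)
        for b, c in itertools.product(range(8), repeat=2):
            n = b + c
            if n == 0 or n > 15:
                continue
            observed = min(b, c)
            extreme = sum(
                1
                for bits in itertools.product((0, 1), repeat=n)
                if min(sum(bits), n - sum(bits)) <= observed
            )
            assert mcnemar_exact(b, c) == pytest.approx(min(1.0, extreme / 2**n))

    def test_agrees_with_statsmodels_exact(self):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        for b, c in [(3, 0), (19, 2), (5, 5), (1, 10)]:
            ours = mcnemar_exact(b, c)
            theirs = sm.mcnemar([[0, b], [c, 0]], exact=True).pvalue
            assert ours == pytest.approx(float(theirs))

    def test_rejects_negative(self):
        with pytest.raises(DomainError):
            mcnemar_exact(-1, 2)


class TestCompareDichotomized:
    def test_planted_discordance(self):
        a = [1] * 20
        b = [101] * 20
        result = compare_dichotomized(a, b, thresholds=(10,), m_tests=5)
        t = result.at(10)
        assert (t.b, t.c) == (20, 0)
        assert t.p_value == pytest.approx(2 * 0.5**20)
        assert t.p_adjusted == pytest.approx(10 * 0.5**20)

    def test_identical_arms_give_p_one(self):
        ranks = [1, 4, 9, 50, 101]
        result = compare_dichotomized(ranks, ranks)
        assert all(t.p_value == 1.0 for t in result.per_threshold)

    def test_swapping_arms_preserves_p(self):
        a, b = [1, 1, 101, 7, 30], [101, 2, 2, 40, 3]
        fwd = compare_dichotomized(a, b)
        rev = compare_dichotomized(b, a)
        for t1, t2 in zip(fwd.per_threshold, rev.per_threshold):
            assert (t1.b, t1.c, t1.p_value) == (t2.c, t2.b, t2.p_value)

    def test_adjustment_capped_and_order_preserving(self):
        result = compare_dichotomized([1, 101], [101, 1], thresholds=(1, 5))
        for t in result.per_threshold:
            assert t.p_adjusted <= 1.0
            assert t.p_adjusted >= t.p_value

    def test_length_mismatch_raises(self):
        with pytest.raises(DomainError):
            compare_dichotomized([1], [1, 2])


class TestSpearman:
    def record(self, i, size, rank):
        return CausalRankRecord(f"D{i}", f"G{i}", size, rank_all=rank)

    def test_perfect_monotone(self):
        records = [self.record(i, s, r) for i, (s, r) in
                   enumerate([(1, 1), (2, 2), (3, 3)])]
        rho, _ = spearman_profile_size_effect(records)
        assert rho == pytest.approx(1.0)

    def test_perfect_antitone(self):
        records = [self.record(i, s, r) for i, (s, r) in
                   enumerate([(1, 3), (2, 2), (3, 1)])]
        rho, _ = spearman_profile_size_effect(records)
        assert rho == pytest.approx(-1.0)

    def test_hand_computed_rho(self):
        records = [self.record(i, s, r) for i, (s, r) in
                   enumerate([(1, 2), (2, 1), (3, 4), (4, 3)])]
        rho, _ = spearman_profile_size_effect(records)
        assert rho == pytest.approx(0.6)

    def test_censored_records_excluded(self):
        records = [self.record(i, s, r) for i, (s, r) in
                   enumerate([(1, 2), (2, 1), (3, 4), (4, 3), (5, 101)])]
        rho, _ = spearman_profile_size_effect(records, k=100)
        assert rho == pytest.approx(0.6)

    def test_too_few_records_raises(self):
        records = [self.record(0, 1, 1), self.record(1, 2, 2)]
        with pytest.raises(InsufficientDataError):
            spearman_profile_size_effect(records)


class TestEvaluateAll:
    @pytest.fixture
    def kb(self, planted_kb):
        return planted_kb

    def test_planted_store_ranks_causal_first(self, kb, planted_store):
        records = evaluate_all(kb, planted_store, k=100)
        assert all(r.rank_all == 1 for r in records)

    def test_empty_subset_is_censored(self, kb, planted_store):
        records = evaluate_all(kb, planted_store, k=100)
        by_id = {r.disease_id: r for r in records}
        # DIS2 has no clinical phenotypes -> censored sentinel
        assert by_id["DIS2"].rank_clinical == 101

    def test_deterministic(self, kb, planted_store):
        first = evaluate_all(kb, planted_store, k=100)
        second = evaluate_all(kb, planted_store, k=100)
        assert first == second

    def test_baseline_present_and_worse_than_causal(self, kb, planted_store):
        records = evaluate_all(kb, planted_store, k=100)
        for r in records:
            assert r.baseline_rank is not None
            assert r.baseline_rank > r.rank_all
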