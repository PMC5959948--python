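"""Sentence tallying and association scoring."""

import itertools
import random

import pytest

from phenorank.cooccur import (
    GENE,
    PHENOTYPE,
    SentenceRecord,
    association_score,
    build_store,
    profile_score,
    read_sentences,
    read_store,
    write_sentences,
    write_store,
)
from phenorank.errors import DomainError, InputError
from phenorank.kb_io import PhenotypeProfile

from conftest import g, make_term, p, sent


class TestBuildStore:
    def test_single_cooccurrence(self):
        store = build_store([sent("S1", g("g1"), p("p1"))])
        assert (store.n("g1"), store.n("p1"), store.n_pair("g1", "p1")) == (1, 1, 1)

    def test_marginals_and_joints_tally_independently(self):
        store = build_store(
            [sent("S1", g("g1"), p("p1")), sent("S2", g("g1")), sent("S3", p("p1"))]
        )
        assert (store.n("g1"), store.n("p1"), store.n_pair("g1", "p1")) == (2, 2, 1)

    def test_multi_gene_sentence_expands_pairwise(self):
        store = build_store([sent("S1", g("g1"), g("g2"), p("p1"))])
        assert store.n_pair("g1", "p1") == 1
        assert store.n_pair("g2", "p1") == 1

    def test_duplicate_sentence_id_raises(self):
        with pytest.raises(InputError, match="duplicate"):
            build_store([sent("S1", g("g1")), sent("S1", g("g2"))])

    def test_inconsistent_entity_type_raises(self):
        with pytest.raises(InputError):
            build_store([sent("S1", ("x", GENE)), sent("S2", ("x", PHENOTYPE))])

    def test_gene_universe(self):
        store = build_store([sent("S1", g("g1"), g("g2"), p("p1"))])
        assert store.gene_universe == {"g1", "g2"}

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_bruteforce_recount(self, seed):
        rng = random.Random(seed)
        genes = [f"g{i}" for i in range(8)]
        phens = [f"p{i}" for i in range(8)]
        sentences = []
        for i in range(400):
            mentions = {(e, GENE) for e in rng.sample(genes, rng.randint(0, 3))}
            mentions |= {(e, PHENOTYPE) for e in rng.sample(phens, rng.randint(0, 3))}
            if not mentions:
                mentions = {(genes[0], GENE)}
            sentences.append(SentenceRecord(f"S{i}", frozenset(mentions)))
        store = build_store(sentences)

        # oracle: direct recount from the sentence list
        for e in genes + phens:
            expected = sum(
                1 for s in sentences if any(eid == e for eid, _ in s.mentions)
            )
            assert store.n(e) == expected
        for a, b in itertools.product(genes, phens):
            expected = sum(
                1
                for s in sentences
                if {a, b} <= {eid for eid, _ in s.mentions}
            )
            assert store.n_pair(a, b) == expected


class TestAssociationScore:
    @pytest.fixture
    def store(self):
        # n(g)=3, n(p)=1, n(g,p)=1
        return build_store(
            [sent("S1", g("g1"), p("p1")), sent("S2", g("g1")), sent("S3", g("g1"))]
        )

    def test_sum_mode_arithmetic(self, store):
        assert association_score(store, "g1", "p1", "sum") == pytest.approx(0.25)

    def test_union_mode_arithmetic(self, store):
        assert association_score(store, "g1", "p1", "union") == pytest.approx(1 / 3)

    def test_exclusive_mode_arithmetic(self, store):
        assert association_score(store, "g1", "p1", "exclusive") == pytest.approx(0.5)

    @pytest.mark.parametrize("mode", ["sum", "union", "exclusive"])
    def test_zero_joint_is_zero(self, mode):
        store = build_store([sent("S1", g("g1")), sent("S2", p("p1"))])
        assert association_score(store, "g1", "p1", mode) == 0.0

    def test_perfect_association_union_is_one(self):
        store = build_store([sent(f"S{i}", g("g1"), p("p1")) for i in range(4)])
        assert association_score(store, "g1", "p1", "union") == 1.0

    def test_unknown_entities_score_zero(self, store):
        assert association_score(store, "nope", "p1") == 0.0

    def test_unknown_mode_raises(self, store):
        with pytest.raises(DomainError):
            association_score(store, "g1", "p1", "dice")

    def test_union_equals_jaccard_of_sentence_sets(self):
        rng = random.Random(7)
        sentences, by_entity = [], {"g1": set(), "p1": set()}
        for i in range(200):
            mentions = set()
            if rng.random() < 0.4:
                mentions.add(("g1", GENE)); by_entity["g1"].add(i)
            if rng.random() < 0.4:
                mentions.add(("p1", PHENOTYPE)); by_entity["p1"].add(i)
            if not mentions:
                mentions.add(("filler", GENE))
            sentences.append(SentenceRecord(f"S{i}", frozenset(mentions)))
        store = build_store(sentences)
        inter = by_entity["g1"] & by_entity["p1"]
        union = by_entity["g1"] | by_entity["p1"]
        expected = len(inter) / len(union) if union else 0.0
        assert association_score(store, "g1", "p1", "union") == pytest.approx(expected)

    def test_monotone_in_joint_count_at_fixed_marginals(self):
        # raise n(g,p) holding n(g)=n(p)=4 (denominators stay positive)
        def make(joint):
            sentences = [sent(f"J{i}", g("g1"), p("p1")) for i in range(joint)]
            sentences += [sent(f"G{i}", g("g1")) for i in range(4 - joint)]
            sentences += [sent(f"P{i}", p("p1")) for i in range(4 - joint)]
            return build_store(sentences)

        for mode in ("sum", "union", "exclusive"):
            scores = [association_score(make(j), "g1", "p1", mode) for j in (1, 2, 3)]
            assert scores == sorted(scores)


class TestProfileScore:
    @pytest.fixture
    def profile(self):
        return PhenotypeProfile(
            (make_term("p1", "one"), make_term("p2", "two")), "D1"
        )

    @pytest.fixture
    def store(self):
        return build_store(
            [
                sent("S1", g("g1"), p("p1")),
                sent("S2", g("g1"), p("p2")),
                sent("S3", g("g1")),
                sent("S4", p("p2")),
            ]
        )

    def test_additivity(self, store, profile):
        expected = association_score(store, "g1", "p1") + association_score(
            store, "g1", "p2"
        )
        assert profile_score(store, "g1", profile) == pytest.approx(expected)

    def test_single_phenotype_equals_association(self, store):
        single = PhenotypeProfile((make_term("p1", "one"),), "D1")
        assert profile_score(store, "g1", single) == association_score(
            store, "g1", "p1"
        )

    def test_order_independent(self, store, profile):
        flipped = PhenotypeProfile(tuple(reversed(profile.phenotypes)), "D1")
        assert profile_score(store, "g1", profile) == profile_score(
            store, "g1", flipped
        )

    def test_unresolvable_phenotypes_skipped(self, store, profile):
        score = profile_score(store, "g1", profile, entity_map={"p1": "p1"})
        assert score == association_score(store, "g1", "p1")

    def test_profile_resolving_to_nothing_raises(self, store, profile):
        with pytest.raises(DomainError):
            profile_score(store, "g1", profile, entity_map={})


def test_sentence_and_store_round_trip(tmp_path):
    sentences = [
        sent("S1", g("g1"), p("p1")),
        sent("S2", g("g2")),
        sent("S3", g("g1"), g("g2"), p("p2")),
    ]
    path = tmp_path / "corpus.tsv"
    write_sentences(sentences, path)
    assert read_sentences(path) == sentences

    store = build_store(sentences)
    write_store(store, tmp_path / "store")
    loaded = read_store(tmp_path / "store")
    assert loaded.entity_counts == store.entity_counts
    assert loaded.pair_counts == store.pair_counts
    assert loaded.entity_types == store.entity_types
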