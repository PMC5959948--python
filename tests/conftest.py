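"""Shared fixtures: tiny hand-built worlds with known answers."""

from __future__ import annotations

import random

import pytest

from phenorank.cooccur import GENE, PHENOTYPE, SentenceRecord, build_store
from phenorank.kb_io import (
    DiseaseGenePair,
    Knowledgebase,
    Ontology,
    OntologyTerm,
    PhenotypeProfile,
    PhenotypeTerm,
)


def make_term(term_id, name, category="biochemical", specimen=None):
    return PhenotypeTerm(term_id, name, category, specimen)


def make_pair(disease_id, gene_id, terms):
    return DiseaseGenePair(
        disease_id=disease_id,
        disease_name=f"disease {disease_id}",
        gene_id=gene_id,
        profile=PhenotypeProfile(tuple(terms), disease_id),
    )


def sent(sid, *mentions):
    return SentenceRecord(sid, frozenset(mentions))


def g(gene_id):
    return (gene_id, GENE)


def p(phen_id):
    return (phen_id, PHENOTYPE)


@pytest.fixture
def diamond_ontology():
    """Root with two subclasses S1, S2; leaf L under both; M under S1 only."""
    terms = {
        "T:R": OntologyTerm("T:R", "root"),
        "T:S1": OntologyTerm("T:S1", "system one", parent_ids=("T:R",)),
        "T:S2": OntologyTerm("T:S2", "system two", parent_ids=("T:R",)),
        "T:L": OntologyTerm("T:L", "shared leaf", parent_ids=("T:S1", "T:S2")),
        "T:M": OntologyTerm(
            "T:M", "lonely leaf", synonyms=("leaf alone",), parent_ids=("T:S1",)
        ),
    }
    return Ontology(terms=terms, root_id="T:R")


@pytest.fixture
def planted_kb():
    """Three diseases; DIS2's profile is purely biochemical."""
    return Knowledgebase(
        (
            make_pair(
                "DIS1",
                "G1",
                [
                    make_term("P1", "Dopamine", "biochemical", "plasma"),
                    make_term("P2", "Seizures", "clinical"),
                ],
            ),
            make_pair(
                "DIS2",
                "G2",
                [
                    make_term("P3", "Homovanillic acid", "biochemical", "urine"),
                    make_term("P4", "Epinephrine", "biochemical", "plasma"),
                ],
            ),
            make_pair(
                "DIS3",
                "G3",
                [
                    make_term("P5", "Hypotonia", "clinical"),
                    make_term("P6", "Lactate", "biochemical", "serum"),
                ],
            ),
        )
    )


@pytest.fixture
def planted_store(planted_kb):
    """Corpus where each causal gene co-occurs only with its own phenotypes."""
    sentences = []
    sid = 0
    for pair in planted_kb:
        for term in pair.profile.phenotypes:
            for _ in range(3):
                sid += 1
                sentences.append(sent(f"S{sid}", g(pair.gene_id), p(term.term_id)))
    # a few marginal-only mentions so denominators differ across genes
    for extra in ("G1", "G2"):
        sid += 1
        sentences.append(sent(f"S{sid}", g(extra)))
    return build_store(sentences)


def random_dag_ontology(rng: random.Random, n_nodes: int, max_parents: int = 2,
                        max_synonyms: int = 2) -> Ontology:
    """Random rooted DAG: node i chooses parents among earlier nodes."""
    terms = {"N0": OntologyTerm("N0", "root")}
    ids = ["N0"]
    for i in range(1, n_nodes):
        k = rng.randint(1, min(max_parents, len(ids)))
        parents = tuple(sorted(rng.sample(ids, k)))
        syns = tuple(
            f"syn {i} {j}" for j in range(rng.randint(0, max_synonyms))
        )
        tid = f"N{i}"
        terms[tid] = OntologyTerm(tid, f"node {i}", synonyms=syns, parent_ids=parents)
        ids.append(tid)
    return Ontology(terms=terms, root_id="N0")
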