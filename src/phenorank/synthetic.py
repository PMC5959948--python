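"""Synthetic knowledgebase, ontology and literature corpus.

The generator produces a world with the statistical structure the
prioritization analysis assumes, at desk scale:

- a knowledgebase of diseases, each with a unique causal gene and a
  phenotypic profile mixing biochemical phenotypes (carrying specimen
  qualifiers such as "(plasma)") and clinical phenotypes;
- a corpus of "sentences", each a set of entity mentions. A signal
  sentence co-mentions a causal gene with one of its own disease's
  phenotypes (biochemical phenotypes optionally upweighted); a background
  sentence mentions a random gene-phenotype pair or a single entity.
  Per-gene mention propensity follows a heavy-tailed (log-normal) draw,
  emulating the very uneven depth of literature across genes;
- a toy ontology rooted at a phenotypic-abnormality-style class with a
  configurable number of top-level subclasses, whose leaf names overlap
  the knowledgebase vocabulary by plan (exact / containment / disjoint),
  to exercise lexical term mapping.

All randomness flows from a single seed; a fixed config yields a
byte-identical world.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .cooccur import GENE, PHENOTYPE, SentenceRecord
from .errors import ConfigurationError
from .kb_io import (
    DiseaseGenePair,
    Knowledgebase,
    Ontology,
    OntologyTerm,
    PhenotypeProfile,
    PhenotypeTerm,
)

SPECIMENS = ("plasma", "urine", "serum", "cerebrospinal fluid")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic world.

    Rates are probabilities in [0, 1]: ``signal_rate`` is the probability
    that a sentence is a signal sentence (causal gene + own phenotype);
    among non-signal sentences, ``background_rate`` is the probability of
    a random gene-phenotype co-mention (the rest are single-entity
    mentions). ``biochem_signal_boost`` multiplies the sampling weight of
    biochemical phenotypes inside signal sentences, creating the
    biochemical-over-clinical signal asymmetry.
    ``literature_depth_dispersion`` is the log-normal sigma of per-gene
    mention propensity (0 = homogeneous literature).
    """

    n_diseases: int = 200
    n_genes: int = 2000
    n_phenotypes: int = 400
    r_min: int = 3
    r_max: int = 12
    biochemical_fraction: float = 0.5
    n_sentences: int = 20_000
    signal_rate: float = 0.25
    background_rate: float = 0.5
    biochem_signal_boost: float = 3.0
    literature_depth_dispersion: float = 1.0
    shared_causal_genes: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("signal_rate", "background_rate", "biochemical_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.r_min < 1 or self.r_max < self.r_min:
            raise ConfigurationError("need 1 <= r_min <= r_max")
        if self.r_max > self.n_phenotypes:
            raise ConfigurationError("profile size exceeds phenotype vocabulary")
        if not self.shared_causal_genes and self.n_genes < self.n_diseases:
            raise ConfigurationError("need n_genes >= n_diseases for unique causal genes")
        if self.biochem_signal_boost < 0:
            raise ConfigurationError("biochem_signal_boost must be >= 0")
        if self.n_sentences < 0 or self.n_diseases < 1:
            raise ConfigurationError("n_sentences >= 0 and n_diseases >= 1 required")


@dataclass
class SyntheticWorld:
    """A generated knowledgebase, corpus, and ground truth."""

    config: SimulationConfig
    knowledgebase: Knowledgebase
    sentences: tuple[SentenceRecord, ...]
    causal_gene: dict[str, str]  # disease_id -> gene_id
    phenotype_category: dict[str, str]  # term_id -> category

    @property
    def truth(self) -> dict:
        return {
            "causal_gene": self.causal_gene,
            "phenotype_category": self.phenotype_category,
        }


def _phenotype_vocabulary(
    config: SimulationConfig, rng: np.random.Generator
) -> list[PhenotypeTerm]:
    n_biochem = int(round(config.n_phenotypes * config.biochemical_fraction))
    terms = []
    for i in range(config.n_phenotypes):
        term_id = f"PHEN{i + 1:05d}"
        if i < n_biochem:
            specimen = SPECIMENS[int(rng.integers(len(SPECIMENS)))]
            terms.append(
                PhenotypeTerm(term_id, f"Metabolite {i + 1:03d}", "biochemical", specimen)
            )
        else:
            terms.append(
                PhenotypeTerm(term_id, f"Clinical sign {i + 1:03d}", "clinical")
            )
    return terms


def generate_world(config: SimulationConfig) -> SyntheticWorld:
    """Generate a full synthetic world from the config (deterministic per seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = [f"GENE{i + 1:05d}" for i in range(config.n_genes)]
    vocab = _phenotype_vocabulary(config, rng)
    biochem = [t for t in vocab if t.category == "biochemical"]
    clinical = [t for t in vocab if t.category == "clinical"]

    # causal genes: a random draw, unique per disease unless shared allowed
    if config.shared_causal_genes:
        causal_idx = rng.integers(config.n_genes, size=config.n_diseases)
    else:
        causal_idx = rng.permutation(config.n_genes)[: config.n_diseases]

    pairs = []
    causal_gene: dict[str, str] = {}
    for d in range(config.n_diseases):
        disease_id = f"DIS{d + 1:04d}"
        gene_id = genes[int(causal_idx[d])]
        r = int(rng.integers(config.r_min, config.r_max + 1))
        n_bio = int(round(r * config.biochemical_fraction))
        n_bio = min(n_bio, len(biochem))
        n_cli = min(r - n_bio, len(clinical))
        profile_terms: list[PhenotypeTerm] = []
        if n_bio:
            idx = rng.choice(len(biochem), size=n_bio, replace=False)
            profile_terms.extend(biochem[i] for i in sorted(idx))
        if n_cli:
            idx = rng.choice(len(clinical), size=n_cli, replace=False)
            profile_terms.extend(clinical[i] for i in sorted(idx))
        causal_gene[disease_id] = gene_id
        pairs.append(
            DiseaseGenePair(
                disease_id=disease_id,
                disease_name=f"Synthetic disorder {d + 1:04d}",
                gene_id=gene_id,
                profile=PhenotypeProfile(tuple(profile_terms), disease_id),
            )
        )
    kb = Knowledgebase(tuple(pairs))

    # heavy-tailed per-gene literature depth
    if config.literature_depth_dispersion > 0:
        gene_weights = rng.lognormal(
            mean=0.0, sigma=config.literature_depth_dispersion, size=config.n_genes
        )
    else:
        gene_weights = np.ones(config.n_genes)
    gene_weights = gene_weights / gene_weights.sum()

    sentences = []
    all_phen_ids = [t.term_id for t in vocab]
    profile_weights = {}
    for pair in pairs:
        w = np.array(
            [
                config.biochem_signal_boost if p.category == "biochemical" else 1.0
                for p in pair.profile.phenotypes
            ]
        )
        total = w.sum()
        profile_weights[pair.disease_id] = w / total if total > 0 else None

    for s in range(config.n_sentences):
        sentence_id = f"S{s + 1:07d}"
        if rng.random() < config.signal_rate:
            pair = pairs[int(rng.integers(config.n_diseases))]
            w = profile_weights[pair.disease_id]
            phen = pair.profile.phenotypes[
                int(rng.choice(pair.profile.size, p=w))
            ]
            mentions = {(pair.gene_id, GENE), (phen.term_id, PHENOTYPE)}
        elif rng.random() < config.background_rate:
            g = genes[int(rng.choice(config.n_genes, p=gene_weights))]
            p = all_phen_ids[int(rng.integers(config.n_phenotypes))]
            mentions = {(g, GENE), (p, PHENOTYPE)}
        elif rng.random() < 0.5:
            g = genes[int(rng.choice(config.n_genes, p=gene_weights))]
            mentions = {(g, GENE)}
        else:
            p = all_phen_ids[int(rng.integers(config.n_phenotypes))]
            mentions = {(p, PHENOTYPE)}
        sentences.append(SentenceRecord(sentence_id, frozenset(mentions)))

    return SyntheticWorld(
        config=config,
        knowledgebase=kb,
        sentences=tuple(sentences),
        causal_gene=causal_gene,
        phenotype_category={t.term_id: t.category for t in vocab},
    )


# ---------------------------------------------------------------------------
# Toy ontology
# ---------------------------------------------------------------------------

ROOT_ID = "TOY:0000118"


def generate_toy_ontology(
    n_subclasses: int = 26,
    depth: int = 2,
    branching: int = 2,
    seed: int = 0,
    iem_names: list[str] | None = None,
    n_exact: int = 0,
    n_containment: int = 0,
    n_multi: int = 0,
    synonym_fraction: float = 0.0,
) -> Ontology:
    """Build a rooted DAG ontology with planted vocabulary overlap.

    The root gets ``n_subclasses`` direct children, each the apex of a
    tree of the given depth and branching factor with generic, disjoint
    leaf names. When ``iem_names`` is given, the first ``n_exact`` names
    are planted verbatim as extra leaves, the next ``n_containment``
    as "Elevated <name> level" (a strict token superset), and
    ``n_multi`` extra leaves are attached under two subclasses each.
    A ``synonym_fraction`` of filler terms receives one synonym.
    """
    if n_subclasses < 1 or depth < 0 or branching < 1:
        raise ConfigurationError("n_subclasses >= 1, depth >= 0, branching >= 1")
    need = n_exact + n_containment
    if iem_names is not None and need > len(iem_names):
        raise ConfigurationError("overlap plan exceeds supplied vocabulary")

    rng = np.random.default_rng(seed)
    terms: dict[str, OntologyTerm] = {
        ROOT_ID: OntologyTerm(ROOT_ID, "Phenotypic abnormality")
    }
    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"TOY:1{counter[0]:06d}"  # disjoint from the root's id range

    subclass_ids = []
    for i in range(n_subclasses):
        tid = new_id()
        subclass_ids.append(tid)
        terms[tid] = OntologyTerm(
            tid, f"Abnormality of system {i + 1:02d}", parent_ids=(ROOT_ID,)
        )
        frontier = [tid]
        for _ in range(depth):
            next_frontier = []
            for parent in frontier:
                for _ in range(branching):
                    cid = new_id()
                    name = f"Finding {counter[0]:05d}"
                    synonyms = ()
                    if rng.random() < synonym_fraction:
                        synonyms = (f"{name} variant",)
                    terms[cid] = OntologyTerm(
                        cid, name, synonyms=synonyms, parent_ids=(parent,)
                    )
                    next_frontier.append(cid)
            frontier = next_frontier

    def attach(name: str, parents: tuple[str, ...]) -> None:
        tid = new_id()
        terms[tid] = OntologyTerm(tid, name, parent_ids=parents)

    if iem_names is not None:
        for name in iem_names[:n_exact]:
            attach(name, (subclass_ids[int(rng.integers(n_subclasses))],))
        for name in iem_names[n_exact:need]:
            attach(
                f"Elevated {name} level",
                (subclass_ids[int(rng.integers(n_subclasses))],),
            )
    for j in range(n_multi):
        a, b = rng.choice(n_subclasses, size=2, replace=False)
        attach(f"Crosscutting finding {j + 1:03d}", (subclass_ids[a], subclass_ids[b]))

    return Ontology(terms=terms, root_id=ROOT_ID)


# ---------------------------------------------------------------------------
# Serialization of a world to a directory
# ---------------------------------------------------------------------------

def write_world(world: SyntheticWorld, out_dir, ontology: Ontology | None = None) -> None:
    """Write kb.csv, corpus.tsv, truth.json (and onto.obo) under out_dir."""
    import os

    from .cooccur import write_sentences
    from .kb_io import write_knowledgebase, write_obo

    os.makedirs(out_dir, exist_ok=True)
    write_knowledgebase(world.knowledgebase, os.path.join(out_dir, "kb.csv"))
    write_sentences(world.sentences, os.path.join(out_dir, "corpus.tsv"))
    with open(os.path.join(out_dir, "truth.json"), "w", encoding="utf-8") as fh:
        json.dump(
            {"config": asdict(world.config), **world.truth}, fh, indent=2, sort_keys=True
        )
    if ontology is not None:
        write_obo(ontology, os.path.join(out_dir, "onto.obo"))
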