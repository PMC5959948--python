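"""Sentence-level co-occurrence store and gene-phenotype association scores.

The evidence unit is a sentence in which entities (genes and phenotype
concepts) are mentioned. The store keeps, per entity, the number of
sentences mentioning it, and per (gene, phenotype) pair, the number of
sentences mentioning both. The association between a gene g and a
phenotype p is the ratio of the joint sentence count to a marginal
denominator; the association with a full phenotypic profile P is the sum
of the per-phenotype scores, s_{g,P} = sum_i score(g, p_i).

Three denominator conventions are supported:

- ``sum``       n(g,p) / (n(g) + n(p))                       (default)
- ``union``     n(g,p) / (n(g) + n(p) - n(g,p))              (Jaccard)
- ``exclusive`` n(g,p) / ((n(g) - n(g,p)) + (n(p) - n(g,p)))

All are monotone in the joint count at fixed marginals; a zero denominator
scores 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import DomainError, InputError
from .kb_io import PhenotypeProfile

logger = logging.getLogger(__name__)

GENE = "gene"
PHENOTYPE = "phenotype"
DENOMINATOR_MODES = ("sum", "union", "exclusive")


@dataclass(frozen=True)
class SentenceRecord:
    """One sentence as the set of entities it mentions."""

    sentence_id: str
    mentions: frozenset[tuple[str, str]]  # (entity_id, entity_type)

    def __post_init__(self) -> None:
        if not self.mentions:
            raise InputError(f"sentence {self.sentence_id} has no mentions")
        ids = [e for e, _ in self.mentions]
        if len(set(ids)) != len(ids):
            raise InputError(
                f"sentence {self.sentence_id} lists an entity with two types"
            )


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class CooccurrenceStore:
    """Per-entity and per-pair sentence counts; the sole evidence source."""

    entity_counts: dict[str, int] = field(default_factory=dict)
    pair_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    entity_types: dict[str, str] = field(default_factory=dict)

    @property
    def gene_universe(self) -> set[str]:
        return {e for e, t in self.entity_types.items() if t == GENE}

    def n(self, entity_id: str) -> int:
        return self.entity_counts.get(entity_id, 0)

    def n_pair(self, a: str, b: str) -> int:
        return self.pair_counts.get(_pair_key(a, b), 0)

    def validate(self) -> None:
        for (a, b), npair in self.pair_counts.items():
            if npair > min(self.n(a), self.n(b)):
                raise InputError(
                    f"pair count n({a},{b})={npair} exceeds a marginal"
                )
            if npair < 0:
                raise InputError("negative pair count")


def build_store(sentences: Iterable[SentenceRecord]) -> CooccurrenceStore:
    """Tally sentence-level presence/absence counts into a store.

    Each sentence contributes at most 1 to any entity or pair count.
    Pair counts are kept only for (gene, phenotype) pairs co-mentioned at
    least once; same-type pairs are not stored.
    """
    store = CooccurrenceStore()
    seen_ids: set[str] = set()
    for sent in sentences:
        if sent.sentence_id in seen_ids:
            raise InputError(f"duplicate sentence_id {sent.sentence_id!r}")
        seen_ids.add(sent.sentence_id)
        mentions = sorted(sent.mentions)
        for entity_id, entity_type in mentions:
            known = store.entity_types.get(entity_id)
            if known is not None and known != entity_type:
                raise InputError(
                    f"entity {entity_id!r} typed both {known} and {entity_type}"
                )
            store.entity_types[entity_id] = entity_type
            store.entity_counts[entity_id] = store.entity_counts.get(entity_id, 0) + 1
        genes = [e for e, t in mentions if t == GENE]
        phens = [e for e, t in mentions if t == PHENOTYPE]
        for g in genes:
            for p in phens:
                key = _pair_key(g, p)
                store.pair_counts[key] = store.pair_counts.get(key, 0) + 1
    return store


def association_score(
    store: CooccurrenceStore,
    gene_id: str,
    phenotype_id: str,
    denominator_mode: str = "sum",
) -> float:
    """Per-phenotype association score of one gene.

    Unknown entities have count 0 and score 0 — incomplete literature
    coverage is expected, not an error.
    """
    if denominator_mode not in DENOMINATOR_MODES:
        raise DomainError(f"unknown denominator_mode {denominator_mode!r}")
    joint = store.n_pair(gene_id, phenotype_id)
    if joint == 0:
        return 0.0
    ng, np_ = store.n(gene_id), store.n(phenotype_id)
    if denominator_mode == "sum":
        denom = ng + np_
    elif denominator_mode == "union":
        denom = ng + np_ - joint
    else:  # exclusive
        denom = (ng - joint) + (np_ - joint)
    return joint / denom if denom > 0 else 0.0


def profile_score(
    store: CooccurrenceStore,
    gene_id: str,
    profile: PhenotypeProfile,
    entity_map: Mapping[str, str] | None = None,
    denominator_mode: str = "sum",
) -> float:
    """Association score s_{g,P} between a gene and a full profile.

    ``entity_map`` translates phenotype term_ids to corpus entity ids
    (identity when omitted). Phenotypes that do not resolve are skipped
    with a warning; a profile resolving to zero entities is an error.
    """
    resolved = []
    for p in profile.phenotypes:
        if entity_map is None:
            resolved.append(p.term_id)
        elif p.term_id in entity_map:
            resolved.append(entity_map[p.term_id])
        else:
            logger.warning(
                "phenotype %s of %s has no corpus entity; skipped",
                p.term_id, profile.disease_ref,
            )
    if not resolved:
        raise DomainError(
            f"profile {profile.disease_ref} resolves to zero corpus entities"
        )
    return sum(
        association_score(store, gene_id, e, denominator_mode) for e in resolved
    )


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------

def read_sentences(path) -> list[SentenceRecord]:
    """Read a sentences TSV: sentence_id <tab> entity_id:type,entity_id:type."""
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                sentence_id, mention_field = line.split("\t")
                mentions = frozenset(
                    tuple(tok.rsplit(":", 1)) for tok in mention_field.split(",")
                )
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: malformed sentence line") from exc
            records.append(SentenceRecord(sentence_id, mentions))
    return records


def write_sentences(sentences: Iterable[SentenceRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sent in sentences:
            field_ = ",".join(f"{e}:{t}" for e, t in sorted(sent.mentions))
            fh.write(f"{sent.sentence_id}\t{field_}\n")


def write_store(store: CooccurrenceStore, out_dir) -> None:
    """Persist the store as entities.tsv and pairs.tsv under out_dir."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    entity_rows = [
        {"entity_id": e, "entity_type": store.entity_types[e], "n": n}
        for e, n in sorted(store.entity_counts.items())
    ]
    pd.DataFrame(entity_rows, columns=["entity_id", "entity_type", "n"]).to_csv(
        os.path.join(out_dir, "entities.tsv"), sep="\t", index=False
    )
    rows = [
        {"entity_a": a, "entity_b": b, "n_pair": n}
        for (a, b), n in sorted(store.pair_counts.items())
    ]
    pd.DataFrame(rows, columns=["entity_a", "entity_b", "n_pair"]).to_csv(
        os.path.join(out_dir, "pairs.tsv"), sep="\t", index=False
    )


def read_store(store_dir) -> CooccurrenceStore:
    """Load a store from the entities.tsv/pairs.tsv pair written by write_store."""
    import os

    entities = pd.read_csv(os.path.join(store_dir, "entities.tsv"), sep="\t")
    pairs = pd.read_csv(os.path.join(store_dir, "pairs.tsv"), sep="\t")
    store = CooccurrenceStore(
        entity_counts={r.entity_id: int(r.n) for r in entities.itertuples()},
        pair_counts={
            _pair_key(r.entity_a, r.entity_b): int(r.n_pair)
            for r in pairs.itertuples()
        },
        entity_types={
            r.entity_id: r.entity_type for r in entities.itertuples()
        },
    )
    store.validate()
    return store
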