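"""Lexical normalization and containment mapping of phenotype vocabularies.

Two curated vocabularies rarely share exact phenotype wording. The mapping
here reduces each name to a normalized bag of word tokens — lowercase,
punctuation-free, stop words dropped, plurals reduced, duplicates removed,
alphabetically sorted — and declares a match when an ontology term's token
set either equals (exact) or strictly contains (containment) a
knowledgebase term's token set. The direction is deliberately asymmetric:
the more richly worded ontology name may contain the terse biochemical
name ("elevated urinary homovanillic acid" contains "homovanillic acid"),
never the reverse.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import DomainError
from .kb_io import Ontology, PhenotypeTerm, top_level_subclasses

logger = logging.getLogger(__name__)

#: minimal English stop-word list; configurable per call.
DEFAULT_STOP_WORDS = frozenset(
    {"a", "an", "and", "by", "for", "in", "of", "on", "or", "the", "to", "with"}
)

#: bucket label for ontology terms reachable through several top-level classes
MULTI_SUBCLASS = "multiple_subclasses"

_NON_ALNUM_RE = re.compile(r"[^a-z0-9]+")


@dataclass(frozen=True)
class NormalizedName:
    """Sorted, deduplicated lowercase token set with its source string."""

    tokens: tuple[str, ...]
    source: str

    @property
    def is_normalizable(self) -> bool:
        return len(self.tokens) > 0

    @property
    def token_set(self) -> frozenset[str]:
        return frozenset(self.tokens)


@dataclass(frozen=True)
class TermMapping:
    """One knowledgebase term mapped to one ontology term."""

    iem_term_id: str
    hpo_term_id: str
    match_kind: str  # "exact" or "containment"
    matched_string: str


@dataclass
class MappingSummary:
    """Counts describing a vocabulary mapping run.

    ``n_associations`` counts (knowledgebase term, ontology term) pairs;
    one knowledgebase term may associate with many ontology terms.
    """

    n_iem_mapped: int
    n_associations: int
    n_unique_hpo: int
    n_iem_unmapped: int
    total_iem: int
    per_subclass: pd.DataFrame  # columns: subclass_id, n_associations, n_unique_hpo
    adjacency: pd.DataFrame  # long format: iem_term_id, subclass_id, count

    def mapped_percent(self, decimals: int = 0) -> float:
        """Share of knowledgebase terms with at least one mapping, in %."""
        return round(100.0 * self.n_iem_mapped / self.total_iem, decimals)


def _reduce_plural(token: str) -> str:
    """Ordered suffix rules approximating singular/plural merging."""
    if len(token) > 3 and token.endswith("ies"):
        return token[:-3] + "y"
    if len(token) > 3 and token.endswith("ses"):
        return token[:-3] + "sis"
    if len(token) > 3 and token.endswith("xes"):
        return token[:-2]
    if len(token) > 1 and token.endswith("s") and not token.endswith(("ss", "us", "is")):
        return token[:-1]
    return token


def normalize_name(
    raw: str, stop_words: Iterable[str] = DEFAULT_STOP_WORDS
) -> NormalizedName:
    """Normalize a phenotype name to a sorted token tuple.

    Case, punctuation, stop words, plural suffixes, duplicate tokens and
    word order are all removed, so two names differing only in those
    respects normalize identically. A name consisting entirely of stop
    words/punctuation yields an empty token tuple (``is_normalizable``
    False); callers exclude such names from matching.
    """
    if not raw:
        raise DomainError("cannot normalize an empty string")
    stop = frozenset(stop_words)
    words = _NON_ALNUM_RE.sub(" ", raw.lower()).split()
    # filter stop words both before and after plural reduction: a reduced
    # token may itself be a stop word, and idempotence requires it to go
    reduced = {_reduce_plural(w) for w in words if w not in stop}
    tokens = sorted(t for t in reduced if t not in stop)
    if not tokens:
        logger.warning("name %r normalizes to zero tokens; unnormalizable", raw)
    return NormalizedName(tokens=tuple(tokens), source=raw)


def is_match(hpo_name: NormalizedName, iem_name: NormalizedName) -> str | None:
    """Classify the (ontology, knowledgebase) name pair.

    Returns ``"exact"`` when the token sets are equal, ``"containment"``
    when the ontology tokens strictly contain the knowledgebase tokens,
    and ``None`` otherwise. Containment never holds in the reverse
    direction.
    """
    if not hpo_name.is_normalizable or not iem_name.is_normalizable:
        return None
    h, i = hpo_name.token_set, iem_name.token_set
    if h == i:
        return "exact"
    if h > i:
        return "containment"
    return None


def map_vocabularies(
    iem_terms: Sequence[PhenotypeTerm],
    hpo_strings: Sequence[tuple[str, str]],
    stop_words: Iterable[str] = DEFAULT_STOP_WORDS,
    category: str | None = None,
) -> list[TermMapping]:
    """All-pairs containment mapping of knowledgebase terms onto ontology strings.

    ``hpo_strings`` is the (term_id, name-or-synonym) collection produced by
    :func:`phenorank.kb_io.abnormality_subtree`. Matches through different
    synonym strings of the same ontology term collapse to a single record,
    keeping the best match kind (exact beats containment).

    ``category`` optionally restricts the knowledgebase side (the curation
    assessment runs on biochemical terms only).
    """
    if category is not None:
        iem_terms = [t for t in iem_terms if t.category == category]
    if not iem_terms or not hpo_strings:
        logger.warning("empty vocabulary side; no mappings produced")
        return []

    normalized_hpo: list[tuple[str, str, NormalizedName]] = []
    for term_id, string in hpo_strings:
        norm = normalize_name(string, stop_words)
        if norm.is_normalizable:
            normalized_hpo.append((term_id, string, norm))

    best: dict[tuple[str, str], TermMapping] = {}
    rank = {"exact": 0, "containment": 1}
    for iem in iem_terms:
        iem_norm = normalize_name(iem.name, stop_words)
        if not iem_norm.is_normalizable:
            continue
        for hpo_id, string, hpo_norm in normalized_hpo:
            kind = is_match(hpo_norm, iem_norm)
            if kind is None:
                continue
            key = (iem.term_id, hpo_id)
            prev = best.get(key)
            if prev is None or rank[kind] < rank[prev.match_kind]:
                best[key] = TermMapping(iem.term_id, hpo_id, kind, string)
    return sorted(best.values(), key=lambda m: (m.iem_term_id, m.hpo_term_id))


def summarize_mapping(
    mappings: Sequence[TermMapping],
    ontology: Ontology,
    total_iem: int,
) -> MappingSummary:
    """Aggregate mapping records into counts grouped by top-level subclass.

    An ontology term reachable through several top-level subclasses is
    tallied once in a dedicated multiple-subclasses bucket rather than
    double-counted.
    """
    subclass_of: dict[str, str] = {}
    for hpo_id in {m.hpo_term_id for m in mappings}:
        if hpo_id not in ontology:
            raise DomainError(f"mapped term {hpo_id!r} not in ontology")
        tops = top_level_subclasses(ontology, hpo_id)
        subclass_of[hpo_id] = MULTI_SUBCLASS if len(tops) > 1 else next(iter(tops))

    rows = [
        {
            "iem_term_id": m.iem_term_id,
            "hpo_term_id": m.hpo_term_id,
            "subclass_id": subclass_of[m.hpo_term_id],
        }
        for m in mappings
    ]
    df = pd.DataFrame(rows, columns=["iem_term_id", "hpo_term_id", "subclass_id"])
    if df.empty:
        per_subclass = pd.DataFrame(
            columns=["subclass_id", "n_associations", "n_unique_hpo"]
        )
        adjacency = pd.DataFrame(columns=["iem_term_id", "subclass_id", "count"])
    else:
        per_subclass = (
            df.groupby("subclass_id")
            .agg(
                n_associations=("hpo_term_id", "size"),
                n_unique_hpo=("hpo_term_id", "nunique"),
            )
            .reset_index()
            .sort_values("subclass_id", ignore_index=True)
        )
        adjacency = (
            df.groupby(["iem_term_id", "subclass_id"])
            .size()
            .rename("count")
            .reset_index()
            .sort_values(["iem_term_id", "subclass_id"], ignore_index=True)
        )

    n_mapped = df["iem_term_id"].nunique() if not df.empty else 0
    summary = MappingSummary(
        n_iem_mapped=n_mapped,
        n_associations=len(mappings),
        n_unique_hpo=df["hpo_term_id"].nunique() if not df.empty else 0,
        n_iem_unmapped=total_iem - n_mapped,
        total_iem=total_iem,
        per_subclass=per_subclass,
        adjacency=adjacency,
    )
    assert summary.n_iem_mapped + summary.n_iem_unmapped == total_iem
    return summary
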