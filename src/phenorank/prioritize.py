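"""Rank the gene universe by profile association score, keep the top K.

Every gene in the universe is scored against the profile; genes are sorted
by score descending with ties broken by ascending gene id so the ordering
is fully deterministic, then the list is truncated to the K best (default
100). Genes with score exactly 0 are not retained by default — zero
evidence should not occupy top-list slots by id order. A causal gene that
falls outside the retained list gets the censored sentinel rank K + 1:
all that is known is "worse than K".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .cooccur import CooccurrenceStore, profile_score
from .errors import ConfigurationError
from .kb_io import PhenotypeProfile

DEFAULT_K = 100


@dataclass(frozen=True)
class RankEntry:
    gene_id: str
    score: float
    rank: int


@dataclass(frozen=True)
class RankedPredictions:
    """Ordered top-K gene predictions for one disease profile."""

    disease_id: str
    entries: tuple[RankEntry, ...]
    k: int

    def __post_init__(self) -> None:
        scores = [e.score for e in self.entries]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ConfigurationError("entry scores must be non-increasing")
        if [e.rank for e in self.entries] != list(range(1, len(self.entries) + 1)):
            raise ConfigurationError("ranks must be 1..len without gaps")

    @property
    def censored_sentinel(self) -> int:
        return self.k + 1


def rank_genes(
    store: CooccurrenceStore,
    profile: PhenotypeProfile,
    gene_universe: Iterable[str] | None = None,
    k: int = DEFAULT_K,
    entity_map: Mapping[str, str] | None = None,
    denominator_mode: str = "sum",
    include_zero: bool = False,
) -> RankedPredictions:
    """Score and rank every gene in the universe for one profile.

    ``gene_universe`` defaults to the store's gene entities. With
    ``include_zero`` False (default), zero-score genes are dropped before
    truncation, so the retained list may be shorter than K.
    """
    universe = sorted(gene_universe) if gene_universe is not None else sorted(
        store.gene_universe
    )
    if not universe:
        raise ConfigurationError("gene universe is empty")
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")

    scored = [
        (g, profile_score(store, g, profile, entity_map, denominator_mode))
        for g in universe
    ]
    if not include_zero:
        scored = [(g, s) for g, s in scored if s > 0.0]
    scored.sort(key=lambda gs: (-gs[1], gs[0]))
    entries = tuple(
        RankEntry(gene_id=g, score=s, rank=i)
        for i, (g, s) in enumerate(scored[:k], start=1)
    )
    return RankedPredictions(disease_id=profile.disease_ref, entries=entries, k=k)


def causal_rank(predictions: RankedPredictions, gene_id: str) -> tuple[int, bool]:
    """Rank of ``gene_id`` in the retained list, or (K+1, censored=True)."""
    for entry in predictions.entries:
        if entry.gene_id == gene_id:
            return entry.rank, False
    return predictions.censored_sentinel, True
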