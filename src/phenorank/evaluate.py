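"""Rank-based evaluation of causal-gene prioritization.

For every disease d with causal gene g_d, the rank of g_d in the top-K
predictions for d's profile is recorded (censored at K+1 when not
retained). Three views are computed: the full profile, the biochemical
subset and the clinical subset. A literature-prominence baseline assigns
each causal gene the median of its ranks across the predictions of all
diseases it does NOT cause. Performance is summarized as top-N success
tables (N = 1, 5, 10, 20, 100) and paired arms are compared with the
exact (central binomial) McNemar test, Bonferroni-corrected over the five
thresholds. The effect of profile size on rank is tested with Spearman
correlation among non-censored diseases.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

from scipy import stats

from .cooccur import CooccurrenceStore
from .errors import DomainError, InsufficientDataError
from .kb_io import Knowledgebase, PhenotypeProfile
from .prioritize import DEFAULT_K, RankedPredictions, causal_rank, rank_genes

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (1, 5, 10, 20, 100)
SUBSETS = ("all", "biochemical", "clinical")


@dataclass(frozen=True)
class CausalRankRecord:
    """Per-disease causal-gene ranks under each phenotype subset."""

    disease_id: str
    gene_id: str
    profile_size: int
    rank_all: int | None = None
    rank_biochemical: int | None = None
    rank_clinical: int | None = None
    baseline_rank: float | None = None

    def rank(self, subset_or_field: str) -> int | float | None:
        key = {
            "all": "rank_all",
            "biochemical": "rank_biochemical",
            "clinical": "rank_clinical",
            "baseline": "baseline_rank",
        }.get(subset_or_field, subset_or_field)
        return getattr(self, key)


@dataclass(frozen=True)
class SuccessTable:
    """Counts and percentages of diseases whose causal gene ranked <= N."""

    thresholds: tuple[int, ...]
    counts: tuple[int, ...]
    percentages: tuple[float, ...]
    n_total: int

    def count_at(self, n: int) -> int:
        return self.counts[self.thresholds.index(n)]

    def percent_at(self, n: int) -> float:
        return self.percentages[self.thresholds.index(n)]

    def unresolved_at(self, n: int) -> int:
        """Diseases whose causal gene was NOT within the top n."""
        return self.n_total - self.count_at(n)


@dataclass(frozen=True)
class ThresholdComparison:
    n: int
    b: int  # arm A success, arm B failure
    c: int  # arm A failure, arm B success
    p_value: float
    p_adjusted: float


@dataclass(frozen=True)
class ComparisonResult:
    label: str
    per_threshold: tuple[ThresholdComparison, ...]

    def at(self, n: int) -> ThresholdComparison:
        for t in self.per_threshold:
            if t.n == n:
                return t
        raise KeyError(n)


def _round_half_up(value: Decimal, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(value.quantize(q, rounding=ROUND_HALF_UP))


def success_at_n(
    ranks: Sequence[int | float],
    n_total: int | None = None,
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
) -> SuccessTable:
    """Top-N success table from a collection of (possibly censored) ranks.

    Censored ranks are represented by any value exceeding every threshold
    (e.g. the K+1 sentinel). Percentages are 100*count/n_total rounded
    half-up to one decimal, matching conventional table formatting.
    """
    if n_total is None:
        n_total = len(ranks)
    if n_total < 1:
        raise DomainError("n_total must be >= 1")
    thresholds = tuple(thresholds)
    counts = tuple(sum(1 for r in ranks if r is not None and r <= n) for n in thresholds)
    percentages = tuple(
        _round_half_up(Decimal(100 * c) / Decimal(n_total), 1) for c in counts
    )
    return SuccessTable(thresholds, counts, percentages, n_total)


def mcnemar_exact(b: int, c: int) -> float:
    """Two-sided exact McNemar p-value from discordant pair counts.

    The conditional central binomial test: under the null the b discordant
    pairs of one kind among n = b + c follow Binomial(n, 1/2), and
    p = min(1, 2 * sum_{i=0}^{min(b,c)} C(n, i) / 2^n). Concordant pairs
    carry no information; b + c = 0 gives p = 1.
    """
    if b < 0 or c < 0 or b != int(b) or c != int(c):
        raise DomainError("discordant counts must be non-negative integers")
    n = b + c
    if n == 0:
        return 1.0
    tail = sum(math.comb(n, i) for i in range(min(b, c) + 1)) / 2.0**n
    return min(1.0, 2.0 * tail)


def compare_dichotomized(
    ranks_a: Sequence[int | float],
    ranks_b: Sequence[int | float],
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
    m_tests: int | None = None,
    label: str = "A-vs-B",
) -> ComparisonResult:
    """Paired comparison of two rank arms dichotomized at each threshold.

    At each N, a disease is a success in an arm when its rank there is
    <= N; b and c count the discordant diseases in either direction and
    feed the exact McNemar test. Bonferroni adjustment multiplies by
    ``m_tests`` (default: the number of thresholds) and caps at 1.
    """
    if len(ranks_a) != len(ranks_b):
        raise DomainError(
            f"paired arms differ in length: {len(ranks_a)} vs {len(ranks_b)}"
        )
    thresholds = tuple(thresholds)
    if m_tests is None:
        m_tests = len(thresholds)
    out = []
    for n in thresholds:
        b = sum(1 for ra, rb in zip(ranks_a, ranks_b) if ra <= n < rb)
        c = sum(1 for ra, rb in zip(ranks_a, ranks_b) if rb <= n < ra)
        p = mcnemar_exact(b, c)
        out.append(ThresholdComparison(n, b, c, p, min(1.0, m_tests * p)))
    return ComparisonResult(label=label, per_threshold=tuple(out))


def bonferroni(p: float, m_tests: int) -> float:
    """Bonferroni-adjusted p-value, capped at 1."""
    return min(1.0, m_tests * p)


# ---------------------------------------------------------------------------
# End-to-end evaluation over a knowledgebase
# ---------------------------------------------------------------------------

def _subset_profile(profile: PhenotypeProfile, subset: str) -> PhenotypeProfile | None:
    if subset == "all":
        return profile
    terms = profile.subset(subset)
    if not terms:
        return None
    return PhenotypeProfile(terms, profile.disease_ref)


def predictions_by_disease(
    kb: Knowledgebase,
    store: CooccurrenceStore,
    k: int = DEFAULT_K,
    subset: str = "all",
    entity_map: Mapping[str, str] | None = None,
    denominator_mode: str = "sum",
) -> dict[str, RankedPredictions | None]:
    """Top-K predictions per disease for one phenotype subset.

    A disease whose profile is empty under the subset filter maps to None
    (its causal rank will be censored) with a warning.
    """
    if subset not in SUBSETS:
        raise DomainError(f"subset must be one of {SUBSETS}")
    out: dict[str, RankedPredictions | None] = {}
    for pair in kb.pairs:
        sub = _subset_profile(pair.profile, subset)
        if sub is None:
            logger.warning(
                "disease %s has no %s phenotypes; rank censored",
                pair.disease_id, subset,
            )
            out[pair.disease_id] = None
            continue
        out[pair.disease_id] = rank_genes(
            store, sub, k=k, entity_map=entity_map,
            denominator_mode=denominator_mode,
        )
    return out


def baseline_median_ranks(
    predictions: Mapping[str, RankedPredictions | None],
    causal_gene: Mapping[str, str],
    k: int = DEFAULT_K,
) -> dict[str, float | None]:
    """Median rank of each causal gene across diseases it does not cause.

    Censored occurrences enter the median as the K+1 sentinel; with an
    even number of values the median is the mean of the two middle values.
    A gene causal for every disease has no baseline (None).
    """
    sentinel = k + 1
    out: dict[str, float | None] = {}
    for gene in set(causal_gene.values()):
        ranks = []
        for disease_id, preds in predictions.items():
            if causal_gene[disease_id] == gene:
                continue
            if preds is None:
                ranks.append(float(sentinel))
            else:
                r, _ = causal_rank(preds, gene)
                ranks.append(float(r))
        out[gene] = float(statistics.median(ranks)) if ranks else None
    return out


def evaluate_all(
    kb: Knowledgebase,
    store: CooccurrenceStore,
    k: int = DEFAULT_K,
    subsets: Sequence[str] = SUBSETS,
    entity_map: Mapping[str, str] | None = None,
    denominator_mode: str = "sum",
    with_baseline: bool = True,
) -> list[CausalRankRecord]:
    """One CausalRankRecord per disease with ranks for each requested subset.

    Ranks are censored at K+1 when the causal gene is outside the top K or
    the subset filter empties the profile. The baseline is computed from
    the full-profile ("all") predictions when those are requested.
    """
    causal = {pair.disease_id: pair.gene_id for pair in kb.pairs}
    ranks: dict[str, dict[str, int]] = {}
    all_predictions = None
    for subset in subsets:
        preds = predictions_by_disease(
            kb, store, k=k, subset=subset,
            entity_map=entity_map, denominator_mode=denominator_mode,
        )
        if subset == "all":
            all_predictions = preds
        ranks[subset] = {
            d: (k + 1 if p is None else causal_rank(p, causal[d])[0])
            for d, p in preds.items()
        }

    baseline: dict[str, float | None] = {}
    if with_baseline and all_predictions is not None:
        baseline = baseline_median_ranks(all_predictions, causal, k=k)

    records = []
    for pair in kb.pairs:
        records.append(
            CausalRankRecord(
                disease_id=pair.disease_id,
                gene_id=pair.gene_id,
                profile_size=pair.profile.size,
                rank_all=ranks.get("all", {}).get(pair.disease_id),
                rank_biochemical=ranks.get("biochemical", {}).get(pair.disease_id),
                rank_clinical=ranks.get("clinical", {}).get(pair.disease_id),
                baseline_rank=baseline.get(pair.gene_id),
            )
        )
    return records


def spearman_profile_size_effect(
    records: Sequence[CausalRankRecord],
    k: int = DEFAULT_K,
    rank_field: str = "rank_all",
) -> tuple[float, float]:
    """Spearman correlation of profile size with causal rank.

    Restricted to diseases whose causal gene is within the top K (rank not
    censored). Returns (rho, two-sided p) with tie correction and the
    t-approximation for significance.
    """
    qualifying = [
        (r.profile_size, getattr(r, rank_field))
        for r in records
        if getattr(r, rank_field) is not None and getattr(r, rank_field) <= k
    ]
    if len(qualifying) < 3:
        raise InsufficientDataError(
            f"need >= 3 non-censored records, have {len(qualifying)}"
        )
    sizes, ranks = zip(*qualifying)
    if len(set(sizes)) < 2 or len(set(ranks)) < 2:
        raise InsufficientDataError("correlation undefined for constant input")
    res = stats.spearmanr(sizes, ranks)
    return float(res.statistic), float(res.pvalue)
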