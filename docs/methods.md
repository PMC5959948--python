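# Methods

## Problem setting

A curated knowledgebase couples each disease *d* to a causal gene *g_d*
and a phenotypic profile *P* = {p₁, …, p_r}, where each phenotype is
labelled *biochemical* (laboratory-observable, often with a specimen
qualifier such as "(plasma)") or *clinical* (observable on examination).
The package answers two questions: how much of the biochemical
vocabulary an ontology of abnormal phenotypes already covers, and how
well sentence-level literature co-occurrence alone prioritizes *g_d*
from *P*.

## Lexical normalization and containment mapping

Phenotype names are reduced to normalized token sets: lowercase; every
non-alphanumeric character becomes a token boundary; stop words are
dropped (default list: a, an, and, by, for, in, of, on, or, the, to,
with — configurable); plural suffixes are reduced by ordered rules
(…ies→y, …ses→sis, …xes→x, trailing s dropped unless the token ends in
ss/us/is); tokens are deduplicated and sorted. Stop words are filtered
again after plural reduction because a reduced token can itself be a
stop word; this makes normalization idempotent, which the property suite
enforces. The normalizer emulates the behaviour of lexical-variant
normalization tools used in clinical NLP; it is deterministic and fully
specified rather than delegated to an external binary.

A match between an ontology string (name or synonym) and a knowledgebase
name is *exact* when their token sets are equal and *containment* when
the ontology tokens strictly contain the knowledgebase tokens.
Containment is token-set based, not substring based, and deliberately
asymmetric: the more verbose ontology name may contain the terse
biochemical name, never the reverse. Matches through different synonym
strings of one ontology term collapse to a single term-level mapping,
exact beating containment. Names that normalize to zero tokens are
flagged unnormalizable and excluded with a warning.

Specimen qualifiers — a single trailing parenthesized group in a raw
name, e.g. "Dopamine (plasma)" — are split into a separate field before
any matching, so specimen words cannot leak into lexical comparison.

Per-subclass summaries group mapped ontology terms by the root's direct
children from which they are reachable; a term reachable through several
subclasses goes once into a dedicated multiple-subclasses bucket rather
than being double-counted. A long-format adjacency table (knowledgebase
term, subclass, count) is emitted for external chord-style plotting.

## Association score and ranking

The evidence store keeps sentence-level presence/absence counts: n(e)
sentences mentioning entity e, n(g, p) sentences mentioning both gene g
and phenotype p (multiple mentions within one sentence count once). The
default per-phenotype score is

    score(g, p) = n(g, p) / (n(g) + n(p)),

the most literal reading of "sentences where the two appeared
individually" as a denominator. Two alternatives are selectable and
recorded in provenance: *union* (n(g)+n(p)−n(g,p), the Jaccard index of
the two sentence sets) and *exclusive* ((n(g)−n(g,p)) + (n(p)−n(g,p)),
zero denominator scoring 0). All modes are monotone in the joint count
at fixed marginals (exclusive only away from its degenerate
denominator-zero point). Unknown entities score 0 rather than erroring:
incomplete literature coverage is an expected property of the data, not
a fault. Profile scores are plain sums of per-phenotype scores, without
per-phenotype renormalization.

Ranking sorts all universe genes by score descending with ties broken by
ascending gene id, making the output fully deterministic; ordinal ranks
are assigned after the tie-break and the list is truncated to K
(default 100). Genes with score exactly 0 are excluded from retention by
default so that zero-evidence genes cannot occupy top slots by id order.
A causal gene outside the retained list gets the censored sentinel
K + 1, carrying exactly the information "worse than K".

## Evaluation

Per disease, causal ranks are computed for the full profile and for its
biochemical-only and clinical-only subsets; a subset that empties a
profile yields a censored rank with a warning. The baseline assigns each
causal gene the median of its ranks in the predictions of every disease
it does not cause, censored occurrences entering as the K + 1 sentinel
(the median is over all non-causal predictions, but only top-K ranks
exist; the sentinel preserves the ordering "beyond K" without inventing
precise ranks — dropping censored values instead is available as a
sensitivity mode through the underlying function). Success tables count
ranks ≤ N for N ∈ {1, 5, 10, 20, 100}; percentages are rounded half-up
to one decimal to match conventional table formatting.

Paired arms are compared with the exact McNemar test in its central
two-sided binomial form: with discordant counts b and c,
p = min(1, 2·Σ_{i≤min(b,c)} C(b+c, i)/2^{b+c}), and p = 1 when
b + c = 0. This closed form matches the default behaviour of the
standard exact-2×2 implementations and is verified in the tests both
against full enumeration of all 2^{b+c} outcomes (b + c ≤ 15) and
against an independent library implementation. Bonferroni adjustment
multiplies by 5 — the five thresholds form the test family — and caps
at 1. The profile-size effect is a tie-corrected Spearman correlation
between r and the causal rank, restricted to non-censored diseases,
with the t-approximation p-value; fewer than 3 qualifying records, or
constant inputs, raise an insufficient-data error rather than returning
NaN.

## Synthetic worlds

The generator emulates the statistical structure the analysis assumes,
not its surface: sentences are sets of entity identifiers, because the
evidence unit is the co-mention and nothing downstream reads natural
language. Each sentence is a signal sentence with probability
`signal_rate` — a uniformly chosen disease's causal gene paired with one
of its profile phenotypes, biochemical phenotypes upweighted by
`biochem_signal_boost` — otherwise a background sentence: with
probability `background_rate` a random gene–phenotype co-mention, else a
single-entity mention. Per-gene mention propensity is log-normal with
configurable sigma, reproducing the heavy-tailed, uneven depth of
literature across genes that limits recommendation systems in practice.
Causal genes are unique per disease by default (a flag allows sharing,
to exercise the baseline median across several non-causal diseases).
All randomness flows from a single seed; a fixed config is
byte-reproducible.

Default conditions (200 diseases, 2000-gene universe, 400 phenotypes,
profile sizes 3–12 with half biochemical, 20 000 sentences, signal rate
0.25 over background rate 0.5, boost 3, dispersion 1.0) were chosen once
as a desk-scale regime that keeps the qualitative behaviour of a
PubMed-scale corpus over a genome-wide universe: imperfect top-100
recovery, a biochemical-over-clinical advantage, and rank degradation
for under-described genes. The toy ontology plants vocabulary overlap by
plan — exact leaves, "Elevated … level" containment leaves, disjoint
filler — so mapping counts are known by construction.

What the worlds do **not** emulate: real medical vocabulary and its
lexical pathologies (the synthetic names are clean, so mapping tests
exercise the matching logic, not curation quality), semantic relations
between co-mentioned entities (a co-mention is counted whatever the
sentence asserted), citation-network correlation between genes, and
ontology semantics beyond is_a structure. Passing recovery tests
therefore shows the pipeline is correct and calibrated under its own
model; it does not predict absolute performance on real literature.

## Numerical and design choices

- Percentage rounding is decimal half-up (not banker's), via exact
  decimal division, so printed-table arithmetic is reproduced digit for
  digit.
- Ontology parsing accepts OBO 1.2 id/name/synonym/is_a/is_obsolete and
  ignores other tags; obsolete terms are dropped at parse time; the is_a
  graph must be acyclic (checked at construction). Parsing is delegated
  to `obonet`; parse failures are wrapped with file context.
- Tie between exact and containment for the same term pair resolves to
  exact; predictions tie-break by gene id; both choices exist purely for
  determinism.
- Problem sizes in the test and acceptance suites (worlds of 20–200
  diseases, corpora of 2 000–20 000 sentences, 10–20 seeds per
  statistical check) are desk-scale choices that keep every statistical
  property testable in seconds while leaving the asymptotic regimes
  (signal dominance, null exchangeability) clearly separated.

## Known limitations

- The manual-review step that a human curator would apply to machine
  matches cannot be automated; reported mappings are machine matches
  only, an upper bound on lexical (not semantic) agreement.
- Sentence-level co-occurrence has no semantic representation: a gene
  mentioned alongside a metabolite it does not regulate still counts.
  The generator reproduces this failure mode only through its uniform
  background co-mentions.
- The censored-sentinel convention for baseline medians is one defensible
  reading of "median rank" when only top-K ranks exist; conclusions at
  small K should be checked under the drop-censored sensitivity mode.
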