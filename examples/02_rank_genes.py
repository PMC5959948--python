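"""Score and rank genes for one phenotypic profile from a tiny corpus.

Six hand-written "sentences" (sets of entity mentions) are tallied into a
co-occurrence store; each gene's association with the two-phenotype
profile is the sum over phenotypes of n(g,p) / (n(g) + n(p)).
"""

from phenorank import (
    PhenotypeProfile,
    PhenotypeTerm,
    SentenceRecord,
    association_score,
    build_store,
    rank_genes,
)

sentences = [
    SentenceRecord("S1", frozenset({("DBH", "gene"), ("dopamine", "phenotype")})),
    SentenceRecord("S2", frozenset({("DBH", "gene"), ("dopamine", "phenotype")})),
    SentenceRecord("S3", frozenset({("DBH", "gene"), ("hypotension", "phenotype")})),
    SentenceRecord("S4", frozenset({("TH", "gene"), ("dopamine", "phenotype")})),
    SentenceRecord("S5", frozenset({("TH", "gene")})),
    SentenceRecord("S6", frozenset({("PAH", "gene"), ("phenylalanine", "phenotype")})),
]
store = build_store(sentences)

profile = PhenotypeProfile(
    (
        PhenotypeTerm("dopamine", "Dopamine", "biochemical", "plasma"),
        PhenotypeTerm("hypotension", "Hypotension, orthostatic", "clinical"),
    ),
    disease_ref="DBH-deficiency",
)

for gene in ("DBH", "TH", "PAH"):
    per = [association_score(store, gene, p.term_id) for p in profile.phenotypes]
    print(f"{gene}: per-phenotype scores {[round(s, 3) for s in per]}, "
          f"profile score {sum(per):.3f}")

predictions = rank_genes(store, profile, k=100)
print("\nranked predictions (score descending, ties by gene id):")
for entry in predictions.entries:
    print(f"  rank {entry.rank}: {entry.gene_id} (s = {entry.score:.3f})")
# DBH tops the list: it co-occurs with both profile phenotypes, whereas TH
# shares only the dopamine literature and PAH shares none.
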