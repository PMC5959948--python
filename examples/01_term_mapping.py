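"""Map a small biochemical-phenotype vocabulary onto a toy ontology.

Builds a toy ontology whose leaves overlap a six-term knowledgebase
vocabulary by plan (two exact names, three "Elevated ... level" supersets,
one unrelated term), then runs lexical normalization + containment
matching and prints the mapping summary.
"""

from phenorank import (
    PhenotypeTerm,
    abnormality_subtree,
    generate_toy_ontology,
    map_vocabularies,
    normalize_name,
    summarize_mapping,
)

names = [
    "Homovanillic acid",
    "Lactate",
    "Phenylalanine",
    "Glutaric acid",
    "Methionine",
    "Orotic acid",
]
terms = [
    PhenotypeTerm(f"IEM:{i:03d}", name, "biochemical", "plasma")
    for i, name in enumerate(names)
]

ontology = generate_toy_ontology(
    n_subclasses=5, depth=1, branching=2, seed=0,
    iem_names=names, n_exact=2, n_containment=3, n_multi=1,
)

print("normalization example:")
norm = normalize_name("Hypotension, orthostatic")
print(f"  'Hypotension, orthostatic' -> tokens {norm.tokens}")

strings = abnormality_subtree(ontology)
mappings = map_vocabularies(terms, strings, category="biochemical")
summary = summarize_mapping(mappings, ontology, total_iem=len(terms))

print(f"\nontology strings under root: {len(strings)}")
for m in mappings:
    print(f"  {m.iem_term_id} -> {m.hpo_term_id} ({m.match_kind})"
          f" via '{m.matched_string}'")
print(
    f"\n{summary.n_iem_mapped}/{summary.total_iem} vocabulary terms mapped "
    f"({summary.mapped_percent(0):.0f}%), {summary.n_associations} associations "
    f"with {summary.n_unique_hpo} unique ontology terms; "
    f"{summary.n_iem_unmapped} unmapped."
)
# The mapped fraction mirrors the curation-coverage question: how much of a
# terse biochemical vocabulary a broader ontology already expresses.
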