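"""Evaluate prioritization on a synthetic world, end to end.

Generates a 60-disease world in which biochemical phenotypes carry five
times the per-sentence signal of clinical ones, ranks genes per disease
under the full / biochemical / clinical profiles, and prints top-N
success tables, the baseline comparison and the exact McNemar test of
biochemical vs clinical performance.
"""

from phenorank import (
    SimulationConfig,
    build_store,
    compare_dichotomized,
    evaluate_all,
    generate_world,
    spearman_profile_size_effect,
    success_at_n,
)

config = SimulationConfig(
    n_diseases=60, n_genes=800, n_phenotypes=200, n_sentences=4000,
    signal_rate=0.12, background_rate=0.6, biochem_signal_boost=5.0,
    literature_depth_dispersion=1.5, seed=11,
)
world = generate_world(config)
store = build_store(world.sentences)
records = evaluate_all(world.knowledgebase, store, k=100)

for subset, field in [("all", "rank_all"), ("biochemical", "rank_biochemical"),
                      ("clinical", "rank_clinical")]:
    table = success_at_n([getattr(r, field) for r in records])
    row = "  ".join(
        f"top{n}: {c} ({p}%)"
        for n, c, p in zip(table.thresholds, table.counts, table.percentages)
    )
    print(f"{subset:12s} {row}")

causal = [r.rank_all for r in records]
baseline = [r.baseline_rank for r in records]
comp = compare_dichotomized(causal, baseline, label="causal-vs-baseline")
print("\ncausal vs literature-prominence baseline (exact McNemar, Bonferroni x5):")
for t in comp.per_threshold:
    print(f"  N={t.n:3d}: b={t.b:2d} c={t.c:2d} adjusted p={t.p_adjusted:.3g}")

comp = compare_dichotomized(
    [r.rank_biochemical for r in records],
    [r.rank_clinical for r in records],
    label="biochemical-vs-clinical",
)
print("\nbiochemical vs clinical subsets:")
for t in comp.per_threshold:
    print(f"  N={t.n:3d}: b={t.b:2d} c={t.c:2d} adjusted p={t.p_adjusted:.3g}")

rho, p = spearman_profile_size_effect(records)
print(f"\nprofile-size effect on rank (non-censored diseases): "
      f"rho={rho:.3f}, p={p:.3f}")
# Larger b than c at every N says the biochemical subset alone recovers the
# causal gene more often than the clinical subset alone - the planted
# asymmetry the generator was configured with.
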