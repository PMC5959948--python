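"""One-shot orchestration: simulate/load -> map -> count -> rank -> evaluate.

A :class:`RunConfig` names either real input files (knowledgebase CSV,
OBO ontology, sentence corpus TSV) or a simulation block; the pipeline
executes every stage in order, writes each stage's outputs plus a
machine-readable ``summary.json`` under the output directory, and echoes
the config verbatim for provenance. Identical config and seed give
identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any, Sequence

import pandas as pd

from . import cooccur, evaluate, kb_io, prioritize, synthetic, term_mapping
from .errors import ConfigurationError, InsufficientDataError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs, parameters and output location of one pipeline run."""

    out_dir: str
    kb_path: str | None = None
    obo_path: str | None = None
    corpus_path: str | None = None
    simulate: dict[str, Any] | None = None
    k: int = prioritize.DEFAULT_K
    denominator_mode: str = "sum"
    thresholds: tuple[int, ...] = evaluate.DEFAULT_THRESHOLDS
    subsets: tuple[str, ...] = evaluate.SUBSETS
    stop_words: tuple[str, ...] = tuple(sorted(term_mapping.DEFAULT_STOP_WORDS))
    mapping_category: str = "biochemical"
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for name in ("thresholds", "subsets", "stop_words"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def validate(self) -> None:
        if self.simulate is None and (self.kb_path is None or self.corpus_path is None):
            raise ConfigurationError(
                "either a simulate block or kb_path + corpus_path is required"
            )
        if max(self.thresholds) > self.k:
            raise ConfigurationError("thresholds must not exceed k")


def _write_records(records, path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
        path, sep="\t", index=False
    )


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all stages; returns (and writes) the run summary."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    with open(os.path.join(config.out_dir, "config.json"), "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, sort_keys=True)

    # -- stage: inputs (simulate or load) ---------------------------------
    if config.simulate is not None:
        sim_cfg = synthetic.SimulationConfig(
            **{**config.simulate, "seed": config.simulate.get("seed", config.seed)}
        )
        world = synthetic.generate_world(sim_cfg)
        kb = world.knowledgebase
        sentences = world.sentences
        biochem_names = [
            t.name for t in kb.phenotypes if t.category == "biochemical"
        ]
        ontology = synthetic.generate_toy_ontology(
            seed=sim_cfg.seed,
            iem_names=biochem_names,
            n_exact=max(1, len(biochem_names) // 10),
            n_containment=max(1, len(biochem_names) // 7),
            n_multi=5,
            synonym_fraction=0.2,
        )
        synthetic.write_world(world, config.out_dir, ontology=ontology)
        logger.info(
            "stage=simulate diseases=%d genes=%d sentences=%d",
            sim_cfg.n_diseases, sim_cfg.n_genes, len(sentences),
        )
    else:
        kb = kb_io.read_knowledgebase(config.kb_path)
        sentences = cooccur.read_sentences(config.corpus_path)
        ontology = (
            kb_io.read_obo(config.obo_path) if config.obo_path is not None else None
        )
        logger.info(
            "stage=load diseases=%d sentences=%d", len(kb), len(sentences)
        )

    summary: dict[str, Any] = {
        "n_diseases": len(kb),
        "n_sentences": len(sentences),
        "k": config.k,
        "denominator_mode": config.denominator_mode,
        "seed": config.seed,
    }

    # -- stage: term mapping ----------------------------------------------
    if ontology is not None:
        hpo_strings = kb_io.abnormality_subtree(ontology)
        iem_terms = kb.phenotypes
        mappings = term_mapping.map_vocabularies(
            iem_terms, hpo_strings,
            stop_words=config.stop_words, category=config.mapping_category,
        )
        total = sum(1 for t in iem_terms if t.category == config.mapping_category)
        map_summary = term_mapping.summarize_mapping(mappings, ontology, total)
        pd.DataFrame([dataclasses.asdict(m) for m in mappings]).to_csv(
            os.path.join(config.out_dir, "mappings.tsv"), sep="\t", index=False
        )
        map_summary.per_subclass.to_csv(
            os.path.join(config.out_dir, "mapping_per_subclass.tsv"),
            sep="\t", index=False,
        )
        map_summary.adjacency.to_csv(
            os.path.join(config.out_dir, "mapping_adjacency.tsv"),
            sep="\t", index=False,
        )
        summary["mapping"] = {
            "n_iem_mapped": map_summary.n_iem_mapped,
            "n_associations": map_summary.n_associations,
            "n_unique_hpo": map_summary.n_unique_hpo,
            "n_iem_unmapped": map_summary.n_iem_unmapped,
            "mapped_percent": map_summary.mapped_percent(1),
        }
        logger.info(
            "stage=map-terms mapped=%d associations=%d",
            map_summary.n_iem_mapped, map_summary.n_associations,
        )

    # -- stage: co-occurrence store ---------------------------------------
    store = cooccur.build_store(sentences)
    cooccur.write_store(store, os.path.join(config.out_dir, "store"))
    summary["n_genes_in_corpus"] = len(store.gene_universe)
    logger.info("stage=build-store entities=%d", len(store.entity_counts))

    # -- stage: prioritize + evaluate -------------------------------------
    records = evaluate.evaluate_all(
        kb, store, k=config.k, subsets=config.subsets,
        denominator_mode=config.denominator_mode,
    )
    _write_records(records, os.path.join(config.out_dir, "records.tsv"))

    sentinel = config.k + 1
    tables: dict[str, evaluate.SuccessTable] = {}
    for subset in config.subsets:
        field_name = {"all": "rank_all", "biochemical": "rank_biochemical",
                      "clinical": "rank_clinical"}[subset]
        ranks = [getattr(r, field_name) for r in records]
        tables[subset] = evaluate.success_at_n(
            ranks, thresholds=config.thresholds
        )
    success_rows = []
    for subset, table in tables.items():
        for n, count, pct in zip(table.thresholds, table.counts, table.percentages):
            success_rows.append(
                {"subset": subset, "N": n, "count": count, "percent": pct}
            )
    pd.DataFrame(success_rows).to_csv(
        os.path.join(config.out_dir, "success_tables.tsv"), sep="\t", index=False
    )
    summary["success"] = {
        subset: dict(zip(map(str, t.thresholds), t.percentages))
        for subset, t in tables.items()
    }

    comparisons = {}
    if "all" in config.subsets:
        paired = [
            (r.rank_all, r.baseline_rank)
            for r in records if r.baseline_rank is not None
        ]
        if paired:
            a, b = zip(*paired)
            comparisons["causal_vs_baseline"] = evaluate.compare_dichotomized(
                a, b, thresholds=config.thresholds, label="causal-vs-baseline"
            )
    if {"biochemical", "clinical"} <= set(config.subsets):
        a = [r.rank_biochemical for r in records]
        b = [r.rank_clinical for r in records]
        comparisons["biochemical_vs_clinical"] = evaluate.compare_dichotomized(
            a, b, thresholds=config.thresholds, label="biochemical-vs-clinical"
        )
    summary["comparisons"] = {
        name: [dataclasses.asdict(t) for t in comp.per_threshold]
        for name, comp in comparisons.items()
    }
    with open(os.path.join(config.out_dir, "comparisons.json"), "w",
              encoding="utf-8") as fh:
        json.dump(summary["comparisons"], fh, indent=2)

    try:
        rho, p = evaluate.spearman_profile_size_effect(records, k=config.k)
        summary["profile_size_effect"] = {"rho": rho, "p": p}
    except InsufficientDataError:
        summary["profile_size_effect"] = None

    with open(os.path.join(config.out_dir, "summary.json"), "w",
              encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("stage=report out=%s", config.out_dir)
    return summary
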