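"""Knowledgebase and ontology input/output.

The knowledgebase is a long-format CSV: one row per (disease, gene,
phenotype). Phenotype names may carry a trailing parenthesized specimen
qualifier, e.g. ``Dopamine (plasma)``, which is split off into a separate
field before any lexical matching. The ontology is an OBO 1.2 flat file
(id / name / synonym / is_a / is_obsolete tags) rooted, for the analyses
here, at a "phenotypic abnormality"-style class whose direct children act
as top-level phenotype categories.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet
import pandas as pd

from .errors import (
    ConfigurationError,
    DomainError,
    EmptyInputError,
    OboParseError,
)

logger = logging.getLogger(__name__)

CATEGORIES = ("biochemical", "clinical")

#: default CSV header -> field mapping; override any entry via the
#: ``columns`` argument of :func:`read_knowledgebase`.
DEFAULT_COLUMNS: Mapping[str, str] = {
    "disease_id": "disease_id",
    "disease_name": "disease_name",
    "gene_id": "gene_id",
    "phenotype_name": "phenotype_name",
    "category": "category",
}

_SPECIMEN_RE = re.compile(r"^(?P<base>.*\S)\s*\((?P<specimen>[^()]+)\)\s*$")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypeTerm:
    """One curated phenotype of a disease profile.

    Parameters
    ----------
    term_id : str
        Opaque identifier, unique within the knowledgebase vocabulary.
    name : str
        Phenotype name with any specimen qualifier already removed.
    category : str
        ``"biochemical"`` (laboratory-observable abnormality) or
        ``"clinical"`` (abnormality observable on clinical examination).
    specimen : str or None
        Specimen qualifier if the raw name carried one, e.g. ``"plasma"``.
    """

    term_id: str
    name: str
    category: str
    specimen: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise DomainError("phenotype name must be non-empty")
        if self.category not in CATEGORIES:
            raise DomainError(
                f"category must be one of {CATEGORIES}, got {self.category!r}"
            )


@dataclass(frozen=True)
class PhenotypeProfile:
    """The set of phenotypes {p_1..p_r} describing one disease."""

    phenotypes: tuple[PhenotypeTerm, ...]
    disease_ref: str

    def __post_init__(self) -> None:
        if len(self.phenotypes) < 1:
            raise DomainError(f"profile for {self.disease_ref} is empty")
        ids = [p.term_id for p in self.phenotypes]
        if len(set(ids)) != len(ids):
            raise DomainError(f"duplicate term_ids in profile {self.disease_ref}")

    @property
    def size(self) -> int:
        return len(self.phenotypes)

    def subset(self, category: str) -> tuple[PhenotypeTerm, ...]:
        """Phenotypes of one category; may be empty."""
        return tuple(p for p in self.phenotypes if p.category == category)


@dataclass(frozen=True)
class DiseaseGenePair:
    """A disease coupled to its causal gene and phenotypic profile."""

    disease_id: str
    disease_name: str
    gene_id: str
    profile: PhenotypeProfile

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise DomainError(f"pair {self.disease_id} has empty gene_id")


@dataclass(frozen=True)
class Knowledgebase:
    """The set D of disease-gene pairs under study."""

    pairs: tuple[DiseaseGenePair, ...]

    def __post_init__(self) -> None:
        ids = [p.disease_id for p in self.pairs]
        if len(set(ids)) != len(ids):
            raise DomainError("disease_ids are not unique")
        for p in self.pairs:
            if p.profile.disease_ref != p.disease_id:
                raise DomainError(
                    f"profile of {p.disease_id} references {p.profile.disease_ref}"
                )

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def phenotypes(self) -> tuple[PhenotypeTerm, ...]:
        """All distinct phenotype terms across profiles (by term_id)."""
        seen: dict[str, PhenotypeTerm] = {}
        for pair in self.pairs:
            for p in pair.profile.phenotypes:
                seen.setdefault(p.term_id, p)
        return tuple(seen.values())


@dataclass(frozen=True)
class OntologyTerm:
    term_id: str
    name: str
    synonyms: tuple[str, ...] = ()
    parent_ids: tuple[str, ...] = ()


@dataclass
class Ontology:
    """An is_a DAG of ontology terms with a designated root class."""

    terms: dict[str, OntologyTerm]
    root_id: str
    _children: dict[str, list[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.root_id not in self.terms:
            raise ConfigurationError(f"root term {self.root_id!r} not in ontology")
        graph = nx.DiGraph()
        graph.add_nodes_from(self.terms)
        for term in self.terms.values():
            for parent in term.parent_ids:
                if parent not in self.terms:
                    raise OboParseError(
                        f"parent {parent!r} of {term.term_id!r} does not resolve"
                    )
                graph.add_edge(parent, term.term_id)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise OboParseError(f"is_a graph contains a cycle: {cycle}")
        self._children = {t: [] for t in self.terms}
        for term in self.terms.values():
            for parent in term.parent_ids:
                self._children[parent].append(term.term_id)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def children(self, term_id: str) -> tuple[str, ...]:
        return tuple(self._children[term_id])

    def descendants(self, term_id: str) -> set[str]:
        """All strict descendants of ``term_id`` (set semantics on a DAG)."""
        if term_id not in self.terms:
            raise DomainError(f"unknown term {term_id!r}")
        out: set[str] = set()
        stack = list(self._children[term_id])
        while stack:
            node = stack.pop()
            if node in out:
                continue
            out.add(node)
            stack.extend(self._children[node])
        return out


# ---------------------------------------------------------------------------
# Knowledgebase CSV
# ---------------------------------------------------------------------------

def split_specimen(raw_name: str) -> tuple[str, str | None]:
    """Split a single trailing parenthesized qualifier off a phenotype name.

    ``"Dopamine (plasma)"`` -> ``("Dopamine", "plasma")``; names without a
    trailing parenthesis are returned unchanged with specimen ``None``.
    """
    m = _SPECIMEN_RE.match(raw_name.strip())
    if m:
        return m.group("base"), m.group("specimen").strip()
    return raw_name.strip(), None


def read_knowledgebase(
    path,
    columns: Mapping[str, str] | None = None,
) -> Knowledgebase:
    """Read a long-format disease/gene/phenotype CSV into a Knowledgebase.

    Rows sharing (disease, gene) are merged into one pair; duplicate
    phenotype rows within a disease are dropped (a profile is a set).
    A ``specimen`` column, if present, overrides qualifier splitting.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"knowledgebase file {path} is empty") from exc
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing required columns: {missing}")
    if df.empty:
        raise EmptyInputError(f"knowledgebase file {path} has no data rows")

    specimen_col = colmap.get("specimen", "specimen")
    pairs: list[DiseaseGenePair] = []
    seen_pairing: dict[str, str] = {}
    for (disease_id, disease_name, gene_id), grp in df.groupby(
        [colmap["disease_id"], colmap["disease_name"], colmap["gene_id"]],
        sort=False,
    ):
        if disease_id in seen_pairing:
            raise DomainError(
                f"disease {disease_id!r} appears with more than one gene"
            )
        seen_pairing[disease_id] = gene_id
        if len(grp) > grp[colmap["phenotype_name"]].nunique():
            logger.warning(
                "duplicate phenotype rows for disease %s merged", disease_id
            )
        terms: dict[str, PhenotypeTerm] = {}
        for _, row in grp.iterrows():
            raw = row[colmap["phenotype_name"]]
            if specimen_col in grp.columns and not pd.isna(row[specimen_col]):
                name, specimen = raw.strip(), row[specimen_col]
            else:
                name, specimen = split_specimen(raw)
            term_id = row.get("term_id")
            if term_id is None or pd.isna(term_id):
                term_id = f"{disease_id}:{name}" + (f" ({specimen})" if specimen else "")
            term = PhenotypeTerm(
                term_id=str(term_id),
                name=name,
                category=row[colmap["category"]].strip().lower(),
                specimen=specimen,
            )
            terms.setdefault(term.term_id, term)
        pairs.append(
            DiseaseGenePair(
                disease_id=str(disease_id),
                disease_name=str(disease_name),
                gene_id=str(gene_id),
                profile=PhenotypeProfile(tuple(terms.values()), str(disease_id)),
            )
        )
    return Knowledgebase(tuple(pairs))


def write_knowledgebase(kb: Knowledgebase, path) -> None:
    """Write the long-format CSV that :func:`read_knowledgebase` reads."""
    rows = []
    for pair in kb.pairs:
        for p in pair.profile.phenotypes:
            rows.append(
                {
                    "disease_id": pair.disease_id,
                    "disease_name": pair.disease_name,
                    "gene_id": pair.gene_id,
                    "term_id": p.term_id,
                    "phenotype_name": p.name,
                    "category": p.category,
                    "specimen": p.specimen if p.specimen is not None else "",
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Ontology (OBO)
# ---------------------------------------------------------------------------

_SYNONYM_RE = re.compile(r'^\s*"(?P<text>.*)"')


def _clean_synonym(raw: str) -> str:
    """Strip OBO quoting and trailing scope/xref qualifiers from a synonym."""
    m = _SYNONYM_RE.match(raw)
    return m.group("text") if m else raw.strip()


def read_obo(path, root_id: str | None = None) -> Ontology:
    """Parse an OBO 1.2 file into an :class:`Ontology`.

    Only id/name/synonym/is_a/is_obsolete are used; other tags are ignored
    (obsolete terms are excluded entirely). ``root_id`` names the
    phenotypic-abnormality-style root; if omitted and the file has exactly
    one parentless term, that term is used.
    """
    try:
        graph = obonet.read_obo(path, ignore_obsolete=True)
    except Exception as exc:  # obonet raises bare ValueError on bad stanzas
        raise OboParseError(f"failed to parse OBO file {path}: {exc}") from exc

    terms: dict[str, OntologyTerm] = {}
    for node, data in graph.nodes(data=True):
        parents = tuple(p for p in data.get("is_a", ()) if graph.has_node(p))
        synonyms = tuple(_clean_synonym(s) for s in data.get("synonym", ()))
        terms[node] = OntologyTerm(
            term_id=node,
            name=data.get("name", node),
            synonyms=synonyms,
            parent_ids=parents,
        )
    if not terms:
        raise EmptyInputError(f"OBO file {path} contains no usable terms")

    if root_id is None:
        roots = [t for t in terms.values() if not t.parent_ids]
        if len(roots) != 1:
            raise ConfigurationError(
                f"root_id not given and ontology has {len(roots)} roots"
            )
        root_id = roots[0].term_id
    return Ontology(terms=terms, root_id=root_id)


def write_obo(ontology: Ontology, path) -> None:
    """Write the minimal OBO 1.2 serialization read_obo understands."""
    buf = io.StringIO()
    buf.write("format-version: 1.2\n")
    for term in sorted(ontology.terms.values(), key=lambda t: t.term_id):
        buf.write("\n[Term]\n")
        buf.write(f"id: {term.term_id}\n")
        buf.write(f"name: {term.name}\n")
        for syn in term.synonyms:
            buf.write(f'synonym: "{syn}" EXACT []\n')
        for parent in term.parent_ids:
            buf.write(f"is_a: {parent} ! {ontology.terms[parent].name}\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def abnormality_subtree(
    ontology: Ontology, root_id: str | None = None
) -> list[tuple[str, str]]:
    """All (term_id, name-or-synonym) strings under the root class.

    Every strict descendant of the root contributes its name plus each
    distinct synonym: a term with k distinct synonyms yields k+1 strings.
    The root itself is excluded.
    """
    root = root_id if root_id is not None else ontology.root_id
    if root not in ontology:
        raise ConfigurationError(f"root term {root!r} absent from ontology")
    out: list[tuple[str, str]] = []
    for term_id in sorted(ontology.descendants(root)):
        term = ontology.terms[term_id]
        strings = dict.fromkeys((term.name, *term.synonyms))
        out.extend((term_id, s) for s in strings)
    return out


def top_level_subclasses(ontology: Ontology, term_id: str) -> set[str]:
    """Direct children of the root from which ``term_id`` is reachable.

    A direct child of the root maps to itself; a term reachable through
    several top-level classes returns them all (the "multiple subclasses"
    situation in per-category summaries).
    """
    root = ontology.root_id
    if term_id not in ontology:
        raise DomainError(f"unknown term {term_id!r}")
    if term_id != root and term_id not in ontology.descendants(root):
        raise DomainError(f"{term_id!r} is not a descendant of root {root!r}")
    result = set()
    for child in ontology.children(root):
        if term_id == child or term_id in ontology.descendants(child):
            result.add(child)
    return result
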