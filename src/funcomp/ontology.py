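"""Annotation input formats and ontology-level projection.

Readers for the annotation formats a profile analysis starts from —
two-column gene/term TSV and GAF 2.x association files — and for OBO 1.4
ontology graphs (via ``obonet``).  The projection step maps each gene's
raw term set onto a fixed ontology level: the set of ancestors (or the
term itself) lying exactly at that level, where the namespace root is
level 1 and "level L" means a minimum is_a distance of L - 1 from the
root.  Genes annotated below several level-L terms become multi-class
members, which is precisely what the expanded-profile machinery models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from .profiles import AnnotationIndex

__all__ = [
    "read_annotation_tsv",
    "read_gaf",
    "read_obo",
    "LevelCut",
    "level_cut",
    "ancestor_closure",
    "project_annotations",
]

log = logging.getLogger(__name__)

#: canonical namespace roots of the Gene Ontology
GO_ROOTS = {
    "molecular_function": "GO:0003674",
    "biological_process": "GO:0008150",
    "cellular_component": "GO:0005575",
}


def read_annotation_tsv(path) -> dict[str, set[str]]:
    """Two-column TSV (gene, term); duplicates collapsed, '#' comments allowed."""
    mapping: dict[str, set[str]] = {}
    n_bad = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                n_bad += 1
                continue
            mapping.setdefault(parts[0], set()).add(parts[1])
    if n_bad:
        log.warning("skipped %d malformed annotation line(s)", n_bad)
    if not mapping:
        raise ValueError("no usable annotation records")
    return mapping


def read_gaf(path, evidence_exclude: set[str] | None = None) -> dict[str, set[str]]:
    """GAF 2.x reader: DB Object ID (col 2) -> GO ID (col 5).

    Rows with a NOT qualifier are skipped (they assert absence of the
    annotation); ``evidence_exclude`` optionally drops evidence codes
    (e.g. {"IEA"}).  Malformed rows are counted and skipped.
    """
    mapping: dict[str, set[str]] = {}
    n_bad = n_not = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 7 or not cols[1] or not cols[4]:
                n_bad += 1
                continue
            qualifiers = cols[3].split("|") if cols[3] else []
            if "NOT" in qualifiers:
                n_not += 1
                continue
            if evidence_exclude and cols[6] in evidence_exclude:
                continue
            mapping.setdefault(cols[1], set()).add(cols[4])
    if n_bad:
        log.warning("skipped %d malformed GAF row(s)", n_bad)
    if n_not:
        log.debug("skipped %d NOT-qualified GAF row(s)", n_not)
    if not mapping:
        raise ValueError("no usable GAF records")
    return mapping


def read_obo(path, include_part_of: bool = False) -> nx.MultiDiGraph:
    """Parse an OBO 1.4 file into a child -> parent MultiDiGraph.

    Only is_a edges are kept unless ``include_part_of``; obsolete terms
    are dropped by the parser.  Node attribute ``alt_ids`` from the OBO
    is preserved by obonet, enabling alt_id resolution.
    """
    import obonet

    graph = obonet.read_obo(path)
    keep = {"is_a"}
    if include_part_of:
        keep.add("part_of")
    drop = [(u, v, key) for u, v, key in graph.edges(keys=True) if key not in keep]
    graph.remove_edges_from(drop)
    return graph


def resolve_alt_ids(graph: nx.MultiDiGraph) -> dict[str, str]:
    """Mapping alt_id -> primary id, from node 'alt_id' attributes."""
    table: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        for alt in data.get("alt_id", []):
            table[alt] = node
    return table


@dataclass
class LevelCut:
    """Ordered class ids whose minimum root distance is level - 1."""

    namespace: str
    level: int
    classes: list[str]

    @property
    def s(self) -> int:
        return len(self.classes)


def _namespace_root(graph: nx.MultiDiGraph, namespace: str) -> str:
    if namespace in GO_ROOTS and GO_ROOTS[namespace] in graph:
        return GO_ROOTS[namespace]
    roots = [n for n, d in graph.nodes(data=True)
             if d.get("namespace", namespace) == namespace
             and graph.out_degree(n) == 0]
    if len(roots) != 1:
        raise ValueError(f"cannot identify a unique root for namespace "
                         f"{namespace!r} (candidates: {roots})")
    return roots[0]


def level_cut(graph: nx.MultiDiGraph, namespace: str, level: int) -> LevelCut:
    """Classes at a fixed level: root = level 1, its children = level 2.

    A term reachable from the root at several depths is assigned its
    minimum is_a depth.  Class order is lexicographic for reproducible
    profile vectors.
    """
    if level < 2:
        raise ValueError("level must be >= 2 (level 1 is the root itself)")
    root = _namespace_root(graph, namespace)
    # edges run child -> parent; walk them backwards from the root
    depth = nx.single_source_shortest_path_length(graph.reverse(copy=False), root)
    classes = sorted(t for t, d in depth.items() if d == level - 1)
    if not classes:
        raise ValueError(f"no classes at level {level} under {root}")
    return LevelCut(namespace=namespace, level=level, classes=classes)


def ancestor_closure(graph: nx.MultiDiGraph, term: str) -> set[str]:
    """The term and every ancestor reachable along child -> parent edges."""
    if term not in graph:
        return set()
    return {term} | nx.descendants(graph, term)


def project_annotations(ann: dict[str, set[str]], graph: nx.MultiDiGraph,
                        cut: LevelCut) -> AnnotationIndex:
    """Replace each gene's terms by their level-cut ancestors.

    A gene annotated below several cut classes keeps all of them; genes
    with no ancestor in the cut end up unannotated and are excluded later
    by the profile-building policy.  Idempotent at a fixed cut, since a
    cut class is its own unique level-L ancestor.
    """
    cut_set = set(cut.classes)
    alt = resolve_alt_ids(graph)
    closure_cache: dict[str, frozenset[str]] = {}

    def project_term(t: str) -> frozenset[str]:
        t = alt.get(t, t)
        if t not in closure_cache:
            closure_cache[t] = frozenset(ancestor_closure(graph, t) & cut_set)
        return closure_cache[t]

    projected = {
        gene: frozenset().union(*(project_term(t) for t in terms)) if terms else frozenset()
        for gene, terms in ann.items()
    }
    return AnnotationIndex(projected, cut.classes)
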