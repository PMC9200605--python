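"""Ontology parsing and sub-ontology (sub-GO) enumeration.

The Gene Ontology is a set of three rooted directed acyclic graphs
(biological_process, molecular_function, cellular_component) whose edges
(``is_a`` and ``part_of``) point from more specific to more general terms.
A *sub-GO* is the subgraph induced by one term (its root) together with all
of its descendants; every term therefore defines one sub-GO, and the family
of sub-GOs segments the full ontology into overlapping functional units of
every size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")

#: edge relations treated as parent links; everything else is ignored
PARENT_RELATIONS = ("is_a", "part_of")


class OntologyError(ValueError):
    """Raised for structurally invalid ontologies (cycles, dangling ids...)."""


@dataclass(frozen=True)
class SubGO:
    """A rooted sub-ontology: one term plus its full descendant closure."""

    root: str
    nodes: frozenset[str]

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.nodes


@dataclass
class OntologyDAG:
    """Parsed ontology: term ids, labels, namespaces and parent links.

    ``parents`` holds the union of ``is_a`` and ``part_of`` edges; obsolete
    terms are excluded at parse time. Ancestor/descendant closures are
    memoised because the per-sub-GO similarity machinery queries them
    heavily.
    """

    terms: set[str]
    names: dict[str, str]
    namespace: dict[str, str]
    parents: dict[str, set[str]]
    _children: dict[str, set[str]] = field(default_factory=dict, repr=False)
    _anc_cache: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)
    _desc_cache: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._children = {t: set() for t in self.terms}
        for child, ps in self.parents.items():
            for p in ps:
                self._children[p].add(child)

    def children(self, term: str) -> set[str]:
        return self._children[term]

    def ancestors(self, term: str, include_self: bool = True) -> frozenset[str]:
        """All terms reachable by following parent edges (self-inclusive)."""
        cached = self._anc_cache.get(term)
        if cached is None:
            cached = self._closure(term, self.parents, self._anc_cache)
        return cached if include_self else cached - {term}

    def descendants(self, term: str, include_self: bool = True) -> frozenset[str]:
        cached = self._desc_cache.get(term)
        if cached is None:
            cached = self._closure(term, self._children, self._desc_cache)
        return cached if include_self else cached - {term}

    @staticmethod
    def _closure(
        term: str,
        step: dict[str, set[str]],
        cache: dict[str, frozenset[str]],
    ) -> frozenset[str]:
        # iterative BFS (cached per term) so deep ontologies never hit the
        # recursion limit; reuses any closure already in the cache
        seen = {term}
        stack = [term]
        while stack:
            t = stack.pop()
            for nxt in step.get(t, ()):
                if nxt in seen:
                    continue
                hit = cache.get(nxt)
                if hit is not None:
                    seen.update(hit)
                else:
                    seen.add(nxt)
                    stack.append(nxt)
        out = frozenset(seen)
        cache[term] = out
        return out

    def namespace_root(self, ns: str) -> str:
        roots = sorted(t for t in self.terms if self.namespace[t] == ns and not self.parents[t])
        if len(roots) != 1:
            raise OntologyError(
                f"namespace {ns!r} must have exactly one root, found {roots}"
            )
        return roots[0]

    def namespaces_present(self) -> list[str]:
        return sorted({self.namespace[t] for t in self.terms})

    def subgo(self, root: str) -> SubGO:
        return SubGO(root=root, nodes=self.descendants(root, include_self=True))


def parse_obo(path) -> OntologyDAG:
    """Parse an OBO 1.2 flat file into an :class:`OntologyDAG`.

    Obsolete terms are dropped, ``alt_id`` aliases are mapped to their
    canonical ids, only ``is_a``/``part_of`` relations become parent edges,
    and the result is checked for acyclicity and dangling parent ids.
    """
    graph = obonet.read_obo(path, ignore_obsolete=True)
    fmt = graph.graph.get("format-version")
    if fmt != "1.2":
        raise OntologyError(f"expected OBO format-version 1.2, got {fmt!r}")
    default_ns = graph.graph.get("default-namespace")
    if isinstance(default_ns, list):
        default_ns = default_ns[0] if default_ns else None

    # stanza-backed nodes carry a name; bare nodes were only referenced
    defined = {n for n, d in graph.nodes(data=True) if d}
    alt_to_canonical: dict[str, str] = {}
    for n in defined:
        for alt in graph.nodes[n].get("alt_id", []):
            alt_to_canonical[alt] = n

    names: dict[str, str] = {}
    namespace: dict[str, str] = {}
    for n in defined:
        data = graph.nodes[n]
        names[n] = data.get("name", n)
        ns = data.get("namespace", default_ns)
        if ns is None:
            raise OntologyError(f"term {n} has no namespace and no default-namespace")
        namespace[n] = ns

    parents: dict[str, set[str]] = {t: set() for t in defined}
    dangling: set[str] = set()
    for child, parent, rel in graph.edges(keys=True):
        if rel not in PARENT_RELATIONS:
            continue
        parent = alt_to_canonical.get(parent, parent)
        child = alt_to_canonical.get(child, child)
        if child not in defined:
            continue
        if parent not in defined:
            dangling.add(parent)
            continue
        if namespace[child] != namespace[parent]:
            logger.warning(
                "dropping cross-namespace edge %s -> %s (%s vs %s)",
                child, parent, namespace[child], namespace[parent],
            )
            continue
        parents[child].add(parent)
    if dangling:
        raise OntologyError(f"dangling parent ids: {sorted(dangling)}")

    dg = nx.DiGraph((c, p) for c, ps in parents.items() for p in ps)
    dg.add_nodes_from(defined)
    if not nx.is_directed_acyclic_graph(dg):
        edge = nx.find_cycle(dg)[0]
        raise OntologyError(f"ontology contains a cycle through edge {edge[0]} -> {edge[1]}")

    dag = OntologyDAG(terms=set(defined), names=names, namespace=namespace, parents=parents)
    for ns in dag.namespaces_present():
        dag.namespace_root(ns)  # raises when a namespace lacks a unique root
    return dag


def enumerate_subgos(
    dag: OntologyDAG,
    min_nodes: int = 1,
    namespace: str | None = None,
) -> list[SubGO]:
    """One sub-GO per term whose descendant closure has at least ``min_nodes``.

    Returned sorted by root id so downstream runs are deterministic.
    """
    if min_nodes < 1:
        raise ValueError("min_nodes must be >= 1")
    out = []
    for root in sorted(dag.terms):
        if namespace is not None and dag.namespace[root] != namespace:
            continue
        sg = dag.subgo(root)
        if len(sg) >= min_nodes:
            out.append(sg)
    return out
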