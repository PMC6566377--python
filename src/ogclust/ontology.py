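"""Gene Ontology DAG handling: OBO parsing and term-level computation.

Only ``is_a`` edges are used; ``part_of``/``regulates`` relations are out of
scope. A term's *level* is 1 + the length of the shortest is_a path to its
namespace root (root = level 1); a longest-path convention is available as an
option since "level" is not standardized across GO tooling.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Mapping, Optional, Set

import networkx as nx
import obonet

from .errors import OntologyError


class GODag:
    """An is_a DAG over ontology terms with per-namespace roots.

    ``graph`` holds directed child -> parent edges.
    """

    def __init__(self, graph: nx.DiGraph):
        if not nx.is_directed_acyclic_graph(graph):
            raise OntologyError("ontology contains an is_a cycle")
        self.graph = graph
        self.roots: Dict[str, str] = {}
        for node, data in graph.nodes(data=True):
            if graph.out_degree(node) == 0:
                ns = data.get("namespace", "")
                if ns in self.roots:
                    raise OntologyError(
                        f"namespace {ns!r} has multiple roots: "
                        f"{self.roots[ns]}, {node}"
                    )
                self.roots[ns] = node
        for node in graph.nodes:
            ns = graph.nodes[node].get("namespace", "")
            if ns not in self.roots:
                raise OntologyError(f"term {node} has no root in namespace {ns!r}")
        self._levels: Optional[Dict[str, int]] = None
        self._levels_longest: Optional[Dict[str, int]] = None

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def __len__(self) -> int:
        return len(self.graph)

    @property
    def terms(self) -> Iterable[str]:
        return self.graph.nodes

    def name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", "")

    def namespace(self, term: str) -> str:
        return self.graph.nodes[term].get("namespace", "")

    def parents(self, term: str) -> Set[str]:
        return set(self.graph.successors(term))

    def _compute_levels(self, convention: str) -> Dict[str, int]:
        levels: Dict[str, int] = {}
        rev = self.graph.reverse(copy=False)  # root -> leaves direction
        if convention == "shortest":
            for root in self.roots.values():
                for node, dist in nx.single_source_shortest_path_length(
                    rev, root
                ).items():
                    level = dist + 1
                    if node not in levels or level < levels[node]:
                        levels[node] = level
        elif convention == "longest":
            for node in nx.topological_sort(rev):
                if rev.in_degree(node) == 0:
                    levels[node] = 1
                else:
                    levels[node] = 1 + max(
                        levels[p] for p in rev.predecessors(node)
                    )
        else:
            raise ValueError(f"unknown level convention {convention!r}")
        return levels

    def levels(self, convention: str = "shortest") -> Mapping[str, int]:
        if convention == "shortest":
            if self._levels is None:
                self._levels = self._compute_levels("shortest")
            return self._levels
        if self._levels_longest is None:
            self._levels_longest = self._compute_levels("longest")
        return self._levels_longest

    def terms_at_level(self, level: int, convention: str = "shortest") -> List[str]:
        lv = self.levels(convention)
        return sorted(t for t, l in lv.items() if l == level)


def term_level(dag: GODag, term_id: str, convention: str = "shortest") -> int:
    """Level of ``term_id``: 1 + shortest is_a path to its namespace root."""
    if term_id not in dag:
        raise OntologyError(f"unknown term {term_id!r}")
    return dag.levels(convention)[term_id]


def parse_obo(path_or_handle) -> GODag:
    """Parse an OBO 1.2 file into a :class:`GODag`.

    Obsolete terms are dropped; only is_a edges are kept. Cycles and is_a
    references to terms without their own stanza are errors.
    """
    multi = obonet.read_obo(path_or_handle, ignore_obsolete=True)
    graph = nx.DiGraph()
    for node, data in multi.nodes(data=True):
        if "name" not in data:
            raise OntologyError(f"is_a target {node!r} has no [Term] stanza")
        graph.add_node(node, name=data.get("name", ""), namespace=data.get("namespace", ""))
    for u, v, key in multi.edges(keys=True):
        if key == "is_a":
            if v not in graph:
                raise OntologyError(f"dangling is_a target {v!r}")
            graph.add_edge(u, v)
    return GODag(graph)


def parse_go_map(path) -> Dict[str, Set[str]]:
    """Parse a reference->GO ID-mapping TSV: ``ref<TAB>GO:...;GO:...``."""
    mapping: Dict[str, Set[str]] = {}
    for line in open(path):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        ref, _, terms = line.partition("\t")
        term_set = {t for t in terms.split(";") if t}
        mapping[ref] = mapping.get(ref, set()) | term_set
    return mapping


def write_go_map(mapping: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        for ref in sorted(mapping):
            fh.write(f"{ref}\t" + ";".join(sorted(mapping[ref])) + "\n")
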