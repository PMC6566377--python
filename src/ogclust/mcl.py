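"""Similarity graph construction and from-scratch Markov clustering (MCL).

Filtered all-vs-all hits are turned into an undirected graph whose edge
weights are symmetrized -log10(E-value); MCL then alternates expansion
(matrix squaring) and inflation (element-wise powering with column
renormalization) on the column-stochastic transition matrix until a fixed
point. The attractor structure of the limit matrix defines the clusters.

Because the transition matrix is block-diagonal over connected components,
the iteration is run per component: this is exact (expansion and inflation
never mix blocks) and keeps the dense linear algebra small.
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .errors import TaxonomyError
from .hits import SimilarityHit
from .phyletic import Cluster

PRUNE_THRESHOLD = 1e-8


def build_similarity_graph(
    filtered_hits: Iterable[SimilarityHit],
    protein_species_map: Mapping[str, str],
    evalue_floor: float = 1e-200,
) -> nx.Graph:
    """Build the weighted similarity graph from filtered hits.

    Every protein in ``protein_species_map`` becomes a node (isolated if it
    has no surviving edges). For each ordered query->subject pair only the
    best surviving row (lowest E, then highest bitscore) counts; the
    unordered edge weight is the mean of -log10(max(E, floor)) over the one
    or two directed best rows. Each node carries a self-loop equal to its
    maximum incident edge weight (1.0 if isolated).
    """
    best: Dict[Tuple[str, str], SimilarityHit] = {}
    for h in filtered_hits:
        for p in (h.query_id, h.subject_id):
            if p not in protein_species_map:
                raise TaxonomyError(f"protein {p!r} in hits but not in species map")
        key = (h.query_id, h.subject_id)
        prev = best.get(key)
        if prev is None or (h.evalue, -h.bitscore) < (prev.evalue, -prev.bitscore):
            best[key] = h

    graph = nx.Graph()
    for protein, species in protein_species_map.items():
        graph.add_node(protein, species=species)

    pair_weights: Dict[Tuple[str, str], List[float]] = {}
    for (q, s), h in best.items():
        pair = (q, s) if q < s else (s, q)
        w = -np.log10(max(h.evalue, evalue_floor))
        pair_weights.setdefault(pair, []).append(w)

    for (a, b), ws in pair_weights.items():
        graph.add_edge(a, b, weight=float(np.mean(ws)))

    for node in graph.nodes:
        incident = [
            d["weight"] for _, v, d in graph.edges(node, data=True) if v != node
        ]
        graph.add_edge(node, node, weight=max(incident) if incident else 1.0)
    return graph


def _mcl_component(
    nodes: Sequence[str],
    graph: nx.Graph,
    inflation: float,
    max_iter: int,
    tol: float,
) -> Tuple[List[Set[str]], bool]:
    """Run the MCL iteration on one connected component; returns clusters and
    a convergence flag."""
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    A = np.zeros((n, n))
    for u, v, d in graph.subgraph(nodes).edges(data=True):
        i, j = index[u], index[v]
        A[i, j] = d["weight"]
        A[j, i] = d["weight"]
    M = A / A.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        prev = M
        M = M @ M                              # expansion
        M = np.power(M, inflation)             # inflation
        M /= M.sum(axis=0, keepdims=True)
        M[M < PRUNE_THRESHOLD] = 0.0           # prune tiny entries per column
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M /= colsum
        if np.max(np.abs(M - prev)) < tol:
            converged = True
            break

    # Attractors: nodes with mass on their own diagonal. Attractors sharing
    # limit-matrix support belong to one attractor system; every node is
    # assigned to the system holding most of its column mass, ties broken by
    # the lexicographically smallest attractor label.
    attractors = [i for i in range(n) if M[i, i] > PRUNE_THRESHOLD]
    if not attractors:  # degenerate non-converged state: everything together
        return [set(nodes)], converged

    sys_graph = nx.Graph()
    sys_graph.add_nodes_from(attractors)
    for i in attractors:
        for k in attractors:
            if i < k and (M[i, k] > PRUNE_THRESHOLD or M[k, i] > PRUNE_THRESHOLD):
                sys_graph.add_edge(i, k)
    system_of: Dict[int, int] = {}
    systems: List[Set[int]] = []
    for comp in nx.connected_components(sys_graph):
        sid = len(systems)
        systems.append(set(comp))
        for i in comp:
            system_of[i] = sid

    clusters: List[Set[str]] = [set() for _ in systems]
    for j in range(n):
        mass = [(M[i, j], i) for i in attractors if M[i, j] > 0]
        if mass:
            best_mass = max(m for m, _ in mass)
            candidates = [i for m, i in mass if m == best_mass]
            target = min(candidates, key=lambda i: nodes[i])
            clusters[system_of[target]].add(nodes[j])
        else:  # no attractor mass (numerically starved column): singleton
            clusters.append({nodes[j]})
    return [c for c in clusters if c], converged


def mcl(
    graph: nx.Graph,
    inflation: float = 1.5,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> List[Cluster]:
    """Partition the similarity graph into clusters with Markov clustering.

    Every node ends up in exactly one cluster. Non-convergence within
    ``max_iter`` raises a warning and interprets the current matrix.
    """
    if inflation <= 1:
        raise ValueError(f"inflation must exceed 1, got {inflation}")
    out: List[Cluster] = []
    unconverged = 0
    for comp in nx.connected_components(graph):
        nodes = sorted(comp)
        member_sets, converged = _mcl_component(nodes, graph, inflation, max_iter, tol)
        if not converged:
            unconverged += 1
        for members in member_sets:
            species = frozenset(graph.nodes[m]["species"] for m in members)
            out.append(Cluster(members=frozenset(members), species_set=species))
    if unconverged:
        warnings.warn(
            f"MCL did not converge within {max_iter} iterations on "
            f"{unconverged} component(s); current matrix interpreted",
            RuntimeWarning,
        )
    out.sort(key=lambda c: min(c.members))
    return out


def retain_multispecies(
    clusters: Iterable[Cluster],
) -> Tuple[List[Cluster], int]:
    """Apply the OGC retention rule: keep clusters with >=2 proteins from >=2
    species; return (retained clusters, number of excluded proteins)."""
    retained: List[Cluster] = []
    excluded = 0
    for c in clusters:
        if len(c.members) >= 2 and len(c.species_set) >= 2:
            retained.append(c)
        else:
            excluded += len(c.members)
    return retained, excluded


def write_groups(clusters: Sequence[Cluster], path) -> None:
    """Write clusters in OrthoMCL groups style: ``OGC<k>: prot1 prot2 ...``."""
    with open(path, "w") as fh:
        for k, c in enumerate(clusters, start=1):
            fh.write(f"OGC{k}: " + " ".join(sorted(c.members)) + "\n")


def read_groups(path, protein_species_map: Mapping[str, str]) -> List[Cluster]:
    clusters = []
    for line in open(path):
        if not line.strip():
            continue
        _, _, members = line.partition(":")
        prots = frozenset(members.split())
        species = frozenset(protein_species_map[p] for p in prots)
        clusters.append(Cluster(members=prots, species_set=species))
    return clusters
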