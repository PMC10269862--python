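"""Orthologous-group inference by Markov clustering (MCL).

This module clusters a precomputed protein-similarity graph into
orthologous groups with plain MCL and reads/writes OrthoMCL-style groups
files so precomputed assignments can bypass clustering.  It deliberately
implements only the clustering stage: no BLAST is run, no reciprocal-best-
hit normalization or inter-species weight rescaling is applied.  The
downstream association stage needs nothing but a partition of proteins
into groups.

Protein ids have the form ``strain|protein``; the strain prefix is what
turns a partition into a presence/absence matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .mgwa import GenePresenceMatrix


class ParseError(ValueError):
    """A malformed input line, reported with its line number."""


@dataclass
class OgPartition:
    """Disjoint assignment of proteins to orthologous groups."""

    groups: dict[str, frozenset[str]]
    converged: bool = True

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for og, members in self.groups.items():
            if not members:
                raise ValueError(f"group {og} is empty")
            for protein in members:
                if protein in seen:
                    raise ValueError(
                        f"protein {protein!r} appears in both {seen[protein]} and {og}"
                    )
                seen[protein] = og

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def protein_to_og(self) -> dict[str, str]:
        return {p: og for og, members in self.groups.items() for p in members}

    def as_blocks(self) -> set[frozenset[str]]:
        """Label-free view used for partition comparison."""
        return set(self.groups.values())

    def to_presence(self, strains: list[str] | None = None) -> GenePresenceMatrix:
        """Derive the binary OG x strain presence matrix.

        A group is present in a strain iff some member protein carries that
        strain prefix.  Protein ids must contain ``|``.
        """
        presence: dict[str, set[str]] = {}
        for og, members in self.groups.items():
            strains_here = set()
            for protein in members:
                if "|" not in protein:
                    raise ValueError(
                        f"protein id {protein!r} lacks the strain|protein form"
                    )
                strains_here.add(protein.split("|", 1)[0])
            presence[og] = strains_here
        if strains is None:
            strains = sorted(set().union(*presence.values()))
        data = pd.DataFrame(
            {s: [int(s in presence[og]) for og in sorted(presence)] for s in strains},
            index=sorted(presence),
        )
        data.index.name = "og_id"
        return GenePresenceMatrix(data, provenance="clustered")


def read_abc_graph(path) -> nx.Graph:
    """Read a 3-column (source, target, weight) similarity edge list.

    The graph is undirected; duplicate edges keep the maximum weight;
    self-loops are rejected.  Malformed lines raise :class:`ParseError`
    naming the line.
    """
    graph = nx.Graph()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ParseError(f"line {lineno}: expected 3 columns, got {len(parts)}")
            src, dst, raw_weight = parts
            try:
                weight = float(raw_weight)
            except ValueError:
                raise ParseError(
                    f"line {lineno}: non-numeric weight {raw_weight!r}"
                ) from None
            if weight < 0:
                raise ParseError(f"line {lineno}: negative weight {weight}")
            if src == dst:
                raise ParseError(f"line {lineno}: self-loop on {src!r}")
            if graph.has_edge(src, dst):
                graph[src][dst]["weight"] = max(graph[src][dst]["weight"], weight)
            else:
                graph.add_edge(src, dst, weight=weight)
    return graph


def write_abc_graph(edges: pd.DataFrame, path) -> None:
    """Write a (source, target, weight) edge table as whitespace-separated ABC."""
    edges.to_csv(path, sep="\t", index=False, header=False, float_format="%.6f")


def _normalize_columns(matrix: np.ndarray) -> np.ndarray:
    sums = matrix.sum(axis=0)
    sums[sums == 0] = 1.0
    return matrix / sums


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 1.5,
    expansion: int = 2,
    max_iter: int = 100,
    prune_threshold: float = 1e-5,
    tol: float = 1e-6,
) -> OgPartition:
    """Markov clustering of a weighted similarity graph.

    Standard MCL: self-loops are added at each node's maximum incident
    weight, columns are normalized to a stochastic matrix, and expansion
    (matrix power) alternates with inflation (entrywise power plus
    renormalization) and pruning of entries below ``prune_threshold``
    until the matrix changes by less than ``tol`` or ``max_iter`` passes.
    Clusters are read off the attractors (nodes with positive diagonal
    mass); a node drawn to several attractor systems joins the cluster of
    its largest-weight attractor, ties broken toward the lexicographically
    smallest cluster.  Group ids are assigned by each cluster's smallest
    member.
    """
    if inflation <= 1:
        raise ValueError("inflation must exceed 1")
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = sorted(graph.nodes())
    a = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    loop = a.max(axis=0)
    loop[loop == 0] = 1.0  # isolated nodes keep themselves
    np.fill_diagonal(a, loop)
    m = _normalize_columns(a)

    converged = False
    for _ in range(max_iter):
        previous = m
        m = np.linalg.matrix_power(m, expansion)
        m = np.power(m, inflation)
        m[m < prune_threshold] = 0.0
        m = _normalize_columns(m)
        if np.max(np.abs(m - previous)) < tol:
            converged = True
            break

    clusters = _extract_clusters(m, nodes)
    width = max(4, len(str(len(clusters))))
    groups = {
        f"OG_{i:0{width}d}": frozenset(members)
        for i, members in enumerate(
            sorted(clusters, key=lambda ms: sorted(ms)[0]), start=1
        )
    }
    return OgPartition(groups, converged=converged)


def _extract_clusters(m: np.ndarray, nodes: list[str]) -> list[set[str]]:
    n = len(nodes)
    diag = np.diag(m)
    attractors = np.where(diag > 0)[0]
    if attractors.size == 0:  # numerically degenerate; fall back to singletons
        return [{node} for node in nodes]
    # attractor systems: attractors linked by mutual mass form one cluster core
    sub = m[np.ix_(attractors, attractors)]
    link = nx.Graph()
    link.add_nodes_from(range(attractors.size))
    for i in range(attractors.size):
        for j in range(i + 1, attractors.size):
            if sub[i, j] > 0 or sub[j, i] > 0:
                link.add_edge(i, j)
    systems = [sorted(attractors[list(c)]) for c in nx.connected_components(link)]
    system_of_attractor = {}
    for sid, members in enumerate(systems):
        for a_idx in members:
            system_of_attractor[a_idx] = sid
    clusters: list[set[str]] = [set(nodes[i] for i in members) for members in systems]
    # order systems deterministically for tie-breaking
    order = sorted(range(len(clusters)), key=lambda s: sorted(clusters[s])[0])
    rank = {sid: r for r, sid in enumerate(order)}
    for j in range(n):
        if j in system_of_attractor:
            continue
        mass = m[attractors, j]
        if mass.max() <= 0:
            clusters.append({nodes[j]})
            continue
        best = mass.max()
        candidates = {
            system_of_attractor[a]
            for a, w in zip(attractors, mass)
            if np.isclose(w, best, rtol=0, atol=1e-12)
        }
        winner = min(candidates, key=lambda s: rank[s])
        clusters[winner].add(nodes[j])
    return [c for c in clusters if c]


def read_groups(path) -> OgPartition:
    """Read an OrthoMCL-style groups file (``OGID: strain|prot ...``)."""
    groups: dict[str, frozenset[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            if ":" not in line:
                raise ParseError(f"line {lineno}: missing ':' separator")
            og, rest = line.split(":", 1)
            og = og.strip()
            members = rest.split()
            if not og or not members:
                raise ParseError(f"line {lineno}: empty group id or member list")
            if og in groups:
                raise ParseError(f"line {lineno}: duplicate group id {og!r}")
            groups[og] = frozenset(members)
    return OgPartition(groups)


def write_groups(partition: OgPartition, path) -> None:
    """Write a groups file; round-trips with :func:`read_groups`."""
    with open(path, "w") as handle:
        for og in sorted(partition.groups):
            members = " ".join(sorted(partition.groups[og]))
            handle.write(f"{og}: {members}\n")
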