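"""Residue communication graphs and k-shortest hydrogen-bonded paths.

Protein residues are graph nodes.  A hydrogen bond observed between
residues i and j with occurrence probability HB_ij contributes an
undirected edge with communication cost

    C_ij = -ln(HB_ij)

so highly probable bonds are cheap to traverse; consecutive covalently
bound residues are connected at zero cost.  Minimum-cost loopless paths
between nucleotide-binding-pocket residues then trace candidate
allosteric communication routes, and path statistics (participation
frequencies, block-averaged path lengths, interface crossings) summarise
them.

Zero-cost edges create cost ties; determinism is guaranteed by a
secondary ordering on (path length in residues, lexicographic residue
sequence).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .hbonds import HBondProbabilityMatrix
from .structure import Residue

__all__ = [
    "CommunicationGraph",
    "ResiduePath",
    "NoPath",
    "DEFAULT_ENDPOINT_PAIRS",
    "build_graph",
    "path_cost",
    "shortest_path",
    "k_shortest_paths",
    "participation_frequency",
    "path_length_statistics",
    "BlockPathStats",
    "interface_crossings",
    "aggregate_crossings",
    "default_cassette_partition",
]

CommunicationGraph = nx.Graph

#: pocket-to-pocket endpoint pairs used for the Brr2 cassette analysis
#: (chain A, author numbering)
DEFAULT_ENDPOINT_PAIRS: list[tuple[Residue, Residue]] = [
    (("A", 616), ("A", 1455)),
    (("A", 509), ("A", 1356)),
    (("A", 820), ("A", 1692)),
    (("A", 484), ("A", 1332)),
    (("A", 855), ("A", 1455)),
    (("A", 510), ("A", 1357)),
]

#: first residue of the C-terminal cassette; residues below it are NC
NC_CC_BOUNDARY = 1282


@dataclass(frozen=True)
class ResiduePath:
    """A loopless residue path with its total communication cost."""

    residues: tuple[Residue, ...]
    cost: float

    def __post_init__(self) -> None:
        if len(set(self.residues)) != len(self.residues):
            raise ValueError("path contains a repeated residue")

    @property
    def length(self) -> int:
        """Number of connected residues on the path."""
        return len(self.residues)

    @property
    def source(self) -> Residue:
        return self.residues[0]

    @property
    def target(self) -> Residue:
        return self.residues[-1]


@dataclass(frozen=True)
class NoPath:
    """Explicit no-path result for a disconnected endpoint pair."""

    source: Residue
    target: Residue


def build_graph(
    matrix: HBondProbabilityMatrix,
    adjacency: set[tuple[Residue, Residue]],
) -> CommunicationGraph:
    """Weighted communication graph from occupancies plus covalent adjacency.

    Hydrogen-bond edges carry cost -ln(HB_ij); covalent consecutive-residue
    edges carry cost 0.  A pair with both keeps the minimum (zero) cost and
    covalent provenance, with the hydrogen-bond probability retained as an
    edge attribute.  HB_ij = 0 yields no edge (infinite-cost limit).
    """
    g = nx.Graph()
    g.add_nodes_from(matrix.residues)
    for (a, b), p in matrix.probabilities.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {p} for {(a, b)} outside [0, 1]")
        if p == 0.0:
            continue
        g.add_edge(a, b, cost=float(-np.log(p)), probability=p, provenance="hbond")
    for a, b in adjacency:
        if g.has_edge(a, b):
            g[a][b].update(cost=0.0, provenance="covalent")
        else:
            g.add_edge(a, b, cost=0.0, provenance="covalent")
        g.add_nodes_from([a, b])
    return g


def path_cost(graph: CommunicationGraph, nodes: list[Residue]) -> float:
    return float(sum(graph[u][v]["cost"] for u, v in zip(nodes, nodes[1:])))


def _path_key(graph: CommunicationGraph, nodes: list[Residue]):
    return (round(path_cost(graph, nodes), 9), len(nodes), tuple(nodes))


def k_shortest_paths(
    graph: CommunicationGraph,
    source: Residue,
    target: Residue,
    k: int = 10,
    tie_tol: float = 1e-9,
    max_candidates: int = 10_000,
) -> list[ResiduePath] | NoPath:
    """Up to k distinct loopless paths in nondecreasing cost order.

    Candidate paths are generated by Yen's deviation search
    (networkx ``shortest_simple_paths``); generation continues past the
    k-th path while costs tie (within ``tie_tol``) so that the final
    ordering by (cost, residue count, lexicographic residue sequence) is
    deterministic.  Fewer than k simple paths simply yields them all; a
    disconnected pair yields :class:`NoPath`.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if source == target:
        raise ValueError("source and target must differ")
    for node in (source, target):
        if node not in graph:
            raise KeyError(f"residue {node} not in graph")
    candidates: list[list[Residue]] = []
    costs: list[float] = []
    try:
        for nodes in nx.shortest_simple_paths(graph, source, target, weight="cost"):
            c = path_cost(graph, nodes)
            if len(candidates) >= k and c > costs[k - 1] + tie_tol:
                break
            candidates.append(nodes)
            costs.append(c)
            costs.sort()
            if len(candidates) >= max_candidates:
                warnings.warn(
                    f"k-shortest tie collection capped at {max_candidates} "
                    "candidate paths; ordering of equal-cost paths beyond the "
                    "cap is not guaranteed",
                    stacklevel=2,
                )
                break
    except nx.NetworkXNoPath:
        return NoPath(source, target)
    candidates.sort(key=lambda nodes: _path_key(graph, nodes))
    return [
        ResiduePath(tuple(nodes), path_cost(graph, nodes)) for nodes in candidates[:k]
    ]


def shortest_path(
    graph: CommunicationGraph, source: Residue, target: Residue
) -> ResiduePath | NoPath:
    """Minimum-cost loopless path (deterministic tie-break as in k-shortest)."""
    result = k_shortest_paths(graph, source, target, k=1)
    if isinstance(result, NoPath):
        return result
    return result[0]


def participation_frequency(paths: list[ResiduePath]) -> dict[Residue, float]:
    """Fraction of paths containing each residue (endpoints included)."""
    if not paths:
        raise ValueError("need at least one path")
    counts: Counter[Residue] = Counter()
    for p in paths:
        counts.update(set(p.residues))
    return {res: c / len(paths) for res, c in sorted(counts.items())}


@dataclass
class BlockPathStats:
    """Mean +/- SEM of the average path length over temporal blocks."""

    mean_length: float
    sem_length: float | None
    n_blocks_used: int
    excluded_blocks: list[int] = field(default_factory=list)


def path_length_statistics(
    path_sets_per_block: list["list[ResiduePath] | NoPath"],
) -> BlockPathStats:
    """Block-averaged path length (number of connected residues).

    Each element of ``path_sets_per_block`` is the path set computed from
    one temporal block's occupancy graph.  Blocks with no path are
    excluded and reported.  SEM is undefined (None) for a single usable
    block.
    """
    block_means: list[float] = []
    excluded: list[int] = []
    for i, paths in enumerate(path_sets_per_block):
        if isinstance(paths, NoPath) or not paths:
            excluded.append(i)
            continue
        block_means.append(float(np.mean([p.length for p in paths])))
    if not block_means:
        raise ValueError("no block produced any path")
    mean = float(np.mean(block_means))
    sem = (
        float(np.std(block_means, ddof=1) / np.sqrt(len(block_means)))
        if len(block_means) >= 2
        else None
    )
    return BlockPathStats(mean, sem, len(block_means), excluded)


def default_cassette_partition(residue: Residue) -> str:
    """NC/CC assignment by author number (CC construct starts at 1282)."""
    return "NC" if residue[1] < NC_CC_BOUNDARY else "CC"


def interface_crossings(
    path: ResiduePath,
    partition=default_cassette_partition,
) -> list[tuple[Residue, Residue]]:
    """Edges of a path whose endpoints lie in different cassettes."""
    crossings = []
    for a, b in zip(path.residues, path.residues[1:]):
        ca, cb = partition(a), partition(b)
        if ca not in ("NC", "CC") or cb not in ("NC", "CC"):
            raise ValueError(f"residue {a if ca not in ('NC', 'CC') else b} unpartitioned")
        if ca != cb:
            crossings.append((a, b) if a <= b else (b, a))
    return crossings


def aggregate_crossings(
    paths: list[ResiduePath],
    partition=default_cassette_partition,
) -> Counter:
    """Tally of interface-crossing residue pairs over a path set."""
    tally: Counter = Counter()
    for p in paths:
        tally.update(interface_crossings(p, partition))
    return tally
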