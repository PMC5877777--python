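"""Correlation-weighted residue graphs and allosteric pathway search.

Residues are nodes (Cβ scheme, Cα for glycine); an edge between two residues
is kept only if their node atoms are within a distance cutoff (default
5.7 Å) in at least a threshold fraction of trajectory frames (default 0.5,
with exactly 0.5 retained — the pruning rule removes frequencies *below*
the threshold).  Each retained edge carries the motion correlation C_ij as
its weight and a strictly positive path cost derived from it; the default
cost transform is −ln|C| so that strongly coupled (correlated *or*
anticorrelated) residues are close in path space.  The minimum-cost path
between two residues is read as the likely allosteric pathway between them.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from allonet.correlation import CorrelationMatrix
from allonet.regions import RegionSet
from allonet.structure_io import Trajectory

DEFAULT_CONTACT_CUTOFF = 5.7   # Å
DEFAULT_FREQ_THRESHOLD = 0.5
_CORR_FLOOR = 1.0 - 1e-12      # |C| floored below 1 so costs stay positive

COST_TRANSFORMS = ("neglog", "linear")


def _edge_cost(correlation: float, transform: str) -> float:
    a = min(abs(correlation), _CORR_FLOOR)
    if transform == "neglog":
        return -math.log(a)
    if transform == "linear":
        return max(1.0 - a, 1e-12)
    raise ValueError(f"unknown cost transform {transform!r}; expected {COST_TRANSFORMS}")


@dataclass
class ResidueGraph:
    """Undirected residue graph; nodes are 1-based sequential positions.

    Edge attributes: ``correlation`` (C_ij), ``cost`` (strictly positive
    path cost) and ``contact_freq`` (fraction of frames in contact).
    """

    graph: nx.Graph
    labels: dict[int, str] = field(default_factory=dict)

    @classmethod
    def empty(cls, nodes, labels: dict[int, str] | None = None) -> "ResidueGraph":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        return cls(g, labels or {})

    def add_edge(self, i: int, j: int, correlation: float, cost: float,
                 contact_freq: float) -> None:
        if not (cost > 0 and math.isfinite(cost)):
            raise ValueError(f"edge ({i},{j}) has non-positive or non-finite cost {cost}")
        self.graph.add_edge(i, j, correlation=correlation, cost=cost,
                            contact_freq=contact_freq)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def is_connected(self) -> bool:
        return self.n_nodes > 0 and nx.is_connected(self.graph)

    def edges(self):
        return self.graph.edges(data=True)

    def to_tsv(self, precision: int = 6) -> str:
        lines = ["res_i\tres_j\tcorrelation\tcost\tcontact_freq"]
        for i, j, d in sorted(self.graph.edges(data=True),
                              key=lambda e: (min(e[0], e[1]), max(e[0], e[1]))):
            a, b = (i, j) if i < j else (j, i)
            lines.append(
                f"{a}\t{b}\t{d['correlation']:.{precision}f}"
                f"\t{d['cost']:.{precision}f}\t{d['contact_freq']:.{precision}f}"
            )
        return "\n".join(lines) + "\n"


@dataclass
class PathResult:
    """A shortest path: ordered residue positions, total and per-edge costs."""

    residues: list[int]
    cost: float
    edge_costs: list[float]
    found: bool = True

    def __post_init__(self) -> None:
        if self.found and self.edge_costs:
            assert abs(self.cost - sum(self.edge_costs)) <= 1e-9 * max(1.0, self.cost)


# ---------------------------------------------------------------------------
# construction


def contact_frequencies(
    trajectory: Trajectory, cutoff: float = DEFAULT_CONTACT_CUTOFF
) -> np.ndarray:
    """Fraction of frames in which each node pair lies within ``cutoff`` Å."""
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if trajectory.n_frames == 0:
        raise ValueError("empty trajectory")
    n = trajectory.n_residues
    acc = np.zeros((n, n))
    for frame in trajectory.frames:
        d = squareform(pdist(frame))
        acc += d <= cutoff
    freq = acc / trajectory.n_frames
    np.fill_diagonal(freq, 1.0)
    return freq


def build_weighted_network(
    dccm: CorrelationMatrix,
    freqs: np.ndarray,
    freq_threshold: float = DEFAULT_FREQ_THRESHOLD,
    transform: str = "neglog",
) -> ResidueGraph:
    """Contact-filtered, correlation-weighted residue graph.

    Edge (i, j) is retained iff contact frequency f_ij ≥ ``freq_threshold``
    (edges with frequency strictly below the threshold are pruned) and
    C_ij ≠ 0 (zero correlation would give infinite cost).
    """
    n = dccm.n_residues
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (n, n):
        raise ValueError("correlation and contact-frequency matrices differ in size")
    if not (0.0 <= freq_threshold <= 1.0):
        raise ValueError(f"freq_threshold must be in [0,1], got {freq_threshold}")
    labels = {i + 1: r.label() for i, r in enumerate(dccm.residues)}
    rg = ResidueGraph.empty(range(1, n + 1), labels)
    C = dccm.values
    for i in range(n):
        for j in range(i + 1, n):
            if freqs[i, j] < freq_threshold:
                continue
            c = C[i, j]
            if c == 0.0:
                continue
            rg.add_edge(i + 1, j + 1, correlation=float(c),
                        cost=_edge_cost(float(c), transform),
                        contact_freq=float(freqs[i, j]))
    return rg


# ---------------------------------------------------------------------------
# path search


def shortest_path(rg: ResidueGraph, source: int, target: int) -> PathResult:
    """Dijkstra minimum-cost path with deterministic tie-breaking.

    Ties on total cost are broken by fewer hops, then by the
    lexicographically smallest residue-position sequence.  An unreachable
    target yields an explicit not-found result, not an exception.
    """
    G = rg.graph
    for node in (source, target):
        if node not in G:
            raise KeyError(f"residue position {node} not in graph")
    if source == target:
        return PathResult([source], 0.0, [], True)

    done: set[int] = set()
    heap: list[tuple[float, int, tuple[int, ...]]] = [(0.0, 0, (source,))]
    while heap:
        cost, hops, path = heapq.heappop(heap)
        node = path[-1]
        if node in done:
            continue
        done.add(node)
        if node == target:
            edge_costs = [G[a][b]["cost"] for a, b in zip(path, path[1:])]
            return PathResult(list(path), cost, edge_costs, True)
        for nbr in sorted(G[node]):
            if nbr in done:
                continue
            heapq.heappush(
                heap, (cost + G[node][nbr]["cost"], hops + 1, path + (nbr,))
            )
    return PathResult([], math.inf, [], False)


@dataclass
class PathwayBundle:
    """Shortest paths from one site to every residue of a target region.

    ``edge_union`` is the de-duplicated set of traversed edges — the bold
    pathway overlay on the network; shared stems appear once.
    """

    site: int
    paths: dict[int, PathResult]
    edge_union: list[tuple[int, int]]

    def found(self) -> dict[int, PathResult]:
        return {t: p for t, p in self.paths.items() if p.found}


def allosteric_pathways(
    rg: ResidueGraph, site: int, targets: RegionSet
) -> PathwayBundle:
    """One shortest path per target-region residue, plus the edge union."""
    if site not in rg.graph:
        raise KeyError(f"site position {site} not in graph")
    paths: dict[int, PathResult] = {}
    edges: set[tuple[int, int]] = set()
    for t in sorted(targets.residues()):
        if t not in rg.graph:
            paths[t] = PathResult([], math.inf, [], False)
            continue
        p = shortest_path(rg, site, t)
        paths[t] = p
        if p.found:
            for a, b in zip(p.residues, p.residues[1:]):
                edges.add((min(a, b), max(a, b)))
    return PathwayBundle(site, paths, sorted(edges))
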