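"""Betweenness centrality and reachability on the 7.0 Å contact network.

This stage uses *unweighted* graphs: an edge exists iff the Cβ nodes
(Cα for glycine) of two residues are within the distance cutoff (default
7.0 Å) in a frame, and distances are hop counts.  Betweenness centrality
BC(v) counts, over all unordered node pairs (s, t) with s ≠ v ≠ t, the
fraction of equal-length shortest s–t paths passing through v (Brandes
fractional counting).  Reachability L_i is the mean hop distance from
residue i to every residue it can reach; pairs disconnected within a frame
are excluded from the mean and tallied separately.  Profiles are averaged
over frames, and ΔBC / ΔL_i between two states localize residues whose
communication role changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from allonet.structure_io import Trajectory

DEFAULT_CUTOFF = 7.0  # Å


@dataclass
class CentralityProfile:
    """Per-residue centrality profile averaged over frames.

    Fields not produced by a given operation are None.  ``l_values`` holds
    NaN for residues isolated in every frame (flagged, never silently 0).
    """

    positions: np.ndarray
    bc_raw: np.ndarray | None = None
    bc_norm: np.ndarray | None = None
    l_values: np.ndarray | None = None
    unreachable_pairs: np.ndarray | None = None
    n_frames: int = 1

    @property
    def n_residues(self) -> int:
        return int(self.positions.size)

    def missing_l(self) -> np.ndarray:
        if self.l_values is None:
            return np.zeros(self.n_residues, dtype=bool)
        return np.isnan(self.l_values)

    def to_tsv(self, precision: int = 6) -> str:
        cols = ["residue"]
        data = [self.positions.astype(int)]
        for name, arr in (("BC_raw", self.bc_raw), ("BC_norm", self.bc_norm),
                          ("L", self.l_values),
                          ("unreachable_pairs", self.unreachable_pairs)):
            if arr is not None:
                cols.append(name)
                data.append(arr)
        lines = ["\t".join(cols)]
        for i in range(self.n_residues):
            row = [str(int(data[0][i]))]
            for arr in data[1:]:
                v = arr[i]
                row.append("NA" if (isinstance(v, float) or np.isscalar(v))
                           and np.isnan(v) else f"{float(v):.{precision}f}")
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# graph construction


def _frame_graph(coords: np.ndarray, cutoff: float) -> nx.Graph:
    n = coords.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(1, n + 1))
    d = squareform(pdist(coords))
    ii, jj = np.where(np.triu(d <= cutoff, k=1))
    g.add_edges_from(zip((ii + 1).tolist(), (jj + 1).tolist()))
    return g


def build_contact_network(
    source: Trajectory | np.ndarray, cutoff: float = DEFAULT_CUTOFF
) -> list[nx.Graph]:
    """Unweighted contact graph(s) at a distance cutoff.

    A trajectory yields one graph per frame; a single N x 3 coordinate
    array yields a one-element list.  Self-edges are excluded; isolated
    residues remain as nodes.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if isinstance(source, Trajectory):
        frames = source.frames
    else:
        frames = np.asarray(source, dtype=float)
        if frames.ndim == 2:
            frames = frames[None, :, :]
    if frames.size == 0:
        raise ValueError("empty input: no coordinates to build a network from")
    return [_frame_graph(f, cutoff) for f in frames]


def _check_shared_nodes(graphs: list[nx.Graph]) -> int:
    if not graphs:
        raise ValueError("no graphs given")
    nodes = set(graphs[0].nodes)
    for g in graphs[1:]:
        if set(g.nodes) != nodes:
            raise ValueError("graphs do not share a node set")
    return len(nodes)


# ---------------------------------------------------------------------------
# profiles


def betweenness_profile(graphs: list[nx.Graph] | nx.Graph) -> CentralityProfile:
    """Frame-averaged betweenness centrality (raw and normalized).

    Raw BC counts unordered pairs with fractional weighting over tied
    shortest paths; the normalized variant divides by (N−1)(N−2)/2.
    """
    if isinstance(graphs, nx.Graph):
        graphs = [graphs]
    n = _check_shared_nodes(graphs)
    order = sorted(graphs[0].nodes)
    if n < 3:
        warnings.warn("fewer than 3 nodes: betweenness is identically 0")
        zeros = np.zeros(n)
        return CentralityProfile(np.array(order, dtype=float), bc_raw=zeros,
                                 bc_norm=zeros.copy(), n_frames=len(graphs))
    raw = np.zeros(n)
    norm = np.zeros(n)
    for g in graphs:
        b_raw = nx.betweenness_centrality(g, normalized=False)
        b_norm = nx.betweenness_centrality(g, normalized=True)
        raw += np.array([b_raw[v] for v in order])
        norm += np.array([b_norm[v] for v in order])
    f = len(graphs)
    return CentralityProfile(np.array(order, dtype=float),
                             bc_raw=raw / f, bc_norm=norm / f, n_frames=f)


def reachability_profile(graphs: list[nx.Graph] | nx.Graph) -> CentralityProfile:
    """Frame-averaged mean shortest-path length L_i per residue.

    L_i = (Σ_{j≠i, reachable} d(i,j)) / (number reachable); unreachable
    pairs are excluded from the mean and counted per residue.  A residue
    isolated in every frame gets L_i = NaN (flagged as missing).
    """
    if isinstance(graphs, nx.Graph):
        graphs = [graphs]
    n = _check_shared_nodes(graphs)
    order = sorted(graphs[0].nodes)
    l_sum = np.zeros(n)
    l_cnt = np.zeros(n)
    unreach = np.zeros(n)
    for g in graphs:
        for idx, v in enumerate(order):
            lengths = nx.single_source_shortest_path_length(g, v)
            reachable = len(lengths) - 1
            unreach[idx] += (n - 1) - reachable
            if reachable > 0:
                l_sum[idx] += sum(lengths.values()) / reachable
                l_cnt[idx] += 1
    f = len(graphs)
    with np.errstate(invalid="ignore", divide="ignore"):
        l_avg = np.where(l_cnt > 0, l_sum / np.maximum(l_cnt, 1), np.nan)
    if np.any(l_cnt == 0):
        warnings.warn("isolated residue(s): L flagged missing (NaN)")
    return CentralityProfile(np.array(order, dtype=float),
                             l_values=l_avg, unreachable_pairs=unreach / f,
                             n_frames=f)


def centrality_profile(graphs: list[nx.Graph] | nx.Graph) -> CentralityProfile:
    """Convenience: betweenness and reachability in one profile."""
    bc = betweenness_profile(graphs)
    rp = reachability_profile(graphs if isinstance(graphs, list) else [graphs])
    return CentralityProfile(bc.positions, bc_raw=bc.bc_raw, bc_norm=bc.bc_norm,
                             l_values=rp.l_values,
                             unreachable_pairs=rp.unreachable_pairs,
                             n_frames=bc.n_frames)


def delta_profile(profile_a: CentralityProfile,
                  profile_b: CentralityProfile) -> CentralityProfile:
    """Per-residue change ``b − a`` (b conventionally the mutant/later state).

    Negative ΔL_i means the average path to residue i shortened; positive
    means it lengthened.
    """
    if profile_a.n_residues != profile_b.n_residues or \
            not np.array_equal(profile_a.positions, profile_b.positions):
        raise ValueError("profiles are over different node sets")

    def sub(x, y):
        if x is None or y is None:
            return None
        return y - x

    return CentralityProfile(
        profile_a.positions.copy(),
        bc_raw=sub(profile_a.bc_raw, profile_b.bc_raw),
        bc_norm=sub(profile_a.bc_norm, profile_b.bc_norm),
        l_values=sub(profile_a.l_values, profile_b.l_values),
        unreachable_pairs=sub(profile_a.unreachable_pairs,
                              profile_b.unreachable_pairs),
        n_frames=0,
    )


# ---------------------------------------------------------------------------
# peak extraction


def peak_residues(
    profile: CentralityProfile | np.ndarray,
    criterion: str = "zscore",
    k: int = 2,
    z: float = 2.0,
    metric: str = "bc_raw",
) -> list[int]:
    """Residue positions at profile peaks.

    ``"zscore"`` (default): local maxima whose z-score over the profile is
    ≥ ``z`` (a flat profile has no peaks).  ``"topk"``: the ``k`` largest
    values, ties broken by position.  NaN entries never peak.
    """
    if isinstance(profile, CentralityProfile):
        values = getattr(profile, metric)
        if values is None:
            raise ValueError(f"profile has no field {metric!r}")
        positions = profile.positions.astype(int)
    else:
        values = np.asarray(profile, dtype=float)
        positions = np.arange(1, values.size + 1)
    if values.size == 0:
        raise ValueError("empty profile")

    if criterion == "topk":
        order = sorted(range(values.size),
                       key=lambda i: (-(values[i] if np.isfinite(values[i])
                                        else -np.inf), positions[i]))
        return [int(positions[i]) for i in order[:k]]
    if criterion != "zscore":
        raise ValueError(f"unknown criterion {criterion!r}")

    finite = values[np.isfinite(values)]
    if finite.size == 0:
        return []
    mean, std = float(finite.mean()), float(finite.std())
    if std == 0.0:
        return []
    peaks = []
    for i in range(values.size):
        v = values[i]
        if not np.isfinite(v):
            continue
        left = values[i - 1] if i > 0 else -np.inf
        right = values[i + 1] if i < values.size - 1 else -np.inf
        if v >= left and v >= right and (v - mean) / std >= z:
            peaks.append(int(positions[i]))
    return peaks
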