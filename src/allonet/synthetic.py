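"""Synthetic fixtures with known ground truth.

Every pipeline stage is testable without downloads or MD engines:

* :func:`make_helical_bundle` — ideal α-helix bundles with Cα and pseudo-Cβ
  nodes at realistic contact distances;
* :func:`make_correlated_trajectory` — statistical trajectories whose
  residue-pair motion correlations equal a planted matrix in expectation;
* :func:`make_random_graph` — seeded weighted graphs for the path-search
  oracles;
* :func:`make_toy_folding` — small folding-unit systems with known unit
  energies for the ensemble allosteric model.

Trajectories here are statistical, not dynamical: displacements are drawn
per-axis from a multivariate normal over residues with the planted
correlation matrix, identically on x/y/z, which makes the vector-dot
cross-correlation equal the planted scalar ρ in expectation and gives the
tests an analytic oracle.  All randomness flows through one explicit seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from allonet.eam import ToyFoldingSpec
from allonet.network import ResidueGraph
from allonet.structure_io import (
    Residue,
    Structure,
    Trajectory,
    node_coordinates,
    write_structure,
    write_trajectory,
)

# ideal α-helix geometry
_HELIX_RISE = 1.5          # Å per residue along the axis
_HELIX_TWIST = np.deg2rad(100.0)  # per residue
_HELIX_RADIUS = 2.3        # Å, Cα distance from the helix axis
_CB_OFFSET = 1.53          # Å, pseudo-Cβ along the local helix normal


# ---------------------------------------------------------------------------
# structures


def _helix_coords(n_res: int, origin: np.ndarray, phase: float) -> tuple[np.ndarray, np.ndarray]:
    k = np.arange(n_res)
    ang = phase + k * _HELIX_TWIST
    radial = np.stack([np.cos(ang), np.sin(ang), np.zeros(n_res)], axis=1)
    ca = origin + _HELIX_RADIUS * radial
    ca[:, 2] += k * _HELIX_RISE
    # pseudo-Cβ: 1.53 Å from Cα, tilted 45° from the outward helix normal
    # toward the axis, which reproduces the ~5.4 Å Cβ(i)-Cβ(i±1) and
    # ~5.6 Å Cβ(i)-Cβ(i±3) contacts of real α-helices
    tilt = (radial + np.array([0.0, 0.0, 1.0])) / np.sqrt(2.0)
    cb = ca + _CB_OFFSET * tilt
    return ca, cb


def make_helical_bundle(
    n_helices: int,
    residues_per_helix: int,
    seed: int = 0,
    jitter: float = 0.02,
) -> Structure:
    """Build an idealized α-helical bundle with Cα and pseudo-Cβ atoms.

    Helix axes sit on a regular polygon whose spacing is chosen (smallest
    spacing on a fixed deterministic grid) so that inter-helix node
    distances at the interface stay above 4 Å while at least one
    inter-helix pair falls inside the 5.7 Å contact cutoff, guaranteeing
    both intra- and inter-helix contacts for the 5.7 Å and 7.0 Å networks.
    A small seeded jitter (default 0.02 Å) breaks exact symmetry.
    """
    if n_helices < 1 or residues_per_helix < 4:
        raise ValueError(
            "need n_helices >= 1 and residues_per_helix >= 4, got "
            f"{n_helices}, {residues_per_helix}"
        )

    def build(spacing: float) -> tuple[np.ndarray, np.ndarray]:
        cas, cbs = [], []
        if n_helices == 1:
            centers = [np.zeros(3)]
        else:
            circum = spacing / (2.0 * np.sin(np.pi / n_helices))
            centers = [
                circum * np.array([np.cos(2 * np.pi * h / n_helices),
                                   np.sin(2 * np.pi * h / n_helices), 0.0])
                for h in range(n_helices)
            ]
        for h, c in enumerate(centers):
            # phase each helix to face the bundle axis plus a spread
            phase = np.pi + 2 * np.pi * h / max(n_helices, 1) + 0.7 * h
            ca, cb = _helix_coords(residues_per_helix, c, phase)
            cas.append(ca)
            cbs.append(cb)
        return np.concatenate(cas), np.concatenate(cbs)

    if n_helices == 1:
        ca, cb = build(0.0)
    else:
        ca = cb = None
        n_per = residues_per_helix
        for spacing in np.arange(8.0, 14.0 + 1e-9, 0.05):
            ca_try, cb_try = build(float(spacing))
            inter_min = np.inf
            for hi in range(n_helices):
                for hj in range(hi + 1, n_helices):
                    a = cb_try[hi * n_per:(hi + 1) * n_per]
                    b = cb_try[hj * n_per:(hj + 1) * n_per]
                    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
                    inter_min = min(inter_min, float(d.min()))
            if 4.0 <= inter_min <= 5.7:
                ca, cb = ca_try, cb_try
                break
        if ca is None:
            raise RuntimeError("could not pack helices with interface contacts")

    rng = np.random.default_rng(seed)
    ca = ca + jitter * rng.standard_normal(ca.shape)
    cb = cb + jitter * rng.standard_normal(cb.shape)

    n = n_helices * residues_per_helix
    residues = [Residue("A", i + 1, "ALA") for i in range(n)]
    atoms = [{"CA": ca[i], "CB": cb[i]} for i in range(n)]
    return Structure(residues, atoms)


# ---------------------------------------------------------------------------
# planted-correlation trajectories


@dataclass
class PlantedCorrelationSpec:
    """Correlation structure to plant in a synthetic trajectory.

    Each block couples residue set A to residue set B at target correlation
    ρ ∈ [−1, 1] via one latent factor with loadings √|ρ| on A and
    sign(ρ)·√|ρ| on B; unlisted pairs stay at the 0 baseline.  As a
    consequence within-A and within-B pairs of a block are planted at |ρ|
    (the implied matrix must be positive semi-definite, and cross-block
    loadings on a shared residue may not exceed unit variance).
    Residue sets are 1-based sequential positions.
    """

    n_residues: int
    blocks: list[tuple[frozenset, frozenset, float]] = field(default_factory=list)
    displacement_scale: float = 0.3  # Å

    def __post_init__(self) -> None:
        self.blocks = [
            (frozenset(a), frozenset(b), float(rho)) for a, b, rho in self.blocks
        ]
        for a, b, rho in self.blocks:
            if not (-1.0 <= rho <= 1.0):
                raise ValueError(f"target correlation {rho} outside [-1, 1]")
            if a & b:
                raise ValueError(f"block residue sets overlap: {sorted(a & b)}")
            for s in (a, b):
                for r in s:
                    if not (1 <= r <= self.n_residues):
                        raise ValueError(f"residue {r} outside [1,{self.n_residues}]")

    def loadings(self) -> np.ndarray:
        """K x N factor loadings implied by the blocks."""
        lam = np.zeros((len(self.blocks), self.n_residues))
        for k, (a, b, rho) in enumerate(self.blocks):
            root = np.sqrt(abs(rho))
            for r in a:
                lam[k, r - 1] += root
            for r in b:
                lam[k, r - 1] += np.sign(rho) * root
        return lam

    def implied_matrix(self) -> np.ndarray:
        """The planted N x N correlation matrix (validated PSD)."""
        lam = self.loadings()
        resid = 1.0 - (lam ** 2).sum(axis=0)
        if np.any(resid < -1e-12):
            bad = int(np.argmin(resid)) + 1
            raise ValueError(
                f"implied correlation matrix is not positive semi-definite: "
                f"residue {bad} carries total factor variance > 1"
            )
        C = lam.T @ lam + np.diag(np.clip(resid, 0.0, None))
        np.fill_diagonal(C, 1.0)
        if np.linalg.eigvalsh(C).min() < -1e-10:
            raise ValueError("implied correlation matrix is not positive semi-definite")
        return C


def sample_displacements(
    spec: PlantedCorrelationSpec, n_frames: int, seed: int
) -> np.ndarray:
    """Zero-mean F x N x 3 displacements with the planted correlation.

    Per axis, displacements are scale · L z with L Lᵀ the planted matrix
    (eigen-factorization; PSD with zero eigenvalues allowed) and z i.i.d.
    standard normal, independently on x, y, z.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames for any correlation computation")
    if spec.displacement_scale <= 0:
        raise ValueError(
            "displacement_scale must be positive (zero fluctuation makes the "
            "correlation denominators vanish)"
        )
    C = spec.implied_matrix()
    w, V = np.linalg.eigh(C)
    L = V * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(seed)
    disp = np.empty((n_frames, spec.n_residues, 3))
    for axis in range(3):
        z = rng.standard_normal((n_frames, spec.n_residues))
        disp[:, :, axis] = spec.displacement_scale * (z @ L.T)
    return disp


def make_correlated_trajectory(
    structure: Structure,
    spec: PlantedCorrelationSpec,
    n_frames: int,
    seed: int,
    scheme: str = "CA",
) -> tuple[Trajectory, np.ndarray]:
    """Synthesize a trajectory around ``structure`` with planted correlations.

    Returns the trajectory (node coordinates per ``scheme``) and the planted
    correlation matrix as ground truth.  Fully reproducible by seed.
    """
    if structure.n_residues != spec.n_residues:
        raise ValueError(
            f"structure has {structure.n_residues} residues but spec says "
            f"{spec.n_residues}"
        )
    disp = sample_displacements(spec, n_frames, seed)
    nodes = node_coordinates(structure, scheme)
    traj = Trajectory(nodes[None, :, :] + disp, list(structure.residues),
                      scheme=scheme)
    return traj, spec.implied_matrix()


def write_fixture(
    structure: Structure,
    spec: PlantedCorrelationSpec,
    n_frames: int,
    seed: int,
    outdir: str | Path,
) -> dict:
    """Write a complete on-disk fixture: structure, trajectory, ground truth.

    The trajectory PDB applies each residue displacement rigidly to all of
    the residue's atoms, so CA and CB node trajectories extracted from it
    share the planted correlation.  Returns the manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    disp = sample_displacements(spec, n_frames, seed)
    write_structure(structure, outdir / "structure.pdb")
    write_trajectory(structure, disp, outdir / "trajectory.pdb")
    C = spec.implied_matrix()
    header = "\t".join(str(i + 1) for i in range(spec.n_residues))
    rows = [header]
    for i in range(spec.n_residues):
        rows.append("\t".join(f"{v:.6f}" for v in C[i]))
    (outdir / "planted_dccm.tsv").write_text("\n".join(rows) + "\n")
    manifest = {
        "n_residues": spec.n_residues,
        "n_frames": n_frames,
        "seed": seed,
        "displacement_scale": spec.displacement_scale,
        "blocks": [
            {"A": sorted(a), "B": sorted(b), "rho": rho}
            for a, b, rho in spec.blocks
        ],
        "files": ["structure.pdb", "trajectory.pdb", "planted_dccm.tsv"],
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


# ---------------------------------------------------------------------------
# graphs and folding systems


def make_random_graph(
    n_nodes: int,
    edge_prob: float,
    weight_range: tuple[float, float],
    seed: int,
) -> ResidueGraph:
    """Seeded undirected random graph with positive edge costs.

    Edge correlations are back-filled as exp(−cost) so the graph carries the
    same attributes a trajectory-derived network would.
    """
    low, high = weight_range
    if not (0.0 < edge_prob <= 1.0):
        raise ValueError(f"edge_prob must be in (0, 1], got {edge_prob}")
    if not (0.0 < low <= high):
        raise ValueError(
            f"edge costs must be positive (Dijkstra precondition), got "
            f"range ({low}, {high})"
        )
    rng = np.random.default_rng(seed)
    rg = ResidueGraph.empty(range(1, n_nodes + 1))
    for i in range(1, n_nodes + 1):
        for j in range(i + 1, n_nodes + 1):
            if rng.random() <= edge_prob:
                cost = float(rng.uniform(low, high))
                rg.add_edge(i, j, correlation=float(np.exp(-cost)),
                            cost=cost, contact_freq=1.0)
    return rg


def make_toy_folding(
    n_residues: int,
    window: int = 8,
    min_terminal: int = 4,
    overall_dg: float = 5.0,
    temperature: float = 298.15,
    seed: int | None = None,
) -> ToyFoldingSpec:
    """A toy folding system with known unit energies.

    With ``seed=None`` the energies are uniform (summing to ``overall_dg``,
    the study default of 5 kcal/mol at 25 °C); with a seed they are random
    positive weights rescaled to the same total.
    """
    from allonet.eam import make_partition

    partition = make_partition(n_residues, window=window, min_terminal=min_terminal)
    n_units = len(partition.units)
    if seed is None:
        g = np.full(n_units, overall_dg / n_units)
    else:
        rng = np.random.default_rng(seed)
        raw = rng.uniform(0.2, 1.0, size=n_units)
        g = overall_dg * raw / raw.sum()
    return ToyFoldingSpec(
        n_residues=n_residues,
        unit_energies=g,
        overall_dg=overall_dg,
        temperature=temperature,
        window=window,
        min_terminal=min_terminal,
    )
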