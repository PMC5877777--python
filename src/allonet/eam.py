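"""Ensemble allosteric model on folding-unit ensembles.

The chain is tiled into contiguous *folding units* (default window 8
residues, terminal units at least 4).  Each unit is either folded or
unfolded, giving 2^U states; a state's free energy is the sum of the
unfolding penalties g_u (kcal/mol) of its unfolded units, so the fully
folded state sits at G = 0 and the fully unfolded state at the overall
stability (default 5 kcal/mol at 25 °C).  Boltzmann weighting the states
gives each residue j a stability constant

    κ_f,j = Σ P(states with j's unit folded) / Σ P(states with j's unit unfolded)

and a residue-specific free energy ΔG_f,j = −RT ln κ_f,j.  A thermodynamic
alanine scan perturbs the unit containing the mutated residue k by δ_k and
records the thermodynamic coupling ΔΔG_j = ΔG_f,j(mut) − ΔG_f,j(WT) at every
other residue; residues with |ΔΔG| above a cutoff form the susceptible
(cooperative) regions.

The unfolding energetics g_u are a declared surrogate: uniform (calibrated
to the overall stability), user-supplied, or derived from the structure's
contact density.  The ensemble machinery — state enumeration, stability
constants, coupling — is exact for whichever energies are supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from allonet.regions import RegionSet, _merge_runs
from allonet.structure_io import Structure, node_coordinates

R_KCAL = 1.987e-3        # gas constant, kcal / (mol K)
DEFAULT_T = 298.15       # K (25 °C)
DEFAULT_OVERALL_DG = 5.0  # kcal/mol, fully-unfolded vs fully-folded
DEFAULT_WINDOW = 8
DEFAULT_MIN_TERMINAL = 4
MAX_UNITS = 24           # hard cap: 2^U states are enumerated exhaustively

# Side-chain heavy-atom counts, used for the default alanine-scan
# perturbation magnitude (see ``alanine_delta``).
SIDECHAIN_HEAVY_ATOMS = {
    "GLY": 0, "ALA": 1, "SER": 2, "CYS": 2, "THR": 3, "VAL": 3, "PRO": 3,
    "ASN": 4, "ASP": 4, "ILE": 4, "LEU": 4, "MET": 4,
    "GLU": 5, "GLN": 5, "LYS": 5, "HIS": 6, "ARG": 7, "PHE": 7,
    "TYR": 8, "TRP": 10,
}
DELTA_PER_HEAVY_ATOM = 0.15  # kcal/mol per side-chain heavy atom lost to Ala


def alanine_delta(resname: str,
                  per_atom: float = DELTA_PER_HEAVY_ATOM) -> float:
    """Default unfolding-penalty shift for an X→Ala substitution.

    Proportional to the side-chain heavy atoms removed relative to alanine;
    a destabilizing mutation (fewer packing contacts) lowers the unit's
    unfolding penalty, so the shift is negative for residues larger than
    Ala.  Always overridable per run.
    """
    n = SIDECHAIN_HEAVY_ATOMS.get(resname.upper())
    if n is None:
        raise KeyError(f"unknown residue type {resname!r}")
    return -per_atom * (n - SIDECHAIN_HEAVY_ATOMS["ALA"])


# ---------------------------------------------------------------------------
# partition


@dataclass(frozen=True)
class FoldingPartition:
    """Contiguous folding units tiling the chain exactly once.

    ``units`` holds 1-based inclusive residue intervals.  Interior units
    have length ``window``; terminal units are at least
    ``min(min_terminal, window)`` long.
    """

    units: tuple[tuple[int, int], ...]
    window: int = DEFAULT_WINDOW
    min_terminal: int = DEFAULT_MIN_TERMINAL
    shift: int = 0

    def __post_init__(self) -> None:
        expect = 1
        for start, end in self.units:
            if start != expect or end < start:
                raise ValueError(f"units do not tile the chain: {self.units}")
            expect = end + 1

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_residues(self) -> int:
        return self.units[-1][1]

    def unit_of(self, residue: int) -> int:
        """0-based unit index containing a 1-based residue position."""
        for u, (start, end) in enumerate(self.units):
            if start <= residue <= end:
                return u
        raise KeyError(f"residue {residue} outside chain [1,{self.n_residues}]")

    def unit_index(self) -> np.ndarray:
        """Per-residue 0-based unit index, length n_residues."""
        out = np.empty(self.n_residues, dtype=int)
        for u, (start, end) in enumerate(self.units):
            out[start - 1:end] = u
        return out


def make_partition(
    n_residues: int,
    window: int = DEFAULT_WINDOW,
    min_terminal: int = DEFAULT_MIN_TERMINAL,
    shift: int = 0,
) -> FoldingPartition:
    """Tile the chain into folding units from the N-terminus.

    Consecutive blocks of ``window`` residues, optionally preceded by a
    leading block of ``shift`` residues (merged into the first full unit
    when shorter than ``min_terminal``).  A trailing remainder shorter than
    ``min_terminal`` merges into the last unit; a remainder at least that
    long stands as its own terminal unit.
    """
    if window < min_terminal:
        raise ValueError(f"window {window} smaller than min_terminal {min_terminal}")
    if not (0 <= shift < window):
        raise ValueError(f"shift must be in [0, window), got {shift}")
    if n_residues < min_terminal:
        raise ValueError(f"chain of {n_residues} residues shorter than "
                         f"min_terminal {min_terminal}")

    sizes: list[int] = []
    remaining = n_residues
    if shift:
        lead = min(shift, remaining)
        sizes.append(lead)
        remaining -= lead
    while remaining >= window:
        sizes.append(window)
        remaining -= window
    if remaining:
        if remaining >= min_terminal:
            sizes.append(remaining)
        elif sizes:
            sizes[-1] += remaining
        else:
            sizes.append(remaining)
    # leading block shorter than the terminal minimum merges forward
    if shift and sizes[0] < min_terminal and len(sizes) > 1:
        sizes[1] += sizes[0]
        sizes.pop(0)

    units = []
    start = 1
    for s in sizes:
        units.append((start, start + s - 1))
        start += s
    return FoldingPartition(tuple(units), window=window,
                            min_terminal=min_terminal, shift=shift)


# ---------------------------------------------------------------------------
# energies


@dataclass
class ToyFoldingSpec:
    """A small folding system with known unit unfolding energies.

    ``unit_energies=None`` means the uniform default: every unit gets
    ``overall_dg / U`` so the fully unfolded state sits at the overall
    stability.  ``mutations`` optionally maps residue position → δ
    (kcal/mol) perturbations for scanning.
    """

    n_residues: int
    unit_energies: np.ndarray | None = None
    overall_dg: float = DEFAULT_OVERALL_DG
    temperature: float = DEFAULT_T
    window: int = DEFAULT_WINDOW
    min_terminal: int = DEFAULT_MIN_TERMINAL
    mutations: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.unit_energies is not None:
            self.unit_energies = np.asarray(self.unit_energies, dtype=float)
            if not np.all(np.isfinite(self.unit_energies)):
                raise ValueError("unit energies must be finite")
        for delta in self.mutations.values():
            if not math.isfinite(delta):
                raise ValueError("mutation perturbations must be finite")

    def partition(self) -> FoldingPartition:
        return make_partition(self.n_residues, self.window, self.min_terminal)


def unit_energies_from_structure(
    structure: Structure,
    partition: FoldingPartition,
    overall_dg: float = DEFAULT_OVERALL_DG,
    cutoff: float = 7.0,
) -> np.ndarray:
    """Structure-derived surrogate energies: g_u ∝ mean unit contact number.

    Contact number is counted on Cβ nodes (Cα for glycine) at ``cutoff`` Å;
    unit means are rescaled so Σ g_u equals the overall stability.  Densely
    packed units thus cost more to unfold.
    """
    coords = node_coordinates(structure, "CB")
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    contacts = (d <= cutoff).sum(axis=1) - 1  # exclude self
    means = np.array([
        contacts[start - 1:end].mean() for start, end in partition.units
    ], dtype=float)
    if means.sum() <= 0:
        raise ValueError("no contacts: cannot derive unit energies")
    return overall_dg * means / means.sum()


# ---------------------------------------------------------------------------
# ensemble enumeration


@dataclass
class EnsembleModel:
    """Exhaustively enumerated folding-unit ensemble.

    Bit u of a state index set means unit u folded; state 2^U − 1 is the
    native (fully folded, G = 0) state.  ``state_energies`` and
    ``state_probabilities`` are stored for systems small enough to keep in
    memory (U ≤ 16); the per-unit stability constants are always exact.
    """

    partition: FoldingPartition
    unit_energies: np.ndarray
    temperature: float
    z: float
    kappa_units: np.ndarray
    state_energies: np.ndarray | None = None
    state_probabilities: np.ndarray | None = None

    @property
    def rt(self) -> float:
        return R_KCAL * self.temperature

    @property
    def n_units(self) -> int:
        return self.partition.n_units

    def dg_units(self) -> np.ndarray:
        """Unit-level ΔG_f = −RT ln κ; −inf where κ is the +inf sentinel."""
        out = np.empty(self.n_units)
        for u, k in enumerate(self.kappa_units):
            out[u] = -np.inf if np.isinf(k) else -self.rt * math.log(k)
        return out


def _accumulate(g: np.ndarray, rt: float, store_states: bool,
                chunk: int = 1 << 18):
    u_count = g.size
    n_states = 1 << u_count
    bit_vals = np.arange(u_count)
    z = 0.0
    folded_w = np.zeros(u_count)
    energies = np.empty(n_states) if store_states else None
    for start in range(0, n_states, chunk):
        masks = np.arange(start, min(start + chunk, n_states), dtype=np.int64)
        folded = ((masks[:, None] >> bit_vals) & 1).astype(bool)
        G = (~folded) @ g
        w = np.exp(-G / rt)
        z += float(w.sum())
        folded_w += w @ folded
        if store_states:
            energies[start:start + masks.size] = G
    return z, folded_w, energies


def enumerate_ensemble(
    partition_or_spec: FoldingPartition | ToyFoldingSpec,
    energies: np.ndarray | None = None,
    overall_dg: float = DEFAULT_OVERALL_DG,
    temperature: float = DEFAULT_T,
) -> EnsembleModel:
    """Enumerate all 2^U folded/unfolded states and Boltzmann-weight them.

    ``energies=None`` uses the uniform default calibrated so the fully
    unfolded state sits at ``overall_dg``.  Systems above ``MAX_UNITS``
    units are refused outright (no silent sampling) — use a coarser window.
    """
    if isinstance(partition_or_spec, ToyFoldingSpec):
        spec = partition_or_spec
        partition = spec.partition()
        energies = spec.unit_energies if energies is None else energies
        overall_dg = spec.overall_dg
        temperature = spec.temperature
    else:
        partition = partition_or_spec

    u_count = partition.n_units
    if u_count > MAX_UNITS:
        raise ValueError(
            f"{u_count} folding units would require 2^{u_count} states; "
            f"the exhaustive cap is {MAX_UNITS} — use a coarser window"
        )
    if energies is None:
        g = np.full(u_count, overall_dg / u_count)
    else:
        g = np.asarray(energies, dtype=float)
        if g.shape != (u_count,):
            raise ValueError(f"expected {u_count} unit energies, got {g.shape}")
        if not np.all(np.isfinite(g)):
            raise ValueError("unit energies must be finite")

    rt = R_KCAL * temperature
    store = u_count <= 16
    z, folded_w, state_e = _accumulate(g, rt, store)
    unfolded_w = z - folded_w
    with np.errstate(divide="ignore"):
        kappa = np.where(unfolded_w > 0.0, folded_w / np.maximum(unfolded_w, 1e-300),
                         np.inf)
    probs = np.exp(-state_e / rt) / z if store else None
    return EnsembleModel(partition, g, temperature, z, kappa,
                         state_energies=state_e, state_probabilities=probs)


def residue_stability(model: EnsembleModel) -> pd.DataFrame:
    """Per-residue stability constants κ_f,j and free energies ΔG_f,j.

    Residues of the same unit share values.  Where no unfolded state has
    weight, κ is the +inf sentinel and ΔG_f is −inf (flagged, never NaN).
    """
    unit_idx = model.partition.unit_index()
    kappa = model.kappa_units[unit_idx]
    dg = model.dg_units()[unit_idx]
    return pd.DataFrame({
        "residue": np.arange(1, model.partition.n_residues + 1),
        "unit": unit_idx + 1,
        "kappa_f": kappa,
        "dG_f": dg,
    })


def mutation_scan(
    model: EnsembleModel,
    site: int,
    delta: float,
) -> pd.DataFrame:
    """Thermodynamic coupling ΔΔG_j for a perturbation δ at residue ``site``.

    The mutant ensemble shifts the unfolding penalty of the unit containing
    the site by δ (the mutation alters the energetics of every state in
    which that unit is folded, expressed as the equivalent unfolding-penalty
    shift); ΔΔG_j = ΔG_f,j(mut) − ΔG_f,j(WT).  δ = 0 is the identity.
    """
    if not math.isfinite(delta):
        raise ValueError("perturbation must be finite")
    unit = model.partition.unit_of(site)  # raises for sites outside the chain
    g_mut = model.unit_energies.copy()
    g_mut[unit] += delta
    mutant = enumerate_ensemble(model.partition, energies=g_mut,
                                temperature=model.temperature)
    wt = residue_stability(model)
    mu = residue_stability(mutant)
    ddg = mu["dG_f"].to_numpy() - wt["dG_f"].to_numpy()
    return pd.DataFrame({
        "residue": wt["residue"],
        "unit": wt["unit"],
        "dG_f_wt": wt["dG_f"],
        "dG_f_mut": mu["dG_f"],
        "ddG": ddg,
    })


def susceptible_regions(
    ddg: np.ndarray | pd.DataFrame,
    cutoff: float,
    mode: str = "absolute",
    exclude_site: int | None = None,
) -> RegionSet:
    """Residues whose coupling exceeds the susceptibility cutoff, as regions.

    ``mode="absolute"`` (default) takes |ΔΔG_j| > cutoff, ``"signed"``
    takes ΔΔG_j > cutoff; the comparison is strict.  ``exclude_site``
    optionally drops the mutated residue from its own region report.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if mode not in ("absolute", "signed"):
        raise ValueError(f"mode must be 'absolute' or 'signed', got {mode!r}")
    if isinstance(ddg, pd.DataFrame):
        values = ddg["ddG"].to_numpy()
    else:
        values = np.asarray(ddg, dtype=float)
    crit = np.abs(values) > cutoff if mode == "absolute" else values > cutoff
    residues = {int(i) + 1 for i in np.where(crit)[0]}
    if exclude_site is not None:
        residues.discard(exclude_site)
    return RegionSet(_merge_runs(residues, "susceptible"),
                     note=f"cutoff={cutoff} mode={mode} method=eam")
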