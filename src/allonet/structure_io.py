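"""Structure and trajectory I/O on plain-text PDB.

Structures are single models; trajectories are multi-model PDB files, one
MODEL record per frame.  Reading goes through Bio.PDB; writing uses a
fixed-width ATOM formatter so that write -> read -> write round-trips are
byte-identical, which the tests rely on.

Every downstream stage works on one *node* per residue: the Cα atom
(scheme ``"CA"``) or the Cβ atom with Cα substituted for glycine
(scheme ``"CB"``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser

SCHEMES = ("CA", "CB")


@dataclass(frozen=True)
class Residue:
    """Residue identity: (chain id, PDB residue number, 3-letter name)."""

    chain: str
    number: int
    name: str

    def label(self) -> str:
        return f"{self.chain}:{self.name}{self.number}"


@dataclass
class Structure:
    """A single protein model: ordered residues plus per-residue atoms.

    ``atoms[i]`` maps atom name -> 3-vector (Å) for ``residues[i]``.
    Residue numbers must be unique within a chain and strictly increasing
    in file order; coordinates must be finite.
    """

    residues: list[Residue]
    atoms: list[dict[str, np.ndarray]]

    def __post_init__(self) -> None:
        if len(self.residues) != len(self.atoms):
            raise ValueError("residues and atoms lists differ in length")
        last: dict[str, int] = {}
        for res in self.residues:
            if res.chain in last and res.number <= last[res.chain]:
                raise ValueError(
                    f"residue numbers not strictly increasing in chain "
                    f"{res.chain}: {res.number} after {last[res.chain]}"
                )
            last[res.chain] = res.number
        for res, d in zip(self.residues, self.atoms):
            for name, xyz in d.items():
                if not np.all(np.isfinite(xyz)):
                    raise ValueError(f"non-finite coordinate for {res.label()} {name}")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def index_of(self, number: int, chain: str | None = None) -> int:
        """0-based sequential index of a residue by PDB number (and chain)."""
        for i, res in enumerate(self.residues):
            if res.number == number and (chain is None or res.chain == chain):
                return i
        raise KeyError(f"residue {number} (chain {chain}) not found")


@dataclass
class Trajectory:
    """F x N x 3 node coordinates with a residue index map.

    Frames share one atom/node ordering; window selections downstream are
    half-open frame intervals [start, end) with 0-based indices.
    ``frame_spacing_ps`` is metadata only and may be None (unknown).
    """

    frames: np.ndarray
    residues: list[Residue]
    scheme: str = "CA"
    frame_spacing_ps: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be an F x N x 3 array")
        if self.frames.shape[1] != len(self.residues):
            raise ValueError("frame width does not match residue list")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def n_residues(self) -> int:
        return int(self.frames.shape[1])

    def index_of(self, number: int, chain: str | None = None) -> int:
        for i, res in enumerate(self.residues):
            if res.number == number and (chain is None or res.chain == chain):
                return i
        raise KeyError(f"residue {number} (chain {chain}) not found")

    def window(self, start: int, end: int) -> np.ndarray:
        """Frames in the half-open interval [start, end)."""
        if not (0 <= start < end <= self.n_frames):
            raise ValueError(f"invalid window [{start},{end}) for F={self.n_frames}")
        return self.frames[start:end]


# ---------------------------------------------------------------------------
# node coordinates


def node_coordinates(structure: Structure, scheme: str = "CA") -> np.ndarray:
    """One node coordinate per residue.

    ``"CA"`` returns Cα positions; ``"CB"`` returns Cβ positions with the
    Cα substituted for glycine (which has no Cβ).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown node scheme {scheme!r}; expected one of {SCHEMES}")
    coords = np.empty((structure.n_residues, 3))
    for i, (res, atoms) in enumerate(zip(structure.residues, structure.atoms)):
        if scheme == "CA":
            if "CA" not in atoms:
                raise ValueError(f"residue {res.label()} has no CA atom")
            coords[i] = atoms["CA"]
        else:
            if "CB" in atoms:
                coords[i] = atoms["CB"]
            elif res.name == "GLY" and "CA" in atoms:
                coords[i] = atoms["CA"]
            else:
                raise ValueError(
                    f"residue {res.label()} has no CB atom (and is not glycine "
                    "with a CA fallback)"
                )
    return coords


# ---------------------------------------------------------------------------
# reading


def _model_to_structure(model) -> Structure:
    residues: list[Residue] = []
    atoms: list[dict[str, np.ndarray]] = []
    seen: set[tuple[str, int]] = set()
    for chain in model:
        for res in chain:
            hetfield, resseq, _icode = res.id
            if hetfield != " ":
                continue  # HETATM / water ignored by default
            key = (chain.id, resseq)
            if key in seen:
                continue  # insertion-code duplicate: first occurrence kept
            seen.add(key)
            d: dict[str, np.ndarray] = {}
            for atom in res.get_unpacked_list():
                name = atom.get_name()
                if name.startswith("H"):
                    continue  # hydrogens ignored; only heavy atoms consumed
                if name not in d:  # first altloc kept
                    d[name] = np.asarray(atom.get_coord(), dtype=float)
            residues.append(Residue(chain.id, resseq, res.get_resname().strip()))
            atoms.append(d)
    return Structure(residues, atoms)


def _parse_models(path: str | Path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such PDB file: {path}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        parser = PDBParser(QUIET=True)
        entity = parser.get_structure(path.stem, str(path))
    models = list(entity.get_models())
    if not models:
        raise ValueError(f"{path}: no models found")
    return models


def read_structure(path: str | Path, model: int = 1) -> Structure:
    """Read one model (1-based index in file order) from a PDB file."""
    models = _parse_models(path)
    if not (1 <= model <= len(models)):
        raise ValueError(
            f"model absent: requested model {model} but file has {len(models)}"
        )
    return _model_to_structure(models[model - 1])


def read_trajectory(
    path: str | Path,
    scheme: str = "CA",
    frame_spacing_ps: float | None = None,
) -> Trajectory:
    """Read a multi-model PDB as a trajectory, one frame per MODEL record.

    All models must share the same residue list ("inconsistent topology"
    otherwise).  Node coordinates are extracted per ``scheme``.
    """
    models = _parse_models(path)
    structures = [_model_to_structure(m) for m in models]
    ref = structures[0].residues
    for k, s in enumerate(structures[1:], start=2):
        if s.residues != ref:
            raise ValueError(
                f"inconsistent topology: model {k} residue list differs from model 1"
            )
    frames = np.stack([node_coordinates(s, scheme) for s in structures])
    return Trajectory(frames, list(ref), scheme=scheme,
                      frame_spacing_ps=frame_spacing_ps)


# ---------------------------------------------------------------------------
# writing


def _atom_line(serial: int, name: str, res: Residue, xyz: np.ndarray) -> str:
    name_field = name if len(name) >= 4 else (" " + name).ljust(4)
    elem = name[0]
    return (
        f"ATOM  {serial:>5d} {name_field} {res.name:>3s} {res.chain:1s}"
        f"{res.number:>4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.0:6.2f}{0.0:6.2f}          {elem:>2s}"
    )


def _atom_order(d: dict[str, np.ndarray]) -> list[str]:
    # backbone first in conventional order, then remaining names sorted
    conventional = ["N", "CA", "C", "O", "CB"]
    head = [n for n in conventional if n in d]
    tail = sorted(n for n in d if n not in conventional)
    return head + tail


def _structure_lines(structure: Structure, serial_start: int = 1) -> list[str]:
    lines = []
    serial = serial_start
    for res, d in zip(structure.residues, structure.atoms):
        for name in _atom_order(d):
            lines.append(_atom_line(serial, name, res, d[name]))
            serial += 1
    return lines


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a single-model PDB (ATOM records only, deterministic layout)."""
    lines = _structure_lines(structure) + ["END", ""]
    Path(path).write_text("\n".join(lines))


def write_trajectory(
    structure: Structure,
    displacements: np.ndarray,
    path: str | Path,
) -> None:
    """Write a multi-model PDB trajectory.

    ``displacements`` is an F x N x 3 array of per-residue offsets applied
    rigidly to every atom of the residue, so CA- and CB-node trajectories
    extracted from the file carry identical per-residue motion.
    """
    displacements = np.asarray(displacements, dtype=float)
    if displacements.ndim != 3 or displacements.shape[1] != structure.n_residues:
        raise ValueError("displacements must be F x N x 3 with N = n_residues")
    lines: list[str] = []
    for f in range(displacements.shape[0]):
        lines.append(f"MODEL     {f + 1:>4d}")
        serial = 1
        for i, (res, d) in enumerate(zip(structure.residues, structure.atoms)):
            for name in _atom_order(d):
                lines.append(_atom_line(serial, name, res, d[name] + displacements[f, i]))
                serial += 1
        lines.append("ENDMDL")
    lines += ["END", ""]
    Path(path).write_text("\n".join(lines))
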