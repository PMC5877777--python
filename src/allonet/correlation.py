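"""Cross-correlation of residue fluctuations (DCCM) and region classification.

The dynamical cross-correlation map is the normalized covariance of the
3-vector deviations of residue nodes from their trajectory-average position:

    C(i, j) = <Δr_i · Δr_j> / (<Δr_i²>^½ <Δr_j²>^½)

C = +1 is fully correlated (same-phase) motion, −1 fully anti-correlated.
Frames must be rigid-body superposed first so that fluctuations are measured
relative to the average structure rather than global motion.

Region classification partitions residues, relative to an anchor residue,
into correlated tiers (red/orange/yellow by decreasing correlation), an
anticorrelated tier (blue) and unclassified (white) — the tier boundaries
are configuration, recorded in output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from allonet.regions import RegionSet, _merge_runs
from allonet.structure_io import Residue, Trajectory

DEFAULT_TIERS = (0.4, 0.55, 0.7)   # yellow / orange / red lower bounds
DEFAULT_ANTI = -0.4                # blue upper bound
DEFAULT_WINDOW_FRACTION = 0.10     # final fraction of frames used


@dataclass
class CorrelationMatrix:
    """Symmetric per-residue-pair motion correlation matrix in [−1, 1]."""

    values: np.ndarray
    residues: list[Residue]
    window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("correlation matrix must be square")
        if n != len(self.residues):
            raise ValueError("matrix size does not match residue list")

    @property
    def n_residues(self) -> int:
        return int(self.values.shape[0])

    def index_of(self, number: int, chain: str | None = None) -> int:
        for i, res in enumerate(self.residues):
            if res.number == number and (chain is None or res.chain == chain):
                return i
        raise KeyError(f"residue {number} (chain {chain}) not found")

    def to_tsv(self, precision: int = 6) -> str:
        header = "\t".join(r.label() for r in self.residues)
        lines = ["\t" + header]
        for res, row in zip(self.residues, self.values):
            lines.append(
                res.label() + "\t"
                + "\t".join(f"{v:.{precision}f}" for v in row)
            )
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# superposition


def _check_not_degenerate(coords: np.ndarray) -> None:
    centered = coords - coords.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError("degenerate frame: all nodes (nearly) collinear")


def _fit_frame(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Kabsch rigid-body superposition of one frame onto a target."""
    mob_mean = mobile.mean(axis=0)
    tgt_mean = target.mean(axis=0)
    rot, _rssd = Rotation.align_vectors(target - tgt_mean, mobile - mob_mean)
    return rot.apply(mobile - mob_mean) + tgt_mean


def superpose_frames(trajectory: Trajectory, reference: str = "mean") -> Trajectory:
    """Rigid-body superpose every frame (rotation + translation, no scaling).

    ``reference="first"`` fits onto frame 0; ``"mean"`` iterates
    align -> recompute-mean twice, an all-node fit to the average structure.
    """
    if reference not in ("first", "mean"):
        raise ValueError(f"reference must be 'first' or 'mean', got {reference!r}")
    if trajectory.n_frames < 2:
        raise ValueError("need at least 2 frames to superpose")
    frames = trajectory.frames
    for f in frames:
        _check_not_degenerate(f)

    aligned = np.stack([_fit_frame(f, frames[0]) for f in frames])
    if reference == "mean":
        for _ in range(2):
            target = aligned.mean(axis=0)
            _check_not_degenerate(target)
            aligned = np.stack([_fit_frame(f, target) for f in aligned])
    return Trajectory(aligned, list(trajectory.residues),
                      scheme=trajectory.scheme,
                      frame_spacing_ps=trajectory.frame_spacing_ps)


# ---------------------------------------------------------------------------
# DCCM


def default_window(n_frames: int,
                   fraction: float = DEFAULT_WINDOW_FRACTION) -> tuple[int, int]:
    """The final ``fraction`` of frames (at least 2), as [start, end)."""
    n_w = max(2, int(round(n_frames * fraction)))
    n_w = min(n_w, n_frames)
    return n_frames - n_w, n_frames


def compute_dccm(
    trajectory: Trajectory,
    window: tuple[int, int] | None = None,
    window_fraction: float = DEFAULT_WINDOW_FRACTION,
) -> CorrelationMatrix:
    """Cross-correlation matrix of node fluctuations over a frame window.

    ``window`` is a half-open 0-based frame interval; when omitted the final
    ``window_fraction`` of frames is used (mirroring equilibrium-tail
    analysis of a production trajectory).  Frames are assumed already
    superposed.  A zero-variance node is an error (the normalization
    denominator vanishes), reported with the residue's identity.
    """
    if window is None:
        window = default_window(trajectory.n_frames, window_fraction)
    start, end = window
    X = trajectory.window(start, end)
    if X.shape[0] < 2:
        raise ValueError(f"window [{start},{end}) holds fewer than 2 frames")

    delta = X - X.mean(axis=0)
    cov = np.einsum("fni,fmi->nm", delta, delta) / X.shape[0]
    var = np.diag(cov).copy()
    bad = np.where(var <= 0.0)[0]
    if bad.size:
        res = trajectory.residues[bad[0]]
        raise ValueError(
            f"zero fluctuation variance for residue {res.label()}: "
            "correlation undefined"
        )
    C = cov / np.sqrt(np.outer(var, var))
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return CorrelationMatrix(C, list(trajectory.residues), window=(start, end))


# ---------------------------------------------------------------------------
# region classification


def classify_regions(
    dccm: CorrelationMatrix,
    anchor: int,
    thresholds: tuple[float, float, float] = DEFAULT_TIERS,
    anti_threshold: float = DEFAULT_ANTI,
    tier_names: tuple[str, str, str] = ("yellow", "orange", "red"),
) -> RegionSet:
    """Partition residues into correlation tiers relative to an anchor.

    ``anchor`` and the resulting intervals are 1-based sequential residue
    positions.  Defaults: red ≥ 0.7, orange ∈ [0.55, 0.7), yellow ∈
    [0.4, 0.55), anticorrelated ("blue") ≤ −0.4; anything else is left
    unclassified ("white").  The anchor itself reports in the top tier.
    Contiguous runs are merged into intervals.
    """
    lo, mid, hi = thresholds
    if not (lo < mid < hi):
        raise ValueError(f"tiers not ordered: {thresholds} must be strictly increasing")
    if anti_threshold >= 0:
        raise ValueError(f"anticorrelation threshold must be negative, got {anti_threshold}")
    if not (1 <= anchor <= dccm.n_residues):
        raise KeyError(f"anchor position {anchor} outside [1,{dccm.n_residues}]")

    row = dccm.values[anchor - 1]
    positions = np.arange(1, dccm.n_residues + 1)
    top = tier_names[2]
    members: dict[str, set[int]] = {t: set() for t in (*tier_names, "blue")}
    for pos, c in zip(positions, row):
        if pos == anchor:
            members[top].add(int(pos))
        elif c >= hi:
            members[top].add(int(pos))
        elif c >= mid:
            members[tier_names[1]].add(int(pos))
        elif c >= lo:
            members[tier_names[0]].add(int(pos))
        elif c <= anti_threshold:
            members["blue"].add(int(pos))

    intervals = []
    for tier in (*tier_names[::-1], "blue"):  # red, orange, yellow, blue
        intervals.extend(_merge_runs(members[tier], tier))
    anchor_res = dccm.residues[anchor - 1]
    return RegionSet(
        intervals,
        note=(
            f"anchor={anchor_res.label()} pos={anchor} "
            f"tiers={thresholds} anti={anti_threshold} method=dccm"
        ),
    )


def combine_regions(region_sets: list[RegionSet]) -> RegionSet:
    """Residue-level union of several region sets; tier labels are dropped.

    This is the overlay of per-anchor correlation maps into one overall
    coupled-region map.
    """
    residues: set[int] = set()
    for rs in region_sets:
        residues |= rs.residues()
    notes = "; ".join(rs.note for rs in region_sets if rs.note)
    return RegionSet.from_residues(residues, note=f"union of {len(region_sets)} sets"
                                   + (f" [{notes}]" if notes else ""))
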