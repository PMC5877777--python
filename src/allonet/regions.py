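"""Residue region sets: tiered intervals over a 1-based residue index.

A :class:`RegionSet` is the common currency between the correlation stage
(correlated/anticorrelated tiers around an anchor residue), the ensemble
allosteric model (susceptible regions above a free-energy cutoff) and the
consensus metrics.  Regions live on a linear, integer residue index; set
operations act at single-residue resolution and re-merge contiguous runs
into intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence


@dataclass(frozen=True)
class Interval:
    """Closed residue interval ``[start, end]`` with an optional tier label."""

    start: int
    end: int
    tier: str | None = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"interval end {self.end} < start {self.start}")

    def residues(self) -> range:
        return range(self.start, self.end + 1)

    def __len__(self) -> int:
        return self.end - self.start + 1


def _merge_runs(residues: Iterable[int], tier: str | None = None) -> list[Interval]:
    """Merge a set of residue indices into maximal contiguous intervals."""
    out: list[Interval] = []
    run_start = run_end = None
    for r in sorted(set(residues)):
        if run_start is None:
            run_start = run_end = r
        elif r == run_end + 1:
            run_end = r
        else:
            out.append(Interval(run_start, run_end, tier))
            run_start = run_end = r
    if run_start is not None:
        out.append(Interval(run_start, run_end, tier))
    return out


@dataclass
class RegionSet:
    """An ordered collection of tiered residue intervals.

    Parameters
    ----------
    intervals:
        Intervals; within one tier they must be non-overlapping.  They are
        stored sorted by (start, end).
    note:
        Free-text provenance (anchor residue, method, cutoff used).
    """

    intervals: list[Interval] = field(default_factory=list)
    note: str = ""

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: (iv.start, iv.end))
        by_tier: dict[str | None, list[Interval]] = {}
        for iv in self.intervals:
            by_tier.setdefault(iv.tier, []).append(iv)
        for tier, ivs in by_tier.items():
            for a, b in zip(ivs, ivs[1:]):
                if b.start <= a.end:
                    raise ValueError(
                        f"overlapping intervals in tier {tier!r}: "
                        f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                    )

    @classmethod
    def from_residues(
        cls,
        residues: Iterable[int],
        tier: str | None = None,
        note: str = "",
    ) -> "RegionSet":
        return cls(_merge_runs(residues, tier), note=note)

    def residues(self) -> frozenset[int]:
        """All residue indices covered, across every tier."""
        out: set[int] = set()
        for iv in self.intervals:
            out.update(iv.residues())
        return frozenset(out)

    def tier_residues(self, tier: str | None) -> frozenset[int]:
        out: set[int] = set()
        for iv in self.intervals:
            if iv.tier == tier:
                out.update(iv.residues())
        return frozenset(out)

    def tiers(self) -> list[str | None]:
        seen: list[str | None] = []
        for iv in self.intervals:
            if iv.tier not in seen:
                seen.append(iv.tier)
        return seen

    def union(self, other: "RegionSet") -> "RegionSet":
        """Residue-level union; tier labels are dropped (union is untyped)."""
        return RegionSet.from_residues(
            self.residues() | other.residues(),
            note=f"union({self.note!r}, {other.note!r})" if (self.note or other.note) else "",
        )

    def intersection(self, other: "RegionSet") -> "RegionSet":
        """Residue-level intersection, re-merged into plain intervals."""
        return RegionSet.from_residues(self.residues() & other.residues())

    def __or__(self, other: "RegionSet") -> "RegionSet":
        return self.union(other)

    def __and__(self, other: "RegionSet") -> "RegionSet":
        return self.intersection(other)

    def __len__(self) -> int:
        return len(self.residues())

    def __bool__(self) -> bool:
        return bool(self.intervals)

    def same_residues(self, other: "RegionSet") -> bool:
        return self.residues() == other.residues()

    # -- tabular I/O (BED-like TSV: chain, start, end, tier) ------------------

    def to_tsv(self, chain: str = "A") -> str:
        lines = ["chain\tstart\tend\ttier"]
        for iv in self.intervals:
            lines.append(f"{chain}\t{iv.start}\t{iv.end}\t{iv.tier if iv.tier else '.'}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str, note: str = "") -> "RegionSet":
        intervals = []
        for i, line in enumerate(text.splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if i == 0 and line.lower().startswith("chain"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed region line: {line!r}")
            tier = parts[3] if len(parts) > 3 and parts[3] != "." else None
            intervals.append(Interval(int(parts[1]), int(parts[2]), tier))
        return cls(intervals, note=note)


def validate_same_index(sets: Sequence[RegionSet], n_residues: int | None = None) -> None:
    """Check that every region fits inside ``[1, n_residues]`` when given."""
    if n_residues is None:
        return
    for rs in sets:
        for iv in rs.intervals:
            if iv.start < 1 or iv.end > n_residues:
                raise ValueError(
                    f"interval [{iv.start},{iv.end}] outside residue index "
                    f"range [1,{n_residues}]"
                )


def warn_empty_reference() -> None:
    warnings.warn("empty reference region set: percent consistency is undefined",
                  stacklevel=3)
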