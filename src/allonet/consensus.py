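"""Agreement metrics between dynamic networks from different methods.

Percent consistency is directional recall: the share of a *reference*
residue set recovered by a *query* set.  Because the directional reading is
not always the intended one when two methods are compared head-to-head, the
symmetric Jaccard overlap is co-reported in every result.  The module also
intersects region sets (the common network of two methods) and renders
aligned per-residue tracks for side-by-side sequence plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from allonet.regions import RegionSet, validate_same_index, warn_empty_reference


@dataclass
class ConsistencyReport:
    """Overlap between a query and a reference residue set.

    ``percent`` is recall of the reference (recovered / reference × 100;
    None when the reference is empty); ``jaccard_percent`` the symmetric
    variant.  ``per_interval`` breaks recovery down by reference interval.
    """

    query_label: str
    reference_label: str
    query_size: int
    reference_size: int
    recovered: int
    percent: float | None
    jaccard_percent: float | None
    per_interval: list[dict]

    def to_dict(self) -> dict:
        return {
            "query": self.query_label,
            "reference": self.reference_label,
            "query_size": self.query_size,
            "reference_size": self.reference_size,
            "recovered": self.recovered,
            "percent_consistency": self.percent,
            "jaccard_percent": self.jaccard_percent,
            "per_interval": self.per_interval,
        }

    def summary(self) -> str:
        pct = "NA" if self.percent is None else f"{self.percent:.1f}%"
        jac = "NA" if self.jaccard_percent is None else f"{self.jaccard_percent:.1f}%"
        return (
            f"{self.query_label} vs {self.reference_label}: recovered "
            f"{self.recovered}/{self.reference_size} reference residues "
            f"({pct} consistency, Jaccard {jac})"
        )


def consistency_percent(
    query: RegionSet,
    reference: RegionSet,
    query_label: str = "query",
    reference_label: str = "reference",
) -> ConsistencyReport:
    """Recall of the reference residue set by the query set, with Jaccard."""
    q = query.residues()
    r = reference.residues()
    recovered = len(q & r)
    if not r:
        warn_empty_reference()
        percent = None
    else:
        percent = 100.0 * recovered / len(r)
    union = len(q | r)
    jaccard = 100.0 * recovered / union if union else None
    per_interval = [
        {
            "start": iv.start,
            "end": iv.end,
            "tier": iv.tier,
            "size": len(iv),
            "recovered": len(set(iv.residues()) & q),
        }
        for iv in reference.intervals
    ]
    return ConsistencyReport(query_label, reference_label, len(q), len(r),
                             recovered, percent, jaccard, per_interval)


def common_regions(a: RegionSet, b: RegionSet) -> RegionSet:
    """Residue-level intersection of two networks, re-merged into intervals."""
    return a.intersection(b)


def render_track(
    sets: dict[str, RegionSet],
    n_residues: int,
) -> pd.DataFrame:
    """Aligned per-residue presence/absence table, one row per method.

    Columns are residue positions 1..n_residues, values 0/1; a residue
    outside that range is an error.  Deterministic: rows follow insertion
    order of ``sets``.
    """
    if len(set(sets)) != len(sets):
        raise ValueError("track labels must be unique")
    validate_same_index(list(sets.values()), n_residues)
    rows = {}
    for label, rs in sets.items():
        covered = rs.residues()
        rows[label] = [1 if p in covered else 0 for p in range(1, n_residues + 1)]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=range(1, n_residues + 1)
    )
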