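"""Kováts retention indexing and the library-match retention filter.

The retention index (RI) places a compound on the n-alkane scale: an alkane
with n carbons is defined to have RI = 100·n, and an analyte eluting between
the alkanes with n and n+1 carbons gets

    RI = 100 · [ n + (Rt_x − Rt_n) / (Rt_{n+1} − Rt_n) ]

with Rt the retention times under a temperature-programmed run.  No
extrapolation is attempted outside the ladder span — the formula is defined
only for Rt_n < Rt_x < Rt_{n+1}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import AlkaneLadder, PeakTable

__all__ = [
    "RIAssignment",
    "compute_retention_index",
    "assign_retention_indices",
    "filter_by_match_score",
    "ri_assignments_frame",
]


@dataclass(frozen=True)
class RIAssignment:
    """Retention index for one compound plus its bracketing alkane pair."""

    compound_id: str
    ri: float
    bracket: tuple[int, int]

    def __post_init__(self) -> None:
        lo, hi = self.bracket
        if not (100 * lo <= self.ri <= 100 * hi):
            raise ValueError(
                f"RI {self.ri} outside bracket [{100 * lo}, {100 * hi}]"
            )


def compute_retention_index(
    rt_min: float, ladder: AlkaneLadder, compound_id: str = ""
) -> RIAssignment:
    """Interpolate a retention time onto the alkane index scale.

    A query equal to a ladder retention time returns exactly 100·n.  Queries
    outside ``[first ladder RT, last ladder RT]`` raise ``ValueError`` — the
    index is undefined there and extrapolating would silently fabricate one.

    For ladders with gaps in the carbon series the interpolation runs linearly
    on the carbon scale between the bracketing entries, which reduces to the
    classical formula when the carbons are consecutive.
    """
    lo_rt, hi_rt = ladder.span
    if not (lo_rt <= rt_min <= hi_rt):
        raise ValueError(
            f"rt {rt_min} min outside alkane ladder span [{lo_rt}, {hi_rt}] min"
        )
    carbons, rts = ladder.carbons, ladder.rts
    # exact hit on a ladder rung → the alkane's own index, no rounding noise
    hit = np.nonzero(rts == rt_min)[0]
    if hit.size:
        k = int(hit[0])
        n = int(carbons[k])
        left = int(carbons[k - 1]) if k > 0 else n
        right = int(carbons[k + 1]) if k + 1 < len(carbons) else n
        return RIAssignment(compound_id, float(100 * n), (min(left, n), max(right, n)))
    k = int(np.searchsorted(rts, rt_min) - 1)
    n, n_next = int(carbons[k]), int(carbons[k + 1])
    frac = (rt_min - rts[k]) / (rts[k + 1] - rts[k])
    ri = 100.0 * (n + (n_next - n) * frac)
    return RIAssignment(compound_id, float(ri), (n, n_next))


def assign_retention_indices(
    table: PeakTable, ladder: AlkaneLadder
) -> list[RIAssignment]:
    """Compute an RI for every compound with a retention time inside the
    ladder span; compounds without an RT are skipped."""
    out = []
    for c in table.compounds:
        if c.rt_min is None:
            continue
        out.append(compute_retention_index(c.rt_min, ladder, compound_id=c.id))
    return out


def filter_by_match_score(
    table: PeakTable, min_score: float = 80.0, *, strict: bool = False
) -> PeakTable:
    """Retain compounds whose library match score strictly exceeds ``min_score``.

    Compounds identified against a spectral library carry a 0–100 match
    score; only confident identifications (score > 80 by default) are kept.
    A missing score is retained with a warning — curated tables built from
    published compound lists carry no scores — unless ``strict=True``, in
    which case it is an error.
    """
    keep = []
    missing = []
    for i, c in enumerate(table.compounds):
        if c.match_score is None:
            missing.append(c.id)
            keep.append(i)
        elif c.match_score > min_score:
            keep.append(i)
    if missing:
        if strict:
            raise ValueError(
                f"match_score missing for {len(missing)} compound(s): {missing}"
            )
        warnings.warn(
            f"match_score missing for {len(missing)} compound(s); retained",
            stacklevel=2,
        )
    return table.subset(keep)


def ri_assignments_frame(table: PeakTable, assignments: list[RIAssignment]) -> pd.DataFrame:
    """Tabulate RI assignments for export (id, name, rt_min, ri, brackets)."""
    names = {c.id: (c.name, c.rt_min) for c in table.compounds}
    rows = []
    for a in assignments:
        name, rt = names.get(a.compound_id, ("", None))
        rows.append(
            {"id": a.compound_id, "name": name, "rt_min": rt, "ri": a.ri,
             "bracket_low": a.bracket[0], "bracket_high": a.bracket[1]}
        )
    return pd.DataFrame(rows)
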