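"""Key-compound screening and relative odor-activity (rOAV) aroma profiling.

The differential screen keeps compounds with VIP > 1 and t-test p < 0.05
(both strict).  Aroma activity is then scored per group by the relative odor
activity value

    rOAV_i = 100 · (C_i / C_ref) · (T_ref / T_i)

where C is relative content, T the odor threshold (mg/kg), and the reference
compound is the one with the highest content-to-threshold ratio — i.e. the
highest plain odor activity — so the reference scores exactly 100 and every
other compound is scaled relative to it.  Compounds with rOAV ≥ 1 are
*critical* aroma contributors, 0.1 < rOAV < 1 *modifying*, and ≤ 0.1
*negligible*.  Aroma-type profiles sum the rOAV of critical + modifying
compounds over their aroma descriptors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .model import ThresholdTable, ValidationError

__all__ = [
    "ScreenResult",
    "screen_key_compounds",
    "select_reference",
    "RoavTable",
    "compute_roav",
    "classify_roav",
    "AromaProfile",
    "aroma_profile",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# VIP / p screening
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    """Outcome of the double VIP/p screen for one compound set."""

    ids: list[str]
    vip: dict[str, float]
    p: dict[str, float]
    passed: dict[str, bool]

    @property
    def retained(self) -> list[str]:
        """Passing compounds, ordered by descending VIP."""
        keep = [i for i in self.ids if self.passed[i]]
        return sorted(keep, key=lambda i: (-self.vip[i], self.ids.index(i)))

    @property
    def n_passed(self) -> int:
        return sum(self.passed.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "vip": [self.vip[i] for i in self.ids],
                "p": [self.p[i] for i in self.ids],
                "passed": [self.passed[i] for i in self.ids],
            }
        )


def screen_key_compounds(
    vips: Mapping[str, float],
    pvals: Mapping[str, float],
    vip_min: float = 1.0,
    p_max: float = 0.05,
) -> ScreenResult:
    """Apply the strict double criterion VIP > vip_min AND p < p_max.

    Both inequalities are strict: VIP exactly 1 or p exactly 0.05 fail.
    The two mappings must cover the same compound set.
    """
    if set(vips) != set(pvals):
        only_v = sorted(set(vips) - set(pvals))
        only_p = sorted(set(pvals) - set(vips))
        raise KeyError(
            f"compound sets differ: only-in-vip={only_v}, only-in-p={only_p}"
        )
    ids = list(vips)
    passed = {i: (vips[i] > vip_min and pvals[i] < p_max) for i in ids}
    return ScreenResult(ids=ids, vip=dict(vips), p=dict(pvals), passed=passed)


# ---------------------------------------------------------------------------
# rOAV
# ---------------------------------------------------------------------------

def select_reference(
    contents: Mapping[str, float], thresholds: ThresholdTable
) -> str:
    """Pick the reference compound: highest content/threshold ratio.

    Only compounds with positive content and a known threshold compete; ties
    break by input order.  The reference is the group's most odor-active
    compound and anchors the rOAV scale at 100.
    """
    best_name, best_ratio = None, -1.0
    for name, c in contents.items():
        t = thresholds.threshold(name)
        if t is None or c <= 0:
            continue
        ratio = c / t
        if ratio > best_ratio:
            best_name, best_ratio = name, ratio
    if best_name is None:
        raise ValidationError(
            "no compound with positive content and known odor threshold"
        )
    return best_name


def classify_roav(roav: float) -> str:
    """Aroma-activity category: critical (≥1), modifying (0.1–1), negligible."""
    if roav < 0:
        raise ValidationError(f"rOAV must be non-negative, got {roav}")
    if roav >= 1.0:
        return "critical"
    if roav > 0.1:
        return "modifying"
    return "negligible"


@dataclass
class RoavTable:
    """Per-group rOAV scores with activity categories.

    ``excluded`` lists compounds that had content but no known odor threshold
    and therefore could not be scored (reported, never silently dropped).
    """

    group: str
    reference: str
    rows: pd.DataFrame  # columns: name, content_pct, threshold, roav, category
    excluded: list[str]

    def roav_of(self, name: str) -> float:
        hit = self.rows.loc[self.rows["name"] == name, "roav"]
        if hit.empty:
            raise KeyError(f"{name!r} not scored in group {self.group!r}")
        return float(hit.iloc[0])

    def category_of(self, name: str) -> str:
        hit = self.rows.loc[self.rows["name"] == name, "category"]
        if hit.empty:
            raise KeyError(f"{name!r} not scored in group {self.group!r}")
        return str(hit.iloc[0])


def compute_roav(
    contents: Mapping[str, float],
    thresholds: ThresholdTable,
    reference: str | None = None,
    group: str = "",
) -> RoavTable:
    """Score every thresholded compound's rOAV against the reference.

    ``contents`` maps compound name → group-mean relative content (%).  When
    ``reference`` is None it is selected automatically (highest
    content/threshold).  The reference's rOAV is exactly 100 by construction,
    and no compound can exceed 100 under automatic selection.
    """
    if reference is None:
        reference = select_reference(contents, thresholds)
    t_ref = thresholds.threshold(reference)
    if t_ref is None:
        raise ValidationError(f"reference {reference!r} has no odor threshold")
    if t_ref <= 0:
        raise ValidationError(f"reference threshold must be > 0, got {t_ref}")
    c_ref = contents.get(reference, 0.0)
    if c_ref <= 0:
        raise ValidationError(f"reference {reference!r} has no positive content")

    rows, excluded = [], []
    for name, c in contents.items():
        t_i = thresholds.threshold(name)
        if t_i is None:
            if c > 0:
                excluded.append(name)
            continue
        if t_i <= 0:
            raise ValidationError(f"non-positive threshold for {name!r}")
        if name == reference:
            roav = 100.0  # self-normalization, exact by definition
        else:
            roav = 100.0 * (c / c_ref) * (t_ref / t_i)
        rows.append(
            {"name": name, "content_pct": float(c), "threshold": float(t_i),
             "roav": float(roav), "category": classify_roav(roav)}
        )
    if excluded:
        logger.info(
            "group %s: %d compound(s) without odor threshold excluded from "
            "rOAV: %s", group or "?", len(excluded), excluded,
        )
    return RoavTable(group=group, reference=reference,
                     rows=pd.DataFrame(rows), excluded=excluded)


# ---------------------------------------------------------------------------
# Aroma-type profile
# ---------------------------------------------------------------------------

@dataclass
class AromaProfile:
    """Summed rOAV per aroma descriptor term for one group."""

    group: str
    scores: dict[str, float]

    @property
    def ranked(self) -> list[tuple[str, float]]:
        """Terms ranked by descending total score (ties alphabetical)."""
        return sorted(self.scores.items(), key=lambda kv: (-kv[1], kv[0]))

    def to_frame(self) -> pd.DataFrame:
        ranked = self.ranked
        return pd.DataFrame(
            {
                "group": self.group,
                "aroma_term": [t for t, _ in ranked],
                "score": [s for _, s in ranked],
                "rank": range(1, len(ranked) + 1),
            }
        )


def aroma_profile(
    roav_table: RoavTable, thresholds: ThresholdTable
) -> AromaProfile:
    """Aggregate rOAV by aroma type over critical + modifying compounds.

    Each scoring compound contributes its full rOAV to every descriptor term
    it carries; negligible compounds (rOAV ≤ 0.1) are left out.  Terms absent
    from all descriptor lists never appear in the profile.
    """
    scores: dict[str, float] = {}
    for _, row in roav_table.rows.iterrows():
        if row["category"] == "negligible":
            continue
        for term in thresholds.descriptor_list(row["name"]):
            scores[term] = scores.get(term, 0.0) + float(row["roav"])
    return AromaProfile(group=roav_table.group, scores=scores)
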