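"""Relative quantification: area percentages, detection counts, class totals.

GC-MS peak areas are instrument-unit quantities; the standard semi-quantitative
summary is the *relative content*: each compound's share of the sample's total
peak area, in percent.  Group summaries are the mean and sample SD of the
per-sample percentages, matching the usual "mean ± SD" presentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import PeakTable, ValidationError

__all__ = [
    "RelativeContentTable",
    "relative_content",
    "count_detected",
    "class_totals",
    "relative_content_frame",
]


@dataclass
class RelativeContentTable:
    """Per-sample relative contents (%) with per-group mean/SD summaries."""

    table: PeakTable
    percent: np.ndarray  # (n_compounds, n_samples)
    group_mean: dict[str, np.ndarray]
    group_sd: dict[str, np.ndarray]

    @property
    def compounds(self):
        return self.table.compounds

    def mean_contents(self, group: str) -> dict[str, float]:
        """Map compound *name* → group-mean relative content (%)."""
        means = self.group_mean[group]
        return {c.name: float(means[i]) for i, c in enumerate(self.compounds)}


def relative_content(table: PeakTable, *, renormalize: bool = True) -> RelativeContentTable:
    """Convert raw areas to per-sample percentages of total peak area.

    percent_ij = 100 · area_ij / Σ_i area_ij, so each sample column sums to
    100.  With ``renormalize=False`` the areas are taken to already be on a
    percentage scale and passed through unchanged — the mode used for curated
    tables that publish relative contents instead of raw areas, where
    re-normalizing would perturb the published values by their rounding
    residue.

    Group mean/SD use the per-sample percentages with sample (n−1) SD; a
    single-sample group gets SD 0.
    """
    totals = table.areas.sum(axis=0)
    zero = np.nonzero(totals <= 0)[0]
    if zero.size:
        bad = [table.samples[j] for j in zero]
        raise ValidationError(f"sample(s) with zero total area: {bad}")
    if renormalize:
        percent = 100.0 * table.areas / totals[None, :]
    else:
        percent = table.areas.astype(float).copy()

    group_mean: dict[str, np.ndarray] = {}
    group_sd: dict[str, np.ndarray] = {}
    for g in table.group_labels:
        idx = table.group_sample_indices(g)
        sub = percent[:, idx]
        group_mean[g] = sub.mean(axis=1)
        group_sd[g] = sub.std(axis=1, ddof=1) if idx.size > 1 else np.zeros(sub.shape[0])
    return RelativeContentTable(table=table, percent=percent,
                                group_mean=group_mean, group_sd=group_sd)


def count_detected(table: PeakTable, group: str) -> int:
    """Number of compounds detected in at least one sample of ``group``."""
    idx = table.group_sample_indices(group)  # raises KeyError if unknown
    return int(np.any(table.detected[:, idx], axis=1).sum())


def class_totals(rc: RelativeContentTable, group: str) -> dict[str, float]:
    """Sum of group-mean relative contents per compound class."""
    if group not in rc.group_mean:
        raise KeyError(f"unknown group {group!r}")
    means = rc.group_mean[group]
    totals: dict[str, float] = {}
    for i, c in enumerate(rc.compounds):
        totals[c.compound_class] = totals.get(c.compound_class, 0.0) + float(means[i])
    return totals


def relative_content_frame(rc: RelativeContentTable) -> pd.DataFrame:
    """Export table: per-sample percents plus mean/SD columns per group."""
    t = rc.table
    df = pd.DataFrame(
        {
            "id": [c.id for c in t.compounds],
            "name": [c.name for c in t.compounds],
            "class": [c.compound_class for c in t.compounds],
        }
    )
    for j, s in enumerate(t.samples):
        df[s] = rc.percent[:, j]
    for g in t.group_labels:
        df[f"mean_{g}"] = rc.group_mean[g]
        df[f"sd_{g}"] = rc.group_sd[g]
    return df
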