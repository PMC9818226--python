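"""CSV readers and writers for the pipeline's input and result tables.

Canonical dialect: UTF-8, comma separator, "." decimal, first row header.
The canonical peak-table input is wide (one numeric column per sample) with a
companion samples file mapping sample id → group; a long-format reader is
provided as a convenience.  Empty area cells mean "not detected" and become
area 0 with ``detected=False``.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .model import (
    AlkaneLadder,
    Compound,
    FormatError,
    ParseError,
    PeakTable,
    ThresholdTable,
    ValidationError,
)

__all__ = [
    "read_peak_table",
    "read_peak_table_long",
    "write_peak_table",
    "read_alkane_ladder",
    "write_alkane_ladder",
    "read_threshold_table",
    "write_threshold_table",
]

_META_COLUMNS = ["id", "name", "cas", "formula", "class", "rt_min", "match_score"]


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def read_peak_table(peaks_path: str, samples_path: str) -> PeakTable:
    """Read the wide-format peak table plus its samples/groups companion.

    Parameters
    ----------
    peaks_path : CSV with columns ``id, name, cas, formula, class, rt_min,
        match_score`` followed by one numeric column per sample.
    samples_path : CSV with columns ``sample_id, group``.
    """
    peaks = pd.read_csv(peaks_path, dtype={"id": str, "name": str},
                        float_precision="round_trip")
    _require_columns(peaks, ["id", "name", "class", "rt_min"], peaks_path)
    samples_df = pd.read_csv(samples_path, dtype=str)
    _require_columns(samples_df, ["sample_id", "group"], samples_path)

    sample_ids = [str(s) for s in samples_df["sample_id"]]
    groups = dict(zip(sample_ids, (str(g) for g in samples_df["group"])))
    missing_cols = [s for s in sample_ids if s not in peaks.columns]
    if missing_cols:
        raise FormatError(f"{peaks_path}: no area column for sample(s) {missing_cols}")

    compounds = []
    for _, row in peaks.iterrows():
        compounds.append(
            Compound(
                id=str(row["id"]),
                name=str(row["name"]),
                cas="" if pd.isna(row.get("cas", "")) else str(row.get("cas", "")),
                formula="" if pd.isna(row.get("formula", "")) else str(row.get("formula", "")),
                compound_class=str(row["class"]),
                rt_min=_opt_float(row["rt_min"]),
                match_score=_opt_float(row["match_score"]) if "match_score" in peaks.columns else None,
            )
        )

    n_c, n_s = len(compounds), len(sample_ids)
    areas = np.zeros((n_c, n_s))
    detected = np.zeros((n_c, n_s), dtype=bool)
    for j, s in enumerate(sample_ids):
        col = peaks[s]
        for i, raw in enumerate(col):
            if pd.isna(raw) or (isinstance(raw, str) and not raw.strip()):
                continue
            try:
                val = float(raw)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{peaks_path}: non-numeric area {raw!r} at row "
                    f"{i + 2} (compound {compounds[i].id}), column {s!r}"
                ) from None
            areas[i, j] = val
            detected[i, j] = True
    return PeakTable(compounds=compounds, samples=sample_ids, groups=groups,
                     areas=areas, detected=detected)


def read_peak_table_long(path: str) -> PeakTable:
    """Convenience reader for long format: one row per (compound, sample).

    Required columns: ``id, name, class, rt_min, sample_id, group, area``;
    optional: ``cas, formula, match_score``.  An empty ``area`` cell marks a
    missing peak.
    """
    df = pd.read_csv(path, dtype={"id": str, "sample_id": str, "group": str},
                     float_precision="round_trip")
    _require_columns(df, ["id", "name", "class", "rt_min", "sample_id", "group", "area"], path)

    comp_rows: dict[str, pd.Series] = {}
    comp_order: list[str] = []
    sample_order: list[str] = []
    groups: dict[str, str] = {}
    for _, row in df.iterrows():
        cid, sid = str(row["id"]), str(row["sample_id"])
        if cid not in comp_rows:
            comp_rows[cid] = row
            comp_order.append(cid)
        if sid not in groups:
            sample_order.append(sid)
            groups[sid] = str(row["group"])

    compounds = [
        Compound(
            id=cid,
            name=str(r["name"]),
            cas="" if pd.isna(r.get("cas", "")) else str(r.get("cas", "")),
            formula="" if pd.isna(r.get("formula", "")) else str(r.get("formula", "")),
            compound_class=str(r["class"]),
            rt_min=_opt_float(r["rt_min"]),
            match_score=_opt_float(r["match_score"]) if "match_score" in df.columns else None,
        )
        for cid, r in ((c, comp_rows[c]) for c in comp_order)
    ]
    c_index = {c: i for i, c in enumerate(comp_order)}
    s_index = {s: j for j, s in enumerate(sample_order)}
    areas = np.zeros((len(comp_order), len(sample_order)))
    detected = np.zeros_like(areas, dtype=bool)
    for k, row in df.iterrows():
        raw = row["area"]
        if pd.isna(raw) or (isinstance(raw, str) and not str(raw).strip()):
            continue
        try:
            val = float(raw)
        except (TypeError, ValueError):
            raise ParseError(
                f"{path}: non-numeric area {raw!r} at row {k + 2}, column 'area'"
            ) from None
        i, j = c_index[str(row["id"])], s_index[str(row["sample_id"])]
        areas[i, j] = val
        detected[i, j] = True
    return PeakTable(compounds=compounds, samples=sample_order, groups=groups,
                     areas=areas, detected=detected)


def write_peak_table(table: PeakTable, peaks_path: str, samples_path: str) -> None:
    """Write a PeakTable in the canonical wide format (round-trip safe).

    Areas are serialized with ``repr``-level precision so a write → read
    cycle reproduces the matrix bit-identically; undetected cells are empty.
    """
    rows = []
    for i, c in enumerate(table.compounds):
        row: dict[str, object] = {
            "id": c.id, "name": c.name, "cas": c.cas, "formula": c.formula,
            "class": c.compound_class,
            "rt_min": "" if c.rt_min is None else repr(c.rt_min),
            "match_score": "" if c.match_score is None else repr(c.match_score),
        }
        for j, s in enumerate(table.samples):
            row[s] = repr(float(table.areas[i, j])) if table.detected[i, j] else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(peaks_path, index=False)
    pd.DataFrame(
        {"sample_id": table.samples, "group": [table.groups[s] for s in table.samples]}
    ).to_csv(samples_path, index=False)


def read_alkane_ladder(path: str) -> AlkaneLadder:
    """Read the n-alkane ladder CSV (columns ``carbon_number, rt_min``)."""
    df = pd.read_csv(path)
    _require_columns(df, ["carbon_number", "rt_min"], path)
    entries = sorted(
        (int(n), float(rt)) for n, rt in zip(df["carbon_number"], df["rt_min"])
    )
    return AlkaneLadder(entries=tuple(entries))


def write_alkane_ladder(ladder: AlkaneLadder, path: str) -> None:
    pd.DataFrame(ladder.entries, columns=["carbon_number", "rt_min"]).to_csv(
        path, index=False
    )


def read_threshold_table(path: str) -> ThresholdTable:
    """Read odor thresholds (columns ``name, threshold_mg_per_kg,
    descriptors``); descriptors are semicolon-separated aroma terms."""
    df = pd.read_csv(path, dtype={"name": str, "descriptors": str})
    _require_columns(df, ["name", "threshold_mg_per_kg"], path)
    thresholds: dict[str, float] = {}
    descriptors: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        name = str(row["name"])
        t = _opt_float(row["threshold_mg_per_kg"])
        if t is not None and t <= 0:
            raise ValidationError(
                f"{path}: non-positive threshold {t} for {name!r}"
            )
        thresholds[name] = t
        desc = row.get("descriptors", "")
        if pd.isna(desc):
            desc = ""
        descriptors[name] = [d.strip() for d in str(desc).split(";") if d.strip()]
    return ThresholdTable(thresholds=thresholds, descriptors=descriptors)


def write_threshold_table(tt: ThresholdTable, path: str) -> None:
    rows = [
        {
            "name": name,
            "threshold_mg_per_kg": "" if t is None else t,
            "descriptors": ";".join(tt.descriptor_list(name)),
        }
        for name, t in tt.thresholds.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
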