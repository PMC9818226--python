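"""End-to-end orchestration of the differential volatile-aroma analysis.

Stage order: read → retention indexing → match filter → relative content →
Z-score → cluster order → PCA → OPLS-DA (+ permutation validation) →
t-tests → VIP/p screen → rOAV per group → aroma profiles.  Every stage
writes a CSV (with the run-config hash in a header comment) and the run ends
with a machine-readable ``summary.json``.  Identical inputs + seed give
byte-identical outputs.

When the contrasted groups have fewer than two replicates each — as with
curated tables that publish only group means — the multivariate refit is
impossible and the pipeline instead requires externally supplied VIP and p
columns for the screening stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import sys
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as fio
from .aroma import aroma_profile, compute_roav, screen_key_compounds
from .chemometrics import (
    differential_ttests,
    fit_oplsda,
    fit_pca,
    hcluster_order,
    permutation_test,
    zscore,
)
from .model import ValidationError
from .quantify import class_totals, count_detected, relative_content, relative_content_frame
from .retention import assign_retention_indices, filter_by_match_score, ri_assignments_frame

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; message carries the stage name and offending record."""


@dataclass
class RunConfig:
    """Inputs, contrasts, and tunables for one pipeline run."""

    peaks_path: str
    samples_path: str
    outdir: str
    ladder_path: str | None = None
    thresholds_path: str | None = None
    vip_path: str | None = None  # external VIP/p columns (id or name, vip, p)
    min_match_score: float = 80.0
    renormalize: bool = True
    cv_folds: int | str = "auto"
    k_ortho: int | str = "auto"
    n_perm: int = 200
    seed: int = 0
    ttest_variant: str = "pooled"
    scale: bool = True
    vip_min: float = 1.0
    p_max: float = 0.05
    critical_min: float = 1.0
    modifying_min: float = 0.1

    def validate(self) -> None:
        if not (self.vip_min > 0 and 0 < self.p_max < 1):
            raise ValidationError("vip_min must be > 0 and p_max in (0, 1)")
        if not 0 < self.modifying_min < self.critical_min:
            raise ValidationError("need 0 < modifying_min < critical_min")

    def hash(self) -> str:
        """Stable digest of the analysis configuration (outdir excluded)."""
        fields = dataclasses.asdict(self)
        fields.pop("outdir")
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: str, cfg_hash: str) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# config {cfg_hash}\n")
        df.to_csv(fh, index=False)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # annotate with the failing stage
                raise PipelineError(f"stage {name!r}: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run summary (also written as JSON)."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    h = config.hash()
    out = lambda name: os.path.join(config.outdir, name)  # noqa: E731
    summary: dict = {"config_hash": h, "seed": config.seed}

    def log(stage: str, **counts) -> None:
        logger.info("stage=%s %s", stage,
                     " ".join(f"{k}={v}" for k, v in counts.items()))

    table = _stage("read")(fio.read_peak_table)(config.peaks_path, config.samples_path)
    g1, g2 = table.require_two_groups()
    log("read", compounds=table.n_compounds, samples=table.n_samples)

    if config.ladder_path:
        ladder = _stage("ladder")(fio.read_alkane_ladder)(config.ladder_path)
        assignments = _stage("retention_index")(assign_retention_indices)(table, ladder)
        _write_csv(ri_assignments_frame(table, assignments), out("retention_index.csv"), h)
        log("retention_index", assigned=len(assignments))

    table = _stage("match_filter")(filter_by_match_score)(table, config.min_match_score)
    log("match_filter", retained=table.n_compounds)

    rc = _stage("relative_content")(relative_content)(table, renormalize=config.renormalize)
    _write_csv(relative_content_frame(rc), out("relative_content.csv"), h)
    totals = {g: class_totals(rc, g) for g in (g1, g2)}
    counts = {g: count_detected(table, g) for g in (g1, g2)}
    summary["detected"] = counts
    summary["class_totals"] = totals
    log("relative_content", **counts)

    replicated = all(
        table.group_sample_indices(g).size >= 2 for g in (g1, g2)
    )
    vips: dict[str, float] = {}
    pvals: dict[str, float] = {}
    if replicated:
        z = _stage("zscore")(zscore)(table)
        row_order = hcluster_order(z, "rows")
        col_order = hcluster_order(z, "columns")
        _write_csv(
            pd.DataFrame({"row_order": row_order}), out("cluster_rows.csv"), h
        )
        _write_csv(
            pd.DataFrame({"col_order": col_order}), out("cluster_cols.csv"), h
        )
        k = min(table.n_samples - 1, table.n_compounds, 2)
        pca = _stage("pca")(fit_pca)(z, k)
        _write_csv(
            pd.DataFrame(pca.scores, index=table.samples).reset_index(names="sample"),
            out("pca_scores.csv"), h,
        )
        summary["pca_explained_percent"] = [float(v) for v in pca.explained_percent]

        X = z.values.T
        y = [table.groups[s] for s in table.samples]
        model = _stage("oplsda")(fit_oplsda)(
            X, y, k_ortho=config.k_ortho, cv_folds=config.cv_folds,
            seed=config.seed, scale=False,  # rows already z-scored
        )
        summary["oplsda"] = {
            "r2x": model.r2x, "r2y": model.r2y, "q2": model.q2,
            "k_ortho": model.k_ortho, "cv_folds": model.cv_folds,
        }
        _write_csv(
            pd.DataFrame({"id": z.compound_ids,
                          "name": [c.name for c in table.compounds],
                          "vip": model.vip}),
            out("vip.csv"), h,
        )
        perm = _stage("permutation")(permutation_test)(
            X, y, n_perm=config.n_perm, seed=config.seed,
            k_ortho=model.k_ortho, cv_folds=config.cv_folds, scale=False,
        )
        _write_csv(
            pd.DataFrame(perm.triples, columns=["label_corr", "r2y", "q2"]),
            out("permutation.csv"), h,
        )
        summary["permutation"] = {
            "n_perm": perm.n_perm,
            "r2y_intercept": perm.r2y_intercept,
            "q2_intercept": perm.q2_intercept,
        }
        tt = _stage("ttest")(differential_ttests)(table, config.ttest_variant)
        _write_csv(tt, out("ttests.csv"), h)
        vips = dict(zip(z.compound_ids, (float(v) for v in model.vip)))
        pvals = dict(zip(tt["id"], (float(v) for v in tt["p"])))
    else:
        if not config.vip_path:
            raise PipelineError(
                "stage 'chemometrics': groups have < 2 replicates; a "
                "multivariate refit is impossible — supply precomputed "
                "VIP/p columns via vip_path"
            )
        ext = pd.read_csv(config.vip_path, dtype={"id": str, "name": str})
        for col in ("vip", "p"):
            if col not in ext.columns:
                raise PipelineError(f"stage 'screen': vip table lacks column {col!r}")
        key = "id" if "id" in ext.columns else "name"
        vips = dict(zip(ext[key], (float(v) for v in ext["vip"])))
        pvals = dict(zip(ext[key], (float(v) for v in ext["p"])))
        log("chemometrics", skipped=1, external_vip=len(vips))

    screen = _stage("screen")(screen_key_compounds)(
        vips, pvals, vip_min=config.vip_min, p_max=config.p_max
    )
    _write_csv(screen.to_frame(), out("screen.csv"), h)
    summary["n_key_compounds"] = screen.n_passed
    summary["key_compounds"] = screen.retained
    log("screen", passed=screen.n_passed)

    if config.thresholds_path:
        thresholds = _stage("thresholds")(fio.read_threshold_table)(config.thresholds_path)
        roav_frames, profile_frames = [], []
        summary["roav"] = {}
        for g in (g1, g2):
            contents = rc.mean_contents(g)
            rt = _stage("roav")(compute_roav)(contents, thresholds, group=g)
            df = rt.rows.copy()
            df.insert(0, "group", g)
            roav_frames.append(df)
            prof = aroma_profile(rt, thresholds)
            profile_frames.append(prof.to_frame())
            summary["roav"][g] = {
                "reference": rt.reference,
                "n_scored": int(len(rt.rows)),
                "excluded": rt.excluded,
                "top_terms": prof.ranked[:3],
            }
            log("roav", group=g, scored=len(rt.rows))
        _write_csv(pd.concat(roav_frames, ignore_index=True), out("roav.csv"), h)
        _write_csv(pd.concat(profile_frames, ignore_index=True), out("aroma_profile.csv"), h)

    with open(out("summary.json"), "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
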