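"""Synthetic peak-table generator with the structure the analysis assumes.

Emulates a two-group GC-MS volatilomics study: log-normally distributed peak
areas per compound (positive, right-skewed, tight CVs), a subset of
compounds carrying a group-specific fold change, and a subset subject to
group-specific detection dropout (compounds present in only one maturity
stage).  Defaults mirror the study design this pipeline targets: 42
compounds, 2 groups × 3 biological replicates, 6 dropout compounds absent
from group 1, 23 differential compounds at fold change 4, log-scale σ 0.3.

Every draw flows from a single seed, so identical configs give bit-identical
outputs, and the generator returns a truth record naming the injected
differential and dropout compounds for parameter-recovery testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .model import (
    AlkaneLadder,
    Compound,
    PeakTable,
    ThresholdTable,
    ValidationError,
)

__all__ = ["SimConfig", "generate", "write_simulation"]

_DESCRIPTOR_VOCAB = (
    "green", "floral", "fruity", "woody", "sweet", "citrus", "rosy",
    "herbal", "honey", "cedar", "grass", "banana", "pineapple", "orange",
)

_CLASS_CYCLE = (
    "ester", "terpene", "ketone", "aldehyde", "alkane", "alcohol", "alkene",
    "furan",
)


@dataclass
class SimConfig:
    """Generator configuration; defaults encode the target study design."""

    n_compounds: int = 42
    n_replicates: int = 3
    groups: tuple[str, str] = ("DY", "DM")
    #: natural-log-scale location range for base abundances (per compound,
    #: drawn uniformly) and the shared log-scale SD
    log_mu_range: tuple[float, float] = (2.0, 8.0)
    log_sigma: float = 0.3
    #: differential structure: d compounds get the fold change in group 2
    n_differential: int = 23
    log2_fold_change: float = 2.0
    #: dropout structure: compounds zeroed (with this probability per sample)
    #: in the named group, emulating stage-specific volatiles
    n_dropout: int = 6
    dropout_group: str = "DY"
    dropout_probability: float = 1.0
    #: alkane ladder: carbon range and linear RT spacing (min per carbon)
    ladder_carbons: tuple[int, int] = (7, 27)
    ladder_rt_start: float = 3.4
    ladder_rt_per_carbon: float = 2.725
    #: odor thresholds drawn log-uniform over this range (mg/kg); descriptor
    #: terms drawn without replacement from the vocabulary
    threshold_range: tuple[float, float] = (1e-4, 10.0)
    threshold_fraction: float = 1.0
    descriptors_per_compound: tuple[int, int] = (1, 4)
    seed: int = 0

    def validate(self) -> None:
        if self.n_compounds < 1 or self.n_replicates < 1:
            raise ValidationError("n_compounds and n_replicates must be ≥ 1")
        if len(set(self.groups)) != 2:
            raise ValidationError("exactly 2 distinct group labels required")
        if not 0 <= self.n_differential <= self.n_compounds:
            raise ValidationError("n_differential must be in [0, n_compounds]")
        if self.n_dropout < 0 or self.n_differential + self.n_dropout > self.n_compounds:
            raise ValidationError(
                "n_differential + n_dropout must not exceed n_compounds"
            )
        if self.log_sigma <= 0 or self.log2_fold_change < 0:
            raise ValidationError("scale parameters must be positive")
        if not 0 <= self.dropout_probability <= 1:
            raise ValidationError("dropout_probability must be in [0, 1]")
        if self.dropout_group not in self.groups:
            raise ValidationError("dropout_group must be one of the groups")
        if self.threshold_range[0] <= 0 or self.threshold_range[1] <= self.threshold_range[0]:
            raise ValidationError("threshold_range must be positive and increasing")
        if not 0 <= self.threshold_fraction <= 1:
            raise ValidationError("threshold_fraction must be in [0, 1]")
        lo, hi = self.ladder_carbons
        if lo < 5 or hi <= lo:
            raise ValidationError("ladder carbon range invalid")


def generate(
    config: SimConfig | None = None, **overrides
) -> tuple[PeakTable, AlkaneLadder, ThresholdTable, dict]:
    """Draw a synthetic (peak table, ladder, thresholds, truth record).

    The truth record lists the injected differential and dropout compound ids
    plus the seed and fold change, for downstream recovery checks.
    """
    if config is None:
        config = SimConfig(**overrides)
    elif overrides:
        config = SimConfig(**{**asdict(config), **overrides})
    config.validate()
    rng = np.random.default_rng(config.seed)

    n, reps = config.n_compounds, config.n_replicates
    g1, g2 = config.groups
    samples = [f"{g}_{r + 1}" for g in (g1, g2) for r in range(reps)]
    groups = {s: s.rsplit("_", 1)[0] for s in samples}
    group_of_col = np.array([groups[s] for s in samples])

    # differential and dropout subsets are disjoint by construction
    perm = rng.permutation(n)
    diff_idx = np.sort(perm[: config.n_differential])
    drop_idx = np.sort(perm[config.n_differential: config.n_differential + config.n_dropout])

    log_mu = rng.uniform(*config.log_mu_range, size=n)
    log_areas = log_mu[:, None] + config.log_sigma * rng.standard_normal((n, len(samples)))
    areas = np.exp(log_areas)
    # fold change applied in group 2
    fc = 2.0 ** config.log2_fold_change
    areas[np.ix_(diff_idx, np.nonzero(group_of_col == g2)[0])] *= fc
    detected = np.ones_like(areas, dtype=bool)
    drop_cols = np.nonzero(group_of_col == config.dropout_group)[0]
    for i in drop_idx:
        mask = rng.random(drop_cols.size) < config.dropout_probability
        detected[i, drop_cols[mask]] = False
        areas[i, drop_cols[mask]] = 0.0

    lo_c, hi_c = config.ladder_carbons
    ladder = AlkaneLadder(
        entries=tuple(
            (c, config.ladder_rt_start + config.ladder_rt_per_carbon * (c - lo_c))
            for c in range(lo_c, hi_c + 1)
        )
    )
    rt_lo, rt_hi = ladder.span
    rts = np.sort(rng.uniform(rt_lo, rt_hi, size=n))

    compounds = [
        Compound(
            id=f"S{i + 1}",
            name=f"compound-{i + 1:03d}",
            compound_class=_CLASS_CYCLE[i % len(_CLASS_CYCLE)],
            rt_min=float(rts[i]),
            match_score=float(np.round(rng.uniform(80.5, 99.5), 1)),
        )
        for i in range(n)
    ]
    table = PeakTable(compounds=compounds, samples=samples, groups=groups,
                      areas=areas, detected=detected)

    log_lo, log_hi = np.log(config.threshold_range)
    thresholds: dict[str, float] = {}
    descriptors: dict[str, list[str]] = {}
    for c in compounds:
        if rng.random() < config.threshold_fraction:
            thresholds[c.name] = float(np.exp(rng.uniform(log_lo, log_hi)))
            k = int(rng.integers(*config.descriptors_per_compound, endpoint=True))
            descriptors[c.name] = list(
                rng.choice(_DESCRIPTOR_VOCAB, size=k, replace=False)
            )
    tt = ThresholdTable(thresholds=thresholds, descriptors=descriptors)

    truth = {
        "seed": config.seed,
        "fold_change": fc,
        "differential_ids": [compounds[i].id for i in diff_idx],
        "dropout_ids": [compounds[i].id for i in drop_idx],
        "dropout_group": config.dropout_group,
    }
    return table, ladder, tt, truth


def write_simulation(outdir: str, config: SimConfig | None = None, **overrides) -> dict:
    """Generate and write the three canonical CSVs plus a truth.json sidecar."""
    import os

    from .io import write_alkane_ladder, write_peak_table, write_threshold_table

    table, ladder, tt, truth = generate(config, **overrides)
    os.makedirs(outdir, exist_ok=True)
    write_peak_table(table, os.path.join(outdir, "peaks.csv"),
                     os.path.join(outdir, "samples.csv"))
    write_alkane_ladder(ladder, os.path.join(outdir, "ladder.csv"))
    write_threshold_table(tt, os.path.join(outdir, "thresholds.csv"))
    with open(os.path.join(outdir, "truth.json"), "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2)
    return truth
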