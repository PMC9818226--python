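"""Core data containers for the volatile-compound analysis pipeline.

The central object is the :class:`PeakTable`: integrated GC-MS peak areas for a
set of identified volatile compounds across replicate samples, each sample
carrying a group label (the differential design is strictly two-group, e.g.
young vs. mature fruit).  Companion tables hold the n-alkane retention ladder
used for Kováts retention indexing and the odor thresholds / aroma descriptors
used for odor-activity scoring.

Missing peaks (a compound not detected in a sample) are stored as area 0 with
``detected=False`` rather than NaN: the multivariate stages need a complete
matrix, and detection counts use the flag, never the value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "COMPOUND_CLASSES",
    "ValidationError",
    "FormatError",
    "ParseError",
    "Compound",
    "PeakTable",
    "AlkaneLadder",
    "ThresholdTable",
]

#: Closed vocabulary of compound chemical classes.
COMPOUND_CLASSES = frozenset(
    {"alkane", "alkene", "alcohol", "aldehyde", "ketone", "ester", "terpene",
     "furan", "other"}
)


class ValidationError(ValueError):
    """An object violates one of its structural invariants."""


class FormatError(ValidationError):
    """An input file does not match the expected column layout."""


class ParseError(ValidationError):
    """A cell could not be parsed; message carries row/column coordinates."""


@dataclass(frozen=True)
class Compound:
    """One identified volatile compound and its metadata.

    ``match_score`` is the spectral-library match quality in [0, 100] (``None``
    when the upstream identification did not report one); ``rt_min`` is the
    chromatographic retention time in minutes.
    """

    id: str
    name: str
    cas: str = ""
    formula: str = ""
    compound_class: str = "other"
    rt_min: float | None = None
    match_score: float | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("compound id must be non-empty")
        if self.compound_class not in COMPOUND_CLASSES:
            raise ValidationError(
                f"unknown compound class {self.compound_class!r} for {self.id};"
                f" expected one of {sorted(COMPOUND_CLASSES)}"
            )
        if self.rt_min is not None and not self.rt_min > 0:
            raise ValidationError(f"rt_min must be > 0 for {self.id}")
        if self.match_score is not None and not (0 <= self.match_score <= 100):
            raise ValidationError(f"match_score out of [0, 100] for {self.id}")


@dataclass
class PeakTable:
    """Compounds × samples matrix of raw peak areas with group labels.

    Attributes
    ----------
    compounds : list of Compound, order preserved from the input file.
    samples : ordered sample ids.
    groups : map sample id → group label.
    areas : float array ``(n_compounds, n_samples)``, ≥ 0 everywhere.
    detected : bool array, same shape; ``detected=False`` implies area 0.
    """

    compounds: list[Compound]
    samples: list[str]
    groups: dict[str, str]
    areas: np.ndarray
    detected: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if self.detected is None:
            self.detected = self.areas > 0
        self.detected = np.asarray(self.detected, dtype=bool)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n_c, n_s = len(self.compounds), len(self.samples)
        if self.areas.shape != (n_c, n_s):
            raise ValidationError(
                f"areas shape {self.areas.shape} != ({n_c}, {n_s})"
            )
        if self.detected.shape != self.areas.shape:
            raise ValidationError("detected flag matrix shape mismatch")
        if np.any(self.areas < 0):
            raise ValidationError("peak areas must be non-negative")
        if np.any(self.areas[~self.detected] != 0):
            raise ValidationError("undetected cells must carry area 0")
        ids = [c.id for c in self.compounds]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate compound ids: {dupes}")
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample ids")
        missing = [s for s in self.samples if s not in self.groups]
        if missing:
            raise ValidationError(f"samples without group label: {missing}")

    # -- convenience --------------------------------------------------------
    @property
    def n_compounds(self) -> int:
        return len(self.compounds)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def group_labels(self) -> list[str]:
        """Distinct group labels in first-appearance (sample) order."""
        seen: list[str] = []
        for s in self.samples:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return seen

    def compound_ids(self) -> list[str]:
        return [c.id for c in self.compounds]

    def group_sample_indices(self, group: str) -> np.ndarray:
        idx = [j for j, s in enumerate(self.samples) if self.groups[s] == group]
        if not idx:
            raise KeyError(f"unknown or empty group {group!r}")
        return np.asarray(idx, dtype=int)

    def require_two_groups(self) -> tuple[str, str]:
        labels = self.group_labels
        if len(labels) != 2:
            raise ValidationError(
                f"differential analysis requires exactly 2 groups, got {labels}"
            )
        return labels[0], labels[1]

    def subset(self, indices: Sequence[int]) -> "PeakTable":
        """Sub-table of the given compound rows, order as given."""
        idx = list(indices)
        return PeakTable(
            compounds=[self.compounds[i] for i in idx],
            samples=list(self.samples),
            groups=dict(self.groups),
            areas=self.areas[idx, :].copy(),
            detected=self.detected[idx, :].copy(),
        )


@dataclass(frozen=True)
class AlkaneLadder:
    """Monotone map carbon number → retention time for n-alkane standards.

    The ladder anchors the Kováts retention-index scale: an n-alkane with
    ``n`` carbons has index 100·n by definition, and analyte retention times
    are linearly interpolated between the bracketing alkanes.
    """

    entries: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        entries = tuple((int(n), float(rt)) for n, rt in self.entries)
        object.__setattr__(self, "entries", entries)
        if len(entries) < 2:
            raise ValidationError("alkane ladder needs at least 2 entries")
        carbons = [n for n, _ in entries]
        rts = [rt for _, rt in entries]
        if any(n < 5 for n in carbons):
            raise ValidationError("alkane carbon numbers must be ≥ 5")
        if any(b <= a for a, b in zip(carbons, carbons[1:])):
            raise ValidationError("carbon numbers must be strictly increasing")
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValidationError(
                "retention times must increase strictly with carbon number"
            )

    @property
    def carbons(self) -> np.ndarray:
        return np.array([n for n, _ in self.entries], dtype=int)

    @property
    def rts(self) -> np.ndarray:
        return np.array([rt for _, rt in self.entries], dtype=float)

    @property
    def span(self) -> tuple[float, float]:
        return self.entries[0][1], self.entries[-1][1]


@dataclass
class ThresholdTable:
    """Per-compound odor thresholds (mg/kg) and aroma descriptors.

    A compound may lack a threshold (odor-activity scoring then skips it) but
    thresholds, when present, must be strictly positive.  Descriptors are
    short free-text aroma terms ("green", "floral", ...).
    """

    thresholds: dict[str, float]
    descriptors: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, t in self.thresholds.items():
            if not (t is None or t > 0):
                raise ValidationError(
                    f"odor threshold must be > 0, got {t!r} for {name!r}"
                )
        for name in self.descriptors:
            self.descriptors[name] = list(self.descriptors[name])

    def threshold(self, name: str) -> float | None:
        return self.thresholds.get(name)

    def descriptor_list(self, name: str) -> list[str]:
        return list(self.descriptors.get(name, []))

    def __contains__(self, name: str) -> bool:
        return name in self.thresholds and self.thresholds[name] is not None
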