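"""Elementary diagnostic readouts for monocytosis triage.

Three binary classifiers at their published cutoffs — smear dysplasia
score >= 1, Monoscore >= 0.161, classical monocyte fraction >= 94% — plus
detection of the inflammatory "bulbous" subset pattern and rectangular
CD14/CD16 gating of event-level cytometry data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .cohort import (
    DYSPLASIA_LINEAGES,
    DysplasiaAssessment,
    MonocyteSubsetProfile,
    ValidationError,
)

__all__ = [
    "ScoreConfig",
    "EventTable",
    "RectGate",
    "GateSet",
    "default_gateset",
    "dysplasia_score",
    "dysplasia_positive",
    "monoscore_positive",
    "cmo_positive",
    "detect_bulbous",
    "gate_events",
]


@dataclass(frozen=True)
class ScoreConfig:
    """Cutoffs for the elementary classifiers.

    ``monoscore_cutoff`` and ``cmo_cutoff_pct`` are the published decision
    thresholds; ``dysplasia_pct_cutoff`` is the per-lineage significance
    threshold (10% of cells, WHO MDS convention) and
    ``dysplasia_score_cutoff`` the score value calling the smear abnormal.
    The bulbous thresholds quantify "near disappearance" of nonclassical
    monocytes with a raised intermediate fraction; they are a convention of
    this package (see docs/methods.md), not a published cutoff.
    """

    monoscore_cutoff: float = 0.161
    cmo_cutoff_pct: float = 94.0
    dysplasia_pct_cutoff: float = 10.0
    dysplasia_score_cutoff: int = 1
    bulbous_ncmo_max_pct: float = 3.0
    bulbous_imo_min_pct: float = 9.0

    def __post_init__(self) -> None:
        for name in ("monoscore_cutoff", "cmo_cutoff_pct", "dysplasia_pct_cutoff",
                     "bulbous_ncmo_max_pct", "bulbous_imo_min_pct"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        if self.dysplasia_score_cutoff <= 0:
            raise ValidationError("dysplasia_score_cutoff must be strictly positive")
        if self.cmo_cutoff_pct > 100.0:
            raise ValidationError("cmo_cutoff_pct cannot exceed 100")

    def to_dict(self) -> dict:
        return asdict(self)


def dysplasia_score(assessment: DysplasiaAssessment, cfg: ScoreConfig = ScoreConfig()) -> int:
    """One point per lineage with >= 10% dysplastic cells (inclusive); 0-4."""
    return sum(
        1 for ln in DYSPLASIA_LINEAGES
        if assessment.lineage_pct[ln] >= cfg.dysplasia_pct_cutoff
    )


def dysplasia_positive(assessment: DysplasiaAssessment, cfg: ScoreConfig = ScoreConfig()) -> bool:
    """Smear called abnormal: dysplasia score >= 1 (at default config)."""
    return dysplasia_score(assessment, cfg) >= cfg.dysplasia_score_cutoff


def monoscore_positive(monoscore: float, cfg: ScoreConfig = ScoreConfig()) -> bool:
    """Monoscore abnormal at >= 0.161 (inclusive)."""
    if not (0.0 <= monoscore <= 1.0):
        raise ValidationError(f"monoscore must be in [0, 1], got {monoscore!r}")
    return monoscore >= cfg.monoscore_cutoff


def cmo_positive(subsets: MonocyteSubsetProfile, cfg: ScoreConfig = ScoreConfig()) -> bool:
    """Classical monocyte fraction at or above the 94% CMML signature."""
    return subsets.cmo_pct >= cfg.cmo_cutoff_pct


def detect_bulbous(subsets: MonocyteSubsetProfile, cfg: ScoreConfig = ScoreConfig()) -> bool:
    """Inflammatory "bulbous" pattern: nonclassical monocytes nearly absent,
    intermediate fraction raised, while the classical fraction stays below
    the CMML cutoff (a cMo-positive sample is called positive, not bulbous)."""
    return (
        subsets.ncmo_pct <= cfg.bulbous_ncmo_max_pct
        and subsets.imo_pct >= cfg.bulbous_imo_min_pct
        and subsets.cmo_pct < cfg.cmo_cutoff_pct
    )


# --------------------------------------------------------------------------
# Event-level gating
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EventTable:
    """Per-event CD14/CD16 fluorescence intensities on a log-like scale
    (already transformed, as displayed on a cytometer's log axes)."""

    cd14: np.ndarray
    cd16: np.ndarray

    def __post_init__(self) -> None:
        cd14 = np.asarray(self.cd14, dtype=float)
        cd16 = np.asarray(self.cd16, dtype=float)
        if cd14.ndim != 1 or cd16.ndim != 1 or cd14.shape != cd16.shape:
            raise ValidationError("cd14 and cd16 must be 1-D arrays of equal length")
        if cd14.size < 1:
            raise ValidationError("event table must contain at least one event")
        if not (np.isfinite(cd14).all() and np.isfinite(cd16).all()):
            raise ValidationError("event intensities must be finite")
        object.__setattr__(self, "cd14", cd14)
        object.__setattr__(self, "cd16", cd16)

    @property
    def n_events(self) -> int:
        return int(self.cd14.size)


@dataclass(frozen=True)
class RectGate:
    """Axis-aligned rectangle, half-open on the upper edges so adjacent
    gates sharing a boundary stay disjoint."""

    cd14_min: float
    cd14_max: float
    cd16_min: float
    cd16_max: float

    def contains(self, cd14: np.ndarray, cd16: np.ndarray) -> np.ndarray:
        return (
            (cd14 >= self.cd14_min) & (cd14 < self.cd14_max)
            & (cd16 >= self.cd16_min) & (cd16 < self.cd16_max)
        )

    def overlaps(self, other: "RectGate") -> bool:
        return (
            self.cd14_min < other.cd14_max and other.cd14_min < self.cd14_max
            and self.cd16_min < other.cd16_max and other.cd16_min < self.cd16_max
        )


@dataclass(frozen=True)
class GateSet:
    """Rectangular gates for the three monocyte subsets in (CD14, CD16)
    space; events outside all three are left unassigned."""

    cmo: RectGate
    imo: RectGate
    ncmo: RectGate

    def __post_init__(self) -> None:
        pairs = [("cmo", "imo"), ("cmo", "ncmo"), ("imo", "ncmo")]
        for a, b in pairs:
            if getattr(self, a).overlaps(getattr(self, b)):
                raise ValidationError(f"gates {a} and {b} overlap")

    def to_dict(self) -> dict:
        return {name: asdict(getattr(self, name)) for name in ("cmo", "imo", "ncmo")}

    @classmethod
    def from_dict(cls, d: dict) -> "GateSet":
        return cls(**{name: RectGate(**d[name]) for name in ("cmo", "imo", "ncmo")})


def default_gateset() -> GateSet:
    """Default gates on log10-scale arbitrary units.

    Classical monocytes are CD14-bright/CD16-negative, intermediates
    CD14-bright/CD16-positive, nonclassicals CD14-dim/CD16-bright; the
    CD16 positivity boundary sits at 1.25 and the CD14 bright/dim boundary
    at 2.0, matching the simulator's component locations.
    """
    return GateSet(
        cmo=RectGate(2.0, 3.5, -1.0, 1.25),
        imo=RectGate(2.0, 3.5, 1.25, 3.0),
        ncmo=RectGate(0.0, 2.0, 1.25, 3.0),
    )


def gate_events(
    events: EventTable,
    gates: GateSet | None = None,
    cfg: ScoreConfig = ScoreConfig(),
    min_assigned: int = 100,
) -> tuple[MonocyteSubsetProfile, float]:
    """Assign events to subset gates and return the fraction profile.

    Fractions are computed over assigned events only and sum to 100; the
    second return value is the fraction (0-1) of events falling outside all
    gates. Fewer than ``min_assigned`` assigned events makes the sample
    uninterpretable and raises.
    """
    if gates is None:
        gates = default_gateset()
    in_cmo = gates.cmo.contains(events.cd14, events.cd16)
    in_imo = gates.imo.contains(events.cd14, events.cd16)
    in_ncmo = gates.ncmo.contains(events.cd14, events.cd16)
    n_cmo, n_imo, n_ncmo = int(in_cmo.sum()), int(in_imo.sum()), int(in_ncmo.sum())
    n_assigned = n_cmo + n_imo + n_ncmo
    if n_assigned < min_assigned:
        raise ValidationError(
            f"only {n_assigned} of {events.n_events} events fall inside the subset "
            f"gates (minimum {min_assigned}); sample uninterpretable"
        )
    cmo_pct = 100.0 * n_cmo / n_assigned
    imo_pct = 100.0 * n_imo / n_assigned
    # close the composition exactly to dodge float round-off in the invariant
    ncmo_pct = 100.0 - cmo_pct - imo_pct
    profile = MonocyteSubsetProfile(cmo_pct, imo_pct, ncmo_pct, bulbous=False)
    profile = MonocyteSubsetProfile(
        cmo_pct, imo_pct, ncmo_pct, bulbous=detect_bulbous(profile, cfg)
    )
    unassigned = 1.0 - n_assigned / events.n_events
    return profile, unassigned
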