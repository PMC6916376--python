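"""Patient-level domain types, eligibility rules and cohort table I/O.

The unit of analysis is a single monocytosis sample: a complete blood
count (CBC), the flags that would independently trigger a blood-smear
review, the Monoscore value produced by the hematology analyzer, and the
optional downstream readouts (smear dysplasia assessment, flow-cytometric
monocyte subset profile). The consensus diagnosis (CMML vs nonclonal
monocytosis) is an input label established from marrow, cytogenetics and
follow-up; it is never computed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "Sex",
    "Diagnosis",
    "Provenance",
    "CBCPanel",
    "TriggerFlags",
    "DysplasiaAssessment",
    "MonocyteSubsetProfile",
    "PatientRecord",
    "Cohort",
    "ExclusionContext",
    "ExclusionLog",
    "ValidationError",
    "DYSPLASIA_LINEAGES",
    "COHORT_COLUMNS",
    "who_eligible",
    "apply_exclusions",
    "read_cohort",
    "write_cohort",
]


class ValidationError(ValueError):
    """A record or table violates a domain invariant."""


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class Diagnosis(str, Enum):
    CMML = "CMML"
    NONCLONAL = "NONCLONAL"
    UNKNOWN = "UNKNOWN"


class Provenance(str, Enum):
    SYNTHETIC = "synthetic"
    PAPER_FIXTURE = "paper_fixture"
    USER = "user"


#: Blood-cell lineages scored for dysplasia on the smear, in reporting order.
DYSPLASIA_LINEAGES = ("neutrophil", "erythrocyte", "megakaryocytic", "monocyte")


def _check_pct(name: str, value: float) -> None:
    if not (0.0 <= value <= 100.0):
        raise ValidationError(f"{name} must be in [0, 100], got {value!r}")


def _check_nonneg(name: str, value: float) -> None:
    if not (value >= 0.0) or not math.isfinite(value):
        raise ValidationError(f"{name} must be a finite nonnegative number, got {value!r}")


@dataclass(frozen=True)
class CBCPanel:
    """Complete blood count values relevant to monocytosis triage.

    Counts are absolute concentrations in 10^9 cells/L; hemoglobin in g/dL;
    the remaining fields are percentages of the WBC differential.
    """

    wbc: float
    hemoglobin: float
    platelets: float
    neutrophils: float
    monocytes_abs: float
    monocytes_pct: float
    immature_granulocytes_pct: float = 0.0
    blasts_pct: float = 0.0

    def __post_init__(self) -> None:
        for name in ("wbc", "hemoglobin", "platelets", "neutrophils", "monocytes_abs"):
            _check_nonneg(name, getattr(self, name))
        for name in ("monocytes_pct", "immature_granulocytes_pct", "blasts_pct"):
            _check_pct(name, getattr(self, name))
        if self.monocytes_abs > self.wbc + 1e-9:
            raise ValidationError(
                f"monocytes_abs ({self.monocytes_abs}) exceeds wbc ({self.wbc})"
            )


@dataclass(frozen=True)
class TriggerFlags:
    """CBC abnormalities, other than the monocytosis itself, that mandate a
    blood-smear review (analyzer morphology flag, platelets < 100 x 10^9/L,
    immature granulocytes >= 10%, or any free-text criterion such as a
    clinician request)."""

    analyzer_flag: bool = False
    thrombocytopenia: bool = False
    ig_high: bool = False
    other_trigger: bool = False

    @property
    def any_trigger(self) -> bool:
        return self.analyzer_flag or self.thrombocytopenia or self.ig_high or self.other_trigger

    def check_consistent(self, cbc: CBCPanel) -> None:
        """Verify the threshold-derived flags against the CBC values."""
        if self.thrombocytopenia != (cbc.platelets < 100.0):
            raise ValidationError(
                "thrombocytopenia flag inconsistent with platelet count "
                f"({cbc.platelets} x10^9/L)"
            )
        if self.ig_high != (cbc.immature_granulocytes_pct >= 10.0):
            raise ValidationError(
                "ig_high flag inconsistent with immature granulocyte percentage "
                f"({cbc.immature_granulocytes_pct}%)"
            )


@dataclass(frozen=True)
class DysplasiaAssessment:
    """Per-lineage dysplastic-cell percentages from a 200-cell smear review.

    Every lineage must be reported explicitly (0 for absent dysplasia);
    the integer score 0-4 is derived by :func:`monotriage.scores.dysplasia_score`.
    """

    lineage_pct: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = [ln for ln in DYSPLASIA_LINEAGES if ln not in self.lineage_pct]
        if missing:
            raise ValidationError(
                f"dysplasia assessment missing lineages {missing}; report 0, do not omit"
            )
        for lineage, pct in self.lineage_pct.items():
            _check_pct(f"dysplasia[{lineage}]", pct)
        object.__setattr__(self, "lineage_pct", dict(self.lineage_pct))


@dataclass(frozen=True)
class MonocyteSubsetProfile:
    """Flow-cytometric monocyte partitioning readout.

    Percentages of classical (CD14++ CD16-), intermediate (CD14++ CD16+)
    and nonclassical (CD14low/neg CD16++) monocytes, summing to 100, plus
    the inflammatory "bulbous" pattern flag (near-absent nonclassical with
    raised intermediate fraction).
    """

    cmo_pct: float
    imo_pct: float
    ncmo_pct: float
    bulbous: bool = False

    SUM_TOL = 1e-6

    def __post_init__(self) -> None:
        for name in ("cmo_pct", "imo_pct", "ncmo_pct"):
            _check_pct(name, getattr(self, name))
        total = self.cmo_pct + self.imo_pct + self.ncmo_pct
        if abs(total - 100.0) > self.SUM_TOL:
            raise ValidationError(
                f"monocyte subset fractions must sum to 100, got {total!r}"
            )


@dataclass(frozen=True)
class PatientRecord:
    id: str
    age: float
    sex: Sex
    cbc: CBCPanel
    triggers: TriggerFlags
    monoscore: float
    dysplasia: DysplasiaAssessment | None = None
    subsets: MonocyteSubsetProfile | None = None
    crp: float | None = None
    consensus_dx: Diagnosis = Diagnosis.UNKNOWN
    #: True when a repeat flow-cytometry test months later showed cMo >= 94%
    #: in a sample that was "bulbous" at presentation.
    followup_cmo_confirmed: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("patient id must be a nonempty string")
        _check_nonneg("age", self.age)
        if not (0.0 <= self.monoscore <= 1.0):
            raise ValidationError(f"monoscore must be in [0, 1], got {self.monoscore!r}")
        if self.crp is not None:
            _check_nonneg("crp", self.crp)


@dataclass(frozen=True)
class Cohort:
    records: tuple[PatientRecord, ...]
    provenance: Provenance = Provenance.USER

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate patient ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def subset(self, predicate: Callable[[PatientRecord], bool]) -> "Cohort":
        return Cohort(tuple(r for r in self.records if predicate(r)), self.provenance)

    def n_by_diagnosis(self) -> dict[Diagnosis, int]:
        out = {dx: 0 for dx in Diagnosis}
        for r in self.records:
            out[r.consensus_dx] += 1
        return out

    def to_dataframe(self) -> pd.DataFrame:
        """Flatten to one row per patient with the documented column schema."""
        return pd.DataFrame([_record_to_row(r) for r in self.records], columns=COHORT_COLUMNS)


# --------------------------------------------------------------------------
# Eligibility and exclusions
# --------------------------------------------------------------------------

def who_eligible(cbc: CBCPanel) -> bool:
    """WHO monocytosis criterion: absolute monocytes >= 1 x 10^9/L *and*
    monocytes accounting for >= 10% of the WBC count (both inclusive)."""
    return cbc.monocytes_abs >= 1.0 and cbc.monocytes_pct >= 10.0


@dataclass(frozen=True)
class ExclusionContext:
    """Per-record flags needed to apply the cohort exclusion rules."""

    age: float
    sepsis: bool
    sample_age_h: float
    post_aplasia: bool
    has_followup: bool


#: Exclusion reasons, applied and reported in this fixed order.
EXCLUSION_REASONS = ("age_under_50", "active_sepsis", "ineligible_sample", "no_followup")


@dataclass
class ExclusionLog:
    counts: dict[str, int] = field(default_factory=lambda: {r: 0 for r in EXCLUSION_REASONS})
    excluded_ids: dict[str, list[str]] = field(
        default_factory=lambda: {r: [] for r in EXCLUSION_REASONS}
    )

    @property
    def n_excluded(self) -> int:
        return sum(self.counts.values())

    def to_dict(self) -> dict:
        return {"counts": dict(self.counts), "excluded_ids": {k: list(v) for k, v in self.excluded_ids.items()}}


def apply_exclusions(
    cohort: Cohort, context: Mapping[str, ExclusionContext]
) -> tuple[Cohort, ExclusionLog]:
    """Apply the study exclusion cascade and log removals per reason.

    Rules, in order: age < 50; active sepsis (overt nonclonal context);
    ineligible sample (older than 24 h, or drawn during recovery from
    aplasia); no follow-up available. A record is logged under the first
    rule it fails, so the per-reason counts are reproducible.
    """
    missing = [r.id for r in cohort if r.id not in context]
    if missing:
        raise ValidationError(f"missing exclusion context for records: {missing}")
    log = ExclusionLog()
    kept: list[PatientRecord] = []
    for rec in cohort:
        ctx = context[rec.id]
        if ctx.age < 50.0:
            reason = "age_under_50"
        elif ctx.sepsis:
            reason = "active_sepsis"
        elif ctx.sample_age_h > 24.0 or ctx.post_aplasia:
            reason = "ineligible_sample"
        elif not ctx.has_followup:
            reason = "no_followup"
        else:
            kept.append(rec)
            continue
        log.counts[reason] += 1
        log.excluded_ids[reason].append(rec.id)
    return Cohort(tuple(kept), cohort.provenance), log


# --------------------------------------------------------------------------
# CSV serialization
# --------------------------------------------------------------------------

COHORT_COLUMNS = [
    "id",
    "age",
    "sex",
    "wbc",
    "hemoglobin",
    "platelets",
    "neutrophils",
    "monocytes_abs",
    "monocytes_pct",
    "immature_granulocytes_pct",
    "blasts_pct",
    "analyzer_flag",
    "thrombocytopenia",
    "ig_high",
    "other_trigger",
    "monoscore",
    "dys_neutrophil",
    "dys_erythrocyte",
    "dys_megakaryocytic",
    "dys_monocyte",
    "cmo_pct",
    "imo_pct",
    "ncmo_pct",
    "bulbous",
    "followup_cmo_confirmed",
    "crp",
    "consensus_dx",
]

SCHEMA_VERSION = "1"

_BOOL_COLS = ["analyzer_flag", "thrombocytopenia", "ig_high", "other_trigger", "bulbous",
              "followup_cmo_confirmed"]


def _record_to_row(r: PatientRecord) -> dict:
    row: dict = {
        "id": r.id,
        "age": r.age,
        "sex": r.sex.value,
        "wbc": r.cbc.wbc,
        "hemoglobin": r.cbc.hemoglobin,
        "platelets": r.cbc.platelets,
        "neutrophils": r.cbc.neutrophils,
        "monocytes_abs": r.cbc.monocytes_abs,
        "monocytes_pct": r.cbc.monocytes_pct,
        "immature_granulocytes_pct": r.cbc.immature_granulocytes_pct,
        "blasts_pct": r.cbc.blasts_pct,
        "analyzer_flag": int(r.triggers.analyzer_flag),
        "thrombocytopenia": int(r.triggers.thrombocytopenia),
        "ig_high": int(r.triggers.ig_high),
        "other_trigger": int(r.triggers.other_trigger),
        "monoscore": r.monoscore,
        "bulbous": int(r.subsets.bulbous) if r.subsets is not None else None,
        "followup_cmo_confirmed": int(r.followup_cmo_confirmed),
        "crp": r.crp,
        "consensus_dx": r.consensus_dx.value,
    }
    for lineage in DYSPLASIA_LINEAGES:
        row[f"dys_{lineage}"] = (
            r.dysplasia.lineage_pct[lineage] if r.dysplasia is not None else None
        )
    for name in ("cmo_pct", "imo_pct", "ncmo_pct"):
        row[name] = getattr(r.subsets, name) if r.subsets is not None else None
    return row


def _row_to_record(row: Mapping, idx: int) -> PatientRecord:
    def bad(col: str, msg: str) -> ValidationError:
        return ValidationError(f"row {idx}, column {col!r}: {msg}")

    try:
        cbc = CBCPanel(
            wbc=float(row["wbc"]),
            hemoglobin=float(row["hemoglobin"]),
            platelets=float(row["platelets"]),
            neutrophils=float(row["neutrophils"]),
            monocytes_abs=float(row["monocytes_abs"]),
            monocytes_pct=float(row["monocytes_pct"]),
            immature_granulocytes_pct=float(row["immature_granulocytes_pct"]),
            blasts_pct=float(row["blasts_pct"]),
        )
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"row {idx}: invalid CBC values ({exc})") from exc
    triggers = TriggerFlags(
        analyzer_flag=bool(int(row["analyzer_flag"])),
        thrombocytopenia=bool(int(row["thrombocytopenia"])),
        ig_high=bool(int(row["ig_high"])),
        other_trigger=bool(int(row["other_trigger"])),
    )
    dys_vals = {ln: row.get(f"dys_{ln}") for ln in DYSPLASIA_LINEAGES}
    if all(pd.notna(v) for v in dys_vals.values()):
        dysplasia = DysplasiaAssessment({ln: float(v) for ln, v in dys_vals.items()})
    elif all(pd.isna(v) for v in dys_vals.values()):
        dysplasia = None
    else:
        raise bad("dys_*", "dysplasia lineages must be all present or all absent")
    sub_vals = [row.get("cmo_pct"), row.get("imo_pct"), row.get("ncmo_pct")]
    if all(pd.notna(v) for v in sub_vals):
        bulb = row.get("bulbous")
        subsets = MonocyteSubsetProfile(
            cmo_pct=float(sub_vals[0]),
            imo_pct=float(sub_vals[1]),
            ncmo_pct=float(sub_vals[2]),
            bulbous=bool(int(bulb)) if pd.notna(bulb) else False,
        )
    elif all(pd.isna(v) for v in sub_vals):
        subsets = None
    else:
        raise bad("cmo_pct/imo_pct/ncmo_pct", "subset fractions must be all present or all absent")
    try:
        dx = Diagnosis(str(row["consensus_dx"]))
    except ValueError as exc:
        raise bad("consensus_dx", f"unknown diagnosis {row['consensus_dx']!r}") from exc
    crp = row.get("crp")
    return PatientRecord(
        id=str(row["id"]),
        age=float(row["age"]),
        sex=Sex(str(row["sex"])),
        cbc=cbc,
        triggers=triggers,
        monoscore=float(row["monoscore"]),
        dysplasia=dysplasia,
        subsets=subsets,
        crp=float(crp) if pd.notna(crp) else None,
        consensus_dx=dx,
        followup_cmo_confirmed=bool(int(row["followup_cmo_confirmed"])),
    )


def write_cohort(cohort: Cohort, path) -> None:
    """Write one UTF-8 CSV row per patient (booleans as 0/1, '.' decimals).

    Reals are written with 12 significant digits so a write-read round trip
    is lossless at that precision.
    """
    df = cohort.to_dataframe()
    df.to_csv(path, index=False, float_format="%.12g", encoding="utf-8")


def read_cohort(path, strict: bool = True,
                provenance: Provenance = Provenance.USER) -> Cohort:
    """Read a cohort CSV written by :func:`write_cohort`.

    In strict mode any missing or unknown column is an error naming the
    column; otherwise unknown columns are ignored and optional blocks may
    be absent.
    """
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort CSV missing required columns: {missing}")
    if strict:
        unknown = [c for c in df.columns if c not in COHORT_COLUMNS]
        if unknown:
            raise ValidationError(f"cohort CSV has unknown columns (strict mode): {unknown}")
    records = tuple(_row_to_record(row, i) for i, row in df.iterrows())
    return Cohort(records, provenance)
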