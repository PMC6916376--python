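"""The hierarchical monocytosis triage workflow.

Patients with a slide-review trigger beyond the monocytosis itself get a
smear first: significant dysplasia flags CMML directly; otherwise a
negative Monoscore rules out, and a positive one reflexes to flow
cytometry. Patients with isolated monocytosis skip the smear entirely:
a negative Monoscore ends the workup, a positive one reflexes straight to
flow cytometry. At the flow step a classical-monocyte fraction >= 94%
flags CMML; a "bulbous" inflammatory pattern triggers a recommendation to
repeat flow cytometry months later, with the suspicion confirmed only if
that follow-up test is positive.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

from .cohort import Cohort, Diagnosis, PatientRecord, ValidationError
from .scores import (
    ScoreConfig,
    cmo_positive,
    dysplasia_positive,
    dysplasia_score,
    monoscore_positive,
)

__all__ = [
    "Triage",
    "CombinedRule",
    "WorkflowResult",
    "CohortSummary",
    "triage_patient",
    "triage_cohort",
    "combined_rule",
]


class Triage(str, Enum):
    CMML_SUSPECT = "CMML_SUSPECT"
    NONCLONAL = "NONCLONAL"
    CMML_SUSPECT_AFTER_FOLLOWUP = "CMML_SUSPECT_AFTER_FOLLOWUP"

    @property
    def flags_cmml(self) -> bool:
        return self is not Triage.NONCLONAL


class CombinedRule(str, Enum):
    """Pairwise OR-combinations of the elementary classifiers."""

    MS_OR_DYS = "MS_OR_DYS"
    DYS_OR_CMO = "DYS_OR_CMO"
    MS_OR_CMO = "MS_OR_CMO"


@dataclass(frozen=True)
class WorkflowResult:
    patient_id: str
    smear_performed: bool
    monoscore_used: bool
    flow_performed: bool
    followup_flow_recommended: bool
    triage: Triage
    path: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.flow_performed and not (self.monoscore_used or self.smear_performed):
            raise ValidationError("flow cytometry can only follow a smear or Monoscore step")
        if self.followup_flow_recommended and not self.flow_performed:
            raise ValidationError("follow-up flow can only be recommended after flow was performed")


@dataclass(frozen=True)
class CohortSummary:
    n_total: int
    n_smears: int
    n_flow: int
    n_flagged_cmml: int
    n_cmml_detected: int
    n_cmml_missed: int
    pct_flow: float
    pct_smears_avoided: float

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_smears": self.n_smears,
            "n_flow": self.n_flow,
            "n_flagged_cmml": self.n_flagged_cmml,
            "n_cmml_detected": self.n_cmml_detected,
            "n_cmml_missed": self.n_cmml_missed,
            "pct_flow": self.pct_flow,
            "pct_smears_avoided": self.pct_smears_avoided,
        }


def _require(record: PatientRecord, attr: str, branch: str):
    value = getattr(record, attr)
    if value is None:
        raise ValidationError(
            f"patient {record.id}: {attr} readout required on branch {branch!r} but missing"
        )
    return value


def _flow_step(record: PatientRecord, cfg: ScoreConfig, path: list[str],
               smear: bool, mono_used: bool) -> WorkflowResult:
    subsets = _require(record, "subsets", "flow_cytometry")
    path.append("flow_cytometry")
    followup = False
    if cmo_positive(subsets, cfg):
        path.append("cmo_positive")
        triage = Triage.CMML_SUSPECT
    elif subsets.bulbous:
        path.append("bulbous_profile")
        followup = True
        if record.followup_cmo_confirmed:
            path.append("followup_cmo_positive")
            triage = Triage.CMML_SUSPECT_AFTER_FOLLOWUP
        else:
            path.append("followup_pending")
            triage = Triage.NONCLONAL
    else:
        path.append("cmo_negative")
        triage = Triage.NONCLONAL
    return WorkflowResult(
        patient_id=record.id,
        smear_performed=smear,
        monoscore_used=mono_used,
        flow_performed=True,
        followup_flow_recommended=followup,
        triage=triage,
        path=tuple(path),
    )


def triage_patient(record: PatientRecord, cfg: ScoreConfig = ScoreConfig()) -> WorkflowResult:
    """Route one patient through the hierarchical decision tree."""
    path: list[str] = []
    if record.triggers.any_trigger:
        path.append("trigger_present")
        dysplasia = _require(record, "dysplasia", "smear_review")
        path.append("smear_review")
        if dysplasia_score(dysplasia, cfg) >= cfg.dysplasia_score_cutoff:
            path.append("dysplasia_positive")
            return WorkflowResult(record.id, True, False, False, False,
                                  Triage.CMML_SUSPECT, tuple(path))
        path.append("dysplasia_negative")
        path.append("monoscore")
        if not monoscore_positive(record.monoscore, cfg):
            path.append("monoscore_negative")
            return WorkflowResult(record.id, True, True, False, False,
                                  Triage.NONCLONAL, tuple(path))
        path.append("monoscore_positive")
        return _flow_step(record, cfg, path, smear=True, mono_used=True)
    path.append("no_trigger")
    path.append("monoscore")
    if not monoscore_positive(record.monoscore, cfg):
        path.append("monoscore_negative")
        return WorkflowResult(record.id, False, True, False, False,
                              Triage.NONCLONAL, tuple(path))
    path.append("monoscore_positive")
    return _flow_step(record, cfg, path, smear=False, mono_used=True)


def _cmo_resolved_positive(record: PatientRecord, cfg: ScoreConfig) -> bool:
    """cMo classifier on the follow-up-resolved profile: a bulbous sample
    whose repeat test months later showed cMo >= 94% counts as positive."""
    subsets = record.subsets
    if subsets is None:
        raise ValidationError(f"patient {record.id}: subset profile required but missing")
    if cmo_positive(subsets, cfg):
        return True
    return subsets.bulbous and record.followup_cmo_confirmed


def combined_rule(record: PatientRecord, rule: CombinedRule,
                  cfg: ScoreConfig = ScoreConfig()) -> bool:
    """Evaluate a pairwise OR-rule on one patient.

    The cMo component uses the follow-up-resolved status (see
    :func:`_cmo_resolved_positive`), mirroring how bulbous samples are
    eventually classified.
    """
    rule = CombinedRule(rule)
    if rule is CombinedRule.MS_OR_DYS:
        return monoscore_positive(record.monoscore, cfg) or dysplasia_positive(
            _require(record, "dysplasia", rule.value), cfg
        )
    if rule is CombinedRule.DYS_OR_CMO:
        return dysplasia_positive(
            _require(record, "dysplasia", rule.value), cfg
        ) or _cmo_resolved_positive(record, cfg)
    return monoscore_positive(record.monoscore, cfg) or _cmo_resolved_positive(record, cfg)


def triage_cohort(
    cohort: Cohort, cfg: ScoreConfig = ScoreConfig()
) -> tuple[list[WorkflowResult], CohortSummary]:
    """Triage every record and aggregate workload and detection counts.

    Detection counts are computed over records with a known consensus
    diagnosis; a bulbous CMML patient counts as detected only when the
    record carries a follow-up confirmation. ``pct_smears_avoided`` is
    relative to the review-every-eligible-sample policy, i.e. the fraction
    of records with no additional slide-review trigger.
    """
    results: list[WorkflowResult] = []
    for record in cohort:
        try:
            results.append(triage_patient(record, cfg))
        except ValidationError as exc:
            raise ValidationError(f"triage failed for patient {record.id}: {exc}") from exc
    n_total = len(cohort)
    if n_total == 0:
        raise ValidationError("cannot summarize an empty cohort")
    n_smears = sum(r.smear_performed for r in results)
    n_flow = sum(r.flow_performed for r in results)
    n_flagged = sum(r.triage.flags_cmml for r in results)
    by_id = {r.patient_id: r for r in results}
    n_detected = sum(
        1 for rec in cohort
        if rec.consensus_dx is Diagnosis.CMML and by_id[rec.id].triage.flags_cmml
    )
    n_cmml = sum(1 for rec in cohort if rec.consensus_dx is Diagnosis.CMML)
    summary = CohortSummary(
        n_total=n_total,
        n_smears=n_smears,
        n_flow=n_flow,
        n_flagged_cmml=n_flagged,
        n_cmml_detected=n_detected,
        n_cmml_missed=n_cmml - n_detected,
        pct_flow=100.0 * n_flow / n_total,
        pct_smears_avoided=100.0 * (n_total - n_smears) / n_total,
    )
    return results, summary
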