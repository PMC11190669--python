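"""Rule-based classification of suspected lupus-nephritis (LN) episodes.

A visit stream is screened for suspected-LN episodes, exclusion windows are
applied (90 days after rituximab or steroid-pulse therapy; acute infection),
and each remaining episode is classified against its baseline into one of
four renal-outcome categories:

a. improvement  — (i) ≥25 % eGFR rise from an abnormal (<90) baseline,
                  (ii) ≥50 % fall in UPCR or 24-h urine protein,
                  (iii) active → inactive urinary sediment;
b. no change    — stable values, no criterion fired;
c. deterioration— (i) ≥25 % eGFR fall or ESKD (eGFR < 15),
                  (ii) ≥100 % rise in UPCR,
                  (iii) inactive → active sediment;
d. relapse      — (i) persistent urine protein > 0.15 g/day after complete
                  remission, or proteinuria rise > 1 g/24 h,
                  (ii) active urine sediment,
                  (iii) serum creatinine rise > 25 %.

Improvement / no-change episodes are *inactive LN*; deterioration / relapse
are *active LN*; visits failing the clinical LN criteria (an input flag, not
computed here) are *non-LN*.  When criteria from several families fire at
once, precedence is deterioration > relapse > improvement, so mixed signals
count as active disease.

Active urinary sediment: >5 RBC/HPF and >5 WBC/HPF, or ≥1 cellular cast;
inactive: ≤5 RBC and ≤5 WBC and no casts; anything else is indeterminate.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

from .cohort import PatientRecord, VisitRecord
from .errors import (
    DomainError,
    IndeterminateError,
    InsufficientDataError,
    ValidationError,
)
from .renal import egfr_for_visit

ABNORMAL_EGFR = 90.0  # mL/min/1.73 m^2, below which baseline eGFR is abnormal
ESKD_EGFR = 15.0
EXCLUSION_WINDOW_DAYS = 90
REMISSION_PROTEIN_G_DAY = 0.15

A_CRITERIA = frozenset({"a_i", "a_ii", "a_iii"})
C_CRITERIA = frozenset({"c_i", "c_ii", "c_iii"})
D_CRITERIA = frozenset({"d_i", "d_ii", "d_iii"})
ALL_CRITERIA = tuple(sorted(A_CRITERIA | C_CRITERIA | D_CRITERIA))


@dataclass(frozen=True)
class OutcomeCategory:
    category: str  # improvement | no_change | deterioration | relapse
    criteria_met: frozenset[str]


@dataclass(frozen=True)
class EpisodeLabel:
    label: str  # non_ln | inactive_ln | active_ln
    outcome: OutcomeCategory | None = None
    excluded: bool = False
    exclusion_reason: str = "none"


def sediment_state(rbc_hpf: float, wbc_hpf: float, casts: float) -> str:
    """Urinary sediment activity from RBC/WBC per HPF and cellular casts."""
    if rbc_hpf < 0 or wbc_hpf < 0 or casts < 0:
        raise DomainError("sediment counts must be >= 0")
    if (rbc_hpf > 5 and wbc_hpf > 5) or casts >= 1:
        return "active"
    if rbc_hpf <= 5 and wbc_hpf <= 5 and casts == 0:
        return "inactive"
    return "indeterminate"


def _visit_sediment(visit: VisitRecord) -> str | None:
    if visit.urine_rbc_hpf is None or visit.urine_wbc_hpf is None or visit.cellular_casts is None:
        return None
    return sediment_state(visit.urine_rbc_hpf, visit.urine_wbc_hpf, visit.cellular_casts)


def sledai_category(score: int) -> str:
    """SLEDAI activity bin: 0 none, 1-5 mild, 6-10 moderate, 11-19 high, >=20 very high."""
    if score < 0:
        raise DomainError(f"SLEDAI must be >= 0, got {score}")
    if score == 0:
        return "none"
    if score <= 5:
        return "mild"
    if score <= 10:
        return "moderate"
    if score <= 19:
        return "high"
    return "very_high"


def is_suspected_ln(
    visit: VisitRecord,
    baseline: VisitRecord | None = None,
    *,
    upcr_threshold: float = 0.2,
    protein_threshold_g_day: float = 0.15,
    relative_change: float = 0.25,
) -> bool:
    """Screen one visit for a suspected-LN episode.

    True on hematuria (>=5 RBC/HPF, dysmorphic), cellular casts, proteinuria
    (UPCR > 0.2 g/g or protein > 0.15 g/day) or a >25 % creatinine rise
    versus the baseline visit.
    """
    evaluable = False
    if visit.urine_rbc_hpf is not None:
        evaluable = True
        if visit.urine_rbc_hpf >= 5 and visit.dysmorphic_rbc:
            return True
    if visit.cellular_casts is not None:
        evaluable = True
        if visit.cellular_casts >= 1:
            return True
    if visit.upcr is not None:
        evaluable = True
        if visit.upcr > upcr_threshold:
            return True
    if visit.urine_protein_g_day is not None:
        evaluable = True
        if visit.urine_protein_g_day > protein_threshold_g_day:
            return True
    if (
        baseline is not None
        and visit.scr_mg_dl is not None
        and baseline.scr_mg_dl is not None
    ):
        evaluable = True
        if visit.scr_mg_dl > (1.0 + relative_change) * baseline.scr_mg_dl:
            return True
    if not evaluable:
        raise IndeterminateError("no urinalysis, proteinuria or creatinine available")
    return False


def exclusion_filter(
    patient: PatientRecord,
    visit: VisitRecord,
    *,
    window_days: int = EXCLUSION_WINDOW_DAYS,
) -> str:
    """Exclusion reason for a visit, or ``"none"``.

    Visits within ``window_days`` after a rituximab or steroid-pulse event
    (the therapy visit itself is kept) and visits flagged as acute infection
    are excluded.
    """
    for prior in patient.visits:
        if prior.date >= visit.date:
            break
        if prior.therapy_event == "none":
            continue
        gap = (visit.date - prior.date).days
        if 0 < gap <= window_days:
            return (
                "post_rituximab_90d"
                if prior.therapy_event == "rituximab"
                else "post_pulse_90d"
            )
    if visit.acute_infection:
        return "acute_infection"
    return "none"


def evaluate_criteria(
    current: VisitRecord,
    baseline: VisitRecord,
    in_remission: bool = False,
    *,
    egfr_current: float | None = None,
    egfr_baseline: float | None = None,
) -> tuple[frozenset[str], frozenset[str]]:
    """Fire the nine renal-outcome sub-criteria for a visit pair.

    Returns ``(fired, evaluable)`` tag sets.  eGFR-based criteria need the
    precomputed eGFR values (age dispatch lives in :mod:`lnscore.renal`).
    """
    fired: set[str] = set()
    evaluable: set[str] = set()

    if egfr_current is not None and egfr_baseline is not None:
        evaluable |= {"a_i", "c_i"}
        if egfr_baseline < ABNORMAL_EGFR and egfr_current >= 1.25 * egfr_baseline:
            fired.add("a_i")
        if egfr_current <= 0.75 * egfr_baseline or egfr_current < ESKD_EGFR:
            fired.add("c_i")

    if current.upcr is not None and baseline.upcr is not None:
        evaluable |= {"a_ii", "c_ii"}
        if current.upcr <= 0.5 * baseline.upcr:
            fired.add("a_ii")
        if current.upcr >= 2.0 * baseline.upcr:
            fired.add("c_ii")
    if (
        current.urine_protein_g_day is not None
        and baseline.urine_protein_g_day is not None
    ):
        evaluable.add("a_ii")
        if current.urine_protein_g_day <= 0.5 * baseline.urine_protein_g_day:
            fired.add("a_ii")

    sed_cur = _visit_sediment(current)
    sed_base = _visit_sediment(baseline)
    if sed_cur is not None:
        evaluable.add("d_ii")
        if sed_cur == "active":
            fired.add("d_ii")
        if sed_base is not None:
            evaluable |= {"a_iii", "c_iii"}
            if sed_base == "active" and sed_cur == "inactive":
                fired.add("a_iii")
            if sed_base == "inactive" and sed_cur == "active":
                fired.add("c_iii")

    if current.urine_protein_g_day is not None:
        evaluable.add("d_i")
        if in_remission and current.urine_protein_g_day > REMISSION_PROTEIN_G_DAY:
            fired.add("d_i")
        if (
            baseline.urine_protein_g_day is not None
            and current.urine_protein_g_day - baseline.urine_protein_g_day > 1.0
        ):
            fired.add("d_i")

    if current.scr_mg_dl is not None and baseline.scr_mg_dl is not None:
        evaluable.add("d_iii")
        if current.scr_mg_dl > 1.25 * baseline.scr_mg_dl:
            fired.add("d_iii")

    return frozenset(fired), frozenset(evaluable)


def outcome_from_criteria(fired: frozenset[str] | set[str]) -> str:
    """Outcome category from fired sub-criteria, precedence c > d > a > b."""
    fired = set(fired)
    if fired & C_CRITERIA:
        return "deterioration"
    if fired & D_CRITERIA:
        return "relapse"
    if fired & A_CRITERIA:
        return "improvement"
    return "no_change"


def classify_outcome(
    current: VisitRecord,
    baseline: VisitRecord,
    in_remission: bool = False,
    *,
    egfr_current: float | None = None,
    egfr_baseline: float | None = None,
) -> OutcomeCategory:
    """Renal-outcome category for a visit against its baseline."""
    fired, evaluable = evaluate_criteria(
        current,
        baseline,
        in_remission,
        egfr_current=egfr_current,
        egfr_baseline=egfr_baseline,
    )
    if not evaluable:
        raise IndeterminateError("no renal-outcome criterion is evaluable for this pair")
    return OutcomeCategory(outcome_from_criteria(fired), fired)


def classify_episode(meets_ln_criteria: bool, outcome: OutcomeCategory | None) -> EpisodeLabel:
    """Episode label from the clinical LN flag and the renal outcome."""
    if not meets_ln_criteria:
        return EpisodeLabel("non_ln")
    if outcome is None:
        raise ValidationError("LN episode requires a renal-outcome category")
    label = (
        "inactive_ln"
        if outcome.category in ("improvement", "no_change")
        else "active_ln"
    )
    return EpisodeLabel(label, outcome)


def _in_remission(visit: VisitRecord) -> bool:
    # complete-remission proxy: quiescent sediment and sub-nephrotic protein
    sed = _visit_sediment(visit)
    protein_ok = (
        visit.urine_protein_g_day is not None
        and visit.urine_protein_g_day <= REMISSION_PROTEIN_G_DAY
    )
    return sed == "inactive" and protein_ok


def label_episodes(
    patient: PatientRecord,
    *,
    baseline_mode: str = "prior",
    window_days: int = EXCLUSION_WINDOW_DAYS,
) -> list[EpisodeLabel]:
    """Label every visit of a patient: exclusion, outcome, episode class.

    ``baseline_mode`` picks the reference for %-change criteria: ``"prior"``
    (most recent earlier non-excluded visit, the default) or ``"first"``
    (the first non-excluded visit).  The patient's first usable visit is its
    own baseline and is labelled through the no-change pathway.
    """
    if baseline_mode not in ("prior", "first"):
        raise ValidationError(f"baseline_mode must be 'prior' or 'first', got {baseline_mode!r}")
    labels: list[EpisodeLabel] = []
    baseline: VisitRecord | None = None
    first_kept: VisitRecord | None = None
    remission = False
    for visit in patient.visits:
        reason = exclusion_filter(patient, visit, window_days=window_days)
        if reason != "none":
            labels.append(EpisodeLabel("non_ln", excluded=True, exclusion_reason=reason))
            continue
        meets = True if visit.meets_ln_criteria is None else visit.meets_ln_criteria
        ref = baseline if baseline_mode == "prior" else first_kept
        if ref is None:
            outcome = OutcomeCategory("no_change", frozenset())
        else:
            try:
                e_cur = egfr_for_visit(patient, visit).value
            except InsufficientDataError:
                e_cur = None
            try:
                e_ref = egfr_for_visit(patient, ref).value
            except InsufficientDataError:
                e_ref = None
            try:
                outcome = classify_outcome(
                    visit, ref, remission, egfr_current=e_cur, egfr_baseline=e_ref
                )
            except IndeterminateError:
                labels.append(
                    EpisodeLabel("non_ln", excluded=True, exclusion_reason="indeterminate")
                )
                continue
        labels.append(classify_episode(meets, outcome))
        remission = _in_remission(visit)
        if first_kept is None:
            first_kept = visit
        baseline = visit
    return labels


def episode_report(patient: PatientRecord, labels: list[EpisodeLabel]) -> list[dict]:
    """JSON-serializable per-visit label report."""
    out = []
    for visit, lab in zip(patient.visits, labels):
        out.append(
            {
                "patient_id": patient.patient_id,
                "date": visit.date.isoformat(),
                "label": lab.label,
                "criteria_met": sorted(lab.outcome.criteria_met) if lab.outcome else [],
                "outcome": lab.outcome.category if lab.outcome else None,
                "excluded": lab.excluded,
                "exclusion_reason": lab.exclusion_reason,
            }
        )
    return out
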