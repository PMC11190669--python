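"""Estimated glomerular filtration rate (eGFR) and per-patient ΔeGFR.

Two creatinine-based equations are dispatched on exact age at the visit:

* **bedside Schwartz** (pediatric, age < 18 y):  eGFR = 0.413 · height / Scr
  with height in cm and serum creatinine in mg/dL;
* **CKD-EPI 2009** (adult, age ≥ 18 y):
  eGFR = 141 · min(Scr/κ, 1)^α · max(Scr/κ, 1)^−1.209 · 0.993^age
  · 1.018 [female] (· 1.159 if the optional Black-race coefficient of the
  original equation is enabled; off by default),
  κ = 0.7 (F) / 0.9 (M), α = −0.329 (F) / −0.411 (M).

Both return mL/min/1.73 m².  ΔeGFR is last-minus-first over follow-up, so
negative values are decline.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import Cohort, PatientRecord, VisitRecord
from .errors import DispatchError, DomainError, InsufficientDataError

SCHWARTZ_K = 0.413
ADULT_AGE = 18.0


@dataclass(frozen=True)
class EGFRResult:
    value: float  # mL/min/1.73 m^2
    formula: str  # "schwartz" | "ckd_epi"
    age_years: float


@dataclass(frozen=True)
class DeltaEGFR:
    value: float  # signed, last - first
    span_years: float
    n_points: int


def egfr_schwartz(height_cm: float, scr_mg_dl: float) -> float:
    """Bedside Schwartz eGFR, k = 0.413."""
    if height_cm <= 0 or scr_mg_dl <= 0:
        raise DomainError(
            f"height_cm and scr_mg_dl must be > 0 (got {height_cm}, {scr_mg_dl})"
        )
    return SCHWARTZ_K * height_cm / scr_mg_dl


def egfr_ckd_epi(
    scr_mg_dl: float,
    age_years: float,
    sex: str,
    *,
    black_race_coefficient: bool = False,
) -> float:
    """CKD-EPI 2009 creatinine eGFR for adults (age >= 18)."""
    if scr_mg_dl <= 0:
        raise DomainError(f"scr_mg_dl must be > 0, got {scr_mg_dl}")
    if age_years < ADULT_AGE:
        raise DispatchError(
            f"CKD-EPI applies at age >= {ADULT_AGE}; use egfr_schwartz below it"
        )
    if sex == "female":
        kappa, alpha, sex_coef = 0.7, -0.329, 1.018
    elif sex == "male":
        kappa, alpha, sex_coef = 0.9, -0.411, 1.0
    else:
        raise DomainError(f"sex must be 'female' or 'male', got {sex!r}")
    ratio = scr_mg_dl / kappa
    value = (
        141.0
        * min(ratio, 1.0) ** alpha
        * max(ratio, 1.0) ** -1.209
        * 0.993**age_years
        * sex_coef
    )
    if black_race_coefficient:
        value *= 1.159
    return value


def invert_egfr_ckd_epi(
    egfr: float, age_years: float, sex: str
) -> float:
    """Serum creatinine (mg/dL) giving a target CKD-EPI eGFR; exact inverse.

    The equation is strictly decreasing in creatinine, so the piecewise
    branches invert analytically: the branch is picked by comparing the
    target with the value at the knot Scr = κ.
    """
    if egfr <= 0:
        raise DomainError(f"egfr must be > 0, got {egfr}")
    if sex == "female":
        kappa, alpha, sex_coef = 0.7, -0.329, 1.018
    else:
        kappa, alpha, sex_coef = 0.9, -0.411, 1.0
    base = 141.0 * 0.993**age_years * sex_coef  # value at Scr = kappa
    if egfr >= base:
        return kappa * (egfr / base) ** (1.0 / alpha)
    return kappa * (egfr / base) ** (1.0 / -1.209)


def egfr_for_visit(patient: PatientRecord, visit: VisitRecord) -> EGFRResult:
    """Age-dispatched eGFR for one visit; records the formula used.

    Pediatric visits without a height raise rather than silently falling
    back to the adult equation.
    """
    if visit.scr_mg_dl is None:
        raise InsufficientDataError(
            f"patient {patient.patient_id} visit {visit.date}: no serum creatinine"
        )
    age = patient.age_at(visit.date)
    if age < ADULT_AGE:
        if visit.height_cm is None:
            raise InsufficientDataError(
                f"patient {patient.patient_id} visit {visit.date}: "
                "height required for pediatric (Schwartz) eGFR"
            )
        return EGFRResult(egfr_schwartz(visit.height_cm, visit.scr_mg_dl), "schwartz", age)
    return EGFRResult(egfr_ckd_epi(visit.scr_mg_dl, age, patient.sex), "ckd_epi", age)


def egfr_series(patient: PatientRecord) -> list[tuple[VisitRecord, EGFRResult]]:
    """All computable eGFR points for a patient, in visit order.

    Visits lacking creatinine (or height, when pediatric) are skipped.
    """
    out = []
    for v in patient.visits:
        try:
            out.append((v, egfr_for_visit(patient, v)))
        except InsufficientDataError:
            continue
    return out


def delta_egfr(patient: PatientRecord) -> DeltaEGFR:
    """Last minus first eGFR over follow-up (negative = decline)."""
    series = egfr_series(patient)
    if len(series) < 2:
        raise InsufficientDataError(
            f"patient {patient.patient_id}: need >= 2 eGFR points, have {len(series)}"
        )
    first_v, first = series[0]
    last_v, last = series[-1]
    span = (last_v.date - first_v.date).days / 365.25
    return DeltaEGFR(last.value - first.value, span, len(series))


def egfr_span_years(patient: PatientRecord) -> float:
    """Years between the first and last computable eGFR (0 if < 2 points)."""
    series = egfr_series(patient)
    if len(series) < 2:
        return 0.0
    return (series[-1][0].date - series[0][0].date).days / 365.25


def long_term_subcohort(cohort: Cohort, min_span_years: float = 1.0) -> Cohort:
    """Patients whose first-to-last eGFR span strictly exceeds ``min_span_years``."""
    kept = [p for p in cohort.patients if egfr_span_years(p) > min_span_years]
    return Cohort(kept, provenance=f"{cohort.provenance}|span>{min_span_years}y")
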