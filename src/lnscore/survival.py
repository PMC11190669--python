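"""Time-to-event analysis of eGFR decline.

The event is bespoke: a patient "fails" at the first visit where the eGFR
has declined from its first measured value by at least a threshold — in the
stratified analysis, each collapsed score group's own mean ΔeGFR decline
magnitude.  Patients who never reach the threshold are right-censored at
their last eGFR measurement.  Curves are Kaplan–Meier product-limit
estimates; groups are compared with the two-group log-rank test.

Conventions: time origin is the first computable eGFR, times are in years
(days / 365.25), censorings at a tied time are ranked after events, and the
median is the earliest time where S(t) ≤ 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .cohort import Cohort, PatientRecord
from .errors import DomainError, InsufficientDataError, ValidationError
from .renal import delta_egfr, egfr_series
from .scoring import GroupSummary, SubsetScore, group_summary as _group_summary


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    time: float  # years from first eGFR measurement
    event: bool  # True = decline threshold reached, False = censored
    group: int | None = None


@dataclass
class KMCurve:
    event_times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # n at risk just before each event time
    censor_marks: np.ndarray  # censoring times
    median: float | None  # earliest t with S(t) <= 0.5, None if never

    def survival_at(self, t: float) -> float:
        """Step-function value S(t) (right-continuous)."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    p_value: float
    df: int = 1


def derive_event(
    patient: PatientRecord, threshold_decline: float, group: int | None = None
) -> SurvivalRecord:
    """Scan a patient's eGFR stream for the decline-threshold crossing.

    The event fires at the first visit where eGFR − baseline ≤ −threshold
    (reaching the threshold counts); otherwise the record is censored at the
    last eGFR point.
    """
    if threshold_decline <= 0:
        raise DomainError(f"threshold_decline must be > 0, got {threshold_decline}")
    series = egfr_series(patient)
    if len(series) < 2:
        raise InsufficientDataError(
            f"patient {patient.patient_id}: need >= 2 eGFR points"
        )
    t0 = series[0][0].date
    baseline = series[0][1].value
    for visit, res in series[1:]:
        if res.value - baseline <= -threshold_decline:
            return SurvivalRecord(
                patient.patient_id, (visit.date - t0).days / 365.25, True, group
            )
    last = series[-1][0].date
    return SurvivalRecord(patient.patient_id, (last - t0).days / 365.25, False, group)


def km_estimate(records: list[SurvivalRecord]) -> KMCurve:
    """Kaplan–Meier product-limit estimator S(t) = Π (1 − dᵢ/nᵢ)."""
    if not records:
        raise InsufficientDataError("no survival records")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    order = np.lexsort((~events, times))  # ties: events before censorings
    times, events = times[order], events[order]

    event_times, surv, at_risk = [], [], []
    s = 1.0
    n = len(times)
    i = 0
    while i < n:
        t = times[i]
        d = c = 0
        while i < n and times[i] == t:
            if events[i]:
                d += 1
            else:
                c += 1
            i += 1
        n_before = n - np.searchsorted(times, t, side="left")
        if d > 0:
            s *= 1.0 - d / n_before
            event_times.append(t)
            surv.append(s)
            at_risk.append(n_before)
    surv_arr = np.array(surv)
    median = None
    reached = np.nonzero(surv_arr <= 0.5)[0]
    if reached.size:
        median = float(np.array(event_times)[reached[0]])
    return KMCurve(
        np.array(event_times),
        surv_arr,
        np.array(at_risk),
        np.sort(times[~events]),
        median,
    )


def logrank_test(group_a: list[SurvivalRecord], group_b: list[SurvivalRecord]) -> LogRankResult:
    """Two-group log-rank test (hypergeometric variance, χ² with 1 df)."""
    ta = np.array([r.time for r in group_a])
    ea = np.array([r.event for r in group_a])
    tb = np.array([r.time for r in group_b])
    eb = np.array([r.event for r in group_b])
    all_event_times = np.unique(np.concatenate([ta[ea], tb[eb]]))
    if all_event_times.size == 0:
        raise InsufficientDataError("log-rank undefined: no events in either group")
    o_minus_e = 0.0
    var = 0.0
    for t in all_event_times:
        n1 = int((ta >= t).sum())
        n2 = int((tb >= t).sum())
        d1 = int(((ta == t) & ea).sum())
        d2 = int(((tb == t) & eb).sum())
        n = n1 + n2
        d = d1 + d2
        if n1 == 0 or n2 == 0 or n < 2:
            continue
        o_minus_e += d1 - d * n1 / n
        var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var == 0:
        return LogRankResult(0.0, 1.0)
    chi = o_minus_e**2 / var
    return LogRankResult(float(chi), float(sps.chi2.sf(chi, 1)))


def stratified_km(
    cohort: Cohort,
    scores: list[SubsetScore],
    summary: GroupSummary | None = None,
    *,
    common_threshold: float | None = None,
) -> tuple[dict[int, KMCurve], LogRankResult, dict[int, float], list[SurvivalRecord]]:
    """Group-stratified KM curves with group-specific decline thresholds.

    Each collapsed score group's event threshold is that group's own mean
    ΔeGFR decline magnitude (pass ``common_threshold`` to force a single
    threshold as a sensitivity analysis).  Returns the per-group curves, the
    log-rank comparison, the thresholds used, and the per-patient records.
    """
    group_of = {s.patient_id: s.group for s in scores}
    patients = [p for p in cohort.patients if p.patient_id in group_of]
    groups_present = sorted({group_of[p.patient_id] for p in patients})
    if len(groups_present) < 2:
        raise ValidationError(
            f"need both collapsed groups; present: {groups_present}"
        )
    if summary is None:
        deltas = {p.patient_id: delta_egfr(p) for p in patients}
        summary = _group_summary(scores, deltas)
    thresholds: dict[int, float] = {}
    for g in groups_present:
        if common_threshold is not None:
            thresholds[g] = common_threshold
        else:
            mag = summary.decline_magnitude(g)
            if mag <= 0:
                raise ValidationError(
                    f"group {g}: mean ΔeGFR is not a decline; no event threshold"
                )
            thresholds[g] = mag
    records = [
        derive_event(p, thresholds[group_of[p.patient_id]], group_of[p.patient_id])
        for p in patients
    ]
    curves = {
        g: km_estimate([r for r in records if r.group == g]) for g in groups_present
    }
    lr = logrank_test(
        [r for r in records if r.group == groups_present[0]],
        [r for r in records if r.group == groups_present[1]],
    )
    return curves, lr, thresholds, records


def plot_km(curves: dict[int, KMCurve], path, title: str = "eGFR decline to group-mean ΔeGFR") -> None:
    """Step plot of the stratified curves with censor tick marks (SVG/PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for g, curve in sorted(curves.items()):
        t = np.concatenate([[0.0], curve.event_times])
        s = np.concatenate([[1.0], curve.survival])
        line, = ax.step(t, s, where="post", label=f"Group {g}")
        marks = [(ct, curve.survival_at(ct)) for ct in curve.censor_marks]
        if marks:
            ax.plot(*zip(*marks), "|", color=line.get_color(), markersize=8)
    ax.set_xlabel("Follow-up (years)")
    ax.set_ylabel("Probability of no threshold decline")
    ax.set_ylim(0, 1.05)
    ax.legend()
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
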