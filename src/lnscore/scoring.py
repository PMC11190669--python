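"""Median-split lymphocyte-subset scoring of renal-function decline risk.

Per patient, subset percentages are averaged over episodes.  Each candidate
subset is screened by regressing ΔeGFR on its patient-mean percentage; any
subset with a regression P < 0.1 enters the score.  For a subset positively
correlated with ΔeGFR, a mean above the cohort median scores 1 (≤ median
scores 0); for a negatively correlated subset the coding is reversed, so a
score point always marks the favourable side of the median.  Points are
summed (0–3 when three subsets are selected) and collapsed to Group 1
(sum 0–1, higher-risk profile) versus Group 2 (sum 2–3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import SUBSET_NAMES, PatientRecord
from .errors import ConfigError, InsufficientDataError
from .renal import DeltaEGFR
from .stats import ols_fit

#: the subsets the reference analysis carried into the score
DEFAULT_FORCED_SUBSETS = ("nk", "cd4_naive", "cd4_memory")


@dataclass
class SubsetMeans:
    patient_id: str
    means: dict[str, float]  # subset short name -> mean percentage
    n_episodes: int


@dataclass
class SubsetScreenResult:
    subset: str
    slope_sign: str  # "+", "-" or "0"
    p_value: float
    r_squared: float
    selected: bool


@dataclass
class SubsetScore:
    patient_id: str
    categories: dict[str, int]  # subset -> 0/1
    score_sum: int
    group: int  # 1 (sum 0-1) or 2 (sum 2-3)


@dataclass
class GroupSummary:
    """Per-score-sum and per-collapsed-group ΔeGFR summaries."""

    by_score: dict[int, tuple[int, float, float]] = field(default_factory=dict)
    by_group: dict[int, tuple[int, float, float]] = field(default_factory=dict)

    def decline_magnitude(self, group: int) -> float:
        """|mean ΔeGFR| of a collapsed group when the mean is a decline."""
        _, mean, _ = self.by_group[group]
        return -mean if mean < 0 else 0.0


def patient_mean_subsets(patient: PatientRecord, which_episodes=None) -> SubsetMeans:
    """Arithmetic mean of each subset percentage over a patient's panels.

    ``which_episodes`` optionally filters visits (callable VisitRecord -> bool).
    Visits without a panel are skipped; a panel missing one subset does not
    invalidate the others.
    """
    sums: dict[str, float] = {s: 0.0 for s in SUBSET_NAMES}
    counts: dict[str, int] = {s: 0 for s in SUBSET_NAMES}
    n_used = 0
    for visit in patient.visits:
        if visit.subsets is None:
            continue
        if which_episodes is not None and not which_episodes(visit):
            continue
        n_used += 1
        for s in SUBSET_NAMES:
            v = visit.subsets.get(s)
            if v is not None:
                sums[s] += v
                counts[s] += 1
    if n_used == 0:
        raise InsufficientDataError(
            f"patient {patient.patient_id}: no qualifying subset panel"
        )
    means = {s: sums[s] / counts[s] for s in SUBSET_NAMES if counts[s] > 0}
    return SubsetMeans(patient.patient_id, means, n_used)


def screen_subsets(
    means: list[SubsetMeans],
    deltas: dict[str, DeltaEGFR | float],
    alpha: float = 0.1,
    subsets: tuple[str, ...] = SUBSET_NAMES,
) -> list[SubsetScreenResult]:
    """Regress ΔeGFR on each subset's patient-mean percentage.

    Simple least squares with an F-test per subset (equivalently the Pearson
    correlation t-test); a subset is selected when P < ``alpha``.
    """
    if set(m.patient_id for m in means) != set(deltas):
        raise KeyError("patient sets of subset means and deltas differ")
    dvals = {
        pid: (d.value if isinstance(d, DeltaEGFR) else float(d))
        for pid, d in deltas.items()
    }
    out = []
    for s in subsets:
        xs, ys = [], []
        for m in means:
            if s in m.means:
                xs.append(m.means[s])
                ys.append(dvals[m.patient_id])
        fit = ols_fit(xs, ys)
        sign = "+" if fit.slope > 0 else ("-" if fit.slope < 0 else "0")
        out.append(
            SubsetScreenResult(s, sign, fit.p_value, fit.r_squared, fit.p_value < alpha)
        )
    return out


def category_score(mean_pct: float, cohort_median: float, sign: str) -> int:
    """0/1 category from a median split, oriented by the correlation sign.

    Positive sign: above the median scores 1, at or below scores 0.
    Negative sign: the coding flips.
    """
    above = mean_pct > cohort_median
    if sign == "+":
        return 1 if above else 0
    return 0 if above else 1


def score_cohort(
    means: list[SubsetMeans],
    screen: list[SubsetScreenResult],
    forced_subsets: tuple[str, ...] | None = None,
    forced_signs: dict[str, str] | None = None,
) -> list[SubsetScore]:
    """Score every patient on the selected (or forced) subsets.

    Medians are computed over the scored patients themselves.  Score sums of
    0–1 collapse to Group 1, 2–3 to Group 2 (with k selected subsets the
    split is at sum < k/2 + 1/2 versus above, i.e. floor(k/2) + 1).

    ``forced_signs`` overrides the data-estimated correlation signs with a
    fixed orientation (e.g. protective NK/memory, harmful naive).  Because
    the data-driven sign is aligned to the same ΔeGFR the groups are later
    compared on, fixed signs are required whenever the grouping must be
    independent of the outcome under a null — e.g. in calibration studies.
    """
    by_name = {r.subset: r for r in screen}
    if forced_subsets is not None:
        missing = [s for s in forced_subsets if s not in by_name]
        if missing:
            raise ConfigError(f"forced subsets absent from the screen: {missing}")
        chosen = [by_name[s] for s in forced_subsets]
    else:
        chosen = [r for r in screen if r.selected]
    if not chosen:
        raise ConfigError("no subset selected by the screen and none forced")
    signs = {
        r.subset: (forced_signs or {}).get(r.subset, r.slope_sign) for r in chosen
    }
    medians = {}
    for r in chosen:
        vals = [m.means[r.subset] for m in means if r.subset in m.means]
        medians[r.subset] = float(np.median(vals))
    k = len(chosen)
    cut = k // 2  # sums 0..cut -> Group 1; k=3 gives {0,1} vs {2,3}
    scores = []
    for m in means:
        cats = {
            r.subset: category_score(m.means[r.subset], medians[r.subset], signs[r.subset])
            for r in chosen
        }
        total = sum(cats.values())
        scores.append(SubsetScore(m.patient_id, cats, total, 1 if total <= cut else 2))
    return scores


def group_summary(
    scores: list[SubsetScore], deltas: dict[str, DeltaEGFR | float]
) -> GroupSummary:
    """n, mean and sample SD of ΔeGFR per score sum and per collapsed group."""
    dvals = {
        pid: (d.value if isinstance(d, DeltaEGFR) else float(d))
        for pid, d in deltas.items()
    }
    missing = [s.patient_id for s in scores if s.patient_id not in dvals]
    if missing:
        raise KeyError(f"no ΔeGFR for scored patients: {missing}")
    out = GroupSummary()
    for key, attr in (("score_sum", "by_score"), ("group", "by_group")):
        buckets: dict[int, list[float]] = {}
        for s in scores:
            buckets.setdefault(getattr(s, key), []).append(dvals[s.patient_id])
        for g, vals in sorted(buckets.items()):
            arr = np.asarray(vals)
            sd = float(arr.std(ddof=1)) if arr.size > 1 else float("nan")
            getattr(out, attr)[g] = (int(arr.size), float(arr.mean()), sd)
    return out
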