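"""Domain types for longitudinal SLE/lupus-nephritis cohorts and CSV interchange.

A cohort is a list of patients; each patient carries demographics plus an
ordered stream of clinic visits.  One visit holds the labs, urinalysis, the
peripheral-blood lymphocyte-subset panel (already-gated percentages), therapy
events and infection flags used downstream by the episode classifier, the
eGFR module and the subset-scoring system.

Interchange format: one long-format RFC-4180 CSV, one row per visit, with
patient-level constants (id, sex, birth date) repeated on every row.  Missing
values are empty cells, never zero — zero is a legal lab value.  Dates are
ISO-8601; ages are exact year fractions (days / 365.25).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, fields

import pandas as pd

from .errors import SchemaError, ValidationError

DAYS_PER_YEAR = 365.25

#: subset panel short names, in canonical column order
SUBSET_NAMES = (
    "t",
    "b",
    "nk",
    "cd4_total",
    "cd4_naive",
    "cd4_memory",
    "cd3cd8",
    "gd_t",
)

THERAPY_EVENTS = ("none", "rituximab", "steroid_pulse")


@dataclass
class SubsetPanel:
    """Lymphocyte subset percentages from one flow-cytometry panel.

    Percentages are of total lymphocytes.  Because naive and memory CD4+ T
    gates overlap imperfectly with the total CD4+ gate, their sum may exceed
    the total by a small assay tolerance (default 5 percentage points).
    """

    pct_t: float | None = None
    pct_b: float | None = None
    pct_nk: float | None = None
    pct_cd4_total: float | None = None
    pct_cd4_naive: float | None = None
    pct_cd4_memory: float | None = None
    pct_cd3cd8: float | None = None
    pct_gd_t: float | None = None

    def validate(self, composition_tol: float = 5.0) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValidationError(f"{f.name}={v} outside [0, 100]")
        if (
            self.pct_cd4_naive is not None
            and self.pct_cd4_memory is not None
            and self.pct_cd4_total is not None
        ):
            if self.pct_cd4_naive + self.pct_cd4_memory > self.pct_cd4_total + composition_tol:
                raise ValidationError(
                    "naive + memory CD4+ exceeds total CD4+ beyond tolerance: "
                    f"{self.pct_cd4_naive} + {self.pct_cd4_memory} > "
                    f"{self.pct_cd4_total} + {composition_tol}"
                )

    def get(self, name: str) -> float | None:
        """Percentage for a canonical subset short name (e.g. ``"nk"``)."""
        return getattr(self, f"pct_{name}")

    def is_empty(self) -> bool:
        return all(getattr(self, f.name) is None for f in fields(self))


@dataclass
class VisitRecord:
    """One clinical episode: labs, urinalysis, subset panel and flags."""

    date: dt.date
    height_cm: float | None = None
    scr_mg_dl: float | None = None
    urine_rbc_hpf: float | None = None
    urine_wbc_hpf: float | None = None
    cellular_casts: float | None = None
    dysmorphic_rbc: bool = False
    upcr: float | None = None
    urine_protein_g_day: float | None = None
    igg_mg_dl: float | None = None
    anti_dsdna_iu_ml: float | None = None
    c3_mg_dl: float | None = None
    c4_mg_dl: float | None = None
    wbc_k_ul: float | None = None
    hb_g_dl: float | None = None
    platelet_k_ul: float | None = None
    esr_mm_hr: float | None = None
    crp_mg_dl: float | None = None
    sledai: int | None = None
    subsets: SubsetPanel | None = None
    therapy_event: str = "none"
    acute_infection: bool = False
    meets_ln_criteria: bool | None = None

    def __post_init__(self) -> None:
        if self.scr_mg_dl is not None and self.scr_mg_dl <= 0:
            raise ValidationError(f"scr_mg_dl must be > 0, got {self.scr_mg_dl}")
        for name in ("urine_rbc_hpf", "urine_wbc_hpf", "cellular_casts"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")
        if self.sledai is not None and self.sledai < 0:
            raise ValidationError(f"sledai must be >= 0, got {self.sledai}")
        if self.therapy_event not in THERAPY_EVENTS:
            raise ValidationError(f"unknown therapy_event {self.therapy_event!r}")
        if self.subsets is not None:
            if self.subsets.is_empty():
                self.subsets = None
            else:
                self.subsets.validate()


@dataclass
class PatientRecord:
    """Demographics plus visits; the unit of clustering and survival analysis."""

    patient_id: str
    sex: str
    birth_date: dt.date
    visits: list[VisitRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValidationError(f"sex must be 'female' or 'male', got {self.sex!r}")
        self.visits.sort(key=lambda v: v.date)
        dates = [v.date for v in self.visits]
        if len(set(dates)) != len(dates):
            raise ValidationError(f"patient {self.patient_id}: duplicate visit dates")

    def age_at(self, date: dt.date) -> float:
        """Exact age in years (days / 365.25) on a given date."""
        return (date - self.birth_date).days / DAYS_PER_YEAR


@dataclass
class Cohort:
    """A set of patients plus free-text provenance (file path or generator seed)."""

    patients: list[PatientRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate patient_id in cohort")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def get(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)


# ---------------------------------------------------------------------------
# CSV interchange

_REQUIRED_COLUMNS = ("patient_id", "sex", "birth_date", "date", "scr_mg_dl")

_FLOAT_COLUMNS = (
    "height_cm",
    "scr_mg_dl",
    "urine_rbc_hpf",
    "urine_wbc_hpf",
    "cellular_casts",
    "upcr",
    "urine_protein_g_day",
    "igg_mg_dl",
    "anti_dsdna_iu_ml",
    "c3_mg_dl",
    "c4_mg_dl",
    "wbc_k_ul",
    "hb_g_dl",
    "platelet_k_ul",
    "esr_mm_hr",
    "crp_mg_dl",
)

_BOOL_COLUMNS = ("dysmorphic_rbc", "acute_infection")

COLUMNS = (
    "patient_id",
    "sex",
    "birth_date",
    "date",
    *_FLOAT_COLUMNS,
    "sledai",
    *(f"pct_{s}" for s in SUBSET_NAMES),
    "therapy_event",
    *_BOOL_COLUMNS,
    "meets_ln_criteria",
)


def _parse_float(v) -> float | None:
    if v is None or (isinstance(v, float) and pd.isna(v)):
        return None
    s = str(v).strip()
    if s == "":
        return None
    try:
        return float(s)
    except ValueError:
        return None  # unparseable optional field -> missing, never zero


def _parse_bool(v, default: bool | None = False) -> bool | None:
    if v is None or (isinstance(v, float) and pd.isna(v)):
        return default
    s = str(v).strip().lower()
    if s == "":
        return default
    return s in ("true", "1", "yes", "t")


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return str(v)
    if isinstance(v, dt.date):
        return v.isoformat()
    return repr(v) if isinstance(v, float) else str(v)


def read_cohort(path, *, delimiter: str = ",") -> Cohort:
    """Read a long-format cohort CSV into a :class:`Cohort`.

    Visits are grouped per patient and sorted by date.  Rows with an empty
    ``date`` declare a patient without visits.  Unparseable optional fields
    become missing values.

    Raises
    ------
    SchemaError
        if a required column is absent.
    ValidationError
        on duplicate (patient_id, date) pairs.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing from {path}")

    patients: dict[str, PatientRecord] = {}
    seen: set[tuple[str, str]] = set()
    for row in df.itertuples(index=False):
        rec = row._asdict()
        pid = str(rec["patient_id"]).strip()
        sex = str(rec["sex"]).strip().lower()
        birth = dt.date.fromisoformat(str(rec["birth_date"]).strip())
        if pid not in patients:
            patients[pid] = PatientRecord(pid, sex, birth, visits=[])
        date_s = str(rec["date"]).strip()
        if date_s == "":
            continue  # demographics-only row
        if (pid, date_s) in seen:
            raise ValidationError(f"duplicate (patient_id, date) = ({pid}, {date_s})")
        seen.add((pid, date_s))

        panel = SubsetPanel(
            **{f"pct_{s}": _parse_float(rec.get(f"pct_{s}")) for s in SUBSET_NAMES}
        )
        sledai = _parse_float(rec.get("sledai"))
        visit = VisitRecord(
            date=dt.date.fromisoformat(date_s),
            sledai=None if sledai is None else int(sledai),
            subsets=None if panel.is_empty() else panel,
            therapy_event=(str(rec.get("therapy_event", "")).strip() or "none"),
            dysmorphic_rbc=bool(_parse_bool(rec.get("dysmorphic_rbc"))),
            acute_infection=bool(_parse_bool(rec.get("acute_infection"))),
            meets_ln_criteria=_parse_bool(rec.get("meets_ln_criteria"), default=None),
            **{c: _parse_float(rec.get(c)) for c in _FLOAT_COLUMNS},
        )
        patients[pid].visits.append(visit)

    out = []
    for p in patients.values():
        # re-run ordering/duplicate validation after accumulation
        out.append(PatientRecord(p.patient_id, p.sex, p.birth_date, p.visits))
    return Cohort(out, provenance=str(path))


def write_cohort(cohort: Cohort, path, *, delimiter: str = ",") -> None:
    """Write a cohort as a long-format CSV; inverse of :func:`read_cohort`.

    Floats are written with full (repr) precision so the round trip is exact.
    """
    lines = [delimiter.join(COLUMNS)]
    for p in cohort.patients:
        if not p.visits:
            row = {"patient_id": p.patient_id, "sex": p.sex, "birth_date": p.birth_date}
            lines.append(delimiter.join(_fmt(row.get(c)) for c in COLUMNS))
        for v in p.visits:
            row = {
                "patient_id": p.patient_id,
                "sex": p.sex,
                "birth_date": p.birth_date,
                "date": v.date,
                "sledai": v.sledai,
                "therapy_event": v.therapy_event,
                "dysmorphic_rbc": v.dysmorphic_rbc,
                "acute_infection": v.acute_infection,
                "meets_ln_criteria": v.meets_ln_criteria,
            }
            for c in _FLOAT_COLUMNS:
                row[c] = getattr(v, c)
            for s in SUBSET_NAMES:
                row[f"pct_{s}"] = None if v.subsets is None else v.subsets.get(s)
            lines.append(delimiter.join(_fmt(row.get(c)) for c in COLUMNS))
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\n".join(lines) + "\n")
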