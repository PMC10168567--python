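"""Episode-level data model and cohort table I/O.

One row = one pulmonary-embolism (PE) episode in a patient with active cancer,
with the predictors measured immediately before the radiological diagnosis of
the PE and the outcome fields collected during follow-up.  The on-disk format
is a UTF-8 comma-separated table with a fixed snake_case header (see
``models/cohort_schema.yaml``): booleans are 0/1, sets are semicolon-joined
tokens, missing optional values are empty strings.

Validation is total: every row is either accepted or yields at least one named
:class:`ValidationIssue`.  In strict mode any issue aborts the read; otherwise
issues are collected on the returned table and offending rows are flagged.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd
import yaml

MONTH_DAYS = 30.44  # mean calendar month; the source analyses never define one
DAYS_30_IN_MONTHS = 30.0 / MONTH_DAYS

SEXES = {"male", "female"}
RECIST_VALUES = {"cr", "pr", "sd", "ned", "pd", "ne", "uk"}
RECIST_PROGRESSING = {"pd", "ne", "uk"}  # grouped vs {cr, pr, sd, ned}
PRESENTATIONS = {"suspected", "unsuspected_symptomatic", "unsuspected_asymptomatic"}
PE_SYMPTOMS = {"sudden_or_progressive_dyspnea", "chest_pain", "syncope"}
BLEED_STATUS = {"censored", "bleeding", "death_without_bleeding"}
RETHROMBOSIS_STATUS = {"censored", "rethrombosis", "death_without_rethrombosis"}

#: CSV columns, in canonical order.  (name, kind, required)
#: kind: str | int | float | bool | set | cat:<vocab>
_SCHEMA = [
    ("episode_id", "str", True),
    ("age", "int", True),
    ("sex", "cat:sex", True),
    ("ecog_ps", "int", True),
    ("tumor_type", "str", True),
    ("stage_iv", "bool", True),
    ("recist", "cat:recist", True),
    ("primary_resected", "bool", True),
    ("sbp", "float", True),
    ("hr", "float", True),
    ("rr", "float", True),
    ("spo2", "float", True),
    ("pe_symptoms", "set", True),
    ("presentation", "cat:presentation", True),
    ("clinically_relevant_bleeding", "bool", True),
    ("high_bleeding_risk", "bool", True),
    ("platelets", "float", True),
    ("other_admission_criterion", "bool", True),
    ("prior_anticoagulation", "bool", True),
    ("outpatient", "bool", True),
    ("complication_15d", "bool", True),
    ("complication_day", "int", False),
    ("death_30d", "bool", True),
    ("os_time", "float", False),
    ("os_event", "bool", False),
    ("bleed_time", "float", False),
    ("bleed_status", "cat:bleed", False),
    ("rethrombosis_time", "float", False),
    ("rethrombosis_status", "cat:rethrombosis", False),
]

COLUMNS = [name for name, _, _ in _SCHEMA]
_VOCABS = {
    "sex": SEXES,
    "recist": RECIST_VALUES,
    "presentation": PRESENTATIONS,
    "bleed": BLEED_STATUS,
    "rethrombosis": RETHROMBOSIS_STATUS,
}


class CohortValidationError(ValueError):
    """Raised in strict mode when a cohort file violates the schema."""

    def __init__(self, issues: list["ValidationIssue"]):
        self.issues = issues
        head = "; ".join(str(i) for i in issues[:5])
        more = f" (+{len(issues) - 5} more)" if len(issues) > 5 else ""
        super().__init__(f"cohort validation failed: {head}{more}")


@dataclass(frozen=True)
class ValidationIssue:
    row: Optional[int]  # 0-based data row, None for file-level issues
    field: str
    message: str

    def __str__(self) -> str:
        where = "file" if self.row is None else f"row {self.row}"
        return f"[{where}:{self.field}] {self.message}"


@dataclass
class PatientEpisode:
    """One PE episode: predictors at radiological diagnosis plus outcomes."""

    episode_id: str
    age: int
    sex: str
    ecog_ps: int
    tumor_type: str
    stage_iv: bool
    recist: str
    primary_resected: bool
    sbp: float
    hr: float
    rr: float
    spo2: float
    pe_symptoms: frozenset
    presentation: str
    clinically_relevant_bleeding: bool
    high_bleeding_risk: bool
    platelets: float
    other_admission_criterion: bool
    prior_anticoagulation: bool
    outpatient: bool
    complication_15d: bool
    complication_day: Optional[int] = None
    death_30d: bool = False
    os_time: Optional[float] = None
    os_event: Optional[bool] = None
    bleed_time: Optional[float] = None
    bleed_status: Optional[str] = None
    rethrombosis_time: Optional[float] = None
    rethrombosis_status: Optional[str] = None
    extras: dict = field(default_factory=dict)

    @property
    def recist_group(self) -> str:
        """'progressing' for {PD, NE, UK}, else 'controlled' ({CR, PR, SD, NED})."""
        return "progressing" if self.recist in RECIST_PROGRESSING else "controlled"

    @property
    def symptomatic(self) -> bool:
        return self.presentation != "unsuspected_asymptomatic"


@dataclass
class CohortTable:
    """Ordered collection of validated episodes with provenance metadata."""

    frame: pd.DataFrame
    source: Optional[str] = None
    issues: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frame)

    def episodes(self) -> Iterator[PatientEpisode]:
        for rec in self.frame.to_dict("records"):
            yield _record_to_episode(rec)

    def subset(self, mask) -> "CohortTable":
        return CohortTable(self.frame.loc[mask].reset_index(drop=True), self.source)


def _parse_bool(value, *, allow_missing=False):
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        if allow_missing:
            return None
        raise ValueError("missing boolean")
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in {"1", "true", "yes"}:
        return True
    if s in {"0", "false", "no"}:
        return False
    if s.replace(".", "", 1).isdigit():
        return bool(float(s))
    raise ValueError(f"not a boolean: {value!r}")


def _row_issues(rec: dict, row: int) -> list:
    """All invariant violations of one parsed record."""
    issues = []

    def bad(fieldname, msg):
        issues.append(ValidationIssue(row, fieldname, msg))

    if rec["age"] is not None and rec["age"] < 18:
        bad("age", f"age {rec['age']} below the adult eligibility floor of 18")
    if rec["ecog_ps"] is not None and not 0 <= rec["ecog_ps"] <= 4:
        bad("ecog_ps", f"ECOG-PS {rec['ecog_ps']} outside 0-4")
    for v in ("sbp", "hr", "rr", "platelets"):
        if rec[v] is not None and rec[v] < 0:
            bad(v, f"negative value {rec[v]}")
    if rec["spo2"] is not None and not 0 <= rec["spo2"] <= 100:
        bad("spo2", f"SpO2 {rec['spo2']} outside 0-100%")
    if rec["presentation"] == "unsuspected_asymptomatic" and rec["pe_symptoms"]:
        bad(
            "pe_symptoms",
            "asymptomatic presentation is inconsistent with recorded PE symptoms "
            + ";".join(sorted(rec["pe_symptoms"])),
        )
    if rec["complication_15d"] and rec["complication_day"] is not None:
        if not 0 <= rec["complication_day"] <= 15:
            bad("complication_day", f"day {rec['complication_day']} outside 0-15")
    if rec["death_30d"]:
        if rec["os_event"] is False:
            bad("os_event", "death within 30 days requires os_event")
        if rec["os_time"] is not None and rec["os_time"] > DAYS_30_IN_MONTHS + 1e-9:
            bad(
                "os_time",
                f"death within 30 days but os_time {rec['os_time']:.3f} months "
                f"> {DAYS_30_IN_MONTHS:.4f} (30/{MONTH_DAYS} day months)",
            )
    return issues


def _parse_record(raw: dict, row: int, issues: list) -> dict:
    rec = {}
    for name, kind, required in _SCHEMA:
        value = raw.get(name)
        missing = value is None or (isinstance(value, float) and pd.isna(value)) or value == ""
        try:
            if kind == "set" and missing:
                rec[name] = frozenset()  # an empty symptom set is a valid value
                continue
            if missing:
                if required:
                    issues.append(
                        ValidationIssue(row, name, "missing value for a required predictor")
                    )
                rec[name] = None
                continue
            if kind == "str":
                rec[name] = str(value).strip()
            elif kind == "int":
                rec[name] = int(float(value))
            elif kind == "float":
                rec[name] = float(value)
            elif kind == "bool":
                rec[name] = _parse_bool(value)
            elif kind == "set":
                tokens = {t.strip().lower() for t in str(value).split(";") if t.strip()}
                unknown = tokens - PE_SYMPTOMS
                if unknown:
                    issues.append(
                        ValidationIssue(row, name, f"unknown symptom token(s) {sorted(unknown)}")
                    )
                rec[name] = frozenset(tokens & PE_SYMPTOMS)
            elif kind.startswith("cat:"):
                vocab = _VOCABS[kind[4:]]
                s = str(value).strip().lower()
                if s not in vocab:
                    issues.append(
                        ValidationIssue(row, name, f"{s!r} not in {sorted(vocab)}")
                    )
                    rec[name] = None
                else:
                    rec[name] = s
        except (TypeError, ValueError) as exc:
            issues.append(ValidationIssue(row, name, str(exc)))
            rec[name] = None
    if rec.get("pe_symptoms") is None:
        rec["pe_symptoms"] = frozenset()
    return rec


def _record_to_episode(rec: dict) -> PatientEpisode:
    known = {f.name for f in dataclasses.fields(PatientEpisode)} - {"extras"}
    kwargs = {k: rec.get(k) for k in known}
    if isinstance(kwargs.get("pe_symptoms"), str):
        kwargs["pe_symptoms"] = frozenset(
            t for t in kwargs["pe_symptoms"].split(";") if t
        )
    kwargs["pe_symptoms"] = frozenset(kwargs.get("pe_symptoms") or ())
    extras = {k: v for k, v in rec.items() if k not in known and k != "_flagged"}
    return PatientEpisode(extras=extras, **kwargs)


def read_cohort(path, strict: bool = True) -> CohortTable:
    """Read and validate a cohort CSV.

    In strict mode any schema or invariant violation raises
    :class:`CohortValidationError`; otherwise issues are collected on the
    returned table and offending rows carry ``_flagged = True``.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    issues: list = []
    missing_cols = [c for c in COLUMNS if c not in raw.columns]
    for c in missing_cols:
        issues.append(ValidationIssue(None, c, "required column missing from header"))
    if missing_cols:
        raise CohortValidationError(issues)

    records = []
    flagged = []
    for row, raw_rec in enumerate(raw.to_dict("records")):
        before = len(issues)
        rec = _parse_record(raw_rec, row, issues)
        issues.extend(_row_issues(rec, row))
        # preserve unknown columns as extras
        for k, v in raw_rec.items():
            if k not in COLUMNS:
                rec[k] = v
        records.append(rec)
        flagged.append(len(issues) > before)

    ids = [r["episode_id"] for r in records]
    seen: set = set()
    for row, eid in enumerate(ids):
        if eid in seen:
            issues.append(
                ValidationIssue(row, "episode_id", f"duplicate id {eid!r}; one episode per subject")
            )
        seen.add(eid)

    if strict and issues:
        raise CohortValidationError(issues)

    frame = pd.DataFrame.from_records(records)
    frame["pe_symptoms"] = [";".join(sorted(r["pe_symptoms"])) for r in records]
    frame["_flagged"] = flagged
    return CohortTable(frame, source=str(path), issues=issues)


def cohort_from_episodes(episodes: Iterable[PatientEpisode]) -> CohortTable:
    records = []
    for ep in episodes:
        rec = dataclasses.asdict(ep)
        extras = rec.pop("extras", {})
        rec["pe_symptoms"] = ";".join(sorted(ep.pe_symptoms))
        rec.update(extras)
        records.append(rec)
    return CohortTable(pd.DataFrame.from_records(records))


def _format_cell(value, kind):
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    if kind == "bool":
        return str(int(bool(value)))
    if kind == "int":
        return str(int(value))
    if kind == "float":
        return repr(float(value))
    return str(value)


def write_cohort(table: CohortTable, path) -> None:
    """Write the canonical CSV form (lower-case categoricals, 0/1 booleans).

    ``read_cohort(write_cohort(t))`` is the identity on validated tables.
    """
    frame = table.frame
    out = pd.DataFrame(index=frame.index)
    for name, kind, _ in _SCHEMA:
        col = frame[name] if name in frame.columns else pd.Series([None] * len(frame))
        out[name] = [_format_cell(v, kind) for v in col]
    out.to_csv(path, index=False)


# --- endpoint derivation -----------------------------------------------------

#: event tokens understood by :func:`derive_endpoint_flags`; anything in this
#: vocabulary counts as a serious complication when it occurs after diagnosis.
SERIOUS_EVENTS = {
    "hypotension",
    "respiratory_insufficiency",
    "fibrinolysis",
    "major_bleeding",
    "rv_dysfunction",
    "acute_kidney_failure",
    "icu_admission",
    "cpr",
    "niv",
    "intubation",
    "sepsis",
    "death",
    "other_serious",
}


def derive_endpoint_flags(
    episode: PatientEpisode, untimed_policy: str = "outcome"
) -> PatientEpisode:
    """Recode raw timed events into predictor flags vs the 15-day endpoint.

    The episode's ``extras['events']`` may hold a semicolon-joined list of
    ``name@day`` tokens with ``day`` counted from the objective PE diagnosis.
    Events strictly before diagnosis (negative day, or ``@0pre`` for
    same-day-but-pre-imaging events) are folded into the predictor flag
    ``other_admission_criterion``; events on days 0-15 after diagnosis set
    ``complication_15d`` and ``complication_day`` (earliest).  Events with no
    timing follow ``untimed_policy`` ('outcome' or 'predictor').
    """
    if untimed_policy not in {"outcome", "predictor"}:
        raise ValueError(f"untimed_policy {untimed_policy!r}")
    raw = episode.extras.get("events", "")
    if not raw:
        return episode
    predictor = False
    days = []
    for token in str(raw).split(";"):
        token = token.strip()
        if not token:
            continue
        name, _, when = token.partition("@")
        if name not in SERIOUS_EVENTS:
            raise ValueError(f"unknown event token {name!r}")
        if when == "":
            if untimed_policy == "predictor":
                predictor = True
            else:
                days.append(0)
            continue
        if when.endswith("pre"):
            predictor = True
            continue
        day = int(when)
        if day < 0:
            predictor = True
        elif day <= 15:
            days.append(day)
    updates: dict = {}
    if predictor:
        updates["other_admission_criterion"] = True
    if days:
        updates["complication_15d"] = True
        updates["complication_day"] = min(days)
    return dataclasses.replace(episode, **updates) if updates else episode


def schema_path() -> Path:
    return Path(__file__).parent / "models" / "cohort_schema.yaml"


def load_schema() -> dict:
    with open(schema_path()) as fh:
        return yaml.safe_load(fh)
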