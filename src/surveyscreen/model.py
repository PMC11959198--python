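"""Survey-response data model and delimited-text IO.

A :class:`SurveyResponse` is one completed web-survey submission together with
the anti-fraud metadata the screening protocol consumes: submission IP and its
geolocated country, reCAPTCHA bot-likelihood score, completion time, contact
email, and the eligibility/consistency items (social and medical transition,
two fictitious-condition trap items, assigned sex, hormones started at initial
transition, past and current gender terms).

File conventions (shipped as ``data/response_schema.json``):

* CSV, UTF-8, header row, one row per completed response.
* Missing values are empty strings in files and ``None`` in memory.
* Multi-select fields are semicolon-separated tokens; tokens are case-folded
  and whitespace-trimmed on read and written back sorted, so a write/read
  round trip is the identity on valid records.
* Timestamps are ISO-8601 and stored in UTC.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterator, Optional

from .errors import IntegrityError, SchemaError

TRISTATE = ("yes", "no", "unsure")
SELF_REPORT_COUNTRIES = ("US", "CA", "OTHER")
LANGUAGES = ("en", "fr", "es")
SEXES = ("female", "male")
HORMONES = ("estrogen", "testosterone", "blockers", "none")

#: Canonical column order of the response CSV schema.
COLUMNS = (
    "response_id",
    "submitted_at",
    "ip_address",
    "geo_country",
    "self_report_country",
    "recaptcha_score",
    "duration_seconds",
    "email",
    "consent_contact",
    "language",
    "age_years",
    "sex_assigned_at_birth",
    "social_transition",
    "medical_transition",
    "hormones_initial_transition",
    "gender_terms_past",
    "gender_terms_current",
    "social_transition_year",
    "trap_chekalism",
    "trap_syndomitis",
    "geo_subdivision",
)

_WS = re.compile(r"\s+")


def normalize_term(term: str) -> str:
    """Normalize a free-text gender term: lowercase, collapse whitespace."""
    return _WS.sub(" ", term.strip().lower())


@dataclass
class SurveyResponse:
    """One completed survey row (metadata + eligibility/consistency answers)."""

    response_id: str
    submitted_at: datetime
    ip_address: str
    geo_country: Optional[str] = None            # ISO 3166-1 alpha-2 from IP geolocation
    self_report_country: Optional[str] = None    # "US" | "CA" | "OTHER"
    recaptcha_score: Optional[float] = None      # [0, 1]; lower = more bot-like
    duration_seconds: int = 0
    email: Optional[str] = None
    consent_contact: bool = False
    language: str = "en"
    age_years: Optional[int] = None
    sex_assigned_at_birth: Optional[str] = None  # "female" | "male"
    social_transition: str = "no"                # tri-state
    medical_transition: str = "no"               # tri-state
    hormones_initial_transition: frozenset = frozenset()
    gender_terms_past: frozenset = frozenset()
    gender_terms_current: frozenset = frozenset()
    social_transition_year: Optional[int] = None
    trap_chekalism: str = "no"                   # fictitious condition; "yes" flags fraud
    trap_syndomitis: str = "no"                  # fictitious condition; "yes" flags fraud
    geo_subdivision: Optional[str] = None

    def copy(self, **overrides) -> "SurveyResponse":
        return replace(self, **overrides)


@dataclass
class Cohort:
    """Ordered collection of responses with unique ``response_id`` values."""

    responses: list
    source_path: Optional[str] = None
    loaded_at: Optional[datetime] = None
    _by_id: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        seen = {}
        dups = []
        for r in self.responses:
            if r.response_id in seen:
                dups.append(r.response_id)
            seen[r.response_id] = r
        if dups:
            raise IntegrityError(f"duplicate response_id values: {sorted(set(dups))}")
        self._by_id = seen

    def __len__(self) -> int:
        return len(self.responses)

    def __iter__(self) -> Iterator[SurveyResponse]:
        return iter(self.responses)

    def __getitem__(self, response_id: str) -> SurveyResponse:
        return self._by_id[response_id]

    def __contains__(self, response_id: str) -> bool:
        return response_id in self._by_id

    @property
    def ids(self):
        return [r.response_id for r in self.responses]

    def subset(self, ids) -> "Cohort":
        keep = set(ids)
        return Cohort([r for r in self.responses if r.response_id in keep])


def validate_response(r: SurveyResponse) -> list:
    """Return stable violation codes; empty list iff all type invariants hold."""
    codes = []
    if r.recaptcha_score is not None and not (0.0 <= r.recaptcha_score <= 1.0):
        codes.append("recaptcha_out_of_range")
    if r.duration_seconds < 0:
        codes.append("negative_duration")
    for name in ("social_transition", "medical_transition", "trap_chekalism", "trap_syndomitis"):
        if getattr(r, name) not in TRISTATE:
            codes.append(f"bad_tristate_{name}")
    if r.self_report_country is not None and r.self_report_country not in SELF_REPORT_COUNTRIES:
        codes.append("bad_self_report_country")
    if r.language not in LANGUAGES:
        codes.append("bad_language")
    if r.sex_assigned_at_birth is not None and r.sex_assigned_at_birth not in SEXES:
        codes.append("bad_sex_assigned_at_birth")
    if any(h not in HORMONES for h in r.hormones_initial_transition):
        codes.append("bad_hormone_token")
    if r.age_years is not None and r.age_years < 0:
        codes.append("negative_age")
    if not r.response_id:
        codes.append("empty_response_id")
    return codes


# ---------------------------------------------------------------------------
# field parsing / formatting

def _parse_set(value: str) -> frozenset:
    return frozenset(
        normalize_term(tok) for tok in value.split(";") if tok.strip()
    )


def _fmt_set(value: frozenset) -> str:
    return ";".join(sorted(value))


def _parse_timestamp(value: str) -> datetime:
    dt = datetime.fromisoformat(value.replace("Z", "+00:00"))
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.astimezone(timezone.utc)


def _parse_tristate(value: str, name: str) -> str:
    v = value.strip().lower()
    if v not in TRISTATE:
        raise ValueError(f"{name} must be one of {TRISTATE}, got {value!r}")
    return v


def _parse_bool(value: str) -> bool:
    v = value.strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no", ""):
        return False
    raise ValueError(f"cannot parse boolean {value!r}")


def _row_to_response(row: dict) -> SurveyResponse:
    """Coerce one CSV row; raises ValueError with a column-naming message."""

    def opt(name, conv):
        raw = row.get(name, "")
        if raw is None or raw.strip() == "":
            return None
        try:
            return conv(raw.strip())
        except ValueError as exc:
            raise ValueError(f"{name}: {exc}") from exc

    def req(name, conv):
        raw = row.get(name, "")
        if raw is None or raw.strip() == "":
            raise ValueError(f"{name}: required value missing")
        try:
            return conv(raw.strip())
        except ValueError as exc:
            raise ValueError(f"{name}: {exc}") from exc

    return SurveyResponse(
        response_id=req("response_id", str),
        submitted_at=req("submitted_at", _parse_timestamp),
        ip_address=req("ip_address", str),
        geo_country=opt("geo_country", lambda v: v.upper()),
        self_report_country=opt("self_report_country", lambda v: v.upper()),
        recaptcha_score=opt("recaptcha_score", float),
        duration_seconds=req("duration_seconds", int),
        email=opt("email", str),
        consent_contact=_parse_bool(row.get("consent_contact", "")),
        language=req("language", lambda v: v.lower()),
        age_years=opt("age_years", int),
        sex_assigned_at_birth=opt("sex_assigned_at_birth", lambda v: v.lower()),
        social_transition=_parse_tristate(row.get("social_transition", ""), "social_transition"),
        medical_transition=_parse_tristate(row.get("medical_transition", ""), "medical_transition"),
        hormones_initial_transition=_parse_set(row.get("hormones_initial_transition", "")),
        gender_terms_past=_parse_set(row.get("gender_terms_past", "")),
        gender_terms_current=_parse_set(row.get("gender_terms_current", "")),
        social_transition_year=opt("social_transition_year", int),
        trap_chekalism=_parse_tristate(row.get("trap_chekalism", ""), "trap_chekalism"),
        trap_syndomitis=_parse_tristate(row.get("trap_syndomitis", ""), "trap_syndomitis"),
        geo_subdivision=opt("geo_subdivision", str),
    )


def _response_to_row(r: SurveyResponse) -> dict:
    def fmt(value):
        return "" if value is None else str(value)

    return {
        "response_id": r.response_id,
        "submitted_at": r.submitted_at.astimezone(timezone.utc).isoformat(),
        "ip_address": r.ip_address,
        "geo_country": fmt(r.geo_country),
        "self_report_country": fmt(r.self_report_country),
        "recaptcha_score": "" if r.recaptcha_score is None else repr(r.recaptcha_score),
        "duration_seconds": str(r.duration_seconds),
        "email": fmt(r.email),
        "consent_contact": "true" if r.consent_contact else "false",
        "language": r.language,
        "age_years": fmt(r.age_years),
        "sex_assigned_at_birth": fmt(r.sex_assigned_at_birth),
        "social_transition": r.social_transition,
        "medical_transition": r.medical_transition,
        "hormones_initial_transition": _fmt_set(r.hormones_initial_transition),
        "gender_terms_past": _fmt_set(r.gender_terms_past),
        "gender_terms_current": _fmt_set(r.gender_terms_current),
        "social_transition_year": fmt(r.social_transition_year),
        "trap_chekalism": r.trap_chekalism,
        "trap_syndomitis": r.trap_syndomitis,
        "geo_subdivision": fmt(r.geo_subdivision),
    }


@dataclass
class RejectedRow:
    """A data row that failed coercion or invariant checks on load."""

    line_number: int
    response_id: str
    reason: str


def load_responses(path, dialect: str = "excel"):
    """Read a response CSV.

    Returns ``(cohort, rejects)``: rows failing type coercion or the record
    invariants are collected as :class:`RejectedRow` entries, never silently
    dropped, so ``len(cohort) + len(rejects)`` equals the number of data rows.

    Raises
    ------
    SchemaError
        if a required column is absent from the header.
    IntegrityError
        if two accepted rows share a ``response_id``.
    """
    path = Path(path)
    accepted, rejects = [], []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, dialect=dialect)
        header = reader.fieldnames or []
        missing = [c for c in COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        for line_no, row in enumerate(reader, start=2):
            rid = (row.get("response_id") or "").strip()
            try:
                r = _row_to_response(row)
            except ValueError as exc:
                rejects.append(RejectedRow(line_no, rid, str(exc)))
                continue
            codes = validate_response(r)
            if codes:
                rejects.append(RejectedRow(line_no, rid, "; ".join(codes)))
                continue
            accepted.append(r)
    cohort = Cohort(accepted, source_path=str(path), loaded_at=datetime.now(timezone.utc))
    return cohort, rejects


def write_cohort(cohort: Cohort, path) -> Path:
    """Write a cohort CSV with deterministic column order and encodings.

    Missing values become empty strings; set-valued fields are ";"-joined in
    sorted order, so identical cohorts produce byte-identical files.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(COLUMNS), lineterminator="\n")
        writer.writeheader()
        for r in cohort:
            writer.writerow(_response_to_row(r))
    return path


def write_rejects(rejects, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["line_number", "response_id", "reason"])
        for rej in rejects:
            writer.writerow([rej.line_number, rej.response_id, rej.reason])
    return path
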