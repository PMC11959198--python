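"""Human-verification workflow for flagged responses, with readmission.

Responses excluded by the automated protocol that consented to follow-up and
left an email are queued for a live video screening interview. Each case is a
small state machine::

    FLAGGED -> INVITED -> SCHEDULED -> ATTENDED -> VERIFIED | FAILED
                                    -> NO_SHOW

The interview asks six questions (age; current country/subdivision/city;
country/subdivision/city when the survey was accessed; current gender terms;
whether and when the social transition happened; reasons for stopping or
reversing transition) and the answers are checked against the survey record.
Reasons (question 6) are recorded but never auto-scored; vagueness there is a
manual interviewer flag. VERIFIED cases are re-added to the analytic set;
NO_SHOW, FAILED, and unreachable responses stay excluded.

Scheduling metadata feeds two anomaly detectors drawn from observed fraud
behavior: sign-ups from a suspicious or geographically implausible timezone,
and sign-ups from email addresses that were never invited.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional
from zoneinfo import ZoneInfo

from .errors import IntegrityError, StateError
from .exclusion import Criterion, ExclusionReport
from .model import Cohort, SurveyResponse, normalize_term


class CaseState(str, Enum):
    FLAGGED = "FLAGGED"
    INVITED = "INVITED"
    SCHEDULED = "SCHEDULED"
    ATTENDED = "ATTENDED"
    NO_SHOW = "NO_SHOW"
    VERIFIED = "VERIFIED"
    FAILED = "FAILED"


_TRANSITIONS = {
    CaseState.FLAGGED: {CaseState.INVITED},
    CaseState.INVITED: {CaseState.SCHEDULED},
    CaseState.SCHEDULED: {CaseState.ATTENDED, CaseState.NO_SHOW},
    CaseState.ATTENDED: {CaseState.VERIFIED, CaseState.FAILED},
    CaseState.NO_SHOW: set(),
    CaseState.VERIFIED: set(),
    CaseState.FAILED: set(),
}

TERMINAL_STATES = frozenset({CaseState.NO_SHOW, CaseState.VERIFIED, CaseState.FAILED})

#: States a case has necessarily passed through an invitation to reach.
_INVITED_OR_LATER = frozenset(CaseState) - {CaseState.FLAGGED}
_ATTENDED_OR_LATER = frozenset({CaseState.ATTENDED, CaseState.VERIFIED, CaseState.FAILED})


class AnomalyFlag(str, Enum):
    TZ_MISMATCH = "TZ_MISMATCH"
    UNKNOWN_EMAIL = "UNKNOWN_EMAIL"
    AUDIO_ANOMALY = "AUDIO_ANOMALY"
    DAYLIGHT_INCONSISTENT = "DAYLIGHT_INCONSISTENT"
    VAGUE_RESPONSES = "VAGUE_RESPONSES"


@dataclass
class ScreeningCase:
    response_id: str
    state: CaseState = CaseState.FLAGGED
    flagged_reasons: frozenset = frozenset()
    invite_email: str = ""
    scheduled_timezone: Optional[str] = None
    sign_up_email: Optional[str] = None
    anomaly_flags: set = field(default_factory=set)

    def advance(self, new_state: CaseState) -> "ScreeningCase":
        new_state = CaseState(new_state)
        if new_state not in _TRANSITIONS[self.state]:
            raise StateError(f"illegal transition {self.state.value} -> {new_state.value} "
                             f"for case {self.response_id}")
        self.state = new_state
        return self


@dataclass
class ScreeningQueue:
    """FLAGGED cases plus the excluded ids that can never be contacted."""

    cases: list
    unreachable_ids: frozenset

    def __len__(self) -> int:
        return len(self.cases)

    def __iter__(self):
        return iter(self.cases)


def build_screening_queue(report: ExclusionReport, cohort: Cohort) -> ScreeningQueue:
    """One FLAGGED case per excluded response with consent and a nonmissing email.

    Excluded responses without consent or without an email are unreachable:
    terminal, never readmitted.
    """
    cases, unreachable = [], set()
    for d in report.decisions:
        if not d.excluded:
            continue
        if d.response_id not in cohort:
            raise IntegrityError(f"excluded id {d.response_id} not found in cohort")
        r = cohort[d.response_id]
        if r.consent_contact and r.email is not None:
            cases.append(ScreeningCase(
                response_id=r.response_id,
                flagged_reasons=frozenset({d.attributed_criterion} | d.all_matching_criteria),
                invite_email=r.email,
            ))
        else:
            unreachable.add(r.response_id)
    return ScreeningQueue(cases=cases, unreachable_ids=frozenset(unreachable))


@dataclass
class VerificationAnswers:
    """Interview answers to be checked against the survey record."""

    stated_age_years: int
    stated_country: str = ""
    stated_subdivision: str = ""
    stated_city: str = ""
    access_country: str = ""
    access_subdivision: str = ""
    access_city: str = ""
    stated_gender_terms: frozenset = frozenset()
    social_transition_reported: bool = False
    social_transition_year: Optional[int] = None
    reasons_summary: str = ""          # recorded, never auto-scored
    manual_flags: frozenset = frozenset()


@dataclass
class VerificationPolicy:
    """Tolerances for matching interview answers to months-old survey answers."""

    age_tolerance_years: int = 1
    year_tolerance: int = 1
    require_location_match: str = "country_subdivision"  # country | country_subdivision
    gender_match_rule: str = "nonempty_intersection"     # nonempty_intersection | set_equality

    def validate(self) -> None:
        if self.age_tolerance_years < 0 or self.year_tolerance < 0:
            raise ValueError("tolerances must be >= 0")


def _ci_eq(a: str, b: str) -> bool:
    return a.strip().lower() == b.strip().lower()


def verify_case(
    case: ScreeningCase,
    r: SurveyResponse,
    answers: VerificationAnswers,
    policy: VerificationPolicy = None,
) -> CaseState:
    """Resolve an ATTENDED case to VERIFIED or FAILED.

    VERIFIED requires all of: age within tolerance; access-location match per
    policy (case-insensitive; checks skip survey fields that are missing);
    gender terms satisfying the match rule; social-transition report
    consistent with the survey ('unsure' on the survey is consistent with
    either answer), with year within tolerance when both present; and no
    manual interviewer flags. Anything else FAILS.
    """
    policy = policy or VerificationPolicy()
    policy.validate()
    if case.state != CaseState.ATTENDED:
        raise StateError(f"verify_case requires state ATTENDED, case {case.response_id} "
                         f"is {case.state.value}")

    ok = True
    if r.age_years is not None:
        ok &= abs(answers.stated_age_years - r.age_years) <= policy.age_tolerance_years

    survey_country = r.geo_country or r.self_report_country
    if survey_country is not None and answers.access_country:
        ok &= _ci_eq(answers.access_country, survey_country)
    if policy.require_location_match == "country_subdivision" and r.geo_subdivision is not None:
        ok &= _ci_eq(answers.access_subdivision, r.geo_subdivision)

    stated = frozenset(normalize_term(t) for t in answers.stated_gender_terms)
    if r.gender_terms_current:
        if policy.gender_match_rule == "set_equality":
            ok &= stated == r.gender_terms_current
        else:
            ok &= bool(stated & r.gender_terms_current)

    if r.social_transition in ("yes", "no"):
        ok &= answers.social_transition_reported == (r.social_transition == "yes")
    if answers.social_transition_year is not None and r.social_transition_year is not None:
        ok &= abs(answers.social_transition_year - r.social_transition_year) <= policy.year_tolerance

    ok &= not answers.manual_flags

    case.advance(CaseState.VERIFIED if ok else CaseState.FAILED)
    return case.state


# ---------------------------------------------------------------------------
# scheduling anomalies

def load_country_offsets() -> dict:
    """Packaged country -> (min, max) UTC offset range in hours."""
    ref = resources.files("surveyscreen.data") / "country_utc_offsets.csv"
    table = {}
    with resources.as_file(ref) as p, open(p, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            table[row["country"]] = (float(row["min_offset_hours"]), float(row["max_offset_hours"]))
    return table


def load_suspicious_timezones() -> frozenset:
    ref = resources.files("surveyscreen.data") / "suspicious_timezones.txt"
    with resources.as_file(ref) as p:
        lines = Path(p).read_text(encoding="utf-8").splitlines()
    return frozenset(l.strip() for l in lines if l.strip() and not l.startswith("#"))


#: Fixed reference instant for timezone offsets, so DST never flips a verdict.
_OFFSET_REFERENCE = datetime(2024, 1, 15, 12, 0, tzinfo=timezone.utc)


def _tz_offset_hours(tz_name: str) -> float:
    off = _OFFSET_REFERENCE.astimezone(ZoneInfo(tz_name)).utcoffset()
    return off.total_seconds() / 3600.0


def detect_anomalies(
    case: ScreeningCase,
    invited_emails: Iterable[str],
    suspicious_timezones: Optional[Iterable[str]] = None,
    *,
    geo_country: Optional[str] = None,
    offsets_table: Optional[dict] = None,
    max_offset_gap_hours: float = 3.0,
) -> set:
    """Scheduling-stage anomaly flags for a case at or past SCHEDULED.

    TZ_MISMATCH: the scheduling timezone is on the suspicious list, or its UTC
    offset lies more than ``max_offset_gap_hours`` outside the offset range of
    the response's geolocated country. UNKNOWN_EMAIL: the sign-up email was
    never invited (case-insensitive).
    """
    if case.state == CaseState.FLAGGED or case.state == CaseState.INVITED:
        raise StateError(f"anomaly detection requires state >= SCHEDULED, "
                         f"case {case.response_id} is {case.state.value}")
    suspicious = frozenset(suspicious_timezones) if suspicious_timezones is not None \
        else load_suspicious_timezones()
    flags = set()

    if case.scheduled_timezone is not None:
        if case.scheduled_timezone in suspicious:
            flags.add(AnomalyFlag.TZ_MISMATCH)
        elif geo_country is not None:
            table = offsets_table if offsets_table is not None else load_country_offsets()
            rng = table.get(geo_country.upper())
            if rng is not None:
                off = _tz_offset_hours(case.scheduled_timezone)
                gap = max(rng[0] - off, off - rng[1], 0.0)
                if gap > max_offset_gap_hours:
                    flags.add(AnomalyFlag.TZ_MISMATCH)

    if case.sign_up_email is not None:
        invited = {e.lower() for e in invited_emails}
        if case.sign_up_email.lower() not in invited:
            flags.add(AnomalyFlag.UNKNOWN_EMAIL)

    case.anomaly_flags |= flags
    return flags


# ---------------------------------------------------------------------------
# outcomes and final disposition

def apply_outcome_table(queue: ScreeningQueue, outcomes: dict) -> ScreeningQueue:
    """Advance queued cases per an outcome map id -> verified|failed|no_show.

    Cases absent from the map stay FLAGGED (never invited). Listed cases are
    walked through the legal transition chain to their terminal state.
    """
    known = {c.response_id for c in queue.cases}
    unknown = set(outcomes) - known
    if unknown:
        raise IntegrityError(f"outcome table lists unknown case id(s): {sorted(unknown)[:5]}")
    for case in queue.cases:
        outcome = outcomes.get(case.response_id)
        if outcome is None:
            continue
        case.advance(CaseState.INVITED).advance(CaseState.SCHEDULED)
        if outcome == "no_show":
            case.advance(CaseState.NO_SHOW)
        elif outcome in ("verified", "failed"):
            case.advance(CaseState.ATTENDED)
            case.advance(CaseState.VERIFIED if outcome == "verified" else CaseState.FAILED)
        else:
            raise IntegrityError(f"unknown outcome {outcome!r} for case {case.response_id}")
    return queue


@dataclass
class FinalDisposition:
    """Post-readmission analytic set plus the screening funnel summary."""

    pre_screen_retained_ids: frozenset
    readmitted_ids: frozenset
    final_retained_ids: frozenset
    all_ids: frozenset
    funnel: dict
    attendance_rate_pct: Optional[float]

    @property
    def final_excluded_ids(self) -> frozenset:
        return self.all_ids - self.final_retained_ids

    def to_dict(self) -> dict:
        return {
            "pre_screen_retained_ids": sorted(self.pre_screen_retained_ids),
            "readmitted_ids": sorted(self.readmitted_ids),
            "final_retained_ids": sorted(self.final_retained_ids),
            "all_ids": sorted(self.all_ids),
            "funnel": dict(self.funnel),
            "attendance_rate_pct": self.attendance_rate_pct,
        }

    def to_json(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True) + "\n", encoding="utf-8")
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "FinalDisposition":
        return cls(
            pre_screen_retained_ids=frozenset(d["pre_screen_retained_ids"]),
            readmitted_ids=frozenset(d["readmitted_ids"]),
            final_retained_ids=frozenset(d["final_retained_ids"]),
            all_ids=frozenset(d["all_ids"]),
            funnel=dict(d["funnel"]),
            attendance_rate_pct=d["attendance_rate_pct"],
        )

    @classmethod
    def from_json(cls, path) -> "FinalDisposition":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def apply_screening_outcomes(report: ExclusionReport, cases: Iterable[ScreeningCase]) -> FinalDisposition:
    """Fold screening results back into the exclusion report.

    Final retained set = pre-screen retained union VERIFIED case ids; every
    other flagged or unreachable response stays excluded. The funnel summary
    reports flagged/invited/attended/verified/failed/no-show counts and the
    attendance rate (attended/invited, as a percentage, one decimal).
    """
    cases = list(cases)
    excluded = report.excluded_ids
    bad = [c.response_id for c in cases if c.response_id not in excluded]
    if bad:
        raise IntegrityError(f"screening case id(s) not among exclusions: {sorted(bad)[:5]}")

    verified = frozenset(c.response_id for c in cases if c.state == CaseState.VERIFIED)
    n_invited = sum(1 for c in cases if c.state in _INVITED_OR_LATER)
    n_attended = sum(1 for c in cases if c.state in _ATTENDED_OR_LATER)
    funnel = {
        "flagged": len(cases),
        "unreachable": len(excluded) - len(cases),
        "invited": n_invited,
        "attended": n_attended,
        "no_show": sum(1 for c in cases if c.state == CaseState.NO_SHOW),
        "verified": sum(1 for c in cases if c.state == CaseState.VERIFIED),
        "failed": sum(1 for c in cases if c.state == CaseState.FAILED),
        "pending": sum(1 for c in cases if c.state not in TERMINAL_STATES),
    }
    rate = round(100.0 * n_attended / n_invited, 1) if n_invited else None
    all_ids = report.retained_ids | excluded
    return FinalDisposition(
        pre_screen_retained_ids=report.retained_ids,
        readmitted_ids=verified,
        final_retained_ids=report.retained_ids | verified,
        all_ids=all_ids,
        funnel=funnel,
        attendance_rate_pct=rate,
    )


# ---------------------------------------------------------------------------
# CSV plumbing

def write_cases_csv(queue: ScreeningQueue, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["response_id", "state", "flagged_reasons", "invite_email",
                    "scheduled_timezone", "sign_up_email", "anomaly_flags"])
        for c in queue.cases:
            w.writerow([
                c.response_id, c.state.value,
                ";".join(sorted(x.value for x in c.flagged_reasons)),
                c.invite_email, c.scheduled_timezone or "", c.sign_up_email or "",
                ";".join(sorted(x.value for x in c.anomaly_flags)),
            ])
        for rid in sorted(queue.unreachable_ids):
            w.writerow([rid, "UNREACHABLE", "", "", "", "", ""])
    return path


def load_outcomes_csv(path) -> dict:
    """Read a screening-outcome table: columns response_id, outcome."""
    outcomes = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"response_id", "outcome"} <= set(reader.fieldnames):
            raise IntegrityError("outcome table needs columns: response_id, outcome")
        for row in reader:
            outcomes[row["response_id"]] = row["outcome"].strip().lower()
    return outcomes


def write_outcomes_csv(outcomes: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["response_id", "outcome"])
        for rid in sorted(outcomes):
            w.writerow([rid, outcomes[rid]])
    return path
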