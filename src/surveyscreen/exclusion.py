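"""Ordered exclusion protocol for bot, scam, and ineligible responses.

Five criteria are evaluated for every response; an excluded response is
*attributed* to the first matching criterion in the configured order, so the
attribution order changes per-criterion counts but never the excluded set.

Criteria
--------
INELIGIBLE_NONSENSE
    Composite logic/consistency bucket, resolved to a subreason in fixed
    order: neither socially nor medically transitioned; affirmed a
    fictitious-condition trap item; no discordance between past and current
    gender terms; assigned sex conflicts with the hormone started at initial
    medical transition (AFAB + estrogen, AMAB + testosterone); implausible
    (nonsense or hateful) contact email.
GEO_OUTSIDE
    Resolved country outside the allowed region (default US/Canada).
LOW_RECAPTCHA
    reCAPTCHA score strictly below the threshold (default 0.5).
DUPLICATE_IDENTITY
    Shares an IP address and/or email with another completed response.
FAST_COMPLETION
    Completion time strictly below the minimum (default 720 s = 12 min,
    against an expected 35-60 min completion).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Optional

import yaml

from .emailcheck import Lexicon, score_email_plausibility
from .errors import ConfigError, IntegrityError
from .model import Cohort, SurveyResponse


class Criterion(str, Enum):
    INELIGIBLE_NONSENSE = "INELIGIBLE_NONSENSE"
    GEO_OUTSIDE = "GEO_OUTSIDE"
    LOW_RECAPTCHA = "LOW_RECAPTCHA"
    DUPLICATE_IDENTITY = "DUPLICATE_IDENTITY"
    FAST_COMPLETION = "FAST_COMPLETION"


class Subreason(str, Enum):
    NO_TRANSITION = "NO_TRANSITION"
    TRAP_ITEM = "TRAP_ITEM"
    NO_GENDER_DISCORDANCE = "NO_GENDER_DISCORDANCE"
    HORMONE_SEX_MISMATCH = "HORMONE_SEX_MISMATCH"
    EMAIL_IMPLAUSIBLE = "EMAIL_IMPLAUSIBLE"


#: Attribution order used for reporting (matches the published count table).
DEFAULT_CRITERION_ORDER = (
    Criterion.INELIGIBLE_NONSENSE,
    Criterion.GEO_OUTSIDE,
    Criterion.LOW_RECAPTCHA,
    Criterion.DUPLICATE_IDENTITY,
    Criterion.FAST_COMPLETION,
)

#: Fixed resolution order of the composite-bucket subreasons.
SUBREASON_ORDER = (
    Subreason.NO_TRANSITION,
    Subreason.TRAP_ITEM,
    Subreason.NO_GENDER_DISCORDANCE,
    Subreason.HORMONE_SEX_MISMATCH,
    Subreason.EMAIL_IMPLAUSIBLE,
)


@dataclass
class ProtocolConfig:
    """Thresholds, allowed regions, criterion order, and policy switches."""

    recaptcha_threshold: float = 0.5
    min_duration_seconds: int = 720
    allowed_countries: frozenset = frozenset({"US", "CA"})
    criterion_order: tuple = DEFAULT_CRITERION_ORDER
    duplicate_scope: str = "ip_or_email"          # ip | email | ip_or_email
    duplicate_policy: str = "remove_all"          # remove_all | keep_first
    geo_source: str = "ip_geo_then_self_report"   # ip_geo | self_report | ip_geo_then_self_report
    missing_score_policy: str = "retain_flag"     # retain_flag | exclude
    nonsense_lexicon_path: Optional[str] = None   # None -> packaged placeholder lexicon; "" -> empty
    email_entropy_cutoff: float = 3.8
    email_entropy_min_len: int = 10
    email_consonant_run: int = 6

    def __post_init__(self):
        self.allowed_countries = frozenset(c.upper() for c in self.allowed_countries)
        self.criterion_order = tuple(Criterion(c) for c in self.criterion_order)

    def validate(self) -> None:
        if not 0.0 <= self.recaptcha_threshold <= 1.0:
            raise ConfigError("recaptcha_threshold must lie in [0, 1]")
        if self.min_duration_seconds < 0:
            raise ConfigError("min_duration_seconds must be >= 0")
        if sorted(c.value for c in self.criterion_order) != sorted(c.value for c in Criterion):
            raise ConfigError(
                "criterion_order must be a permutation of the five criterion codes, "
                f"got {[c.value for c in self.criterion_order]}"
            )
        for name, allowed in (
            ("duplicate_scope", ("ip", "email", "ip_or_email")),
            ("duplicate_policy", ("remove_all", "keep_first")),
            ("geo_source", ("ip_geo", "self_report", "ip_geo_then_self_report")),
            ("missing_score_policy", ("retain_flag", "exclude")),
        ):
            if getattr(self, name) not in allowed:
                raise ConfigError(f"{name} must be one of {allowed}")

    def lexicon(self) -> Lexicon:
        if self.nonsense_lexicon_path is None:
            return Lexicon.packaged()
        if self.nonsense_lexicon_path == "":
            return Lexicon()
        return Lexicon.from_path(self.nonsense_lexicon_path)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["allowed_countries"] = sorted(self.allowed_countries)
        d["criterion_order"] = [c.value for c in self.criterion_order]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolConfig":
        known = {f for f in cls.__dataclass_fields__}  # noqa: C416
        extra = set(d) - known
        if extra:
            raise ConfigError(f"unknown config key(s): {sorted(extra)}")
        kwargs = dict(d)
        if "allowed_countries" in kwargs:
            kwargs["allowed_countries"] = frozenset(kwargs["allowed_countries"])
        if "criterion_order" in kwargs:
            kwargs["criterion_order"] = tuple(kwargs["criterion_order"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "ProtocolConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# per-criterion predicates

def _resolve_country(r: SurveyResponse, cfg: ProtocolConfig) -> Optional[str]:
    ip_geo = r.geo_country
    self_rep = r.self_report_country  # "OTHER" is a real (non-allowed) answer
    if cfg.geo_source == "ip_geo":
        return ip_geo
    if cfg.geo_source == "self_report":
        return self_rep
    return ip_geo if ip_geo is not None else self_rep


def is_outside_region(r: SurveyResponse, cfg: ProtocolConfig = None) -> bool:
    """True iff the resolved country is present and not allowed.

    With both geolocation and self-report missing the response is retained;
    the runner records a ``geo_unresolved`` flag instead.
    """
    cfg = cfg or ProtocolConfig()
    country = _resolve_country(r, cfg)
    return country is not None and country.upper() not in cfg.allowed_countries


def is_low_recaptcha(r: SurveyResponse, cfg: ProtocolConfig = None) -> bool:
    """Strict inequality: score < threshold excludes, score == threshold retains."""
    cfg = cfg or ProtocolConfig()
    if r.recaptcha_score is None:
        return cfg.missing_score_policy == "exclude"
    return r.recaptcha_score < cfg.recaptcha_threshold


def is_fast_completion(r: SurveyResponse, cfg: ProtocolConfig = None) -> bool:
    cfg = cfg or ProtocolConfig()
    return r.duration_seconds < cfg.min_duration_seconds


def check_no_transition(r: SurveyResponse) -> bool:
    """Neither socially nor medically transitioned ('unsure' is not 'no')."""
    return r.social_transition == "no" and r.medical_transition == "no"


def check_trap_items(r: SurveyResponse) -> bool:
    """Affirmed either fictitious condition; only 'yes' answers trigger."""
    return r.trap_chekalism == "yes" or r.trap_syndomitis == "yes"


def check_gender_discordance(r: SurveyResponse) -> bool:
    """Violation iff past and current gender-term sets are equal and nonempty."""
    past, cur = r.gender_terms_past, r.gender_terms_current
    return bool(past) and bool(cur) and past == cur


def check_hormone_concordance(r: SurveyResponse) -> bool:
    """Violation iff assigned sex conflicts with the initial-transition hormone.

    AFAB + estrogen or AMAB + testosterone conflicts; blockers and 'none'
    never trigger; missing sex is unassessable and retained.
    """
    sex = r.sex_assigned_at_birth
    hormones = r.hormones_initial_transition
    if sex == "female":
        return "estrogen" in hormones
    if sex == "male":
        return "testosterone" in hormones
    return False


def is_ineligible_nonsense(
    r: SurveyResponse, cfg: ProtocolConfig = None, lexicon: Optional[Lexicon] = None
) -> Optional[Subreason]:
    """First triggered subreason of the composite bucket, or None."""
    cfg = cfg or ProtocolConfig()
    if lexicon is None:
        lexicon = cfg.lexicon()
    checks = {
        Subreason.NO_TRANSITION: lambda: check_no_transition(r),
        Subreason.TRAP_ITEM: lambda: check_trap_items(r),
        Subreason.NO_GENDER_DISCORDANCE: lambda: check_gender_discordance(r),
        Subreason.HORMONE_SEX_MISMATCH: lambda: check_hormone_concordance(r),
        Subreason.EMAIL_IMPLAUSIBLE: lambda: r.email is not None
        and score_email_plausibility(
            r.email,
            lexicon,
            entropy_cutoff=cfg.email_entropy_cutoff,
            entropy_min_len=cfg.email_entropy_min_len,
            consonant_run=cfg.email_consonant_run,
        )
        != "ok",
    }
    for sub in SUBREASON_ORDER:
        if checks[sub]():
            return sub
    return None


def duplicate_flags(cohort: Cohort, cfg: ProtocolConfig = None) -> dict:
    """Map response_id -> duplicate-identity verdict for a whole cohort.

    Records sharing an IP and/or a (case-insensitive) email form an identity
    cluster (transitive closure under ``ip_or_email``). Missing emails never
    match each other. Under ``keep_first`` the earliest-submitted member of
    each cluster (ties broken by response_id) is kept.
    """
    cfg = cfg or ProtocolConfig()
    parent = {r.response_id: r.response_id for r in cohort}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    by_key = {}
    for r in cohort:
        keys = []
        if cfg.duplicate_scope in ("ip", "ip_or_email"):
            keys.append(("ip", r.ip_address))
        if cfg.duplicate_scope in ("email", "ip_or_email") and r.email is not None:
            keys.append(("email", r.email.lower()))
        for key in keys:
            if key in by_key:
                union(by_key[key], r.response_id)
            else:
                by_key[key] = r.response_id

    clusters = {}
    for r in cohort:
        clusters.setdefault(find(r.response_id), []).append(r)

    flags = {}
    for members in clusters.values():
        if len(members) == 1:
            flags[members[0].response_id] = False
            continue
        if cfg.duplicate_policy == "remove_all":
            for r in members:
                flags[r.response_id] = True
        else:  # keep_first
            first = min(members, key=lambda r: (r.submitted_at, r.response_id))
            for r in members:
                flags[r.response_id] = r.response_id != first.response_id
    return flags


def is_duplicate_identity(r: SurveyResponse, cohort: Cohort, cfg: ProtocolConfig = None) -> bool:
    return duplicate_flags(cohort, cfg)[r.response_id]


# ---------------------------------------------------------------------------
# runner

@dataclass
class ExclusionDecision:
    response_id: str
    excluded: bool
    attributed_criterion: Optional[Criterion]
    subreason: Optional[Subreason]
    all_matching_criteria: frozenset
    flags: frozenset = frozenset()

    def to_dict(self) -> dict:
        return {
            "response_id": self.response_id,
            "excluded": self.excluded,
            "attributed_criterion": self.attributed_criterion.value if self.attributed_criterion else None,
            "subreason": self.subreason.value if self.subreason else None,
            "all_matching_criteria": sorted(c.value for c in self.all_matching_criteria),
            "flags": sorted(self.flags),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExclusionDecision":
        return cls(
            response_id=d["response_id"],
            excluded=d["excluded"],
            attributed_criterion=Criterion(d["attributed_criterion"]) if d["attributed_criterion"] else None,
            subreason=Subreason(d["subreason"]) if d["subreason"] else None,
            all_matching_criteria=frozenset(Criterion(c) for c in d["all_matching_criteria"]),
            flags=frozenset(d.get("flags", [])),
        )


@dataclass
class ExclusionReport:
    """Outcome of one protocol run: attributions, retained set, config snapshot."""

    input_count: int
    per_criterion_counts: dict
    retained_ids: frozenset
    decisions: list
    config_snapshot: dict = field(default_factory=dict)

    @property
    def excluded_ids(self) -> frozenset:
        return frozenset(d.response_id for d in self.decisions if d.excluded)

    def check_conservation(self) -> None:
        total = len(self.retained_ids) + sum(self.per_criterion_counts.values())
        if total != self.input_count:
            raise IntegrityError(
                f"conservation violated: retained {len(self.retained_ids)} + "
                f"attributed {sum(self.per_criterion_counts.values())} != input {self.input_count}"
            )

    def to_dict(self) -> dict:
        return {
            "input_count": self.input_count,
            "per_criterion_counts": {c.value: n for c, n in self.per_criterion_counts.items()},
            "retained_ids": sorted(self.retained_ids),
            "decisions": [d.to_dict() for d in self.decisions],
            "config_snapshot": self.config_snapshot,
        }

    def to_json(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True) + "\n", encoding="utf-8")
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "ExclusionReport":
        return cls(
            input_count=d["input_count"],
            per_criterion_counts={Criterion(c): n for c, n in d["per_criterion_counts"].items()},
            retained_ids=frozenset(d["retained_ids"]),
            decisions=[ExclusionDecision.from_dict(x) for x in d["decisions"]],
            config_snapshot=d.get("config_snapshot", {}),
        )

    @classmethod
    def from_json(cls, path) -> "ExclusionReport":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def evaluate_response(
    r: SurveyResponse, cfg: ProtocolConfig, dup_flag: bool, lexicon: Lexicon
) -> ExclusionDecision:
    """Evaluate every criterion for one response and attribute the first match."""
    flags = set()
    matching = set()

    sub = is_ineligible_nonsense(r, cfg, lexicon)
    if sub is not None:
        matching.add(Criterion.INELIGIBLE_NONSENSE)
    if not check_gender_discordance(r) and not (r.gender_terms_past and r.gender_terms_current):
        flags.add("discordance_unassessable")
    if r.sex_assigned_at_birth is None:
        flags.add("sex_missing")

    if _resolve_country(r, cfg) is None:
        flags.add("geo_unresolved")
    elif is_outside_region(r, cfg):
        matching.add(Criterion.GEO_OUTSIDE)

    if r.recaptcha_score is None:
        if cfg.missing_score_policy == "exclude":
            matching.add(Criterion.LOW_RECAPTCHA)
        else:
            flags.add("recaptcha_missing")
    elif is_low_recaptcha(r, cfg):
        matching.add(Criterion.LOW_RECAPTCHA)

    if dup_flag:
        matching.add(Criterion.DUPLICATE_IDENTITY)
    if is_fast_completion(r, cfg):
        matching.add(Criterion.FAST_COMPLETION)

    attributed = next((c for c in cfg.criterion_order if c in matching), None)
    return ExclusionDecision(
        response_id=r.response_id,
        excluded=bool(matching),
        attributed_criterion=attributed,
        subreason=sub if attributed == Criterion.INELIGIBLE_NONSENSE else None,
        all_matching_criteria=frozenset(matching),
        flags=frozenset(flags),
    )


def run_protocol(cohort: Cohort, cfg: ProtocolConfig = None) -> ExclusionReport:
    """Apply the full ordered exclusion protocol to a cohort.

    Every response receives exactly one decision; ``all_matching_criteria``
    evaluates every criterion regardless of order, and the attributed
    criterion is the first match in ``cfg.criterion_order``.
    """
    cfg = cfg or ProtocolConfig()
    cfg.validate()
    lexicon = cfg.lexicon()
    dup = duplicate_flags(cohort, cfg)

    decisions = []
    counts = {c: 0 for c in Criterion}
    retained = set()
    for r in cohort:
        d = evaluate_response(r, cfg, dup[r.response_id], lexicon)
        decisions.append(d)
        if d.excluded:
            counts[d.attributed_criterion] += 1
        else:
            retained.add(r.response_id)

    report = ExclusionReport(
        input_count=len(cohort),
        per_criterion_counts=counts,
        retained_ids=frozenset(retained),
        decisions=decisions,
        config_snapshot=cfg.to_dict(),
    )
    report.check_conservation()
    return report


def write_decisions_csv(report: ExclusionReport, path) -> Path:
    import csv as _csv

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = _csv.writer(fh, lineterminator="\n")
        w.writerow(["response_id", "excluded", "attributed_criterion", "subreason",
                    "all_matching_criteria", "flags"])
        for d in report.decisions:
            w.writerow([
                d.response_id,
                "true" if d.excluded else "false",
                d.attributed_criterion.value if d.attributed_criterion else "",
                d.subreason.value if d.subreason else "",
                ";".join(sorted(c.value for c in d.all_matching_criteria)),
                ";".join(sorted(d.flags)),
            ])
    return path
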