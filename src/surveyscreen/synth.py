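"""Seeded synthetic respondent cohorts with persona-structured fraud signals.

Five personas operationalize the fraud modes observed in web-survey screening:

* ``GENUINE``   — eligible respondents; high bot-score, realistic durations.
* ``BOT``       — scripted submissions; low reCAPTCHA, very fast completion,
  frequent trap-item hits and machine-generated emails.
* ``FARM``      — paid click-farm workers; duplicate-IP clusters, submissions
  geolocated outside the allowed region.
* ``TROLL``     — hostile respondents; abusive (placeholder-token) emails.
* ``CARELESS``  — genuine but inattentive respondents who may affirm a
  fictitious condition by accident, the main source of false positives.

All generator parameters are package-defined study conditions, not estimates
of any real dataset. Each persona draws from its own random stream (spawned
in a fixed canonical order), so records of one persona are reproducible under
changes to the other personas' weights. Ground-truth labels record, for every
record, exactly the violations whose protocol predicates fire under the
default :class:`~surveyscreen.exclusion.ProtocolConfig`.

:func:`make_worked_example` builds the fixed screening-funnel fixture: 1377
records with disjointly planted violations (166 ineligible/nonsense, 165
outside-region, 74 low-reCAPTCHA, 30 duplicate-identity, 13 fast-completion;
448 total), 190 reachable flagged responses, and a packaged outcome table
(48 attended: 28 verified + 20 failed; 142 no-shows), which closes the funnel
at 957 eligible of 1377.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .errors import ConfigError
from .exclusion import Criterion, ProtocolConfig, Subreason, run_protocol
from .model import Cohort, SurveyResponse

PERSONA_ORDER = ("GENUINE", "BOT", "FARM", "TROLL", "CARELESS")

_OUTSIDE_COUNTRIES = ("NG", "GH", "KE", "CM", "SN", "IN", "PK", "BD", "BR", "MX")
_US_STATES = ("CA", "NY", "TX", "WA", "OH", "IL", "PA", "MA", "OR", "MI")
_CA_PROVINCES = ("ON", "BC", "QC", "AB", "NS")
_TERMS = ("woman", "man", "trans man", "trans woman", "nonbinary",
          "detransitioned", "genderfluid", "agender")
_NAMES = ("ana", "ben", "eva", "ida", "leo", "mia", "noa", "ora", "uma", "ivo",
          "ada", "eli", "ivy", "oda", "ula", "amy", "ian", "joy", "lee", "may")
_HATE_TOKENS = ("hatetoken", "slurtoken", "bigotoken")
_CONSONANTS = "bcdfghjklmnpqrstvwz"

_EPOCH = datetime(2023, 12, 1, tzinfo=timezone.utc)


# ---------------------------------------------------------------------------
# distribution specs

def sample_dist(rng: np.random.Generator, spec: dict, size: int) -> np.ndarray:
    """Draw from a declarative distribution spec (family + parameters)."""
    try:
        family = spec["family"]
        if family == "beta":
            return rng.beta(spec["a"], spec["b"], size)
        if family == "lognormal":
            # parameterized by median so configs read in natural units
            return spec["median"] * np.exp(spec["sigma"] * rng.standard_normal(size))
        if family == "uniform":
            return rng.uniform(spec["low"], spec["high"], size)
        if family == "uniform_int":
            return rng.integers(spec["low"], spec["high"] + 1, size)
        if family == "constant":
            return np.full(size, float(spec["value"]))
    except KeyError as exc:
        raise ConfigError(f"distribution spec {spec!r} missing parameter {exc}") from exc
    raise ConfigError(f"unknown distribution family {spec.get('family')!r}")


def dist_mean(spec: dict) -> float:
    """Closed-form mean of a distribution spec (used by sanity checks)."""
    family = spec["family"]
    if family == "beta":
        return spec["a"] / (spec["a"] + spec["b"])
    if family == "lognormal":
        return spec["median"] * math.exp(spec["sigma"] ** 2 / 2)
    if family == "uniform":
        return (spec["low"] + spec["high"]) / 2
    if family == "uniform_int":
        return (spec["low"] + spec["high"]) / 2
    if family == "constant":
        return float(spec["value"])
    raise ConfigError(f"unknown distribution family {family!r}")


def dist_sd(spec: dict) -> float:
    family = spec["family"]
    if family == "beta":
        a, b = spec["a"], spec["b"]
        return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
    if family == "lognormal":
        s2 = spec["sigma"] ** 2
        return spec["median"] * math.exp(s2 / 2) * math.sqrt(math.exp(s2) - 1)
    if family == "uniform":
        return (spec["high"] - spec["low"]) / math.sqrt(12)
    if family == "uniform_int":
        n = spec["high"] - spec["low"] + 1
        return math.sqrt((n ** 2 - 1) / 12)
    if family == "constant":
        return 0.0
    raise ConfigError(f"unknown distribution family {family!r}")


# ---------------------------------------------------------------------------
# persona and cohort specs

@dataclass
class PersonaSpec:
    name: str
    weight: float
    recaptcha_dist: dict
    duration_dist: dict
    trap_yes_prob: float = 0.0
    geo_outside_prob: float = 0.0
    duplicate_cluster_size_dist: dict = field(default_factory=lambda: {"family": "constant", "value": 1})
    hormone_mismatch_prob: float = 0.0
    no_transition_prob: float = 0.0
    no_discordance_prob: float = 0.0
    bad_email_prob: float = 0.0
    missing_email_prob: float = 0.05
    consent_prob: float = 0.5
    attend_prob: float = 0.3
    verify_pass_prob: float = 0.5

    def validate(self) -> None:
        if self.weight < 0:
            raise ConfigError(f"persona {self.name}: weight must be >= 0")
        for p in ("trap_yes_prob", "geo_outside_prob", "hormone_mismatch_prob",
                  "no_transition_prob", "no_discordance_prob", "bad_email_prob",
                  "missing_email_prob", "consent_prob", "attend_prob", "verify_pass_prob"):
            v = getattr(self, p)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"persona {self.name}: {p}={v} outside [0, 1]")
        for d in (self.recaptcha_dist, self.duration_dist, self.duplicate_cluster_size_dist):
            dist_mean(d)  # raises ConfigError on a malformed spec

    def to_dict(self) -> dict:
        from dataclasses import asdict
        return asdict(self)


def default_personas() -> list:
    """The package's default study conditions for a contaminated cohort."""
    return [
        PersonaSpec(
            name="GENUINE", weight=0.70,
            recaptcha_dist={"family": "beta", "a": 9, "b": 1},
            duration_dist={"family": "lognormal", "median": 2700, "sigma": 0.25},
            consent_prob=0.6, attend_prob=0.5, verify_pass_prob=0.9,
        ),
        PersonaSpec(
            name="BOT", weight=0.12,
            recaptcha_dist={"family": "beta", "a": 2, "b": 8},
            duration_dist={"family": "lognormal", "median": 240, "sigma": 0.5},
            trap_yes_prob=0.5, no_transition_prob=0.3, bad_email_prob=0.6,
            consent_prob=0.3, attend_prob=0.05, verify_pass_prob=0.05,
        ),
        PersonaSpec(
            name="FARM", weight=0.08,
            recaptcha_dist={"family": "beta", "a": 4, "b": 4},
            duration_dist={"family": "lognormal", "median": 900, "sigma": 0.4},
            geo_outside_prob=0.8,
            duplicate_cluster_size_dist={"family": "uniform_int", "low": 2, "high": 6},
            consent_prob=0.5, attend_prob=0.2, verify_pass_prob=0.1,
        ),
        PersonaSpec(
            name="TROLL", weight=0.05,
            recaptcha_dist={"family": "beta", "a": 6, "b": 3},
            duration_dist={"family": "lognormal", "median": 1500, "sigma": 0.4},
            bad_email_prob=0.9, trap_yes_prob=0.2,
            consent_prob=0.2, attend_prob=0.1, verify_pass_prob=0.0,
        ),
        PersonaSpec(
            name="CARELESS", weight=0.05,
            recaptcha_dist={"family": "beta", "a": 8, "b": 2},
            duration_dist={"family": "lognormal", "median": 2000, "sigma": 0.3},
            trap_yes_prob=0.3,
            consent_prob=0.6, attend_prob=0.5, verify_pass_prob=0.8,
        ),
    ]


@dataclass
class CohortSpec:
    n: int
    personas: list = field(default_factory=default_personas)
    seed: int = 0

    def validate(self) -> None:
        if self.n < 0:
            raise ConfigError("n must be >= 0")
        if not self.personas:
            raise ConfigError("at least one persona is required")
        names = [p.name for p in self.personas]
        if len(set(names)) != len(names):
            raise ConfigError(f"duplicate persona names: {names}")
        total = 0.0
        for p in self.personas:
            p.validate()
            total += p.weight
        if total <= 0:
            raise ConfigError("persona weights must sum to a positive number")

    def persona(self, name: str) -> PersonaSpec:
        for p in self.personas:
            if p.name == name:
                return p
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {"n": self.n, "seed": self.seed,
                "personas": [p.to_dict() for p in self.personas]}

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8")
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        personas = [PersonaSpec(**p) for p in d.get("personas", [])] or default_personas()
        spec = cls(n=d["n"], personas=personas, seed=d.get("seed", 0))
        spec.validate()
        return spec

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class GroundTruthLabel:
    response_id: str
    persona: str
    planted_violations: frozenset   # of Criterion
    subreason: Optional[Subreason] = None

    @property
    def is_fraud_or_ineligible(self) -> bool:
        return bool(self.planted_violations)


# ---------------------------------------------------------------------------
# record synthesis

def _plausible_email(rng: np.random.Generator, persona_idx: int, serial: int) -> str:
    name = _NAMES[int(rng.integers(0, len(_NAMES)))]
    return f"{name}{persona_idx}{serial % 1000:03d}@example.org"


def _nonsense_email(rng: np.random.Generator, serial: int) -> str:
    mash = "".join(_CONSONANTS[int(k)] for k in rng.integers(0, len(_CONSONANTS), 8))
    return f"{mash}{serial % 10000:04d}@randmail.example"


def _hateful_email(rng: np.random.Generator, serial: int) -> str:
    token = _HATE_TOKENS[int(rng.integers(0, len(_HATE_TOKENS)))]
    return f"xq{token}{serial % 1000:03d}@spam.example"


def _cluster_sizes(rng: np.random.Generator, spec: dict, total: int) -> list:
    sizes = []
    covered = 0
    while covered < total:
        s = max(1, int(round(float(sample_dist(rng, spec, 1)[0]))))
        s = min(s, total - covered)
        sizes.append(s)
        covered += s
    return sizes


def _gen_persona_records(p: PersonaSpec, count: int, persona_idx: int,
                         rng: np.random.Generator,
                         cluster_rng: np.random.Generator) -> list:
    """Generate `count` records for one persona (ids/timestamps assigned later).

    Every record consumes an identical, branch-free sequence of draws from
    ``rng``, so record i of a persona is invariant to the other personas'
    weights and to this persona's own probability dials (common random
    numbers: raising a violation probability only flips comparisons, never
    shifts the stream). Duplicate-cluster sizing uses its own stream because
    the number of clusters depends on ``count``.
    """
    if count == 0:
        return []
    sizes = _cluster_sizes(cluster_rng, p.duplicate_cluster_size_dist, count)
    ip_of = []
    for cid, size in enumerate(sizes):
        ip = f"10.{persona_idx}.{cid // 250}.{cid % 250 + 1}"
        ip_of.extend([ip] * size)

    records = []
    for i in range(count):
        recaptcha_i = float(np.clip(sample_dist(rng, p.recaptcha_dist, 1)[0], 0.0, 1.0))
        duration_i = int(max(1, sample_dist(rng, p.duration_dist, 1)[0]))

        sex = "female" if rng.random() < 0.79 else "male"

        u_nt, u_soc, u_med = rng.random(3)
        if u_nt < p.no_transition_prob:
            social, medical = "no", "no"
        else:
            social = "yes" if u_soc < 0.9 else "unsure"
            medical = "yes" if u_med < 0.6 else "no"
            if social != "yes" and medical != "yes":
                social = "yes"

        u_fire, u_which, u_unsure = rng.random(3)
        trap_chek, trap_synd = "no", "no"
        if u_fire < p.trap_yes_prob:
            if u_which < 0.5:
                trap_chek = "yes"
            else:
                trap_synd = "yes"
        elif u_unsure < 0.03:
            trap_chek = "unsure"

        past_idx = int(rng.integers(0, len(_TERMS)))
        u_nodisc = rng.random()
        offset = int(rng.integers(1, len(_TERMS)))
        past = frozenset({_TERMS[past_idx]})
        if u_nodisc < p.no_discordance_prob:
            current = past
        else:
            current = frozenset({_TERMS[(past_idx + offset) % len(_TERMS)]})

        u_mismatch = rng.random()
        horm_idx = int(rng.integers(0, 3))
        if u_mismatch < p.hormone_mismatch_prob:
            hormones = frozenset({"estrogen" if sex == "female" else "testosterone"})
        else:
            pool = ("testosterone", "blockers", "none") if sex == "female" \
                else ("estrogen", "blockers", "none")
            hormones = frozenset({pool[horm_idx]})

        u_out, u_us = rng.random(2)
        out_idx = int(rng.integers(0, len(_OUTSIDE_COUNTRIES)))
        state_idx = int(rng.integers(0, len(_US_STATES)))
        prov_idx = int(rng.integers(0, len(_CA_PROVINCES)))
        u_selfrep = rng.random()
        if u_out < p.geo_outside_prob:
            geo = _OUTSIDE_COUNTRIES[out_idx]
            self_rep = "OTHER" if u_selfrep < 0.7 else "US"
            subdiv = None
        elif u_us < 0.75:
            geo, self_rep = "US", "US"
            subdiv = _US_STATES[state_idx]
        else:
            geo, self_rep = "CA", "CA"
            subdiv = _CA_PROVINCES[prov_idx]

        u_missing, u_bad = rng.random(2)
        good_email = _plausible_email(rng, persona_idx, i)     # draws always consumed
        mash_email = (_hateful_email(rng, i) if p.name == "TROLL"
                      else _nonsense_email(rng, i))
        if u_missing < p.missing_email_prob:
            email = None
        elif u_bad < p.bad_email_prob:
            email = mash_email
        else:
            email = good_email

        age = int(np.clip(16 + rng.lognormal(math.log(8), 0.6), 16, 74))
        year_draw = 2008 + int(rng.integers(0, 16))
        year = year_draw if social == "yes" else None
        u_consent, u_lang, u_lang2 = rng.random(3)

        records.append(SurveyResponse(
            response_id="",  # assigned at assembly
            submitted_at=_EPOCH,
            ip_address=ip_of[i],
            geo_country=geo,
            self_report_country=self_rep,
            recaptcha_score=round(recaptcha_i, 4),
            duration_seconds=duration_i,
            email=email,
            consent_contact=bool(u_consent < p.consent_prob),
            language="en" if u_lang < 0.97 else ("fr" if u_lang2 < 0.7 else "es"),
            age_years=age,
            sex_assigned_at_birth=sex,
            social_transition=social,
            medical_transition=medical,
            hormones_initial_transition=hormones,
            gender_terms_past=past,
            gender_terms_current=current,
            social_transition_year=year,
            trap_chekalism=trap_chek,
            trap_syndomitis=trap_synd,
            geo_subdivision=subdiv,
        ))
    return records


def labels_from_protocol(cohort: Cohort, personas_by_id: dict,
                         cfg: ProtocolConfig = None) -> list:
    """Derive ground-truth labels: the violations actually firing per record."""
    report = run_protocol(cohort, cfg or ProtocolConfig())
    labels = []
    for d in report.decisions:
        labels.append(GroundTruthLabel(
            response_id=d.response_id,
            persona=personas_by_id.get(d.response_id, "GENUINE"),
            planted_violations=d.all_matching_criteria,
            subreason=d.subreason,
        ))
    return labels


def generate_cohort(spec: CohortSpec):
    """Generate a cohort and ground-truth labels, deterministically per seed.

    Returns ``(cohort, labels)``. Persona streams are spawned in the fixed
    canonical order ``PERSONA_ORDER`` (then alphabetically for custom names),
    so a persona's records are stable under other personas' weight changes.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    canonical = [n for n in PERSONA_ORDER] + sorted(
        {p.name for p in spec.personas} - set(PERSONA_ORDER))
    children = ss.spawn(len(canonical) + 1)
    assembly_rng = np.random.default_rng(children[0])
    stream, cluster_stream = {}, {}
    for k, name in enumerate(canonical):
        fields_ss, clusters_ss = children[1 + k].spawn(2)
        stream[name] = np.random.default_rng(fields_ss)
        cluster_stream[name] = np.random.default_rng(clusters_ss)

    weights = np.array([p.weight for p in spec.personas], dtype=float)
    counts = assembly_rng.multinomial(spec.n, weights / weights.sum()) if spec.n else \
        np.zeros(len(spec.personas), dtype=int)

    tagged = []
    for p, count in zip(spec.personas, counts):
        persona_idx = canonical.index(p.name)
        recs = _gen_persona_records(p, int(count), persona_idx, stream[p.name],
                                    cluster_stream[p.name])
        tagged.extend((p.name, r) for r in recs)

    order = assembly_rng.permutation(len(tagged)) if tagged else []
    responses, personas_by_id = [], {}
    for pos, j in enumerate(order):
        name, r = tagged[int(j)]
        rid = f"S{pos:05d}"
        responses.append(r.copy(
            response_id=rid,
            submitted_at=_EPOCH + timedelta(seconds=613 * pos),
        ))
        personas_by_id[rid] = name

    cohort = Cohort(responses)
    labels = labels_from_protocol(cohort, personas_by_id)
    return cohort, labels


# ---------------------------------------------------------------------------
# fixed worked-example fixture

WORKED_EXAMPLE_SEED = 20240501

_WE_TERM_PAIRS = (
    (frozenset({"woman"}), frozenset({"nonbinary"})),
    (frozenset({"man"}), frozenset({"detransitioned"})),
    (frozenset({"trans man"}), frozenset({"man"})),
    (frozenset({"trans woman"}), frozenset({"woman"})),
    (frozenset({"nonbinary", "genderfluid"}), frozenset({"detransitioned"})),
)


def _we_base(i: int) -> SurveyResponse:
    """Clean record i of the worked example: passes every criterion."""
    sex = "female" if i % 5 < 4 else "male"
    past, current = _WE_TERM_PAIRS[i % 5]
    inside_us = i % 4 != 0
    hormones = (("testosterone", "none", "blockers") if sex == "female"
                else ("estrogen", "none", "blockers"))[i % 3]
    return SurveyResponse(
        response_id=f"W{i:04d}",
        submitted_at=_EPOCH + timedelta(seconds=600 * i),
        ip_address=f"198.51.{i // 200}.{i % 200 + 1}",
        geo_country="US" if inside_us else "CA",
        self_report_country="US" if inside_us else "CA",
        recaptcha_score=round(0.6 + (i * 7 % 40) / 100, 2),
        duration_seconds=2100 + (i * 37) % 1800,
        email=f"{_NAMES[i % 20]}{i:04d}@example.org",
        consent_contact=i % 3 == 0,
        language="fr" if i % 60 == 0 else ("es" if i % 300 == 7 else "en"),
        age_years=16 + (i * 7) % 45,
        sex_assigned_at_birth=sex,
        social_transition="yes",
        medical_transition="yes" if i % 3 else "no",
        hormones_initial_transition=frozenset({hormones}),
        gender_terms_past=past,
        gender_terms_current=current,
        social_transition_year=2010 + i % 14,
        trap_chekalism="unsure" if i % 17 == 0 else "no",
        trap_syndomitis="no",
        geo_subdivision=(_US_STATES[i % 10] if inside_us else _CA_PROVINCES[i % 5]),
    )


# (block name, count, persona tag, reachable quota)
_WE_BLOCKS = (
    ("clean", 929, "GENUINE", 0),
    ("no_transition", 60, "CARELESS", 60),
    ("trap", 55, "BOT", 10),
    ("no_discordance", 30, "CARELESS", 0),
    ("hormone", 16, "CARELESS", 0),
    ("email", 5, "TROLL", 0),
    ("geo", 165, "FARM", 70),
    ("recaptcha", 74, "BOT", 30),
    ("duplicate", 30, "FARM", 14),
    ("fast", 13, "BOT", 6),
)

_WE_VERIFIED, _WE_FAILED = 28, 20


def make_worked_example(seed: int = WORKED_EXAMPLE_SEED):
    """Build the fixed 1377-record funnel fixture.

    Violations are planted disjointly (each excluded record fires exactly one
    criterion), so attribution is order-independent on this fixture. Returns
    ``(cohort, labels, outcomes)`` where ``outcomes`` maps the 190 reachable
    flagged ids to ``verified`` (28), ``failed`` (20), or ``no_show`` (142).
    The seed only shuffles presentation order; all counts are structural.
    """
    records, personas_by_id, reachable = [], {}, []
    i = 0
    for block, count, persona, quota in _WE_BLOCKS:
        for k in range(count):
            r = _we_base(i)
            if block == "no_transition":
                r = r.copy(social_transition="no", medical_transition="no",
                           social_transition_year=None,
                           hormones_initial_transition=frozenset({"none"}))
            elif block == "trap":
                r = r.copy(trap_chekalism="yes" if k % 2 == 0 else "no",
                           trap_syndomitis="yes" if k % 2 == 1 else "no")
            elif block == "no_discordance":
                same = _WE_TERM_PAIRS[k % 5][0]
                r = r.copy(gender_terms_past=same, gender_terms_current=same)
            elif block == "hormone":
                bad = "estrogen" if r.sex_assigned_at_birth == "female" else "testosterone"
                r = r.copy(hormones_initial_transition=frozenset({bad}))
            elif block == "email":
                r = r.copy(email=f"xq{_HATE_TOKENS[k % 3]}{k:02d}@spam.example")
            elif block == "geo":
                r = r.copy(geo_country=_OUTSIDE_COUNTRIES[k % 10],
                           self_report_country="OTHER", geo_subdivision=None)
            elif block == "recaptcha":
                r = r.copy(recaptcha_score=round(0.05 + (k % 9) * 0.05, 2))
            elif block == "duplicate":
                r = r.copy(ip_address=f"203.0.113.{k // 2 + 1}")
            elif block == "fast":
                r = r.copy(duration_seconds=60 + k * 50)

            if block != "clean":
                if k < quota:
                    r = r.copy(consent_contact=True)  # email already present
                    reachable.append(r.response_id)
                elif block == "email":
                    r = r.copy(consent_contact=False)  # email defines the violation
                elif k % 2 == 0:
                    r = r.copy(consent_contact=False)
                else:
                    r = r.copy(consent_contact=True, email=None)
            personas_by_id[r.response_id] = persona
            records.append(r)
            i += 1

    rng = np.random.default_rng(seed)
    cohort = Cohort([records[int(j)] for j in rng.permutation(len(records))])
    labels = labels_from_protocol(cohort, personas_by_id)

    outcomes = {}
    for pos, rid in enumerate(reachable):
        if pos < _WE_VERIFIED:
            outcomes[rid] = "verified"
        elif pos < _WE_VERIFIED + _WE_FAILED:
            outcomes[rid] = "failed"
        else:
            outcomes[rid] = "no_show"
    return cohort, labels, outcomes


# ---------------------------------------------------------------------------
# label IO

def write_labels_csv(labels, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["response_id", "persona", "planted_violations", "subreason"])
        for lab in labels:
            w.writerow([
                lab.response_id, lab.persona,
                ";".join(sorted(c.value for c in lab.planted_violations)),
                lab.subreason.value if lab.subreason else "",
            ])
    return path


def load_labels_csv(path) -> list:
    labels = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            viols = frozenset(Criterion(c) for c in row["planted_violations"].split(";") if c)
            labels.append(GroundTruthLabel(
                response_id=row["response_id"],
                persona=row["persona"],
                planted_violations=viols,
                subreason=Subreason(row["subreason"]) if row["subreason"] else None,
            ))
    return labels
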