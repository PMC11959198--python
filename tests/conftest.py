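"""Shared fixtures: worked-example funnel fixture and randomized cohorts.

The random cohort builder here is deliberately independent of the package's
synthetic generator so protocol property tests do not inherit its structure:
it throws together messy records (missing fields, shared IPs/emails, boundary
scores/durations) directly.
"""

from __future__ import annotations

from datetime import datetime, timedelta, timezone

import numpy as np
import pytest

from surveyscreen import Cohort, SurveyResponse, make_worked_example, run_protocol

_T0 = datetime(2024, 1, 1, tzinfo=timezone.utc)
_TERMS = ("woman", "man", "nonbinary", "trans man", "detransitioned", "genderfluid")
_COUNTRIES = ("US", "CA", "NG", "GB", "IN", None)


def random_cohort(seed: int, n: int = 200) -> Cohort:
    """Messy cohort exercising every criterion, duplicates, and missingness."""
    rng = np.random.default_rng(seed)
    ips = [f"192.0.2.{k}" for k in range(1, max(2, int(n * 0.7)))]
    emails = [f"user{k}@mail.example" for k in range(max(2, int(n * 0.8)))]
    records = []
    for i in range(n):
        tri = lambda: ("yes", "no", "unsure")[int(rng.integers(0, 3))]
        past = frozenset(rng.choice(_TERMS, size=int(rng.integers(0, 3)), replace=False))
        current = past if rng.random() < 0.3 else frozenset(
            rng.choice(_TERMS, size=int(rng.integers(0, 3)), replace=False))
        records.append(SurveyResponse(
            response_id=f"X{i:04d}",
            submitted_at=_T0 + timedelta(minutes=int(rng.integers(0, 10_000))),
            ip_address=ips[int(rng.integers(0, len(ips)))],
            geo_country=_COUNTRIES[int(rng.integers(0, len(_COUNTRIES)))],
            self_report_country=("US", "CA", "OTHER", None)[int(rng.integers(0, 4))],
            recaptcha_score=None if rng.random() < 0.1 else round(float(rng.random()), 3),
            duration_seconds=int(rng.integers(0, 4000)),
            email=None if rng.random() < 0.2 else emails[int(rng.integers(0, len(emails)))],
            consent_contact=bool(rng.integers(0, 2)),
            language=("en", "fr", "es")[int(rng.integers(0, 3))],
            age_years=None if rng.random() < 0.1 else int(rng.integers(16, 75)),
            sex_assigned_at_birth=(None, "female", "male")[int(rng.integers(0, 3))],
            social_transition=tri(),
            medical_transition=tri(),
            hormones_initial_transition=frozenset(
                rng.choice(("estrogen", "testosterone", "blockers", "none"),
                           size=int(rng.integers(0, 3)), replace=False)),
            gender_terms_past=past,
            gender_terms_current=current,
            social_transition_year=None if rng.random() < 0.3 else int(rng.integers(2005, 2024)),
            trap_chekalism=tri(),
            trap_syndomitis=tri(),
            geo_subdivision=None if rng.random() < 0.5 else ("NY", "ON", "TX")[int(rng.integers(0, 3))],
        ))
    return Cohort(records)


@pytest.fixture(scope="session")
def worked_example():
    return make_worked_example()


@pytest.fixture(scope="session")
def worked_report(worked_example):
    cohort, _, _ = worked_example
    return run_protocol(cohort)
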