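"""Exclusion criteria predicates and the ordered protocol runner.

The brute-force oracle below re-derives the excluded set independently:
every rule is applied as a flat, order-free predicate (duplicate detection by
per-key counting rather than the engine's identity clustering), and a record
is excluded iff any rule fires. Under the default remove_all policy the two
formulations must agree exactly.
"""

from __future__ import annotations

import itertools
from collections import Counter
from datetime import datetime, timedelta, timezone

import pytest

from surveyscreen import (
    Cohort,
    Criterion,
    ProtocolConfig,
    Subreason,
    check_gender_discordance,
    check_hormone_concordance,
    check_no_transition,
    check_trap_items,
    is_duplicate_identity,
    is_ineligible_nonsense,
    is_low_recaptcha,
    is_outside_region,
    run_protocol,
    score_email_plausibility,
)
from surveyscreen.errors import ConfigError

from conftest import random_cohort
from test_model_io import make_response

UTC = timezone.utc


def brute_force_excluded(cohort: Cohort, cfg: ProtocolConfig) -> set:
    """Independent order-free oracle for the excluded set (default policies)."""
    assert cfg.duplicate_policy == "remove_all" and cfg.duplicate_scope == "ip_or_email"
    assert cfg.geo_source == "ip_geo_then_self_report"
    assert cfg.missing_score_policy == "retain_flag"
    lex = cfg.lexicon()
    ip_counts = Counter(r.ip_address for r in cohort)
    email_counts = Counter(r.email.lower() for r in cohort if r.email is not None)
    excluded = set()
    for r in cohort:
        rules = [
            r.social_transition == "no" and r.medical_transition == "no",
            r.trap_chekalism == "yes" or r.trap_syndomitis == "yes",
            bool(r.gender_terms_past) and r.gender_terms_past == r.gender_terms_current,
            r.sex_assigned_at_birth == "female" and "estrogen" in r.hormones_initial_transition,
            r.sex_assigned_at_birth == "male" and "testosterone" in r.hormones_initial_transition,
            r.email is not None and score_email_plausibility(r.email, lex) != "ok",
        ]
        country = r.geo_country if r.geo_country is not None else r.self_report_country
        rules.append(country is not None and country not in cfg.allowed_countries)
        rules.append(r.recaptcha_score is not None
                     and r.recaptcha_score < cfg.recaptcha_threshold)
        rules.append(ip_counts[r.ip_address] >= 2
                     or (r.email is not None and email_counts[r.email.lower()] >= 2))
        rules.append(r.duration_seconds < cfg.min_duration_seconds)
        if any(rules):
            excluded.add(r.response_id)
    return excluded


class TestGeo:
    @pytest.mark.parametrize("country, expect", [("NG", True), ("CA", False), ("US", False)])
    def test_ip_geolocated_country(self, country, expect):
        assert is_outside_region(make_response(geo_country=country)) is expect

    @pytest.mark.parametrize(
        "geo_source, geo, self_rep, expect",
        # precedence matrix: ip geolocation first, then self-report
        [
            ("ip_geo", None, "OTHER", False),          # unresolved -> retained
            ("ip_geo", "NG", "US", True),
            ("self_report", "NG", "US", False),
            ("self_report", "US", "OTHER", True),
            ("ip_geo_then_self_report", None, "US", False),
            ("ip_geo_then_self_report", None, "OTHER", True),
            ("ip_geo_then_self_report", "NG", "US", True),
            ("ip_geo_then_self_report", None, None, False),  # fully unresolved
        ],
    )
    def test_geo_source_precedence(self, geo_source, geo, self_rep, expect):
        cfg = ProtocolConfig(geo_source=geo_source)
        r = make_response(geo_country=geo, self_report_country=self_rep)
        assert is_outside_region(r, cfg) is expect

    def test_unresolved_geo_is_flagged_by_runner(self):
        cohort = Cohort([make_response(geo_country=None, self_report_country=None)])
        report = run_protocol(cohort)
        assert "geo_unresolved" in report.decisions[0].flags


class TestRecaptcha:
    def test_strict_inequality_at_threshold(self):
        assert is_low_recaptcha(make_response(recaptcha_score=0.49)) is True
        assert is_low_recaptcha(make_response(recaptcha_score=0.5)) is False

    def test_missing_score_policy(self):
        r = make_response(recaptcha_score=None)
        assert is_low_recaptcha(r, ProtocolConfig()) is False
        assert is_low_recaptcha(r, ProtocolConfig(missing_score_policy="exclude")) is True


class TestEligibilityRules:
    @pytest.mark.parametrize("social, medical",
                             list(itertools.product(("yes", "no", "unsure"), repeat=2)))
    def test_no_transition_is_strict_conjunction_of_no(self, social, medical):
        r = make_response(social_transition=social, medical_transition=medical)
        assert check_no_transition(r) is (social == "no" and medical == "no")

    @pytest.mark.parametrize(
        "chek, synd, expect",
        [("yes", "no", True), ("no", "yes", True), ("no", "no", False),
         ("unsure", "unsure", False), ("yes", "yes", True)],
    )
    def test_trap_items_fire_only_on_yes(self, chek, synd, expect):
        r = make_response(trap_chekalism=chek, trap_syndomitis=synd)
        assert check_trap_items(r) is expect

    def test_gender_discordance_set_equality_is_order_free(self):
        r = make_response(gender_terms_past=frozenset({"nonbinary", "trans man"}),
                          gender_terms_current=frozenset({"trans man", "nonbinary"}))
        assert check_gender_discordance(r) is True
        r2 = make_response(gender_terms_past=frozenset({"man"}),
                           gender_terms_current=frozenset({"woman"}))
        assert check_gender_discordance(r2) is False
        empty = make_response(gender_terms_past=frozenset(), gender_terms_current=frozenset())
        assert check_gender_discordance(empty) is False

    @pytest.mark.parametrize(
        "sex, hormones, expect",
        [
            ("female", {"estrogen"}, True),
            ("female", {"testosterone"}, False),
            ("male", {"testosterone", "blockers"}, True),
            ("male", {"estrogen"}, False),
            ("female", {"blockers", "none"}, False),
            (None, {"estrogen", "testosterone"}, False),
        ],
    )
    def test_hormone_sex_concordance(self, sex, hormones, expect):
        r = make_response(sex_assigned_at_birth=sex,
                          hormones_initial_transition=frozenset(hormones))
        assert check_hormone_concordance(r) is expect


class TestDuplicates:
    def _trio(self, **third_over):
        t0 = datetime(2024, 1, 1, tzinfo=UTC)
        return Cohort([
            make_response(response_id="A", ip_address="10.0.0.1", email="a@x.com",
                          submitted_at=t0),
            make_response(response_id="B", ip_address="10.0.0.1", email="b@x.com",
                          submitted_at=t0 + timedelta(hours=1)),
            make_response(response_id="C", ip_address="10.0.0.1", email="c@x.com",
                          submitted_at=t0 + timedelta(hours=2), **third_over),
        ])

    def test_remove_all_excludes_every_member_of_an_ip_cluster(self):
        cohort = self._trio()
        cfg = ProtocolConfig(duplicate_policy="remove_all")
        assert all(is_duplicate_identity(r, cohort, cfg) for r in cohort)

    def test_unique_ip_and_email_is_not_duplicate(self):
        cohort = Cohort([make_response(response_id="A", ip_address="10.0.0.1", email="a@x.com"),
                         make_response(response_id="B", ip_address="10.0.0.2", email="b@x.com")])
        assert not is_duplicate_identity(cohort["A"], cohort)

    def test_keep_first_retains_earliest_submission(self):
        t0 = datetime(2024, 1, 1, tzinfo=UTC)
        cohort = Cohort([
            make_response(response_id="L", ip_address="10.0.0.9", email="l@x.com",
                          submitted_at=t0 + timedelta(hours=2)),
            make_response(response_id="E", ip_address="10.0.0.9", email="e@x.com",
                          submitted_at=t0),
        ])
        cfg = ProtocolConfig(duplicate_policy="keep_first")
        assert is_duplicate_identity(cohort["E"], cohort, cfg) is False
        assert is_duplicate_identity(cohort["L"], cohort, cfg) is True

    def test_email_match_is_case_insensitive_and_missing_never_matches(self):
        cohort = Cohort([
            make_response(response_id="A", ip_address="10.0.0.1", email="Same@X.com"),
            make_response(response_id="B", ip_address="10.0.0.2", email="same@x.com"),
            make_response(response_id="C", ip_address="10.0.0.3", email=None),
            make_response(response_id="D", ip_address="10.0.0.4", email=None),
        ])
        assert is_duplicate_identity(cohort["A"], cohort)
        assert is_duplicate_identity(cohort["B"], cohort)
        assert not is_duplicate_identity(cohort["C"], cohort)
        assert not is_duplicate_identity(cohort["D"], cohort)

    def test_scope_ip_ignores_shared_email(self):
        cohort = Cohort([
            make_response(response_id="A", ip_address="10.0.0.1", email="same@x.com"),
            make_response(response_id="B", ip_address="10.0.0.2", email="same@x.com"),
        ])
        cfg = ProtocolConfig(duplicate_scope="ip")
        assert not is_duplicate_identity(cohort["A"], cohort, cfg)


class TestIneligibleNonsense:
    def test_subreason_attribution_follows_fixed_order(self):
        # violates both the trap rule and the hormone rule: trap wins
        r = make_response(trap_chekalism="yes", sex_assigned_at_birth="female",
                          hormones_initial_transition=frozenset({"estrogen"}))
        assert is_ineligible_nonsense(r) == Subreason.TRAP_ITEM

    def test_no_transition_outranks_everything(self):
        r = make_response(social_transition="no", medical_transition="no",
                          trap_syndomitis="yes")
        assert is_ineligible_nonsense(r) == Subreason.NO_TRANSITION

    def test_clean_record_has_no_subreason(self):
        assert is_ineligible_nonsense(make_response()) is None

    def test_email_subreason_is_last_resort(self):
        r = make_response(email="xkqzwtrvplq@x.com")
        assert is_ineligible_nonsense(r) == Subreason.EMAIL_IMPLAUSIBLE


class TestRunner:
    def test_empty_cohort(self):
        report = run_protocol(Cohort([]))
        assert report.input_count == 0
        assert sum(report.per_criterion_counts.values()) == 0
        assert report.retained_ids == frozenset()

    def test_invalid_criterion_order_is_config_error(self):
        with pytest.raises(ConfigError, match="permutation"):
            ProtocolConfig(criterion_order=("GEO_OUTSIDE",)).validate()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_retained_set_matches_brute_force_oracle(self, seed):
        cohort = random_cohort(seed, n=300)
        cfg = ProtocolConfig()
        report = run_protocol(cohort, cfg)
        oracle_excluded = brute_force_excluded(cohort, cfg)
        assert report.excluded_ids == oracle_excluded
        assert report.retained_ids == set(cohort.ids) - oracle_excluded

    @pytest.mark.parametrize("seed", [3, 4])
    def test_conservation_invariant(self, seed):
        report = run_protocol(random_cohort(seed, n=250))
        report.check_conservation()
        assert report.input_count == len(report.retained_ids) + \
            sum(report.per_criterion_counts.values())

    def test_excluded_set_is_order_invariant(self):
        cohort = random_cohort(7, n=200)
        base = run_protocol(cohort).excluded_ids
        for perm in itertools.islice(itertools.permutations([c.value for c in Criterion]), 0, 24):
            cfg = ProtocolConfig(criterion_order=perm)
            assert run_protocol(cohort, cfg).excluded_ids == base

    def test_idempotence_on_retained_set(self):
        cohort = random_cohort(11, n=250)
        report = run_protocol(cohort)
        rerun = run_protocol(cohort.subset(report.retained_ids))
        assert rerun.excluded_ids == frozenset()

    def test_threshold_monotonicity(self):
        cohort = random_cohort(13, n=250)
        base = run_protocol(cohort, ProtocolConfig()).excluded_ids
        stricter_score = run_protocol(cohort, ProtocolConfig(recaptcha_threshold=0.8)).excluded_ids
        stricter_time = run_protocol(cohort, ProtocolConfig(min_duration_seconds=1500)).excluded_ids
        assert stricter_score >= base
        assert stricter_time >= base

    def test_duplicate_policy_dominance(self):
        cohort = random_cohort(17, n=250)
        remove_all = run_protocol(cohort, ProtocolConfig(duplicate_policy="remove_all"))
        keep_first = run_protocol(cohort, ProtocolConfig(duplicate_policy="keep_first"))
        assert remove_all.excluded_ids >= keep_first.excluded_ids

    def test_attribution_is_first_match_in_configured_order(self):
        # record that matches both GEO_OUTSIDE and FAST_COMPLETION
        r = make_response(geo_country="NG", duration_seconds=60)
        cohort = Cohort([r])
        default = run_protocol(cohort)
        assert default.decisions[0].attributed_criterion == Criterion.GEO_OUTSIDE
        flipped = ProtocolConfig(criterion_order=(
            "FAST_COMPLETION", "DUPLICATE_IDENTITY", "LOW_RECAPTCHA",
            "GEO_OUTSIDE", "INELIGIBLE_NONSENSE"))
        assert run_protocol(cohort, flipped).decisions[0].attributed_criterion \
            == Criterion.FAST_COMPLETION

    def test_subreason_only_reported_for_nonsense_attribution(self):
        r = make_response(geo_country="NG", trap_chekalism="yes")
        order = ("GEO_OUTSIDE", "INELIGIBLE_NONSENSE", "LOW_RECAPTCHA",
                 "DUPLICATE_IDENTITY", "FAST_COMPLETION")
        d = run_protocol(Cohort([r]), ProtocolConfig(criterion_order=order)).decisions[0]
        assert d.attributed_criterion == Criterion.GEO_OUTSIDE
        assert d.subreason is None
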