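"""Evaluation against ground truth, operating-characteristic sweeps, and
flow/demographic reporting.

A record counts as *positive* (fraudulent or ineligible) iff its planted
violation set is nonempty; predictions are taken from the final,
post-readmission disposition. The flow summary is the Sankey/CONSORT-style
edge list (completed -> per-criterion exclusions -> screening funnel -> final
eligible) with conservation enforced at every internal node. Demographic
helpers reproduce the report semantics of multi-select tables (percentages
may sum past 100; skipped respondents reported separately) and the age
summary (sample SD, linear-interpolation quantiles).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, IntegrityError, SchemaError
from .exclusion import Criterion, ExclusionReport, ProtocolConfig, run_protocol
from .model import Cohort
from .screening import (
    CaseState,
    FinalDisposition,
    apply_screening_outcomes,
    build_screening_queue,
)
from .synth import CohortSpec, generate_cohort


# ---------------------------------------------------------------------------
# truth evaluation

@dataclass
class EvaluationResult:
    """Confusion counts and screening-protocol operating characteristics.

    Rates with an undefined denominator are ``None``. ``screening_cost`` is
    screenings performed (attended interviews) per readmitted response.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    per_criterion_sensitivity: dict = field(default_factory=dict)
    screening_cost: Optional[float] = None
    false_positive_ids: tuple = ()

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv,
            "per_criterion_sensitivity": {c.value: v for c, v in self.per_criterion_sensitivity.items()},
            "screening_cost": self.screening_cost,
            "false_positive_ids": list(self.false_positive_ids),
        }


def _rate(num: int, den: int) -> Optional[float]:
    return num / den if den else None


def evaluate_against_truth(disposition: FinalDisposition, labels) -> EvaluationResult:
    """Confusion matrix of final exclusion decisions against planted truth."""
    by_id = {lab.response_id: lab for lab in labels}
    missing = disposition.all_ids - set(by_id)
    if missing:
        raise IntegrityError(f"unlabeled response id(s): {sorted(missing)[:5]}")

    excluded = disposition.final_excluded_ids
    tp = fp = tn = fn = 0
    false_positives = []
    for rid in disposition.all_ids:
        positive = by_id[rid].is_fraud_or_ineligible
        if positive and rid in excluded:
            tp += 1
        elif positive:
            fn += 1
        elif rid in excluded:
            fp += 1
            false_positives.append(rid)
        else:
            tn += 1

    per_crit = {}
    for crit in Criterion:
        with_c = [lab for lab in labels
                  if lab.response_id in disposition.all_ids and crit in lab.planted_violations]
        per_crit[crit] = _rate(sum(1 for lab in with_c if lab.response_id in excluded), len(with_c))

    n_readmitted = len(disposition.readmitted_ids)
    attended = disposition.funnel.get("attended", 0)
    return EvaluationResult(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=_rate(tp, tp + fn),
        specificity=_rate(tn, tn + fp),
        ppv=_rate(tp, tp + fp),
        npv=_rate(tn, tn + fn),
        per_criterion_sensitivity=per_crit,
        screening_cost=_rate(attended, n_readmitted),
        false_positive_ids=tuple(sorted(false_positives)),
    )


# ---------------------------------------------------------------------------
# screening simulation (used by the OC sweep)

def simulate_screening(cohort: Cohort, report: ExclusionReport, labels, spec: CohortSpec,
                       rng: np.random.Generator) -> FinalDisposition:
    """Simulate attendance and verification with persona probabilities.

    Flagged cases attend with their persona's ``attend_prob``; attendees pass
    verification with ``verify_pass_prob``. Everyone else no-shows.
    """
    persona_of = {lab.response_id: lab.persona for lab in labels}
    queue = build_screening_queue(report, cohort)
    for case in queue.cases:
        p = spec.persona(persona_of[case.response_id])
        case.advance(CaseState.INVITED).advance(CaseState.SCHEDULED)
        if rng.random() < p.attend_prob:
            case.advance(CaseState.ATTENDED)
            case.advance(CaseState.VERIFIED if rng.random() < p.verify_pass_prob
                         else CaseState.FAILED)
        else:
            case.advance(CaseState.NO_SHOW)
    return apply_screening_outcomes(report, queue.cases)


# ---------------------------------------------------------------------------
# operating-characteristic sweep

def _apply_override(spec: CohortSpec, key: str, value) -> CohortSpec:
    """Override 'n', 'seed', or 'PERSONA.field' on a copy of the spec."""
    import copy

    spec = copy.deepcopy(spec)
    if key in ("n", "seed"):
        setattr(spec, key, value)
        return spec
    persona_name, _, fieldname = key.partition(".")
    if not fieldname:
        raise ConfigError(f"grid key {key!r} must be 'n', 'seed', or 'PERSONA.field'")
    p = spec.persona(persona_name)
    if not hasattr(p, fieldname):
        raise ConfigError(f"persona {persona_name} has no field {fieldname!r}")
    setattr(p, fieldname, value)
    return spec


def child_seed(seed: int, point_index: int, rep: int) -> int:
    """Deterministic per-(grid point, replicate) seed below 2**31."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(point_index, rep))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_oc_point(base_spec: CohortSpec, overrides: dict, seed: int,
                 cfg: ProtocolConfig = None) -> dict:
    """One replicate: generate, run the protocol, simulate screening, score."""
    spec = base_spec
    for key, value in overrides.items():
        spec = _apply_override(spec, key, value)
    spec.seed = seed
    cohort, labels = generate_cohort(spec)
    report = run_protocol(cohort, cfg or ProtocolConfig())
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(7,)))
    disposition = simulate_screening(cohort, report, labels, spec, rng)
    ev = evaluate_against_truth(disposition, labels)
    n = len(cohort)
    return {
        "sensitivity": ev.sensitivity,
        "specificity": ev.specificity,
        "eligible_yield": len(disposition.final_retained_ids) / n if n else None,
        "screenings_per_readmission": ev.screening_cost,
        "n_positives": ev.tp + ev.fn,
        "n_excluded_final": ev.tp + ev.fp,
    }


METRICS = ("sensitivity", "specificity", "eligible_yield", "screenings_per_readmission")


def oc_sweep(base_spec: CohortSpec, grid: dict, reps: int, seed: int,
             cfg: ProtocolConfig = None) -> pd.DataFrame:
    """Sweep protocol operating characteristics over a parameter grid.

    ``grid`` maps override keys (``'n'``, ``'seed'``, or ``'PERSONA.field'``)
    to value lists; the cross product defines the grid points. Each point is
    replicated ``reps`` times with deterministic per-replicate seeds, so the
    sweep is reproducible row-for-row. Returns a tidy per-replicate frame.
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ConfigError("parameter grid must be nonempty")
    if reps < 1:
        raise ConfigError("reps must be >= 1")
    keys = sorted(grid)
    rows = []
    for pi, values in enumerate(itertools.product(*(grid[k] for k in keys))):
        point = dict(zip(keys, values))
        for rep in range(reps):
            metrics = run_oc_point(base_spec, point, child_seed(seed, pi, rep), cfg)
            rows.append({**point, "point": pi, "rep": rep, **metrics})
    return pd.DataFrame(rows)


def oc_summary(table: pd.DataFrame, grid_keys) -> pd.DataFrame:
    """Per-grid-point means with Monte-Carlo standard errors."""
    grid_keys = list(grid_keys)
    out = []
    for point_vals, grp in table.groupby(grid_keys, dropna=False):
        if not isinstance(point_vals, tuple):
            point_vals = (point_vals,)
        row = dict(zip(grid_keys, point_vals))
        row["reps"] = len(grp)
        for m in METRICS:
            vals = grp[m].dropna().astype(float)
            row[f"{m}_mean"] = vals.mean() if len(vals) else None
            row[f"{m}_se"] = (vals.std(ddof=1) / np.sqrt(len(vals))
                              if len(vals) > 1 else None)
        out.append(row)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# flow summary

@dataclass
class FlowSummary:
    """Directed edge list with counts; conserves flow at every internal node."""

    edges: list  # (source, target, count)

    def node_balance(self) -> dict:
        balance = {}
        for src, dst, count in self.edges:
            balance[src] = balance.get(src, 0) - count
            balance[dst] = balance.get(dst, 0) + count
        return balance

    def check_conservation(self, sources=("completed",), sinks=("final_eligible", "removed")) -> None:
        for node, bal in self.node_balance().items():
            if node in sources or node in sinks:
                continue
            if bal != 0:
                raise IntegrityError(f"flow not conserved at node {node!r}: imbalance {bal}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["source", "target", "count"])

    def write_csv(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False, lineterminator="\n")
        return path


def flow_summary(report: ExclusionReport,
                 disposition: Optional[FinalDisposition] = None) -> FlowSummary:
    """Build the exclusion/screening Sankey edge list.

    Without a disposition: completed -> retained/each criterion -> removed.
    With one: exclusions flow through reachable/unreachable, the screening
    funnel (attended, no-show, pending), and readmissions into the final
    eligible pool.
    """
    edges = []
    n_retained = len(report.retained_ids)
    edges.append(("completed", "retained_pre_screen", n_retained))
    for crit in Criterion:
        count = report.per_criterion_counts.get(crit, 0)
        if count:
            edges.append(("completed", f"excluded:{crit.value}", count))
            edges.append((f"excluded:{crit.value}", "excluded_pool", count))

    if disposition is None:
        pool = sum(report.per_criterion_counts.values())
        if pool:
            edges.append(("excluded_pool", "removed", pool))
        summary = FlowSummary([e for e in edges if e[2] > 0])
        summary.check_conservation(sinks=("retained_pre_screen", "removed"))
        return summary

    if disposition.pre_screen_retained_ids != report.retained_ids:
        raise IntegrityError("disposition does not match report: retained sets differ "
                             "(node retained_pre_screen)")
    f = disposition.funnel
    edges.append(("excluded_pool", "flagged", f["flagged"]))
    edges.append(("excluded_pool", "unreachable", f["unreachable"]))
    edges.append(("flagged", "attended", f["attended"]))
    edges.append(("flagged", "no_show", f["no_show"]))
    not_interviewed = f["flagged"] - f["attended"] - f["no_show"]
    edges.append(("flagged", "not_interviewed", not_interviewed))
    edges.append(("attended", "readmitted", f["verified"]))
    edges.append(("attended", "screen_failed", f["failed"]))
    edges.append(("retained_pre_screen", "final_eligible", n_retained))
    edges.append(("readmitted", "final_eligible", f["verified"]))
    for terminal in ("unreachable", "no_show", "not_interviewed", "screen_failed"):
        count = sum(c for _, dst, c in edges if dst == terminal)
        if count:
            edges.append((terminal, "removed", count))
    summary = FlowSummary([e for e in edges if e[2] > 0])
    summary.check_conservation()
    if len(disposition.final_retained_ids) != n_retained + f["verified"]:
        raise IntegrityError("flow not conserved at node 'final_eligible'")
    return summary


# ---------------------------------------------------------------------------
# demographic reporting

_SET_FIELDS = ("hormones_initial_transition", "gender_terms_past", "gender_terms_current")


def tabulate_multiselect(cohort: Cohort, fieldname: str) -> pd.DataFrame:
    """Frequency table for a multi-select field.

    The denominator is the number of respondents with a nonempty answer, so
    percentages may sum past 100. Respondents with an empty answer are
    reported separately via ``df.attrs['skipped']``.
    """
    if fieldname not in _SET_FIELDS:
        raise SchemaError(f"{fieldname!r} is not a set-valued field; choose from {_SET_FIELDS}")
    counts = {}
    answered = skipped = 0
    for r in cohort:
        values = getattr(r, fieldname)
        if not values:
            skipped += 1
            continue
        answered += 1
        for v in sorted(values):
            counts[v] = counts.get(v, 0) + 1
    rows = [
        {"option": opt, "count": counts[opt],
         "percent": round(100.0 * counts[opt] / answered, 1)}
        for opt in sorted(counts, key=lambda o: (-counts[o], o))
    ]
    df = pd.DataFrame(rows, columns=["option", "count", "percent"])
    df.attrs["denominator"] = answered
    df.attrs["skipped"] = skipped
    return df


@dataclass
class AgeSummary:
    n: int
    missing: int
    mean: Optional[float]
    sd: Optional[float]      # sample SD (n-1); None when n < 2
    median: Optional[float]
    q1: Optional[float]
    q3: Optional[float]
    iqr: Optional[float]
    age_min: Optional[int]
    age_max: Optional[int]
    hist_bin_edges: tuple = ()
    hist_counts: tuple = ()

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["hist_bin_edges"] = list(self.hist_bin_edges)
        d["hist_counts"] = list(self.hist_counts)
        return d


def age_summary(cohort: Cohort, bin_width: int = 5) -> AgeSummary:
    """Mean/SD/median/IQR/range and histogram of nonmissing ages.

    Quantiles use linear interpolation; SD uses the n-1 denominator. With no
    nonmissing ages an empty summary (n=0, all statistics None) is returned.
    """
    ages = np.array([r.age_years for r in cohort if r.age_years is not None], dtype=float)
    missing = len(cohort) - len(ages)
    if len(ages) == 0:
        return AgeSummary(0, missing, None, None, None, None, None, None, None, None)
    q1, med, q3 = np.quantile(ages, [0.25, 0.5, 0.75])  # linear interpolation
    lo = int(np.floor(ages.min() / bin_width) * bin_width)
    hi = int(np.ceil((ages.max() + 1) / bin_width) * bin_width)
    edges = np.arange(lo, hi + 1, bin_width)
    counts, _ = np.histogram(ages, bins=edges)
    return AgeSummary(
        n=len(ages),
        missing=missing,
        mean=float(ages.mean()),
        sd=float(ages.std(ddof=1)) if len(ages) > 1 else None,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        iqr=float(q3 - q1),
        age_min=int(ages.min()),
        age_max=int(ages.max()),
        hist_bin_edges=tuple(int(e) for e in edges),
        hist_counts=tuple(int(c) for c in counts),
    )


def write_evaluation_json(result: EvaluationResult, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(result.to_dict(), indent=1, sort_keys=True) + "\n",
                    encoding="utf-8")
    return path
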