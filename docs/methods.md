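# Methods

## Problem and model

Web surveys of small, hard-to-reach populations attract fraudulent
submissions — scripted bots, paid click-farm workers, hostile trolls — at
rates that can rival the genuine response volume, especially when a
completion incentive exists. `surveyscreen` models anti-fraud screening as a
two-stage decision procedure over a table of completed responses:

1. a deterministic, ordered **exclusion protocol** of five criteria (logic
   and consistency checks, geolocation, bot score, duplicate identity,
   completion speed), where the excluded *set* is the union of all matches
   and the attribution *order* only decides which criterion a response is
   counted under; and
2. a human **verification workflow** with readmission: reachable excluded
   respondents are interviewed, their answers compared to the survey record,
   and consistent cases returned to the analytic set.

Because real screening decisions hinge on free-text judgment in places, the
package deliberately automates only the mechanizable rules and exposes the
judgment calls as manual interviewer flags (vague answers, audio anomalies,
daylight inconsistencies). Reasons for stopping or reversing transition
(interview question six) are recorded but never auto-scored; semantic
matching of open-ended motivations would overreach what a rule can defend.

## Exclusion criteria and parameters

| Parameter | Default | Unit | Rationale |
|---|---|---|---|
| `recaptcha_threshold` | 0.5 | score in [0,1] | platform guidance for likely-bot traffic; strict `<` so 0.5 is retained |
| `min_duration_seconds` | 720 | s | 12 min against an expected 35–60 min completion; strict `<` |
| `allowed_countries` | {US, CA} | ISO alpha-2 | the study's sampling frame |
| `geo_source` | ip_geo_then_self_report | — | IP geolocation is harder to fake than self-report, so it takes precedence; self-report fills gaps |
| `duplicate_scope` | ip_or_email | — | "identity" = shared IP and/or case-insensitive email (transitive closure); missing emails never match each other |
| `duplicate_policy` | remove_all | — | every member of a duplicate cluster is removed; `keep_first` (earliest submission kept) is offered for studies that retain one response per identity |
| `missing_score_policy` | retain_flag | — | excluding unscored traffic would punish a platform artifact; flagged instead |
| email entropy cutoff / min length / consonant run | 3.8 bits / 10 / 6 | — | see below |

The ineligible/nonsense bucket resolves subreasons in a fixed order
(no transition → trap item → no gender discordance → hormone–sex mismatch →
implausible email), chosen from strongest to weakest signal: the logic rules
are definitional, the email heuristic is probabilistic. "Unsure" never
triggers any rule — only affirmative trap answers and explicit double-"no"
transition answers exclude. A record whose discordance check cannot be
assessed (empty term sets) or whose geolocation cannot be resolved is
retained and flagged (`discordance_unassessable`, `geo_unresolved`) rather
than excluded; screening is the place to resolve ambiguity, not the filter.

**Email plausibility.** No published rule defines a "nonsense" or "hateful"
address, so the classifier is an explicit heuristic: hateful iff a lexicon
term occurs (substring or whole-token entries); nonsense iff the local part
has ≥ 6 consecutive consonants or, at length ≥ 10, character-bigram entropy
above 3.8 bits. The entropy bound is only reachable at ≥ 15 characters
(log₂(14) ≈ 3.81), which is intended: short ordinary names can never trip
it, keyboard mashes almost always do. The packaged lexicon contains clearly
synthetic placeholder tokens only; deployments must supply a curated list.
The default configuration loads this packaged lexicon so the hateful
category is exercisable out of the box; setting `nonsense_lexicon_path: ""`
disables it.

## Verification workflow

Cases move through `FLAGGED → INVITED → SCHEDULED → {ATTENDED, NO_SHOW}`,
`ATTENDED → {VERIFIED, FAILED}`; all other transitions raise. Verification
compares interview answers with the months-old survey record under
tolerances: age ±1 year (a birthday may have passed), social-transition year
±1, location match at country+subdivision level (case-insensitive; survey
fields that are missing are skipped rather than failed), and gender terms by
nonempty intersection — identities in this population are multi-select and
fluid, so demanding set equality would fail genuine respondents; strict
equality remains available. Any manual interviewer flag fails the case
regardless of answer agreement.

Scheduling anomalies reflect observed fraud behavior: sign-ups from a
suspicious timezone list (packaged: the West African cluster) or from a
timezone whose UTC offset lies more than 3 h outside the response country's
offset range (packaged country table; offsets evaluated at a fixed January
reference instant so DST cannot flip a verdict), and sign-ups from emails
never invited. These feed the manual review, they do not auto-fail a case.

## Synthetic cohorts

The generator emulates a contaminated respondent pool through five personas
(GENUINE, BOT, FARM, TROLL, CARELESS) with declarative distributions:
GENUINE durations lognormal with median 45 min and reCAPTCHA Beta(9,1)
(mean 0.9); BOT median 4 min, Beta(2,8), frequent trap hits and nonsense
emails; FARM duplicate-IP clusters of 2–6 and 80% out-of-region origin;
TROLL placeholder-token emails; CARELESS genuine-like respondents with a
30% accidental trap-hit rate, the designed source of false positives. All
parameters are package-defined study conditions — no distribution is an
estimate of any real dataset, and passing tests on these cohorts shows the
protocol's accounting and ordering behave correctly, not that the thresholds
would achieve any particular sensitivity on real traffic. Real-data features
deliberately not emulated: free-text answer content, coordinated timing
bursts, IP rotation within a submission session, and plausible-but-fake
identity documents.

Each persona draws from its own spawned random stream in a fixed canonical
order, and every record consumes an identical branch-free draw sequence, so
(a) a persona's records are invariant to other personas' weights and (b)
raising a violation probability only flips per-record comparisons (common
random numbers), which the monotonicity tests rely on. Duplicate-cluster
sizing uses a separate stream because cluster count depends on cohort size.
Ground-truth labels are defined as the violations whose predicates actually
fire under the default configuration, checked exhaustively per cohort.

## The worked example

`make_worked_example()` is a fixed 1377-record fixture whose planted
violations are disjoint — each excluded record fires exactly one criterion —
so attribution is order-independent and the per-criterion counts
(166 ineligible/nonsense, 165 outside-region, 74 low-reCAPTCHA, 30
duplicate, 13 fast; 448 total) are structural, not sampled. Among the
excluded, exactly 190 consented and left an email; the packaged outcome
table records 48 attendees (25.3%), of whom 28 verify and 20 fail, with 142
no-shows, closing the funnel at 957 eligible of 1377 (69.5%). Overlapping
violations for order-sensitivity tests come from the randomized generator
instead. The source material's own funnel arithmetic is internally
inconsistent (its results text implies 20 readmissions, its discussion 30,
while only 28 closes to the headline 957); the fixture adopts the
28-readmission closure because it is the unique value consistent with the
headline count, and takes no position on which printed sentence erred.

The ineligible/nonsense bucket's internal split (60 no-transition, 55 trap,
30 no-discordance, 16 hormone-mismatch, 5 hateful-email) is package-defined:
only the bucket total and the five hateful-email removals are externally
anchored.

## Numerical and design choices

* Thresholds use strict inequality at both boundaries (score 0.5 and 720 s
  are retained), matching the "<" wording of the protocol they implement.
* Duplicate keep-first ties on identical timestamps break by response id.
* Quantiles (age IQR) use linear interpolation; SD uses the n−1 denominator;
  percentages in report tables round to one decimal.
* Multi-select tables use respondents-with-a-nonempty-answer as the
  denominator, so percentages may sum past 100; skips are reported
  separately.
* The flow summary enforces conservation at every internal Sankey node and
  refuses to render an unbalanced funnel (e.g., unresolved ATTENDED cases).
* OC sweeps seed each (grid point, replicate) pair independently below 2³¹
  via `SeedSequence(seed, spawn_key=(point, rep))`, making tables
  reproducible row-for-row; summaries report Monte-Carlo standard errors.
* Problem sizes in the test suite and sweeps (cohorts of 200–500, a 3-point
  × 5-replicate sweep at n = 400) were chosen as the smallest sizes at which
  every property is exercised, including duplicate clusters and all five
  criteria simultaneously.

## Limitations

* The email heuristic is a deliberately simple stand-in for human review;
  its thresholds are defensible but not validated against labeled fraud.
* IP geolocation is consumed as a column; no lookup service is called, and
  geolocation error is outside the model.
* Evaluation treats planted-violation records as ground-truth positives;
  with generator-derived labels, pre-screen sensitivity and specificity are
  1 by construction, so discrimination claims require hand-built or external
  labels (the evaluation API accepts any label set).
* The state machine models one invitation round; re-invitations, rescheduling,
  and partial interviews are not represented.
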