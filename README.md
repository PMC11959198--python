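# surveyscreen

Screening pipeline for web-survey datasets contaminated by bot, scam, and
ineligible responses, built for studies that recruit hard-to-reach
populations online — the motivating case is a US/Canada survey of people with
experience of stopping, shifting, or reversing a gender transition, where
gift-card incentives attract large volumes of fraudulent submissions.

The package is for survey methodologists and study teams who need to (a)
apply a transparent, ordered exclusion protocol to a raw response export,
(b) run a verification-interview workflow that can readmit wrongly excluded
respondents, and (c) quantify the operating characteristics of the whole
protocol on synthetic cohorts with known ground truth.

## The protocol

Each completed response `r` is tested against five criteria; the excluded
set is the union of all matches, and each excluded response is *attributed*
to the first matching criterion in a configurable order (attribution changes
per-criterion counts, never membership):

1. **Ineligible / nonsense answers** — a composite bucket resolved in fixed
   subreason order: neither socially nor medically transitioned; answered
   "yes" to a fictitious-condition trap item ("chekalism", "syndomitis");
   no discordance between past and current gender-term sets
   (`past = current ≠ ∅`); assigned sex conflicts with the hormone started
   at initial transition (AFAB + estrogen, AMAB + testosterone); nonsense or
   hateful contact email (consonant-run ≥ 6 or bigram entropy > 3.8 bits,
   lexicon match).
2. **Outside allowed region** — resolved country (IP geolocation, falling
   back to self-report) not in {US, CA}.
3. **Low reCAPTCHA score** — score < 0.5 (strict; 0.5 is retained).
4. **Duplicate identity** — shares an IP and/or case-insensitive email with
   another completed response (remove-all by default; keep-first optional).
5. **Fast completion** — duration < 720 s (12 min) against an expected
   35–60 min completion.

Excluded respondents who consented to contact and left an email enter a
screening queue (`FLAGGED → INVITED → SCHEDULED → ATTENDED/NO_SHOW →
VERIFIED/FAILED`); interview answers are checked against the survey record
with configurable tolerances, and `VERIFIED` cases are readmitted to the
analytic set.

## Worked example

The packaged worked example is a seeded synthetic cohort of 1377 responses
with disjointly planted violations and a fixed screening-outcome table:

```bash
surveyscreen synth --preset worked-example --outdir out/synth
surveyscreen screen --input out/synth/cohort.csv --outdir out/screen
surveyscreen finalize --input out/synth/cohort.csv \
    --report out/screen/exclusion_report.json \
    --outcomes out/synth/screening_outcomes.csv --outdir out/final
cat out/final/funnel.json
```

prints

```json
{
 "attendance_rate_pct": 25.3,
 "attended": 48,
 "failed": 20,
 "final_eligible": 957,
 "flagged": 190,
 "invited": 190,
 "no_show": 142,
 "pending": 0,
 "unreachable": 258,
 "verified": 28
}
```

Reading the funnel: of 1377 completed responses, 448 are excluded by the
automated protocol (166 ineligible/nonsense, 165 outside US/Canada, 74 low
reCAPTCHA, 30 duplicate identity, 13 too fast — see
`out/screen/exclusion_report.json`). Of the excluded, 190 were reachable and
invited to a verification interview; 48 attended (25.3%), 28 were verified
and readmitted, so the final analytic set holds 957 responses (69.5% of
1377). `out/final/flow_edges.csv` is a Sankey-ready edge list of the same
accounting.

Library use mirrors the CLI: `make_worked_example()`, `run_protocol()`,
`build_screening_queue()`, `apply_screening_outcomes()`,
`evaluate_against_truth()`, `oc_sweep()`.

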