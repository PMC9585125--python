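# Methods

## The assessment scheme

Structural alerts — substructures hypothesised to drive a toxicological
effect — vary enormously in how well they are documented, validated and
mechanistically grounded. `alertconfide` implements a structured rubric for
making that variation explicit and comparable.

Twelve assessable criteria cover the definition of an alert (structural
description, property domain, endpoint/adversity, species specificity,
metabolic domain), its mechanistic grounding (mechanistic interpretation and
causality), its evidence base (corroborating and supporting evidence), its
stated purpose, and two objective, computable properties (coverage and
performance). Each criterion is assessed at one of three confidence levels —
high (3), moderate (2), low (1) — or marked not-applicable (NA). The
three-level scale is deliberately coarse: finer gradations invite
false precision in what is ultimately expert judgement.

Criteria carry importance tiers with default weights:

| tier | criteria | weight |
| --- | --- | --- |
| essential | structural description, property domain, toxicity/adversity, species specificity, corroborating evidence | 10 |
| desirable | metabolic domain, mechanistic interpretation, mechanistic causality | 5 |
| optional | purpose, coverage, performance, supporting evidence | 2 |

The weights are acknowledged to be conventional rather than derived; the
registry and weighting scheme are packaged as editable YAML so users can
substitute their own (a `validate_weighting_scheme` report checks coverage
and positivity of any replacement).

## Confidence scores

For a complete profile with numeric levels `s_i` and weights `w_i`, over the
applicable (non-NA) criteria:

    mean score     = (1/n) Σ s_i
    weighted score = Σ(w_i · s_i) / Σ(w_i)

Both live on the scale from 3 (greatest confidence) to 1 (lowest). NA
criteria are excluded from numerator and denominator alike — the only
treatment that preserves the 1–3 scale; a profile that is NA everywhere has
no score and raises an error rather than returning a sentinel.

Numerical notes: the weighted score is a convex combination of values in
[1, 3], but summing uneven float weights can overshoot the bound by one ulp,
so both scores are clamped to [1, 3] after computation. Reports round to 4
decimal places; full precision is kept internally. Profile comparison sorts
by weighted score, then mean score, then alert id (a deterministic
tie-break).

A single score can mask an unacceptable weakness in one criterion, so the
radar representation (criteria ordered essential → desirable → optional, NA
axes drawn as gaps rather than zeros) is the primary reporting view, with the
scores as summaries.

## Use-case fitness

Five packaged requirement profiles give the ideal minimum level per criterion
for: hazard identification, mechanism-based analogue identification, category
identification, classification & labelling, and screening/prioritisation.
Some cells admit two adjacent levels; the default (permissive) reading takes
the lower as the acceptable minimum, and a strict mode takes the higher —
the source scheme does not disambiguate, so both are exposed and neither is
asserted as its intent. A criterion is a *gap* when its assessed numeric
level falls strictly below the required minimum. An NA assessment cannot be
compared numerically: it is reported as a distinct `not_assessable` gap when
the requirement demands moderate or better, and accepted when the requirement
is only low. Fitness is reported per criterion; the package deliberately does
not recommend a "best" use case for an alert.

## Screening statistics

An alert is a disjunction of SMARTS patterns: a molecule matches iff any
pattern matches (real alert collections ship pattern sets, and disjunction is
the standard convention). Molecules are standardised only by RDKit parsing
canonicalisation — no tautomer or charge normalisation by default, since
silent normalisation changes hit counts. Unparseable SMILES are quarantined
with their identifiers (and line numbers when reading CSV), never silently
dropped.

*Coverage* is hits / parseable inventory size; unlabelled molecules count.
*Performance* uses only the labelled subset, as a 2×2 table of hit/no-hit vs
active/inactive:

- **Cooper statistics.** Standard mode reports sensitivity, specificity,
  PPV, NPV, accuracy and the two error rates; any zero denominator is a
  reported error, never a silent NaN. Most alerts flag the *presence* of
  toxicity, so a non-hit is not a negative prediction: `positive_alert` mode
  reports only sensitivity and PPV, with the TN-dependent statistics absent
  by construction (None, not zero).
- **Fisher enrichment.** One-sided exact test toward over-representation of
  actives among hits: p = P(X ≥ TP) for X hypergeometric with the table's
  margins (computed via `scipy.stats.hypergeom`; the test suite checks it
  against exact rational enumeration for every table with total ≤ 30, at
  1e-12). The odds ratio is the sample ratio (TP·TN)/(FP·FN), infinite when
  FP·FN = 0 with TP·TN > 0. Degenerate margins (no hits or no actives) give
  p = 1.0 with an explicit degeneracy flag.

### Suggested levels for the objective criteria

The rubric's semantics for coverage and performance are qualitative (a
specific, low-coverage alert warrants high confidence; an undiscriminating
alert warrants none). The numeric defaults here are this package's own
calibration, always disclosed in reports that use them, and the suggestions
are advisory seeds for a human assessment:

- coverage ≤ 0.05 → high; ≤ 0.20 → moderate; otherwise low;
- performance low when PPV ≤ labelled prevalence (no enrichment over random
  labelling), high when both sensitivity and PPV ≥ 0.90, moderate otherwise.

Threshold configurations must be monotone or they are rejected.

## Synthetic inventories

The generator exists so every statistic is testable with known ground truth.
Exactly `round(n · prevalence)` molecules are built on a scaffold guaranteed
to match the planted SMARTS (default: a primary aliphatic alcohol,
`[CX4][OX2H]` on ethanol) and the remainder on a guaranteed non-matching
scaffold (benzene); both guarantees are re-verified at generation time, so
coverage is exact by construction rather than approximate. Scaffolds are
diversified by attaching one to six sp3 carbons at random positions, each
variant re-verified to preserve its match status, so substructure matching in
tests is not a string comparison in disguise. Activity labels are drawn with
a seeded generator from two conditionals — default P(active|hit) = 0.8,
P(active|no-hit) = 0.1 at planted prevalence 0.3, a clearly enriched but
noisy alert — and identical specs yield byte-identical inventories.

What the generator does *not* emulate: realistic chemical-space
distributions, activity cliffs, toxicokinetics, metabolic activation, or
correlated/contested labels. Passing tests therefore demonstrate the
correctness of the arithmetic and matching machinery on controlled inputs,
not predictive validity of any alert on real inventories.

Test problem sizes: the label-recovery checks use n = 2000 molecules (99%
binomial intervals of the planted conditionals), the score-oracle property
test uses 1000 random profile/weight pairs, and the enrichment oracle
enumerates every 2×2 table with total ≤ 30.

## Known limitations

- The three published worked assessments that accompany the scheme are not
  reproduced; no packaged fixture asserts their scores.
- Only the default 10/5/2 weighting ships; alternative numeric schemes are a
  user concern by design.
- The objective-level thresholds are conventions, not derived quantities.
- No metabolic simulation, 3D/conformer matching or QSAR fitting: the
  metabolic and mechanistic criteria are assessed by the human assessor.
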