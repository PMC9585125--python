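# alertconfide

Confidence assessment, use-case fitness and screening statistics for
toxicological **structural alerts**.

A structural alert is a molecular fragment or substructure hypothesised to be
responsible for a biological or toxicological effect. Alerts power read-across,
hazard identification and inventory screening across predictive toxicology,
but they differ wildly in how well they are defined, documented and validated
— and a prediction is only as trustworthy as the alert behind it. This package
is for computational toxicologists, read-across practitioners and tool
developers who need to make that trust explicit, comparable and reportable.

## What it computes

**Twelve-criterion confidence rubric.** Each alert is assessed against twelve
criteria — its structural description, property domain, endpoint/adversity,
species specificity, metabolic domain, mechanistic interpretation and
causality, purpose, coverage, performance, and corroborating/supporting
evidence — at one of three confidence levels (high = 3, moderate = 2,
low = 1) or marked not-applicable. Criteria carry importance tiers with
default weights: essential 10, desirable 5, optional 2.

**Confidence scores.** For numeric levels `s_i` and weights `w_i` over the
applicable criteria:

    Weighted Confidence Score = Σ(w_i · s_i) / Σ(w_i)

together with the unweighted mean, both on the scale from 3 (greatest
confidence) to 1 (lowest). The per-criterion vector is also exported as a
radar series (essential criteria first) — the score summarises, the radar
shows where confidence is actually missing.

**Use-case fitness.** Five packaged requirement profiles (hazard
identification, mechanism-based analogue identification, category
identification, classification & labelling, screening/prioritisation) state
the ideal minimum level per criterion; gap analysis reports exactly which
criteria fall short for a given use.

**Objective alert statistics.** Given an alert's SMARTS patterns and a SMILES
inventory with optional activity labels: coverage (hit fraction), Cooper
statistics — with a `positive_alert` mode that omits all true-negative-
dependent statistics, since absence of a toxicity alert is not a negative
prediction — and one-sided Fisher exact enrichment of actives among hits.
A seeded synthetic-inventory generator with planted coverage and label rates
makes every statistic testable without external data.

## Worked example

```python
import alertconfide as ac

profile = ac.profile_from_levels(
    "aromatic_amine_dna",
    {
        "structural_description": "high", "property_domain": "moderate",
        "toxicity_or_adversity": "high", "species_specificity": "high",
        "corroborating_evidence": "high", "metabolic_domain": "high",
        "mechanistic_interpretation": "high", "mechanistic_causality": "high",
        "purpose": "high", "coverage": "low", "performance": "low",
        "supporting_evidence": "moderate",
    },
)
result = ac.weighted_confidence_score(profile)
print(f"weighted = {result.weighted_score:.4f}")
print(f"mean     = {result.mean_score:.4f}")
for use_case in ("hazard_identification", "screening_prioritisation"):
    report = ac.gap_analysis(profile, use_case)
    print(use_case, report.verdict.value,
          [(g.criterion_id, g.required.value, g.observed.value) for g in report.gaps])
```

prints

```
weighted = 2.7260
mean     = 2.5000
hazard_identification GAPS_FOUND [('property_domain', 'high', 'moderate'), ('coverage', 'high', 'low'), ('performance', 'high', 'low')]
screening_prioritisation GAPS_FOUND [('performance', 'moderate', 'low')]
```

Read: a well-described, mechanistically grounded alert (weighted score 2.73
of 3; the weighting lifts it above the plain mean of 2.50 because the
essential criteria are strong) whose undocumented coverage and performance
make it unfit for direct hazard identification, while for screening only the
performance shortfall remains open. Screening the alert against an inventory fills
those two criteria in objectively:

```python
spec = ac.SyntheticInventorySpec(n=1000, prevalence=0.3, seed=7)
inventory = ac.generate_inventory(spec)
screen = ac.match_alert(spec.planted_alert(), inventory)
print(ac.coverage(screen))                              # 0.3 (planted exactly)
stats = ac.cooper_statistics(screen, "positive_alert")
print(stats.sensitivity, stats.positive_predictive_value)  # 0.7940 0.7967
print(ac.suggest_objective_levels(screen))              # coverage: low, performance: moderate
```

The same operations are available from the shell:

```sh
alertconfide simulate --n 1000 --prevalence 0.3 --seed 7 -o inventory.csv
alertconfide screen -a alerts.yaml -i inventory.csv --mode positive_alert
alertconfide score -p profile.csv -o report.json --radar radar.svg
alertconfide fitness -p profile.csv -u hazard_identification
```

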