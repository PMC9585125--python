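"""Mean/weighted confidence score arithmetic, validation and serialisation."""

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alertconfide import (
    ConfidenceLevel,
    ConfidenceProfile,
    CriterionAssessment,
    WeightingScheme,
    compare_profiles,
    mean_confidence_score,
    profile_from_levels,
    read_profile,
    uniform_profile,
    validate_profile,
    weighted_confidence_score,
    write_profile,
)
from alertconfide.errors import (
    ConfigurationError,
    NoApplicableCriteriaError,
    ProfileError,
)
from alertconfide.scoring import profile_from_csv, profile_to_csv

CRITERION_IDS = [
    "structural_description", "property_domain", "toxicity_or_adversity",
    "species_specificity", "corroborating_evidence", "metabolic_domain",
    "mechanistic_interpretation", "mechanistic_causality", "purpose",
    "coverage", "performance", "supporting_evidence",
]


# --- validation -----------------------------------------------------------

def test_complete_profile_validates_clean(all_high, registry):
    assert validate_profile(all_high, registry).ok


def test_missing_and_duplicate_criteria_are_reported(registry):
    incomplete = ConfidenceProfile(
        "x",
        tuple(
            CriterionAssessment(cid, ConfidenceLevel.HIGH)
            for cid in CRITERION_IDS
            if cid != "performance"
        ),
    )
    report = validate_profile(incomplete, registry)
    assert [f.subject for f in report.by_kind("missing_criterion")] == ["performance"]

    duplicated = ConfidenceProfile(
        "y",
        tuple(CriterionAssessment(cid, ConfidenceLevel.HIGH) for cid in CRITERION_IDS)
        + (CriterionAssessment("purpose", ConfidenceLevel.LOW),),
    )
    report = validate_profile(duplicated, registry)
    assert [f.subject for f in report.by_kind("duplicate_criterion")] == ["purpose"]


# --- mean score -----------------------------------------------------------

def test_mean_score_examples(registry, all_high):
    assert mean_confidence_score(all_high, registry) == 3.0

    half = profile_from_levels(
        "half",
        {cid: ("high" if i < 6 else "low") for i, cid in enumerate(CRITERION_IDS)},
    )
    assert mean_confidence_score(half, registry) == 2.0

    mixed = profile_from_levels(
        "mixed",
        {
            cid: ("high" if i < 5 else "moderate" if i < 8 else "low")
            for i, cid in enumerate(CRITERION_IDS)
        },
    )
    assert mean_confidence_score(mixed, registry) == pytest.approx(25 / 12)


# --- weighted score -------------------------------------------------------

def test_weighted_score_scale_endpoints(all_high, all_low, scheme, registry):
    assert weighted_confidence_score(all_high, scheme, registry).weighted_score == 3.0
    assert weighted_confidence_score(all_low, scheme, registry).weighted_score == 1.0


def test_weighted_score_tiered_profile(tiered_profile, scheme, registry):
    result = weighted_confidence_score(tiered_profile, scheme, registry)
    assert result.weighted_score == pytest.approx(188 / 73, abs=1e-12)
    assert result.weight_total == 73
    assert result.n_applicable == 12
    # contribution breakdown is consistent
    assert sum(c.contribution for c in result.per_criterion) == pytest.approx(188)


def test_na_criterion_drops_out(all_high, scheme, registry):
    with_na = all_high.with_level("coverage", ConfidenceLevel.NOT_APPLICABLE)
    result = weighted_confidence_score(with_na, scheme, registry)
    assert result.weighted_score == 3.0
    assert result.n_applicable == 11
    assert result.weight_total == 71


def test_all_na_profile_has_no_score(registry, scheme):
    profile = uniform_profile(ConfidenceLevel.NOT_APPLICABLE, registry=registry)
    with pytest.raises(NoApplicableCriteriaError):
        mean_confidence_score(profile, registry)
    with pytest.raises(NoApplicableCriteriaError):
        weighted_confidence_score(profile, scheme, registry)


def test_scheme_missing_an_applicable_criterion_is_configuration_error(
    all_high, scheme, registry
):
    partial = WeightingScheme(
        "partial", {k: v for k, v in scheme.weights.items() if k != "coverage"}
    )
    with pytest.raises(ConfigurationError):
        weighted_confidence_score(all_high, partial, registry)


# --- property tests -------------------------------------------------------

levels_strategy = st.lists(
    st.sampled_from([ConfidenceLevel.HIGH, ConfidenceLevel.MODERATE, ConfidenceLevel.LOW,
                     ConfidenceLevel.NOT_APPLICABLE]),
    min_size=12, max_size=12,
).filter(lambda ls: any(lv.applicable for lv in ls))

weights_strategy = st.lists(
    st.floats(min_value=0.01, max_value=100, allow_nan=False), min_size=12, max_size=12
)


def _profile(levels):
    return profile_from_levels("p", dict(zip(CRITERION_IDS, levels)))


@settings(max_examples=1000, deadline=None, derandomize=True)
@given(levels=levels_strategy, weights=weights_strategy)
def test_weighted_score_matches_independent_summation(levels, weights, registry):
    """Oracle: term-by-term summation over applicable criteria."""
    scheme = WeightingScheme("rand", dict(zip(CRITERION_IDS, weights)))
    result = weighted_confidence_score(_profile(levels), scheme, registry)
    num = den = 0.0
    for lv, w in zip(levels, weights):
        if lv.applicable:
            num += w * lv.numeric_score
            den += w
    assert result.weighted_score == pytest.approx(num / den, rel=1e-12)
    assert 1.0 <= result.weighted_score <= 3.0
    assert 1.0 <= result.mean_score <= 3.0


@settings(max_examples=200, deadline=None, derandomize=True)
@given(levels=levels_strategy, index=st.integers(min_value=0, max_value=11))
def test_raising_one_level_never_lowers_either_score(levels, index, registry, scheme):
    upgrade = {
        ConfidenceLevel.LOW: ConfidenceLevel.MODERATE,
        ConfidenceLevel.MODERATE: ConfidenceLevel.HIGH,
    }
    if levels[index] not in upgrade:
        return
    raised = list(levels)
    raised[index] = upgrade[levels[index]]
    before = weighted_confidence_score(_profile(levels), scheme, registry)
    after = weighted_confidence_score(_profile(raised), scheme, registry)
    assert after.weighted_score > before.weighted_score  # positive weight: strict
    assert after.mean_score >= before.mean_score


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    levels=levels_strategy,
    weights=weights_strategy,
    factor=st.floats(min_value=0.01, max_value=1000, allow_nan=False),
)
def test_weighted_score_invariant_under_weight_rescaling(levels, weights, factor, registry):
    scheme = WeightingScheme("rand", dict(zip(CRITERION_IDS, weights)))
    base = weighted_confidence_score(_profile(levels), scheme, registry)
    scaled = weighted_confidence_score(_profile(levels), scheme.scaled(factor), registry)
    assert scaled.weighted_score == pytest.approx(base.weighted_score, rel=1e-9)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(levels=levels_strategy, index=st.integers(min_value=0, max_value=11))
def test_na_is_equivalent_to_deleting_the_term(levels, index, registry, scheme):
    if not levels[index].applicable:
        return
    if sum(lv.applicable for lv in levels) == 1:
        return  # would leave nothing applicable
    as_na = list(levels)
    as_na[index] = ConfidenceLevel.NOT_APPLICABLE
    result = weighted_confidence_score(_profile(as_na), scheme, registry)
    num = den = 0.0
    for i, lv in enumerate(levels):
        if i != index and lv.applicable:
            w = scheme.weights[CRITERION_IDS[i]]
            num += w * lv.numeric_score
            den += w
    assert result.weighted_score == pytest.approx(num / den, rel=1e-12)


# --- comparison -----------------------------------------------------------

def test_compare_profiles_orders_by_weighted_then_mean_then_id(
    all_high, all_low, scheme, registry
):
    frame = compare_profiles([all_low, all_high], scheme, registry)
    assert list(frame["alert_id"]) == ["all_high", "all_low"]

    twin_a = uniform_profile("moderate", alert_id="b_twin", registry=registry)
    twin_b = uniform_profile("moderate", alert_id="a_twin", registry=registry)
    frame = compare_profiles([twin_a, twin_b], scheme, registry)
    assert list(frame["alert_id"]) == ["a_twin", "b_twin"]

    single = compare_profiles([all_high], scheme, registry)
    assert len(single) == 1 and single.loc[0, "weighted_score"] == 3.0


def test_compare_profiles_aggregates_invalid_offenders(all_high, scheme, registry):
    broken = ConfidenceProfile("broken", all_high.assessments[:-1])
    with pytest.raises(ProfileError, match="broken"):
        compare_profiles([all_high, broken], scheme, registry)


# --- serialisation --------------------------------------------------------

def test_profile_csv_round_trip(tiered_profile):
    text = profile_to_csv(tiered_profile)
    again = profile_from_csv(text)
    assert again == tiered_profile
    assert profile_to_csv(again) == text


@pytest.mark.parametrize("suffix", [".csv", ".yaml", ".json"])
def test_profile_file_round_trip(tmp_path, tiered_profile, suffix):
    path = tmp_path / f"profile{suffix}"
    write_profile(tiered_profile, path)
    assert read_profile(path) == tiered_profile


def test_csv_levels_parse_case_insensitively():
    text = "criterion_id,level,justification\npurpose,HIGH,\ncoverage,Na,\n"
    profile = profile_from_csv(text, default_alert_id="z")
    assert profile.levels()["purpose"] is ConfidenceLevel.HIGH
    assert profile.levels()["coverage"] is ConfidenceLevel.NOT_APPLICABLE
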