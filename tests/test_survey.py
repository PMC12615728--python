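"""Data model, preparation transforms, validation and file round-trips."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietopt import (aggregate_category_profile, apply_yield_factor,
                     derive_price, impute_new_food_sd, read_survey,
                     rescale_ghge_electricity, survey_from_json,
                     survey_to_json, validate_survey, write_survey)


@pytest.mark.parametrize("raw,factor,expected", [
    (100.0, 0.8, 80.0),    # cooking loss
    (250.0, 1.0, 250.0),   # identity
    (100.0, 2.5, 250.0),   # dried-to-cooked expansion
])
def test_yield_factor_scales_raw_mass(raw, factor, expected):
    assert apply_yield_factor(raw, factor) == pytest.approx(expected)


def test_yield_factor_rejects_nonpositive_factor_naming_category():
    with pytest.raises(ValueError, match="beef"):
        apply_yield_factor(100.0, 0.0, category="beef")
    with pytest.raises(ValueError):
        apply_yield_factor(-1.0, 0.5)


@pytest.mark.parametrize("intakes,proteins,expected", [
    ((30.0,), (12.0,), 12.0),          # single item: identity
    ((50.0, 50.0), (10.0, 20.0), 15.0),  # equal weights
    ((75.0, 25.0), (10.0, 20.0), 12.5),  # intake-weighted
])
def test_profile_aggregation_is_intake_weighted(intakes, proteins, expected):
    profiles = [{"protein": p} for p in proteins]
    agg = aggregate_category_profile(intakes, profiles)
    assert agg["protein"] == pytest.approx(expected)


def test_profile_aggregation_rejects_zero_total_and_key_mismatch():
    with pytest.raises(ValueError, match="zero"):
        aggregate_category_profile([0.0, 0.0], [{"a": 1.0}, {"a": 2.0}])
    with pytest.raises(ValueError, match="fat"):
        aggregate_category_profile([1.0, 1.0],
                                   [{"protein": 1.0}, {"fat": 2.0}])


@settings(max_examples=50, derandomize=True)
@given(st.lists(st.tuples(st.floats(0.1, 100.0), st.floats(0.0, 50.0)),
                min_size=1, max_size=6))
def test_profile_aggregation_invariant_to_item_splitting(items):
    """Splitting an item into two half-intake copies changes nothing."""
    intakes = [w for w, _ in items]
    profiles = [{"x": v} for _, v in items]
    split_intakes = [w / 2 for w in intakes for _ in range(2)]
    split_profiles = [p for p in profiles for _ in range(2)]
    a = aggregate_category_profile(intakes, profiles)
    b = aggregate_category_profile(split_intakes, split_profiles)
    assert a["x"] == pytest.approx(b["x"], rel=1e-9)


@pytest.mark.parametrize("gwp_new_rel,expected", [
    (1.0, 1.0),   # unchanged mix
    (0.0, 0.4),   # zero-carbon grid removes the 60% electricity share
    (2.0, 1.6),   # doubled grid GWP
])
def test_electricity_rescaling(gwp_new_rel, expected):
    g = 0.3  # arbitrary grid GWP
    out = rescale_ghge_electricity(1.0, 0.6, g, gwp_new_rel * g)
    assert out == pytest.approx(expected)


@settings(max_examples=50, derandomize=True)
@given(st.floats(0.01, 10.0), st.floats(0.0, 1.0),
       st.floats(0.05, 2.0), st.floats(0.0, 2.0), st.floats(0.0, 2.0))
def test_electricity_rescaling_is_linear_in_new_gwp(coef, share, g_old,
                                                    g_a, g_b):
    f_a = rescale_ghge_electricity(coef, share, g_old, g_a)
    f_b = rescale_ghge_electricity(coef, share, g_old, g_b)
    mid = rescale_ghge_electricity(coef, share, g_old, 0.5 * (g_a + g_b))
    assert mid == pytest.approx(0.5 * (f_a + f_b), rel=1e-9, abs=1e-12)
    assert rescale_ghge_electricity(coef, share, g_old, g_old) == \
        pytest.approx(coef, rel=1e-12)


def test_electricity_rescaling_rejects_bad_inputs():
    with pytest.raises(ValueError):
        rescale_ghge_electricity(1.0, 0.6, 0.0, 0.1)
    with pytest.raises(ValueError):
        rescale_ghge_electricity(1.0, 1.5, 0.2, 0.1)


class TestSdImputation:
    def test_mean_of_named_references(self, tiny_survey):
        tiny_survey.category("beef").intake_sd = 10.0
        tiny_survey.category("chicken").intake_sd = 30.0
        sd = impute_new_food_sd(tiny_survey, ["beef", "chicken"])
        assert sd == pytest.approx(20.0)
        assert tiny_survey.new_food.intake_sd == pytest.approx(20.0)

    def test_singleton_reference(self, tiny_survey):
        tiny_survey.category("beef").intake_sd = 7.5
        assert impute_new_food_sd(tiny_survey, ["beef"]) == pytest.approx(7.5)

    def test_default_uses_largest_host_group_members(self, tiny_survey):
        # beef (50 g) and chicken (30 g) are the host-group references
        sd = impute_new_food_sd(tiny_survey)
        assert sd == pytest.approx((10.0 + 8.0) / 2)

    def test_errors(self, tiny_survey):
        with pytest.raises(ValueError):
            impute_new_food_sd(tiny_survey, [])
        with pytest.raises(KeyError):
            impute_new_food_sd(tiny_survey, ["nope"])


@pytest.mark.parametrize("exp,qty,expected", [
    (14.6, 1.0, 1.46),   # EUR/kg to EUR/100 g
    (10.0, 2.0, 0.5),
])
def test_price_derivation(exp, qty, expected):
    assert derive_price(exp, qty) == pytest.approx(expected)


def test_price_derivation_rejects_zero_quantity():
    with pytest.raises(ValueError):
        derive_price(10.0, 0.0)


class TestValidation:
    def test_well_formed_survey_passes(self, tiny_survey):
        assert validate_survey(tiny_survey) == []

    def test_percentile_order_violation_names_category(self, tiny_survey):
        tiny_survey.category("juice").p5 = 300.0  # above its p95 of 200
        issues = validate_survey(tiny_survey)
        assert len(issues) == 1 and "juice" in issues[0]

    def test_group_total_mismatch_reported(self, tiny_survey):
        tiny_survey.group("meat").baseline_total = 99.0
        issues = validate_survey(tiny_survey)
        assert len(issues) == 1 and "meat" in issues[0]

    def test_new_food_with_positive_baseline_reported(self, tiny_survey):
        tiny_survey.category("myco").baseline_intake = 5.0
        issues = validate_survey(tiny_survey)
        assert any("new food" in v for v in issues)


def test_csv_roundtrip_preserves_survey(tiny_survey, tmp_path):
    write_survey(tiny_survey, tmp_path / "cats.csv", tmp_path / "groups.csv")
    back = read_survey(tmp_path / "cats.csv", tmp_path / "groups.csv",
                       energy_target=tiny_survey.energy_target)
    assert back.category_ids == tiny_survey.category_ids
    assert back.group_ids == tiny_survey.group_ids
    for cid in tiny_survey.category_ids:
        a, b = tiny_survey.category(cid), back.category(cid)
        assert b.baseline_intake == pytest.approx(a.baseline_intake)
        assert b.nutrients == pytest.approx(a.nutrients)
        assert (b.is_new_food, b.is_fixed) == (a.is_new_food, a.is_fixed)
    assert back.group("meat").p95 == pytest.approx(120.0)
    assert validate_survey(back) == []


def test_json_roundtrip_preserves_survey(tiny_survey):
    back = survey_from_json(survey_to_json(tiny_survey))
    assert back.category_ids == tiny_survey.category_ids
    assert back.energy_target == pytest.approx(tiny_survey.energy_target)
    assert validate_survey(back) == []
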