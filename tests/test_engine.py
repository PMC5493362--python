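"""Unit and property tests for the generic Mamdani engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fuzzyair import (
    AggregatedOutput,
    ConfigurationError,
    DegenerateAggregationError,
    FuzzyInferenceSystem,
    FuzzyRule,
    InvalidInputError,
    LinguisticVariable,
    MembershipFunction,
    aggregate,
    defuzzify_centroid,
    fire_strength,
    fuzzify,
    infer,
    load_system,
    membership,
    save_system,
)
from fuzzyair.engine import system_from_dict, system_to_dict


def centroid_oracle(terms_and_strengths, lo, hi, n=200_001):
    """Independent fine-grid quadrature centroid of a clipped-max aggregation."""
    grid = np.linspace(lo, hi, n)
    degrees = np.zeros(n)
    for mf, s in terms_and_strengths:
        degrees = np.maximum(degrees, np.minimum(s, mf(grid)))
    return float(np.sum(grid * degrees) / np.sum(degrees))


# ---------------------------------------------------------------------------
# MembershipFunction
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "bp, x, expected",
    [
        ((0, 0, 25, 50), 10.0, 1.0),     # inside the plateau
        ((0, 0, 25, 50), 37.5, 0.5),     # midpoint of the falling edge
        ((0, 0, 25, 50), -5.0, 1.0),     # open left shoulder holds at 1
        ((0, 0, 25, 50), 60.0, 0.0),     # beyond d
        ((25, 50, 200, 200), 30.0, 0.2),  # (30-25)/(50-25)
        ((25, 50, 200, 200), 250.0, 1.0),  # open right shoulder
        ((25, 50, 200, 200), 10.0, 0.0),  # below a
        ((2, 4, 4, 6), 4.0, 1.0),        # triangle apex
        ((2, 4, 4, 6), 3.0, 0.5),        # triangle rising edge
    ],
)
def test_membership_piecewise_values(bp, x, expected):
    mf = MembershipFunction("t", *bp)
    assert membership(mf, x) == pytest.approx(expected)


def test_membership_matches_interpolation_oracle():
    """Trapezoid evaluation agrees with a dense linear-interpolation oracle."""
    mf = MembershipFunction("t", 25, 50, 200, 200)
    knots_x = [25, 50, 200, 260]
    knots_y = [0.0, 1.0, 1.0, 1.0]  # right shoulder stays at 1
    xs = np.linspace(26, 259, 997)
    expected = np.interp(xs, knots_x, knots_y)
    np.testing.assert_allclose(mf(xs), expected, atol=1e-12)


def test_membership_rejects_nonfinite_input_and_bad_breakpoints():
    mf = MembershipFunction("t", 0, 1, 2, 3)
    with pytest.raises(InvalidInputError):
        mf(float("nan"))
    with pytest.raises(InvalidInputError):
        mf(float("inf"))
    with pytest.raises(ConfigurationError):
        MembershipFunction("bad", 3, 2, 1, 0)
    with pytest.raises(ConfigurationError):
        MembershipFunction("zero-width", 5, 5, 5, 5)


@given(
    st.lists(st.floats(0, 100), min_size=4, max_size=4),
    st.floats(-50, 150),
)
@settings(max_examples=200, derandomize=True)
def test_membership_degree_always_in_unit_interval(raw_bp, x):
    a, b, c, d = sorted(raw_bp)
    if a == d:
        return
    mf = MembershipFunction("t", a, b, c, d)
    assert 0.0 <= mf(x) <= 1.0


# ---------------------------------------------------------------------------
# LinguisticVariable / fuzzify
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def pm10_var():
    from fuzzyair import build_default_system

    return build_default_system().input_variable("pm10")


def test_fuzzify_extremes_and_crossover(pm10_var):
    assert fuzzify(pm10_var, 0.0) == {"good": 1.0, "bad": 0.0}
    # the observed historical maximum sits in the bad plateau
    assert fuzzify(pm10_var, 89.0) == {"good": 0.0, "bad": 1.0}
    # crossover of the default edges: (50-x)/25 = (x-25)/25 at x = 37.5
    degrees = fuzzify(pm10_var, 37.5)
    assert degrees["good"] == pytest.approx(0.5)
    assert degrees["bad"] == pytest.approx(0.5)


def test_fuzzify_clamps_out_of_universe_values(pm10_var):
    assert fuzzify(pm10_var, 500.0) == fuzzify(pm10_var, pm10_var.hi)
    assert fuzzify(pm10_var, -3.0) == fuzzify(pm10_var, pm10_var.lo)
    with pytest.raises(InvalidInputError):
        fuzzify(pm10_var, float("nan"))


def test_variable_invariants():
    t1 = MembershipFunction("x", 0, 0, 5, 10)
    t2 = MembershipFunction("x", 5, 10, 10, 10)
    with pytest.raises(ConfigurationError):
        LinguisticVariable("v", 10, 0, [t1])  # lo >= hi
    with pytest.raises(ConfigurationError):
        LinguisticVariable("v", 0, 10, [t1, t2])  # duplicate term names
    v = LinguisticVariable("v", 0, 10, [t1, MembershipFunction("y", 5, 10, 10, 10)])
    assert v.covers_universe()
    gap = LinguisticVariable("v", 0, 10, [MembershipFunction("y", 0, 0, 2, 3)])
    assert not gap.covers_universe()


# ---------------------------------------------------------------------------
# fire_strength
# ---------------------------------------------------------------------------

def test_fire_strength_is_minimum_of_antecedents():
    rule = FuzzyRule({"a": "hi", "b": "hi", "c": "hi", "d": "hi"}, "out")
    fz = {
        "a": {"hi": 0.8}, "b": {"hi": 0.3}, "c": {"hi": 1.0}, "d": {"hi": 0.6},
    }
    assert fire_strength(rule, fz) == pytest.approx(0.3)
    fz["b"]["hi"] = 0.0
    assert fire_strength(rule, fz) == 0.0
    fz = {k: {"hi": 1.0} for k in "abcd"}
    assert fire_strength(rule, fz) == 1.0


def test_fire_strength_missing_variable_is_configuration_error():
    rule = FuzzyRule({"a": "hi", "b": "hi"}, "out")
    with pytest.raises(ConfigurationError):
        fire_strength(rule, {"a": {"hi": 0.5}})


# ---------------------------------------------------------------------------
# aggregate / defuzzify
# ---------------------------------------------------------------------------

def make_single_output_system(terms, rules, lo=0.0, hi=16.0, resolution=1001):
    """Minimal system with one dummy input used only to host rules."""
    inp = LinguisticVariable(
        "x", 0, 1, [MembershipFunction("on", 0, 0, 1, 1)])
    out = LinguisticVariable("y", lo, hi, terms)
    return FuzzyInferenceSystem(
        inputs=[inp], output=out,
        rules=[FuzzyRule({"x": "on"}, c) for c in rules],
        resolution=resolution, validate_coverage=False)


def test_aggregate_identity_and_clipping():
    tri = MembershipFunction("tri", 4, 8, 8, 12)
    system = make_single_output_system([tri], ["tri"])
    full = aggregate(system, [1.0])
    np.testing.assert_allclose(full.degrees, tri(system.grid))
    clipped = aggregate(system, [0.4])
    np.testing.assert_allclose(clipped.degrees,
                               np.minimum(tri(system.grid), 0.4))


def test_aggregate_pointwise_max_of_disjoint_consequents():
    t1 = MembershipFunction("lo", 0, 1, 2, 3)
    t2 = MembershipFunction("hi", 6, 7, 8, 9)
    system = make_single_output_system([t1, t2], ["lo", "hi"], lo=0, hi=10)
    agg = aggregate(system, [0.4, 0.7])
    expected = np.maximum(np.minimum(t1(system.grid), 0.4),
                          np.minimum(t2(system.grid), 0.7))
    np.testing.assert_allclose(agg.degrees, expected)


def test_aggregate_zero_strength_rule_contributes_nothing():
    t1 = MembershipFunction("lo", 0, 1, 2, 3)
    t2 = MembershipFunction("hi", 6, 7, 8, 9)
    system = make_single_output_system([t1, t2], ["lo", "hi"], lo=0, hi=10)
    with_zero = aggregate(system, [0.5, 0.0])
    only_one = np.minimum(t1(system.grid), 0.5)
    np.testing.assert_allclose(with_zero.degrees, only_one)


def test_aggregate_checks_strength_count_and_range():
    tri = MembershipFunction("tri", 4, 8, 8, 12)
    system = make_single_output_system([tri], ["tri"])
    with pytest.raises(ConfigurationError):
        aggregate(system, [0.5, 0.5])
    with pytest.raises(ConfigurationError):
        aggregate(system, [1.5])


def test_defuzzify_symmetry_and_rectangle():
    tri = MembershipFunction("tri", 4, 8, 8, 12)
    system = make_single_output_system([tri], ["tri"])
    assert defuzzify_centroid(aggregate(system, [1.0])) == pytest.approx(8.0, abs=0.02)
    rect = MembershipFunction("rect", 0, 0, 16, 16)
    system = make_single_output_system([rect], ["rect"])
    assert defuzzify_centroid(aggregate(system, [1.0])) == pytest.approx(8.0, abs=0.02)


def test_defuzzify_right_shoulder_matches_quadrature_oracle():
    shoulder = MembershipFunction("sh", 12, 14, 16, 16)
    system = make_single_output_system([shoulder], ["sh"])
    coarse = defuzzify_centroid(aggregate(system, [1.0]))
    fine = centroid_oracle([(shoulder, 1.0)], 0.0, 16.0)
    assert coarse == pytest.approx(fine, abs=0.05)


def test_defuzzify_degenerate_aggregation_raises():
    tri = MembershipFunction("tri", 4, 8, 8, 12)
    system = make_single_output_system([tri], ["tri"])
    with pytest.raises(DegenerateAggregationError):
        defuzzify_centroid(aggregate(system, [0.0]))


def test_centroid_matches_oracle_on_random_activations(rng):
    """Coarse-grid centroid is within 0.05 of a 2e5-point quadrature oracle."""
    terms = [
        MembershipFunction("very_low", 0, 0, 2, 4),
        MembershipFunction("low", 2, 4, 4, 6),
        MembershipFunction("medium", 5, 8, 8, 11),
        MembershipFunction("high", 10, 12, 12, 14),
        MembershipFunction("very_high", 12, 14, 16, 16),
    ]
    names = [t.name for t in terms]
    system = make_single_output_system(terms, names)
    for _ in range(50):
        strengths = rng.uniform(0, 1, size=5)
        if strengths.max() < 1e-6:
            continue
        coarse = defuzzify_centroid(aggregate(system, strengths))
        fine = centroid_oracle(list(zip(terms, strengths)), 0.0, 16.0)
        assert coarse == pytest.approx(fine, abs=0.05)


# ---------------------------------------------------------------------------
# infer: composition, bounds, stability
# ---------------------------------------------------------------------------

def test_infer_single_rule_reduction(default_system):
    """Deep in every good plateau only the all-good rule fires fully."""
    good_inputs = {"pm10": 5.0, "o3": 20.0, "so2": 2.0, "temp_apparent": 25.0}
    out = infer(default_system, good_inputs)
    very_low = default_system.output.term("very_low")
    assert out == pytest.approx(centroid_oracle([(very_low, 1.0)], 0, 16),
                                abs=0.05)
    bad_inputs = {"pm10": 110.0, "o3": 190.0, "so2": 28.0, "temp_apparent": 2.0}
    very_high = default_system.output.term("very_high")
    assert infer(default_system, bad_inputs) == pytest.approx(
        centroid_oracle([(very_high, 1.0)], 0, 16), abs=0.05)


def test_infer_missing_input_raises(default_system):
    with pytest.raises(InvalidInputError):
        infer(default_system, {"pm10": 10.0, "o3": 50.0, "so2": 5.0})


def test_infer_bounded_away_from_universe_extremes(default_system, rng):
    """Centroid outputs can never reach the ends of the output universe."""
    lo, hi = default_system.output.lo, default_system.output.hi
    for _ in range(300):
        x = {v.name: rng.uniform(v.lo - 20, v.hi + 20)
             for v in default_system.inputs}
        out = infer(default_system, x)
        assert lo < out < hi


def test_infer_resolution_stability(rng):
    """Doubling the output resolution moves the result by < 0.02."""
    from fuzzyair import ModelConfig, build_default_system
    from dataclasses import replace

    coarse_sys = build_default_system(ModelConfig(resolution=1001))
    fine_sys = build_default_system(ModelConfig(resolution=2001))
    for _ in range(25):
        x = {v.name: rng.uniform(v.lo, v.hi) for v in coarse_sys.inputs}
        assert infer(coarse_sys, x) == pytest.approx(infer(fine_sys, x),
                                                     abs=0.02)


def test_disabling_zero_strength_rule_never_changes_output(default_system, rng):
    """Rule-count conservation: dropping non-fired rules is a no-op."""
    from fuzzyair.engine import FuzzyInferenceSystem, fire_strength, fuzzify

    for _ in range(10):
        x = {v.name: rng.uniform(v.lo, v.hi) for v in default_system.inputs}
        fz = {v.name: fuzzify(v, x[v.name]) for v in default_system.inputs}
        live = [r for r in default_system.rules if fire_strength(r, fz) > 0]
        pruned = FuzzyInferenceSystem(
            inputs=default_system.inputs, output=default_system.output,
            rules=live, resolution=default_system.resolution)
        assert infer(pruned, x) == pytest.approx(infer(default_system, x),
                                                 abs=1e-12)


# ---------------------------------------------------------------------------
# System construction and serialization
# ---------------------------------------------------------------------------

def test_system_rejects_bad_rules_and_low_resolution(default_system):
    inputs = default_system.inputs
    output = default_system.output
    with pytest.raises(ConfigurationError):
        FuzzyInferenceSystem(inputs, output,
                             [FuzzyRule({"nope": "good"}, "very_low")])
    with pytest.raises(ConfigurationError):
        FuzzyInferenceSystem(inputs, output,
                             [FuzzyRule({"pm10": "awful"}, "very_low")])
    with pytest.raises(ConfigurationError):
        FuzzyInferenceSystem(inputs, output,
                             [FuzzyRule({"pm10": "good"}, "nope")])
    with pytest.raises(ConfigurationError):
        FuzzyInferenceSystem(inputs, output, list(default_system.rules),
                             resolution=50)


def test_system_requires_input_coverage():
    gapped = LinguisticVariable(
        "x", 0, 10, [MembershipFunction("low", 0, 0, 2, 3)])
    out = LinguisticVariable(
        "y", 0, 1, [MembershipFunction("t", 0, 0, 1, 1)])
    with pytest.raises(ConfigurationError):
        FuzzyInferenceSystem([gapped], out, [FuzzyRule({"x": "low"}, "t")])


@pytest.mark.parametrize("ext", ["yaml", "json"])
def test_system_round_trip_is_lossless(default_system, tmp_path, ext):
    path = tmp_path / f"system.{ext}"
    save_system(default_system, path)
    loaded = load_system(path)
    assert system_to_dict(loaded) == system_to_dict(default_system)
    # and a second round trip through the dict form is also stable
    again = system_from_dict(system_to_dict(loaded))
    x = {"pm10": 30.0, "o3": 100.0, "so2": 12.0, "temp_apparent": 14.0}
    assert infer(again, x) == pytest.approx(infer(default_system, x))
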