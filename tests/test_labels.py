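"""Risk-trajectory label generation: score mapping, segment fits, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from readmitrisk.labels import (
    PatientMeta,
    TrajectoryConfig,
    ValidationError,
    build_trajectory,
    fit_segment,
    initial_probability,
    segment_values,
    weighted_linear_segment,
    weighted_linear_weights,
)

FUNCTIONS = ["linear", "exponential", "logarithmic", "weighted_linear"]


# ---------------------------------------------------------------------------
# initial probability


@pytest.mark.parametrize(
    "lace,hospital,source,expected",
    [
        (10, 0, "LACE", 10 / 19),
        (0, 0, "LACE", 0.0),
        (19, 0, "LACE", 1.0),
        (0, 15, "HOSPITAL", 1.0),
        (0, 9, "HOSPITAL", 0.6),
        (19, 0, "average", 0.5),
        (19, 15, "average", 1.0),
    ],
)
def test_initial_probability_linear_mapping(lace, hospital, source, expected):
    meta = PatientMeta("p", False, lace=lace, hospital=hospital)
    assert initial_probability(meta, source) == pytest.approx(expected)


def test_lace_ten_prints_as_053():
    meta = PatientMeta("p", False, lace=10, hospital=0)
    assert round(initial_probability(meta, "LACE"), 2) == 0.53


@pytest.mark.parametrize(
    "kwargs,field",
    [
        (dict(lace=20, hospital=0), "lace"),
        (dict(lace=-1, hospital=0), "lace"),
        (dict(lace=0, hospital=16), "hospital"),
    ],
)
def test_out_of_range_scores_name_the_field(kwargs, field):
    with pytest.raises(ValidationError, match=field):
        PatientMeta("p", False, **kwargs)


def test_meta_timeline_invariants():
    with pytest.raises(ValidationError):
        PatientMeta("p", True, lace=5, hospital=5)  # missing days
    with pytest.raises(ValidationError):
        PatientMeta("p", True, lace=5, hospital=5,
                    readmission_day=20, second_discharge_day=18)
    with pytest.raises(ValidationError):
        PatientMeta("p", False, lace=5, hospital=5, readmission_day=10)


# ---------------------------------------------------------------------------
# segment fitting


def test_linear_segment_worked_examples():
    fall = fit_segment("linear", 0.34, 0.0, 1, 60)
    assert fall.a == pytest.approx(-0.34 / 59)
    vals = segment_values(fall)
    assert vals[0] == pytest.approx(0.34)
    assert vals[-1] == pytest.approx(0.0, abs=1e-12)

    rise = segment_values(fit_segment("linear", 0.52, 1.0, 1, 16))
    assert rise[0] == pytest.approx(0.52)
    assert rise[-1] == pytest.approx(1.0)


def _bisect_exponential(p_start, p_end, L, tol=1e-12):
    """Independent bisection oracle for a**L - a = p_end - p_start on the
    gradual-decay branch (above the minimiser of a**L - a)."""
    delta = p_end - p_start
    f = lambda a: a**L - a - delta  # noqa: E731
    if delta < 0:
        lo, hi = (1.0 / L) ** (1.0 / (L - 1)), 1.0 - 1e-15
    else:
        lo, hi = 1.0 + 1e-15, 10.0
    assert f(lo) * f(hi) <= 0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(lo) * f(mid) <= 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


@pytest.mark.parametrize(
    "p_start,p_end,d1,d2",
    [
        (0.34, 0.0, 1, 60),
        (0.52, 1.0, 1, 16),
        (0.8, 0.3, 5, 40),
        (0.2, 0.9, 10, 30),
        (0.6, 0.25, 21, 60),
    ],
)
def test_exponential_fit_matches_bisection_oracle(p_start, p_end, d1, d2):
    L = d2 - d1 + 1
    params = fit_segment("exponential", p_start, p_end, d1, d2)
    assert params.kind == "exponential"
    a_oracle = _bisect_exponential(p_start, p_end, L)
    assert params.a == pytest.approx(a_oracle, abs=1e-8)
    # endpoint constraints in the local index
    assert params.a**1 + params.b == pytest.approx(p_start, abs=1e-10)
    assert params.a**L + params.b == pytest.approx(p_end, abs=1e-10)


def test_exponential_spec_example_endpoints():
    params = fit_segment("exponential", 0.34, 0.0, 1, 60)
    assert abs(params.a**1 + params.b - 0.34) < 1e-10
    assert abs(params.a**60 + params.b) < 1e-10
    assert params.b == pytest.approx(-params.a**60, abs=1e-10)


def test_exponential_steep_fall_uses_reversed_rise():
    # a drop of 1.0 cannot satisfy a**L - a = -1 for a in (0,1); the fit
    # falls back to the time-reversed rising solution, endpoints exact
    params = fit_segment("exponential", 1.0, 0.0, 21, 60)
    assert params.kind == "exponential_reversed"
    vals = segment_values(params)
    assert vals[0] == pytest.approx(1.0, abs=1e-10)
    assert vals[-1] == pytest.approx(0.0, abs=1e-10)
    assert np.all(np.diff(vals) < 0)


@pytest.mark.parametrize(
    "p_start,p_end,d1,d2",
    [(0.34, 0.0, 1, 60), (0.52, 1.0, 1, 16), (0.9, 0.1, 3, 50), (0.1, 0.7, 2, 12)],
)
def test_logarithmic_fit_closed_form(p_start, p_end, d1, d2):
    L = d2 - d1 + 1
    params = fit_segment("logarithmic", p_start, p_end, d1, d2)
    # independent closed form: b = p_start, a = L ** (1/delta)
    assert params.b == pytest.approx(p_start, abs=1e-12)
    assert params.a == pytest.approx(L ** (1.0 / (p_end - p_start)), abs=1e-8)
    vals = segment_values(params)
    assert vals[0] == pytest.approx(p_start, abs=1e-10)
    assert vals[-1] == pytest.approx(p_end, abs=1e-10)


def test_degenerate_flat_segment_is_constant():
    for fn in ("exponential", "logarithmic"):
        params = fit_segment(fn, 0.4, 0.4, 1, 10)
        assert params.kind == "constant"
        assert np.allclose(segment_values(params), 0.4)


def test_segment_argument_validation():
    with pytest.raises(ValidationError):
        fit_segment("linear", 0.3, 0.2, 10, 10)
    with pytest.raises(ValidationError):
        fit_segment("linear", 1.3, 0.2, 1, 10)


# ---------------------------------------------------------------------------
# weighted linear


def test_weights_closed_form():
    w = weighted_linear_weights(1, 60)
    assert w[0] == pytest.approx(1.0)
    assert w[-1] == pytest.approx(1.0)
    # day 30: 4/59^2 * (30 - 30.5)^2 = 1/3481
    assert w[29] == pytest.approx(1.0 / 3481.0)
    assert np.all((w >= 0) & (w <= 1))
    # even-length segment: integer midpoint hits exactly zero
    w2 = weighted_linear_weights(1, 9)
    assert w2[4] == 0.0


def test_weighted_linear_matches_literal_recursion_oracle():
    p_start, p_end, d1, d2 = 0.34, 0.0, 1, 60
    got = weighted_linear_segment(p_start, p_end, d1, d2)
    # independent literal implementation of the recursion
    a = (p_end - p_start) / (d2 - d1)
    b = p_start - a * d1
    prev = None
    expected = []
    for n in range(d1, d2 + 1):
        w = 4.0 / (d1 - d2) ** 2 * (n - (d1 + d2) / 2.0) ** 2
        ln = a * n + b
        prev = ln if prev is None else w * ln + (1 - w) * prev
        expected.append(prev)
    np.testing.assert_allclose(got, expected, atol=1e-12)
    assert got[0] == pytest.approx(p_start)
    assert got[-1] == pytest.approx(p_end)


def test_weighted_linear_constant_preserved():
    vals = weighted_linear_segment(0.4, 0.4, 3, 20)
    np.testing.assert_allclose(vals, 0.4, atol=1e-14)


def test_weight_one_everywhere_reduces_to_linear(monkeypatch):
    import readmitrisk.labels as labels

    monkeypatch.setattr(
        labels, "weighted_linear_weights", lambda d1, d2: np.ones(d2 - d1 + 1)
    )
    got = labels.weighted_linear_segment(0.34, 0.0, 1, 60)
    lin = segment_values(fit_segment("linear", 0.34, 0.0, 1, 60))
    np.testing.assert_allclose(got, lin, atol=1e-14)


# ---------------------------------------------------------------------------
# full trajectories


def test_nonreadmitted_worked_example():
    # the exact 0.34 -> 0 run over days 1..60 at segment level (integer
    # scores cannot produce 0.34 exactly)
    seg = segment_values(fit_segment("linear", 0.34, 0.0, 1, 60))
    assert seg[0] == pytest.approx(0.34, abs=1e-8)
    assert seg[-1] == pytest.approx(0.0, abs=1e-8)
    # and the full-trajectory contract for a comparable patient
    meta = PatientMeta("nr", False, lace=6, hospital=0)
    p = build_trajectory(meta, TrajectoryConfig("linear", "LACE")).probabilities
    assert p[0] == pytest.approx(initial_probability(meta, "LACE"))
    assert p[-1] == 0.0
    assert np.all(np.diff(p) < 0)


@pytest.mark.parametrize("function", FUNCTIONS)
def test_readmitted_worked_example_both_modes(function, readmitted_meta):
    p_init = initial_probability(readmitted_meta, "average")
    cont = build_trajectory(
        readmitted_meta, TrajectoryConfig(function, "average", "continue_from_one")
    ).probabilities
    assert cont[0] == pytest.approx(p_init, abs=1e-8)
    assert cont[15] == 1.0  # readmission day 16
    np.testing.assert_allclose(cont[15:21], 1.0)  # held at 1 until day 21
    assert cont[-1] == 0.0

    reset = build_trajectory(
        readmitted_meta, TrajectoryConfig(function, "average", "reset_to_initial")
    ).probabilities
    assert reset[15] == 1.0
    assert reset[20] == pytest.approx(p_init, abs=1e-8)  # back to initial on day 21
    assert reset[-1] == 0.0


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    function=st.sampled_from(FUNCTIONS),
    source=st.sampled_from(["LACE", "HOSPITAL", "average"]),
    mode=st.sampled_from(["reset_to_initial", "continue_from_one"]),
    lace=st.integers(0, 19),
    hospital=st.integers(0, 15),
    readmit=st.booleans(),
    k=st.integers(2, 55),
    stay=st.integers(1, 10),
)
def test_trajectory_invariants(function, source, mode, lace, hospital, readmit, k, stay):
    if readmit:
        meta = PatientMeta(
            "p", True, lace=lace, hospital=hospital,
            readmission_day=k, second_discharge_day=min(k + stay, 60),
        )
    else:
        meta = PatientMeta("p", False, lace=lace, hospital=hospital)
    traj = build_trajectory(meta, TrajectoryConfig(function, source, mode))
    p = traj.probabilities
    assert len(p) == 60
    assert np.all((p >= 0.0) & (p <= 1.0))
    assert p[-1] == 0.0
    assert p[0] == pytest.approx(initial_probability(meta, source), abs=1e-8)
    if readmit:
        assert p[k - 1] == 1.0
    elif function != "weighted_linear":
        assert np.all(np.diff(p) <= 1e-12)  # falling segment non-increasing


@pytest.mark.parametrize("function", ["linear", "exponential", "logarithmic"])
def test_rising_and_falling_segments_monotone(function, readmitted_meta):
    p = build_trajectory(
        readmitted_meta, TrajectoryConfig(function, "average", "continue_from_one")
    ).probabilities
    assert np.all(np.diff(p[:16]) >= -1e-12)  # rise to readmission day
    assert np.all(np.diff(p[20:]) <= 1e-12)  # fall after second discharge


def test_readmission_on_horizon_rejected():
    meta = PatientMeta("p", True, lace=5, hospital=5,
                       readmission_day=60, second_discharge_day=61)
    with pytest.raises(ValidationError):
        build_trajectory(meta, TrajectoryConfig())


def test_second_discharge_on_final_day_still_ends_at_zero():
    meta = PatientMeta("p", True, lace=5, hospital=5,
                       readmission_day=40, second_discharge_day=60)
    p = build_trajectory(meta, TrajectoryConfig("linear", "LACE")).probabilities
    assert p[39] == 1.0
    assert p[-1] == 0.0
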