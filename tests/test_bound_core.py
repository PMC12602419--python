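"""Unit and property tests for the bound components and log-sum-exp smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ivbounds import (
    PiPair, SimplexError, gamma_and_argext, lse, lse_gradient, lse_min,
    margin_gaps, margin_summary, observables_from_types, theta_lower, theta_upper,
)
from ivbounds.bound_core import LSEConfig, ThetaBounds

from conftest import random_feasible_pipair

LOG8 = np.log(8)


# ---------------------------------------------------------------------------
# theta components


@pytest.mark.parametrize(
    "pi_z1, pi_z0, expect_gl, expect_gu",
    [
        # perfect compliance with Y = A: effect point-identified at 1
        ((1, 0, 0, 0), (0, 0, 0, 1), 1.0, 1.0),
        # symmetric Y = A with p = 1/2: all lower components zero
        ((0.5, 0, 0, 0.5), (0.5, 0, 0, 0.5), 0.0, 1.0),
        # always takers with P(Y=1) = 0.3: only the treated arm observable
        ((0.3, 0.7, 0, 0), (0.3, 0.7, 0, 0), -0.7, 0.3),
    ],
)
def test_theta_hand_values(pi_z1, pi_z0, expect_gl, expect_gu):
    pi = PiPair(pi_z0=np.array(pi_z0, float), pi_z1=np.array(pi_z1, float))
    tl, tu = theta_lower(pi), theta_upper(pi)
    assert tl.shape == (8,) and tu.shape == (8,)
    assert tl.max() == pytest.approx(expect_gl, abs=1e-12)
    assert tu.min() == pytest.approx(expect_gu, abs=1e-12)
    assert tl.max() <= 1.0 + 1e-12


def test_theta_symmetric_case_componentwise():
    """Symmetric Y=A case: theta_l all zero, theta_u = (1,1,1,1,1.5,...)."""
    pi = PiPair(pi_z0=[0.5, 0, 0, 0.5], pi_z1=[0.5, 0, 0, 0.5])
    assert np.allclose(theta_lower(pi), 0.0)
    assert np.allclose(theta_upper(pi), [1, 1, 1, 1, 1.5, 1.5, 1.5, 1.5])


def test_theta_rejects_off_simplex():
    with pytest.raises(SimplexError):
        theta_lower(np.array([[0.5, 0.5, 0.1, 0.0], [0.25, 0.25, 0.25, 0.25]]))
    with pytest.raises(SimplexError):
        PiPair(pi_z0=[0.3, 0.3, 0.3, 0.3], pi_z1=[0.25, 0.25, 0.25, 0.25])


def test_theta_matches_independent_transcription():
    """Table-driven evaluation agrees with a hand-typed transcription.

    The eight lower and eight upper component formulas are re-typed here as
    plain arithmetic (independent of the parsed coefficient tables) and both
    are evaluated on 1,000 random simplex pairs.
    """

    def by_hand(p):
        # p[z][ya] with ya in ("11", "01", "10", "00")
        p0 = dict(zip(("11", "01", "10", "00"), p[0]))
        p1 = dict(zip(("11", "01", "10", "00"), p[1]))
        tl = [
            p1["11"] + p0["00"] - 1,
            p0["11"] + p1["00"] - 1,
            -p1["01"] - p1["10"],
            -p0["01"] - p0["10"],
            p0["11"] - p1["11"] - p1["10"] - p0["01"] - p0["10"],
            p1["11"] - p0["11"] - p0["10"] - p1["01"] - p1["10"],
            p1["00"] - p1["01"] - p1["10"] - p0["01"] - p0["00"],
            p0["00"] - p0["01"] - p0["10"] - p1["01"] - p1["00"],
        ]
        tu = [
            1 - p1["01"] - p0["10"],
            1 - p0["01"] - p1["10"],
            p1["11"] + p1["00"],
            p0["11"] + p0["00"],
            -p0["01"] + p1["01"] + p1["00"] + p0["11"] + p0["00"],
            -p1["01"] + p1["11"] + p1["00"] + p0["01"] + p0["00"],
            -p1["10"] + p1["11"] + p1["00"] + p0["11"] + p0["10"],
            -p0["10"] + p0["11"] + p0["00"] + p1["11"] + p1["10"],
        ]
        return np.array(tl), np.array(tu)

    rng = np.random.default_rng(2024)
    pis = rng.dirichlet(np.ones(4), size=(1000, 2))
    tl_ref = np.empty((1000, 8))
    tu_ref = np.empty((1000, 8))
    for i, p in enumerate(pis):
        tl_ref[i], tu_ref[i] = by_hand(p)
    assert np.allclose(theta_lower(pis), tl_ref, atol=1e-12)
    assert np.allclose(theta_upper(pis), tu_ref, atol=1e-12)


def test_feasible_pairs_give_ordered_bounds_in_range():
    """Type-generated cells always satisfy -1 <= gamma_l <= gamma_u <= 1."""
    rng = np.random.default_rng(7)
    for _ in range(300):
        pi = random_feasible_pipair(rng)
        gl = theta_lower(pi).max()
        gu = theta_upper(pi).min()
        assert -1 - 1e-9 <= gl <= gu + 1e-9 <= 1 + 2e-9


# ---------------------------------------------------------------------------
# gamma / argext


def test_gamma_argext_tie_breaks_to_smallest_index():
    tb = gamma_and_argext(np.zeros((1, 8)), np.zeros((1, 8)))
    assert tb.d_l[0] == 1 and tb.d_u[0] == 1
    assert tb.gamma_l[0] == 0.0 and tb.gamma_u[0] == 0.0


def test_gamma_argext_complier_stratum(complier_pi):
    tb = gamma_and_argext(theta_lower(complier_pi)[None, :],
                          theta_upper(complier_pi)[None, :])
    assert tb.gamma_l[0] == pytest.approx(0.10)
    assert tb.gamma_u[0] == pytest.approx(0.10)
    assert tb.d_l[0] == 1
    assert not tb.incompatible[0]


def test_gamma_argext_always_taker_sixway_tie(always_taker_pi):
    tl = theta_lower(always_taker_pi)
    assert np.isclose(tl[:6], -0.7).all() and (tl[6:] < -0.7).all()
    tb = gamma_and_argext(tl[None, :], theta_upper(always_taker_pi)[None, :])
    assert tb.d_l[0] == 1 and tb.gamma_l[0] == pytest.approx(-0.7)


def test_incompatibility_flagged_for_crossing_rows():
    tl = np.zeros((2, 8))
    tu = np.zeros((2, 8))
    tl[1] = 0.5  # gamma_l = 0.5 > gamma_u = 0 in row 1
    tb = gamma_and_argext(tl, tu)
    assert tb.incompatible.tolist() == [False, True]
    assert tb.incompatible_fraction == 0.5


# ---------------------------------------------------------------------------
# log-sum-exp


def test_lse_closed_forms():
    assert lse(np.array([0.0, 0.0]), 1.0) == pytest.approx(np.log(2))
    assert lse(np.array([1.0, 0.0]), 2.0) == pytest.approx(0.5 * np.log(np.e**2 + 1))
    assert lse_min(np.array([0.0, 0.0]), 1.0) == pytest.approx(-np.log(2))
    assert lse_min(np.array([1.0, 0.0]), 2.0) == pytest.approx(
        -0.5 * np.log(1 + np.exp(-2)))
    c = 0.37
    v = np.full(8, c)
    for t in (0.5, 10.0, 740.0):
        assert lse(v, t) == pytest.approx(c + LOG8 / t)
        assert lse_min(v, t) == pytest.approx(c - LOG8 / t)


def test_lse_rejects_nonpositive_temperature():
    for bad in (0.0, -1.0):
        with pytest.raises(ValueError):
            lse(np.zeros(3), bad)
        with pytest.raises(ValueError):
            lse_gradient(np.zeros(3), bad)
        with pytest.raises(ValueError):
            LSEConfig(t=bad)


def test_lse_stable_at_large_temperature():
    v = np.array([0.9, -1.0, 0.2, 0.1, 0.0, -0.5, 0.3, -0.2])
    out = lse(v, 740.0)
    # non-max terms underflow at this temperature: equality to the max is the
    # correct floating-point answer
    assert np.isfinite(out) and 0.9 <= out <= 0.9 + LOG8 / 740.0
    g = lse_gradient(v, 740.0)
    assert np.isfinite(g).all() and g.argmax() == 0


def test_lse_gradient_values():
    assert np.allclose(lse_gradient(np.zeros(8), 3.0), 1 / 8)
    g = lse_gradient(np.array([1.0, 0.0]), 2.0)
    assert np.allclose(g, [np.e**2 / (np.e**2 + 1), 1 / (np.e**2 + 1)])
    # softmax concentrates on the unique argmax as t grows
    g_inf = lse_gradient(np.array([0.3, 0.1, -0.2]), 1e5)
    assert np.allclose(g_inf, [1, 0, 0], atol=1e-12)
    # softmin mirrors on the argmin
    h_inf = lse_gradient(np.array([0.3, 0.1, -0.2]), 1e5, direction="min")
    assert np.allclose(h_inf, [0, 0, 1], atol=1e-12)


@settings(max_examples=150, derandomize=True)
@given(
    v=st.lists(st.floats(-2, 2), min_size=2, max_size=8).map(np.array),
    t=st.floats(0.1, 500.0),
    c=st.floats(-3, 3),
)
def test_lse_properties(v, t, c):
    """Sandwich, shift invariance, monotone coordinates, gradient simplex."""
    val = lse(v, t)
    assert v.max() <= val <= v.max() + np.log(len(v)) / t + 1e-12
    hval = lse_min(v, t)
    assert v.min() - np.log(len(v)) / t - 1e-12 <= hval <= v.min() + 1e-12
    assert lse(v + c, t) == pytest.approx(val + c, abs=1e-9)
    bumped = v.copy()
    bumped[0] += 0.1
    # ">=" because a bump of a far-from-max coordinate can vanish in floats
    assert lse(bumped, t) >= val
    assert lse(v + 0.1, t) == pytest.approx(val + 0.1, abs=1e-9)
    g = lse_gradient(v, t)
    assert g.min() >= 0 and g.sum() == pytest.approx(1.0)
    perm = np.roll(v, 1)
    assert np.allclose(lse_gradient(perm, t), np.roll(g, 1))


# ---------------------------------------------------------------------------
# margins and widths


def test_margin_gaps_hand_values(complier_pi):
    tb = gamma_and_argext(theta_lower(complier_pi)[None, :],
                          theta_upper(complier_pi)[None, :])
    low, up = margin_gaps(tb)
    # runner-up of the lower components is theta_l_8 = -0.15
    assert low[0] == pytest.approx(0.25)
    assert up[0] >= 0
    tb0 = gamma_and_argext(np.zeros((1, 8)), np.zeros((1, 8)))
    l0, u0 = margin_gaps(tb0)
    assert l0[0] == 0.0 and u0[0] == 0.0


def test_margin_gaps_nonnegative_random():
    rng = np.random.default_rng(11)
    tb = ThetaBounds(rng.normal(size=(200, 8)), rng.normal(size=(200, 8)))
    low, up = margin_gaps(tb)
    assert (low >= 0).all() and (up >= 0).all()
    rep = margin_summary(tb)
    assert set(rep) >= {"lower", "upper", "argext_hist_lower", "incompatible_fraction"}
    assert sum(rep["argext_hist_lower"]) == 200


def test_width_by_compliance_class(complier_pi, always_taker_pi):
    """Width 1 where only one arm is observable, 0 where compliance identifies."""
    from ivbounds.simulate import class_pipair

    for pi in (always_taker_pi, class_pipair((0, 0), (0.90, 0.95))):
        width = theta_upper(pi).min() - theta_lower(pi).max()
        assert width == pytest.approx(1.0)
    for pi in (complier_pi, class_pipair((1, 0), (0.65, 0.70))):
        width = theta_upper(pi).min() - theta_lower(pi).max()
        assert width == pytest.approx(0.0, abs=1e-12)
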