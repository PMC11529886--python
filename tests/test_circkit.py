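"""Unit and property tests for the circular-statistics core."""

import itertools
import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from menotaxis import (
    CircularSample,
    bh_adjust,
    circ_mean_R,
    circ_mean_ci95,
    fisher_lee_regression,
    michelson_contrast,
    rayleigh_test,
    vm_kappa_from_R,
    vm_mean_resultant,
    watson_u2,
    watson_williams,
    wrap_deg,
)
from menotaxis.circkit import _u2_statistic


# ---------------------------------------------------------------------------
# wrapping
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("raw, expected", [
    (190.0, -170.0),
    (-180.0, 180.0),
    (45.0, 45.0),
    (180.0, 180.0),
    (360.0, 0.0),
    (-540.0, 180.0),
])
def test_wrap_deg_examples(raw, expected):
    assert wrap_deg(raw) == pytest.approx(expected)


def test_wrap_deg_rejects_non_finite():
    with pytest.raises(ValueError):
        wrap_deg(math.nan)
    with pytest.raises(ValueError):
        wrap_deg(math.inf)


@given(st.floats(-1e6, 1e6))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_wrap_deg_congruent_and_in_range(a):
    w = wrap_deg(a)
    assert -180.0 < w <= 180.0
    # congruence mod 360
    assert math.isclose(math.cos(math.radians(w)), math.cos(math.radians(a)),
                        abs_tol=1e-9)
    assert math.isclose(math.sin(math.radians(w)), math.sin(math.radians(a)),
                        abs_tol=1e-9)


# ---------------------------------------------------------------------------
# descriptive statistics
# ---------------------------------------------------------------------------

def test_circ_mean_examples():
    s = circ_mean_R([45.0, 45.0, 45.0])
    assert s.mean_deg == pytest.approx(45.0)
    assert s.R == pytest.approx(1.0)
    assert s.variance == pytest.approx(0.0)

    s = circ_mean_R([0.0, 180.0])  # antipodal: no resolvable direction
    assert s.mean_deg is None
    assert s.R == pytest.approx(0.0)
    assert s.variance == pytest.approx(1.0)

    s = circ_mean_R([0.0, 90.0])
    assert s.mean_deg == pytest.approx(45.0)
    assert s.R == pytest.approx(math.sqrt(0.5))
    assert s.variance == pytest.approx(1.0 - math.sqrt(0.5))


def test_circ_mean_rejects_empty():
    with pytest.raises(ValueError):
        CircularSample([])


def test_circ_mean_matches_bruteforce_vector_sum(rng):
    """Mean/R agree with explicit unit-vector summation to 1e-9."""
    for _ in range(1000):
        n = rng.integers(1, 51)
        ang = rng.uniform(-180.0, 180.0, n)
        s = circ_mean_R(ang)
        # oracle: naive per-angle accumulation
        cx = sum(math.cos(math.radians(a)) for a in ang) / n
        sx = sum(math.sin(math.radians(a)) for a in ang) / n
        R = math.hypot(cx, sx)
        assert abs(s.R - R) < 1e-9
        assert s.variance == pytest.approx(1.0 - s.R)
        if R > 1e-9:
            mean = math.degrees(math.atan2(sx, cx))
            assert abs(wrap_deg(s.mean_deg - mean)) < 1e-9


@given(st.lists(st.floats(-180.0, 180.0), min_size=2, max_size=40),
       st.floats(-360.0, 360.0))
@settings(max_examples=150, deadline=None, derandomize=True)
def test_rotation_equivariance(angles, delta):
    """Adding delta rotates the mean and leaves R and variance unchanged."""
    s0 = circ_mean_R(angles)
    s1 = circ_mean_R(np.asarray(angles) + delta)
    assert s1.R == pytest.approx(s0.R, abs=1e-9)
    assert s1.variance == pytest.approx(s0.variance, abs=1e-9)
    if s0.mean_deg is not None and s0.R > 1e-6:
        assert abs(wrap_deg(s1.mean_deg - s0.mean_deg - delta)) < 1e-6


def test_ci_zero_dispersion_and_high_variance_rule(rng):
    assert circ_mean_ci95([10.0, 10.0, 10.0, 10.0]) == pytest.approx(0.0)
    # variance > 0.8: CI reported as undefined, not a number
    wide = np.degrees(rng.vonmises(0.0, 0.2, 60))
    summary = circ_mean_R(wide)
    if summary.variance > 0.8:
        assert circ_mean_ci95(wide) is None
    # antipodal sample has variance 1
    assert circ_mean_ci95([0.0, 180.0, 0.0, 180.0]) is None
    with pytest.raises(ValueError):
        circ_mean_ci95([5.0])


def test_ci_coverage_montecarlo(rng):
    """Coverage of the mean-direction CI is ~95% (kappa=4, n=50)."""
    n_rep, covered, computed = 600, 0, 0
    for _ in range(n_rep):
        x = np.degrees(rng.vonmises(math.radians(40.0), 4.0, 50))
        hw = circ_mean_ci95(x)
        if hw is None:
            continue
        computed += 1
        if abs(wrap_deg(circ_mean_R(x).mean_deg - 40.0)) <= hw:
            covered += 1
    assert computed > 0.95 * n_rep
    assert covered / computed == pytest.approx(0.95, abs=0.025)


# ---------------------------------------------------------------------------
# Rayleigh
# ---------------------------------------------------------------------------

def test_rayleigh_examples():
    res = rayleigh_test(np.arange(8) * 45.0)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)

    res = rayleigh_test([45.0] * 20)
    assert res.statistic == pytest.approx(20.0)
    # independent evaluation of the corrected exponential approximation
    n, Rn = 20, 20.0
    expected = math.exp(math.sqrt(1 + 4 * n + 4 * (n * n - Rn * Rn)) - (1 + 2 * n))
    assert res.p_value == pytest.approx(expected, rel=1e-12)
    assert res.p_value < 1e-6

    with pytest.raises(ValueError):
        rayleigh_test([0.0, 10.0, 20.0])


def test_rayleigh_rotation_invariance(rng):
    x = rng.uniform(-180, 180, 30)
    a = rayleigh_test(x)
    b = rayleigh_test(x + 123.4)
    assert a.statistic == pytest.approx(b.statistic, abs=1e-9)
    assert a.p_value == pytest.approx(b.p_value, abs=1e-12)


# ---------------------------------------------------------------------------
# Watson-Williams
# ---------------------------------------------------------------------------

def test_watson_williams_identical_groups(rng):
    g = np.degrees(rng.vonmises(0.3, 8.0, 20))
    res = watson_williams(g, g.copy())
    assert res.statistic == pytest.approx(0.0, abs=1e-9)
    assert res.p_value == pytest.approx(1.0)


def test_watson_williams_symmetry_and_power(rng):
    a = np.degrees(rng.vonmises(0.0, 8.0, 20))
    b = np.degrees(rng.vonmises(math.pi / 2, 8.0, 20))
    r1 = watson_williams(a, b)
    r2 = watson_williams(b, a)
    assert r1.statistic == pytest.approx(r2.statistic)
    assert r1.p_value == pytest.approx(r2.p_value)
    assert r1.p_value < 0.001
    # permutation oracle on the same data: shuffle group labels, compare F
    pooled = np.concatenate([a, b])
    obs = r1.statistic
    count = 0
    n_perm = 400
    prng = np.random.default_rng(5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_perm):
            perm = prng.permutation(pooled)
            if watson_williams(perm[:20], perm[20:]).statistic >= obs:
                count += 1
    assert (count + 1) / (n_perm + 1) < 0.01


def test_watson_williams_warns_when_dispersed(rng):
    a = np.degrees(rng.vonmises(0.0, 0.3, 30))
    b = np.degrees(rng.vonmises(0.0, 0.3, 30))
    with pytest.warns(UserWarning, match="validity"):
        watson_williams(a, b)


def test_watson_williams_degenerate_rejected():
    a = np.arange(8) * 45.0  # R exactly 0
    with pytest.raises(ValueError):
        watson_williams(a, a + 22.5)
    with pytest.raises(ValueError):
        watson_williams([0.0, 1.0, 2.0], [3.0, 4.0, 5.0])  # too small


def test_watson_williams_type_I(rng):
    """Null rejection rate ~5% for shared-mean von Mises groups."""
    n_rep, rej = 800, 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_rep):
            mu = rng.uniform(-math.pi, math.pi)
            a = np.degrees(rng.vonmises(mu, 4.0, 20))
            b = np.degrees(rng.vonmises(mu, 4.0, 20))
            if watson_williams(a, b).p_value < 0.05:
                rej += 1
    assert rej / n_rep == pytest.approx(0.05, abs=0.02)


# ---------------------------------------------------------------------------
# Watson U2
# ---------------------------------------------------------------------------

def test_u2_identical_copy_is_null(rng):
    a = np.degrees(rng.vonmises(0.5, 2.0, 16))
    res = watson_u2(a, a.copy(), n_perm=500, seed=1)
    assert res.p_value == pytest.approx(1.0)


def test_u2_rotation_invariance(rng):
    a = rng.uniform(-180, 180, 15)
    b = rng.uniform(-180, 180, 20)
    u0 = _u2_statistic(np.mod(a, 360), np.mod(b, 360))
    u1 = _u2_statistic(np.mod(a + 77.0, 360), np.mod(b + 77.0, 360))
    assert abs(u0 - u1) < 1e-9


def test_u2_detects_mean_shift(rng):
    a = np.degrees(rng.vonmises(0.0, 8.0, 20))
    b = np.degrees(rng.vonmises(math.radians(120.0), 8.0, 20))
    res = watson_u2(a, b, n_perm=2000, seed=7)
    assert res.p_value < 0.01


def test_u2_handles_ties_via_midranks():
    a = np.array([0.0, 0.0, 90.0, 90.0, 180.0, 180.0, 270.0, 270.0])
    b = a + 0.0  # exact ties everywhere
    assert _u2_statistic(a, b) == pytest.approx(0.0, abs=1e-12)
    res = watson_u2(a, b, n_perm=300, seed=2)
    assert res.p_value > 0.9


def test_u2_small_groups_rejected():
    with pytest.raises(ValueError):
        watson_u2(np.arange(5.0), np.arange(10.0))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def test_bh_examples():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                               [0.03, 0.03, 0.03])
    np.testing.assert_allclose(bh_adjust([0.05]), [0.05])
    with pytest.raises(ValueError):
        bh_adjust([0.2, 1.5])


@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_bh_dominates_raw(ps):
    adj = bh_adjust(ps)
    assert np.all(adj >= np.asarray(ps) - 1e-12)
    assert np.all((adj >= 0) & (adj <= 1))
    assert np.all(np.diff(np.sort(adj)) >= -1e-12)


# ---------------------------------------------------------------------------
# Fisher-Lee regression
# ---------------------------------------------------------------------------

def test_regression_no_signal():
    """Identical responses with a zero covariate: flat fit, p ~ 1."""
    theta = np.full(30, 40.0)
    x = np.zeros((30, 1))
    fit = fisher_lee_regression(theta, x)
    assert fit.coefficients[0] == 0.0
    assert fit.kappa_hat > 1e4
    assert fit.p_values[0] == pytest.approx(1.0)
    assert abs(wrap_deg(fit.intercept_deg - 40.0)) < 1e-6


def test_regression_recovers_binary_shift(rng):
    x = rng.integers(0, 2, 80).astype(float)
    mu = np.where(x > 0, math.pi / 2, 0.0)
    theta = np.degrees(rng.vonmises(mu, 4.0))
    fit = fisher_lee_regression(theta, x[:, None], ["shift"])
    assert fit.converged
    assert fit.p_values[0] < 0.01
    shift = wrap_deg(math.degrees(2 * math.atan(fit.coefficients[0])))
    assert abs(wrap_deg(shift - 90.0)) < 15.0


def test_regression_intercept_ci_coverage(rng):
    """True intercept inside the 95% CI in >=90% of replicates."""
    n_rep, hits = 120, 0
    for _ in range(n_rep):
        x = rng.normal(size=(60, 1))
        mu = math.radians(30.0) + 2.0 * np.arctan(0.4 * x[:, 0])
        theta = np.degrees(rng.vonmises(mu, 4.0))
        fit = fisher_lee_regression(theta, x)
        lo, hi = fit.intercept_ci95_deg
        m = 30.0
        if lo <= m <= hi or lo <= m - 360 <= hi or lo <= m + 360 <= hi:
            hits += 1
    assert hits / n_rep >= 0.90


def test_regression_rejects_bad_designs(rng):
    theta = np.degrees(rng.vonmises(0, 4, 30))
    with pytest.raises(ValueError):  # rank deficient
        fisher_lee_regression(theta, np.ones((30, 2)))
    with pytest.raises(ValueError):  # too few observations
        fisher_lee_regression(theta[:4], np.arange(8.0).reshape(4, 2))


# ---------------------------------------------------------------------------
# Michelson contrast
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("imax, imin, expected", [
    (5.0, 0.0, 1.0),
    (0.37, 0.0, 1.0),
    (4.0, 4.0, 0.0),
    (3.0, 1.0, 0.5),
])
def test_michelson_examples(imax, imin, expected):
    assert michelson_contrast(imax, imin) == pytest.approx(expected)


def test_michelson_invalid():
    with pytest.raises(ValueError):
        michelson_contrast(0.0, 0.0)
    with pytest.raises(ValueError):
        michelson_contrast(1.0, 2.0)


# ---------------------------------------------------------------------------
# von Mises helpers
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kappa", [0.5, 1.0, 2.0, 4.0, 8.0])
def test_kappa_R_round_trip(kappa):
    assert vm_kappa_from_R(vm_mean_resultant(kappa)) == pytest.approx(
        kappa, rel=1e-6)


# ---------------------------------------------------------------------------
# independent library cross-check
# ---------------------------------------------------------------------------

def test_against_pingouin_circular_functions(rng):
    """Mean, R and the Rayleigh statistic agree with pingouin's
    independent implementations."""
    pg = pytest.importorskip("pingouin")
    rad = rng.vonmises(1.0, 3.0, 80)
    ours = circ_mean_R(np.degrees(rad))
    assert ours.R == pytest.approx(float(pg.circ_r(rad)), abs=1e-9)
    assert abs(wrap_deg(ours.mean_deg
                        - math.degrees(float(pg.circ_mean(rad))))) < 1e-9
    z_pg, p_pg = pg.circ_rayleigh(rad)
    res = rayleigh_test(np.degrees(rad))
    assert res.statistic == pytest.approx(float(z_pg), abs=1e-9)
    assert res.p_value == pytest.approx(float(p_pg), rel=1e-6, abs=1e-12)


def test_u2_asymptotic_branch(rng):
    a = np.degrees(rng.vonmises(0.0, 8.0, 30))
    b = np.degrees(rng.vonmises(math.radians(120.0), 8.0, 30))
    asym = watson_u2(a, b, method="asymptotic")
    perm = watson_u2(a, b, n_perm=2000, seed=3)
    assert asym.method == "asymptotic"
    assert asym.statistic == perm.statistic
    assert asym.p_value < 0.01 and perm.p_value < 0.01
    # null case: large-sample tail stays near 1 bounded in [0, 1]
    null = watson_u2(a, a.copy(), method="asymptotic")
    assert 0.0 < null.p_value <= 1.0
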