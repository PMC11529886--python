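"""Circular statistics on heading angles, in degrees.

Descriptive statistics (circular mean, vector strength, circular variance,
95% confidence interval), inferential tests (Rayleigh, Watson-Williams,
two-sample Watson U-squared), Benjamini-Hochberg adjustment, von Mises
regression with a tan-half-angle link, and the Michelson contrast of a
point-source stimulus.

Conventions
-----------
* All public angles are degrees, counterclockwise positive viewed from
  above, wrapped to the half-open interval (-180, 180].
* Circular variance is defined as ``1 - R`` where ``R`` is the mean
  resultant length (vector strength), so it lies on [0, 1].
* The mean direction is reported as undefined (``None``) when the
  resultant is numerically zero (``R < 1e-12``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CircularSample",
    "CircSummary",
    "CircTestResult",
    "CircRegressionFit",
    "wrap_deg",
    "circ_mean_R",
    "circ_mean_ci95",
    "rayleigh_test",
    "watson_williams",
    "watson_u2",
    "bh_adjust",
    "fisher_lee_regression",
    "michelson_contrast",
    "vm_mean_resultant",
    "vm_kappa_from_R",
]

#: resultants shorter than this leave the mean direction undefined
RESOLVABLE_R = 1e-12

#: circular variance above which the 95% CI is reported as undefined
CI_VARIANCE_LIMIT = 0.8

#: pooled mean resultant length below which Watson-Williams is out of its
#: validity range (a warning, not an error)
WW_VALIDITY_RBAR = 0.45


# ---------------------------------------------------------------------------
# angles and samples
# ---------------------------------------------------------------------------

def wrap_deg(angle):
    """Wrap an angle (or array of angles) in degrees to (-180, 180].

    Parameters
    ----------
    angle : float or array-like
        Finite angle(s) in degrees.

    Returns
    -------
    float or ndarray
        ``angle`` reduced modulo 360 into (-180, 180].
    """
    a = np.asarray(angle, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("angles must be finite")
    wrapped = 180.0 - np.mod(180.0 - a, 360.0)
    if np.ndim(angle) == 0:
        return float(wrapped)
    return wrapped


@dataclass(frozen=True)
class CircularSample:
    """A sample of heading angles sharing one reference frame.

    Angles are wrapped to (-180, 180] on construction. ``frame`` tags
    whether the angles are arena-frame (real-world) headings or headings
    measured relative to a stimulus azimuth.
    """

    angles: np.ndarray
    frame: str = "arena"

    def __init__(self, angles, frame: str = "arena"):
        arr = np.atleast_1d(np.asarray(angles, dtype=float))
        if arr.size < 1:
            raise ValueError("sample must contain at least one angle")
        if frame not in ("arena", "stimulus_relative"):
            raise ValueError(f"unknown frame {frame!r}")
        object.__setattr__(self, "angles", wrap_deg(arr))
        object.__setattr__(self, "frame", frame)

    def __len__(self) -> int:
        return self.angles.size

    def rotated(self, delta_deg: float) -> "CircularSample":
        """Return the sample with ``delta_deg`` added to every angle."""
        return CircularSample(self.angles + delta_deg, frame=self.frame)


@dataclass(frozen=True)
class CircSummary:
    """Descriptive circular statistics for one sample.

    ``mean_deg`` is None when the resultant is numerically zero;
    ``ci95_halfwidth_deg`` is None when the variance exceeds 0.8 or the
    closed form is outside its validity range.
    """

    mean_deg: Optional[float]
    R: float
    variance: float
    n: int
    ci95_halfwidth_deg: Optional[float] = None


@dataclass(frozen=True)
class CircTestResult:
    """Outcome of a circular hypothesis test."""

    test_name: str
    statistic: float
    p_value: float
    df: tuple = ()
    method: str = "asymptotic"


@dataclass(frozen=True)
class CircRegressionFit:
    """Maximum-likelihood fit of a von Mises regression.

    The mean direction of observation *i* is
    ``intercept + 2*arctan(x_i . beta)`` (tan-half-angle link); slopes are
    on the link scale, the intercept in degrees.
    """

    intercept_deg: float
    coefficients: np.ndarray
    kappa_hat: float
    loglik: float
    p_values: np.ndarray
    converged: bool
    intercept_ci95_deg: Optional[tuple] = None
    covariate_names: tuple = ()


def _as_sample(x) -> CircularSample:
    return x if isinstance(x, CircularSample) else CircularSample(x)


# ---------------------------------------------------------------------------
# descriptive statistics
# ---------------------------------------------------------------------------

def _resultant(rad: np.ndarray):
    c = np.cos(rad).mean()
    s = np.sin(rad).mean()
    return c, s, math.hypot(c, s)


def circ_mean_R(sample) -> CircSummary:
    """Circular mean direction, vector strength and circular variance.

    The vector strength ``R`` is the length of the mean of the unit
    vectors of all angles; a value of 1 means the heading never changed,
    values near 0 mean the heading was broadly spread. Circular variance
    is ``1 - R``. The mean direction is undefined for a (numerically)
    zero resultant, e.g. antipodal pairs.
    """
    s = _as_sample(sample)
    rad = np.deg2rad(s.angles)
    c, sn, R = _resultant(rad)
    R = min(R, 1.0)
    if R < RESOLVABLE_R:
        mean = None
        R = 0.0
    else:
        mean = wrap_deg(math.degrees(math.atan2(sn, c)))
    return CircSummary(mean_deg=mean, R=R, variance=1.0 - R, n=len(s))


def circ_mean_ci95(sample) -> Optional[float]:
    """Half-width (deg) of the 95% CI for the mean direction, or None.

    Uses the large-sample dispersion-based closed form (Fisher 1993):
    the circular dispersion ``delta = (1 - rho2) / (2 R^2)`` with
    ``rho2`` the mean cosine of twice the deviations from the mean, and
    half-width ``arcsin(z_0.975 * sqrt(delta / n))``. Returns None when
    the circular variance exceeds 0.8 (the spread is too wide for a
    meaningful interval) or when the arcsin argument leaves [-1, 1].
    """
    s = _as_sample(sample)
    if len(s) < 2:
        raise ValueError("CI requires at least 2 angles")
    summ = circ_mean_R(s)
    if summ.variance > CI_VARIANCE_LIMIT or summ.mean_deg is None:
        return None
    rad = np.deg2rad(s.angles)
    mu = math.radians(summ.mean_deg)
    dev = rad - mu
    rho2 = np.cos(2.0 * dev).mean()
    if summ.R >= 1.0 - 1e-12:  # zero dispersion
        return 0.0
    delta = (1.0 - rho2) / (2.0 * summ.R**2)
    arg = stats.norm.ppf(0.975) * math.sqrt(max(delta, 0.0) / len(s))
    if arg > 1.0:
        return None
    return math.degrees(math.asin(arg))


# ---------------------------------------------------------------------------
# inferential tests
# ---------------------------------------------------------------------------

def rayleigh_test(sample) -> CircTestResult:
    """Rayleigh test of circular uniformity.

    The statistic is ``z = n * R**2``; the p-value uses the standard
    small-sample-corrected exponential approximation
    ``p = exp(sqrt(1 + 4n + 4(n^2 - Rn^2)) - (1 + 2n))`` where
    ``Rn = n * R`` (Zar 1999 eq. 27.4).
    """
    s = _as_sample(sample)
    n = len(s)
    if n < 4:
        raise ValueError("Rayleigh asymptotics need n >= 4")
    summ = circ_mean_R(s)
    Rn = n * summ.R
    z = n * summ.R**2
    p = math.exp(math.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - Rn * Rn)) - (1.0 + 2.0 * n))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return CircTestResult("rayleigh", z, p, df=(), method="asymptotic")


def watson_williams(group_a, group_b) -> CircTestResult:
    """Watson-Williams F test for equal mean direction of two groups.

    Applies the ``1 + 3/(8*kappa_hat)`` correction factor, with kappa
    estimated from the pooled within-group mean resultant length. Emits
    a warning (never an error) when that pooled resultant is below the
    test's validity range (~0.45), because heading data are often widely
    dispersed.
    """
    a, b = _as_sample(group_a), _as_sample(group_b)
    n1, n2 = len(a), len(b)
    if n1 < 5 or n2 < 5:
        raise ValueError("Watson-Williams needs n >= 5 per group")
    N = n1 + n2
    sa, sb = circ_mean_R(a), circ_mean_R(b)
    if sa.R < RESOLVABLE_R and sb.R < RESOLVABLE_R:
        raise ValueError(
            "both groups have zero resultant; mean directions undefined"
        )
    R1, R2 = n1 * sa.R, n2 * sb.R
    pooled = CircularSample(np.concatenate([a.angles, b.angles]))
    Rt = N * circ_mean_R(pooled).R
    rbar = (R1 + R2) / N
    if rbar < WW_VALIDITY_RBAR:
        warnings.warn(
            "Watson-Williams: pooled mean resultant length "
            f"{rbar:.3f} < {WW_VALIDITY_RBAR}; the F approximation is "
            "outside its validity range",
            UserWarning,
            stacklevel=2,
        )
    kappa = vm_kappa_from_R(rbar)
    K = 1.0 + 3.0 / (8.0 * kappa) if kappa > 0 else 1.0
    denom = N - (R1 + R2)
    if denom <= 0:  # both groups perfectly concentrated
        F = math.inf if Rt < R1 + R2 - 1e-12 else 0.0
        p = 0.0 if math.isinf(F) else 1.0
        return CircTestResult("watson_williams", F, p, df=(1, N - 2))
    F = K * (N - 2) * (R1 + R2 - Rt) / denom
    F = max(F, 0.0)
    p = float(stats.f.sf(F, 1, N - 2))
    return CircTestResult("watson_williams", F, p, df=(1, N - 2))


def _u2_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sample Watson U^2 from empirical CDF differences.

    Ties are handled by processing each distinct value as a block
    (equivalent to midranks): every observation of a tied block
    contributes the CDF difference evaluated after the whole block.
    Invariant to joint rotation of both samples (the mean of the
    differences is subtracted).
    """
    n, m = x.size, y.size
    N = n + m
    values = np.concatenate([x, y])
    labels = np.concatenate([np.zeros(n), np.ones(m)])
    order = np.argsort(values, kind="mergesort")
    v = values[order]
    lab = labels[order]
    d = np.empty(N)
    cx = cy = 0
    i = 0
    while i < N:
        j = i
        while j < N and v[j] == v[i]:
            if lab[j] == 0:
                cx += 1
            else:
                cy += 1
            j += 1
        d[i:j] = cx / n - cy / m
        i = j
    dbar = d.mean()
    return float(n * m / N**2 * np.sum((d - dbar) ** 2))


def watson_u2(
    group_a,
    group_b,
    n_perm: int = 10_000,
    seed: Optional[int] = None,
    method: str = "permutation",
) -> CircTestResult:
    """Two-sample Watson U^2 test for differing circular distributions.

    The statistic comes from the standard rank/ECDF formulation and is
    invariant to rotating both samples by a common angle. The p-value is
    obtained by random permutation of group labels by default (add-one
    estimator, so p is in (0, 1]); ``method='asymptotic'`` instead uses
    the large-sample tail approximation
    ``p = 2 * exp(-2 * pi^2 * U^2)``.
    """
    a, b = _as_sample(group_a), _as_sample(group_b)
    n, m = len(a), len(b)
    if n < 8 or m < 8:
        raise ValueError("Watson U^2 needs n >= 8 per group")
    # The statistic depends on angles only through their circular order;
    # wrap to [0, 360) for a stable sort.
    x = np.mod(a.angles, 360.0)
    y = np.mod(b.angles, 360.0)
    u2 = _u2_statistic(x, y)
    if method == "asymptotic":
        p = min(1.0, 2.0 * math.exp(-2.0 * math.pi**2 * u2))
        return CircTestResult("watson_u2", u2, p, method="asymptotic")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([x, y])
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if _u2_statistic(perm[:n], perm[n:]) >= u2 - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return CircTestResult("watson_u2", u2, p, method="permutation")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order kept."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# von Mises helpers and regression
# ---------------------------------------------------------------------------

def vm_mean_resultant(kappa: float) -> float:
    """Mean resultant length A(kappa) = I1(kappa)/I0(kappa) of a von Mises."""
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if kappa == 0:
        return 0.0
    return float(special.i1e(kappa) / special.i0e(kappa))


def vm_kappa_from_R(R: float) -> float:
    """Invert A(kappa) = R: maximum-likelihood concentration for a given
    mean resultant length, via the standard piecewise approximation
    (Fisher 1993) refined by one bracketing solve."""
    if not 0.0 <= R <= 1.0:
        raise ValueError("R must lie in [0, 1]")
    if R < 1e-9:
        return 0.0
    if R > 1.0 - 1e-9:
        return math.inf
    if R < 0.53:
        k = 2 * R + R**3 + 5 * R**5 / 6
    elif R < 0.85:
        k = -0.4 + 1.39 * R + 0.43 / (1 - R)
    else:
        k = 1.0 / (R**3 - 4 * R**2 + 3 * R)
    try:
        k = float(
            optimize.brentq(
                lambda kk: vm_mean_resultant(kk) - R, max(k / 4, 1e-8), k * 4
            )
        )
    except ValueError:
        pass  # keep the series approximation
    return k


def _vm_loglik(theta_rad: np.ndarray, mu_rad: np.ndarray, kappa: float) -> float:
    n = theta_rad.size
    return float(
        kappa * np.sum(np.cos(theta_rad - mu_rad))
        - n * (math.log(2 * math.pi) + math.log(special.i0e(kappa)) + kappa)
    )


def _fit_vm_link(theta_rad: np.ndarray, X: Optional[np.ndarray]):
    """Maximize the von Mises likelihood with mean direction
    ``mu0 + 2*atan(X @ beta)``. Returns (params, loglik, converged, hess_inv)
    with params = [mu0, beta..., log kappa]. X may be None (location-only
    model, solved in closed form)."""
    n = theta_rad.size
    c, s = np.cos(theta_rad).mean(), np.sin(theta_rad).mean()
    R = math.hypot(c, s)
    mu0 = math.atan2(s, c)
    kappa0 = min(max(vm_kappa_from_R(min(R, 0.999999)), 1e-6), 1e6)
    if X is None or X.shape[1] == 0:
        ll = _vm_loglik(theta_rad, np.full(n, mu0), kappa0)
        return np.array([mu0, math.log(kappa0)]), ll, True, None

    k = X.shape[1]

    def negll(params):
        mu = params[0] + 2.0 * np.arctan(X @ params[1 : 1 + k])
        kappa = math.exp(min(params[-1], 30.0))
        return -_vm_loglik(theta_rad, mu, kappa)

    x0 = np.concatenate([[mu0], np.zeros(k), [math.log(kappa0)]])
    best = None
    for jitter in (0.0, 0.1, -0.1):
        start = x0.copy()
        start[1 : 1 + k] += jitter
        res = optimize.minimize(negll, start, method="BFGS",
                                options={"maxiter": 500, "gtol": 1e-7})
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    converged = bool(best.success)
    if not converged:
        # BFGS often stops on "precision loss" at an optimum when kappa is
        # large; a derivative-free polish decides whether we are there.
        res = optimize.minimize(negll, best.x, method="Nelder-Mead",
                                options={"maxiter": 4000, "xatol": 1e-8,
                                         "fatol": 1e-10})
        if res.fun <= best.fun + 1e-9:
            best = res if res.fun < best.fun else best
            converged = bool(res.success)
    return best.x, -best.fun, converged, getattr(best, "hess_inv", None)


def fisher_lee_regression(
    responses,
    covariates,
    covariate_names: Optional[Sequence[str]] = None,
) -> CircRegressionFit:
    """von Mises (Fisher-Lee) circular regression with LRT p-values.

    The response mean direction is ``intercept + 2*arctan(X @ beta)``;
    the concentration ``kappa`` is common to all observations. Each
    covariate's p-value is a likelihood-ratio test against the model
    refit without that covariate (chi-squared, 1 df). The intercept's
    95% CI comes from the observed-information (numerical Hessian)
    standard error.
    """
    y = _as_sample(responses)
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    if X.shape[0] != len(y):
        raise ValueError("covariates must have one row per response")
    n, k = X.shape
    if n <= k + 2:
        raise ValueError("need n > n_covariates + 2")
    # identically-zero columns carry no signal but are a legal degenerate
    # input: their coefficient is pinned at 0 with p = 1
    zero_cols = np.where(np.all(X == 0.0, axis=0))[0]
    live = np.setdiff1d(np.arange(k), zero_cols)
    if np.linalg.matrix_rank(
            np.column_stack([np.ones(n), X[:, live]])) < live.size + 1:
        raise ValueError("design matrix is rank deficient")
    names = tuple(covariate_names) if covariate_names else tuple(
        f"x{i}" for i in range(k)
    )
    if len(names) != k:
        raise ValueError("one name per covariate required")

    theta = np.deg2rad(y.angles)
    Xl = X[:, live]
    kl = live.size
    params, ll_full, converged, _ = _fit_vm_link(theta, Xl if kl else None)
    mu0 = params[0]
    beta = np.zeros(k)
    beta[live] = params[1 : 1 + kl]
    kappa = math.exp(params[-1])

    # LRT per covariate: drop one column, refit. Zero columns get p = 1.
    pvals = np.ones(k)
    for idx, j in enumerate(live):
        Xr = np.delete(Xl, idx, axis=1)
        _, ll_red, _, _ = _fit_vm_link(theta, Xr if Xr.shape[1] else None)
        lr = max(0.0, 2.0 * (ll_full - ll_red))
        pvals[j] = float(stats.chi2.sf(lr, 1))

    # intercept CI from a central-difference Hessian of the neg loglik
    ci = None
    try:
        def negll(p):
            mu = p[0] + (2.0 * np.arctan(Xl @ p[1 : 1 + kl]) if kl else 0.0)
            return -_vm_loglik(theta, mu, math.exp(min(p[-1], 30.0)))

        H = _numeric_hessian(negll, params)
        cov = np.linalg.inv(H)
        se0 = math.sqrt(max(cov[0, 0], 0.0))
        z = stats.norm.ppf(0.975)
        half = math.degrees(z * se0)
        mu0_deg = wrap_deg(math.degrees(mu0))
        ci = (mu0_deg - half, mu0_deg + half)
    except (np.linalg.LinAlgError, ValueError):
        ci = None

    return CircRegressionFit(
        intercept_deg=wrap_deg(math.degrees(mu0)),
        coefficients=beta,
        kappa_hat=kappa,
        loglik=ll_full,
        p_values=pvals,
        converged=converged,
        intercept_ci95_deg=ci,
        covariate_names=names,
    )


def _numeric_hessian(f, x, eps: float = 1e-4) -> np.ndarray:
    n = x.size
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * eps * eps)
    return H


# ---------------------------------------------------------------------------
# stimulus characterization
# ---------------------------------------------------------------------------

def michelson_contrast(i_max: float, i_min: float) -> float:
    """Michelson contrast ``(I_max - I_min) / (I_max + I_min)``.

    A point source on a perfectly dark background has contrast 1.0.
    """
    if i_min < 0 or i_max < i_min:
        raise ValueError("require i_max >= i_min >= 0")
    if i_max <= 0:
        raise ValueError("contrast undefined when both intensities are zero")
    return (i_max - i_min) / (i_max + i_min)
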