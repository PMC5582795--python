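"""Maximum-likelihood estimation of type-I functional divergence.

Model
-----
Each usable site k carries integer substitution counts (x1, x2), the minimum
changes observed within the two paralog clusters. Site rates are gamma
distributed with shape alpha and mean 1 (rate = alpha), and counts are Poisson
given the rate, with per-cluster depth factors m1, m2 (expected substitutions
per site at relative rate 1).

Under the null state F0 (no divergence) the two clusters share one rate
lambda, so (x1, x2) is bivariate negative binomial:

    f0(x1, x2) = Gamma(a + x1 + x2) / (x1! x2! Gamma(a))
                 * q1^x1 * q2^x2 * q0^a,
    q_i = m_i / (m1 + m2 + a),  q0 = a / (m1 + m2 + a).

Under the divergent state F1 the post-duplication rates decouple: each
cluster draws its own lambda, so f1 is a product of two univariate negative
binomial marginals with the same shape. A fraction theta of sites is F1; the
log-likelihood is sum_k log[(1 - theta) f0_k + theta f1_k], maximized over
(theta, alpha, m1, m2). theta is the type-I divergence coefficient; its
posterior per site, Q_I(k), flags rate-shifted residues.

The standard error of theta comes from the observed information (inverse
Hessian of the log-likelihood at the optimum, which equals the curvature of
the profile likelihood in theta), and the test of theta = 0 is a likelihood
ratio referred to a 50:50 mixture of a point mass at zero and chi-square(1),
the usual boundary-parameter null.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammaln
from scipy.stats import chi2

__all__ = [
    "Type1Params",
    "DivergenceEstimate",
    "SitePosteriorProfile",
    "type1_site_likelihoods",
    "fit_type1",
    "type1_posteriors",
]


@dataclass
class Type1Params:
    theta: float
    alpha: float
    m1: float
    m2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta < 1.0):
            raise ValueError(f"theta must be in [0, 1), got {self.theta}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.m1 <= 0 or self.m2 <= 0:
            raise ValueError("m1 and m2 must be > 0")


@dataclass
class DivergenceEstimate:
    """Fitted divergence coefficient with uncertainty and test."""

    model: str  # "type-I" | "type-II"
    theta_hat: float
    se_theta: float
    nuisance: dict
    loglik: float
    loglik_null: float
    lrt: float
    p_value: float
    n_sites: int
    boundary: bool = False
    notes: str = ""

    @property
    def ci95(self) -> tuple[float, float]:
        lo = max(0.0, self.theta_hat - 1.96 * self.se_theta)
        hi = min(1.0, self.theta_hat + 1.96 * self.se_theta)
        return lo, hi

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=float)


@dataclass
class SitePosteriorProfile:
    """Per-site posterior probability Q(k) of the divergent state."""

    model: str
    reference_position: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if np.any((self.q < 0) | (self.q > 1)):
            raise ValueError("posteriors must lie in [0, 1]")

    @property
    def r(self) -> np.ndarray:
        """Posterior ratio R(k) = Q(k) / (1 - Q(k)); inf where Q = 1."""
        with np.errstate(divide="ignore"):
            return np.where(self.q < 1.0, self.q / (1.0 - self.q), np.inf)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "reference_position": self.reference_position,
                "Q": self.q,
                "R": self.r,
            }
        )


def _nb_logpmf(x: np.ndarray, alpha: float, m: float) -> np.ndarray:
    """log NB pmf for a gamma(alpha, rate alpha) mixed Poisson with mean m."""
    x = np.asarray(x)
    return (
        gammaln(alpha + x)
        - gammaln(x + 1)
        - gammaln(alpha)
        + x * (np.log(m) - np.log(m + alpha))
        + alpha * (np.log(alpha) - np.log(m + alpha))
    )


def type1_site_likelihoods(
    x1: np.ndarray, x2: np.ndarray, params: Type1Params
) -> tuple[np.ndarray, np.ndarray]:
    """Site likelihoods (f0, f1) under shared vs decoupled cluster rates."""
    x1 = np.asarray(x1)
    x2 = np.asarray(x2)
    for x in (x1, x2):
        if np.any(x < 0) or not np.issubdtype(x.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
    a, m1, m2 = params.alpha, params.m1, params.m2
    s = m1 + m2 + a
    log_f0 = (
        gammaln(a + x1 + x2)
        - gammaln(x1 + 1)
        - gammaln(x2 + 1)
        - gammaln(a)
        + x1 * np.log(m1 / s)
        + x2 * np.log(m2 / s)
        + a * np.log(a / s)
    )
    log_f1 = _nb_logpmf(x1, a, m1) + _nb_logpmf(x2, a, m2)
    return np.exp(log_f0), np.exp(log_f1)


def _loglik(theta: float, alpha: float, m1: float, m2: float,
            x1: np.ndarray, x2: np.ndarray, w: np.ndarray) -> float:
    p = Type1Params(min(theta, 1 - 1e-12), alpha, m1, m2)
    f0, f1 = type1_site_likelihoods(x1, x2, p)
    mix = (1.0 - theta) * f0 + theta * f1
    return float(np.sum(w * np.log(np.maximum(mix, 1e-300))))


_THETA_BOX = (0.0, 0.999)
_ALPHA_BOX = (0.05, 99.0)
_M_BOX = (1e-4, 100.0)


def _aggregate(x1: np.ndarray, x2: np.ndarray):
    pairs = np.stack([x1, x2], axis=1)
    uniq, w = np.unique(pairs, axis=0, return_counts=True)
    return uniq[:, 0], uniq[:, 1], w.astype(float)


def _hessian_se_theta(nll, mle: np.ndarray, bounds) -> float:
    """SE of theta from the inverse observed information.

    The [theta, theta] element of the inverse Hessian equals the inverse
    curvature of the profile likelihood in theta (block-inversion identity),
    matching the usual theta +/- SE reporting.
    """
    k = len(mle)
    steps = np.maximum(1e-4, 1e-3 * np.abs(mle))
    for i, (lo, hi) in enumerate(bounds):
        steps[i] = min(steps[i], max((hi - lo) * 1e-4, 1e-6))
    # central differences need room on both sides; shift the center off any
    # active bound by one step (the SE there is one-sided anyway)
    mle = mle.copy()
    for i, (lo, hi) in enumerate(bounds):
        mle[i] = min(max(mle[i], lo + steps[i]), hi - steps[i])
    hess = np.zeros((k, k))
    f0 = nll(mle)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = steps[i]
            ej = np.zeros(k); ej[j] = steps[j]
            if i == j:
                hess[i, i] = (nll(mle + ei) - 2 * f0 + nll(mle - ei)) / steps[i] ** 2
            else:
                hess[i, j] = hess[j, i] = (
                    nll(mle + ei + ej) - nll(mle + ei - ej)
                    - nll(mle - ei + ej) + nll(mle - ei - ej)
                ) / (4 * steps[i] * steps[j])
    try:
        cov = np.linalg.inv(hess)
        var = cov[0, 0]
    except np.linalg.LinAlgError:
        var = np.nan
    if not np.isfinite(var) or var <= 0:
        # fall back to the marginal curvature (ignores parameter correlation)
        var = 1.0 / hess[0, 0] if hess[0, 0] > 0 else np.nan
    return float(np.sqrt(var)) if np.isfinite(var) and var > 0 else float("nan")


def _boundary_pvalue(lrt: float) -> float:
    """p-value for the 50:50 mix of chi2(0) and chi2(1) boundary null."""
    if lrt <= 0:
        return 1.0
    return float(0.5 * chi2.sf(lrt, df=1))


def fit_type1(table, min_sites: int = 50) -> tuple[DivergenceEstimate, Type1Params]:
    """Fit the type-I mixture to a SiteCountTable (or raw count arrays).

    Grid-seeds (theta, alpha), refines all four parameters with bounded
    L-BFGS-B, then fits the theta = 0 null for the likelihood-ratio test.
    """
    x1 = np.asarray(table.x1, dtype=int)
    x2 = np.asarray(table.x2, dtype=int)
    n = x1.size
    if n < min_sites:
        warnings.warn(f"only {n} usable sites; estimates may be unstable")
    ux1, ux2, w = _aggregate(x1, x2)

    m1_0 = max(float(np.mean(x1)), 1e-3)
    m2_0 = max(float(np.mean(x2)), 1e-3)

    def nll4(v: np.ndarray) -> float:
        return -_loglik(v[0], v[1], v[2], v[3], ux1, ux2, w)

    bounds4 = [_THETA_BOX, _ALPHA_BOX, _M_BOX, _M_BOX]
    seeds = []
    for th in (0.05, 0.2, 0.4, 0.6, 0.8):
        for al in (0.3, 0.7, 1.5, 4.0):
            seeds.append(np.array([th, al, m1_0, m2_0]))
    seeds.sort(key=nll4)
    best = None
    for s in seeds[:3]:
        res = optimize.minimize(nll4, s, method="L-BFGS-B", bounds=bounds4,
                                options={"maxiter": 500, "ftol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("type-I optimizer failed to converge")
    theta_hat, alpha_hat, m1_hat, m2_hat = best.x
    loglik = -best.fun

    def nll3(v: np.ndarray) -> float:
        return -_loglik(0.0, v[0], v[1], v[2], ux1, ux2, w)

    res0 = optimize.minimize(
        nll3, np.array([alpha_hat, m1_hat, m2_hat]), method="L-BFGS-B",
        bounds=[_ALPHA_BOX, _M_BOX, _M_BOX], options={"maxiter": 500, "ftol": 1e-12},
    )
    loglik_null = -res0.fun
    lrt = max(0.0, 2.0 * (loglik - loglik_null))
    p = _boundary_pvalue(lrt)

    boundary = bool(theta_hat <= 1e-6)
    se = _hessian_se_theta(nll4, best.x, bounds4)
    notes = ""
    if boundary:
        notes = "theta at boundary 0; SE is one-sided"
        theta_hat = 0.0

    params = Type1Params(float(theta_hat), float(alpha_hat), float(m1_hat), float(m2_hat))
    est = DivergenceEstimate(
        model="type-I",
        theta_hat=float(theta_hat),
        se_theta=se,
        nuisance={"alpha": float(alpha_hat), "m1": float(m1_hat), "m2": float(m2_hat)},
        loglik=loglik,
        loglik_null=loglik_null,
        lrt=lrt,
        p_value=p,
        n_sites=int(n),
        boundary=boundary,
        notes=notes,
    )
    return est, params


def type1_posteriors(table, params: Type1Params) -> SitePosteriorProfile:
    """Posterior probability Q_I(k) that each site is rate-shifted (F1)."""
    x1 = np.asarray(table.x1, dtype=int)
    x2 = np.asarray(table.x2, dtype=int)
    f0, f1 = type1_site_likelihoods(x1, x2, params)
    th = params.theta
    denom = (1.0 - th) * f0 + th * f1
    q = np.where(denom > 0, th * f1 / np.maximum(denom, 1e-300), 0.0)
    refpos = getattr(table, "data", None)
    if refpos is not None and "reference_position" in table.data:
        positions = table.data["reference_position"].to_numpy()
    else:
        positions = np.arange(1, x1.size + 1)
    return SitePosteriorProfile("type-I", positions, np.clip(q, 0.0, 1.0))
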