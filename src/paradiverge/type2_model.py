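"""Maximum-likelihood estimation of type-II functional divergence.

Type-II divergence is a post-duplication radical shift in a site's
physicochemical property, followed by strong conservation within each
duplicate cluster (the classic picture: a residue hydrophobic across one
ortholog cluster, hydrophilic across the other). The observable per site is

    (c, x1, x2)

where c classifies the change between the two cluster-root residues —
N (identical), C (conserved: same physicochemical group) or R (radical:
different group) — and x1, x2 are the within-cluster substitution counts from
the parsimony stage.

Amino acids fall into four groups: positively charged {K, R, H}, negatively
charged {D, E}, hydrophilic {S, T, N, Q, C, G, P} and hydrophobic
{A, I, L, M, F, W, V, Y}. A replacement crossing groups is radical, within a
group conserved. Of the 190 unordered heterotypic pairs, 137 are radical, so
a property-blind change is radical with probability pi_R = 137/190.

Likelihood. Site rate lambda ~ gamma(alpha, rate alpha), integrated by a
K-category equal-probability discrete gamma. Under F0 (weight 1 - theta) the
early, post-duplication branch changes the residue with probability
1 - exp(-lambda * d_e); a change is radical with probability pi_R. Late-phase
counts are Poisson(lambda * m_i). Under F1 (weight theta, the type-II state)
the early change is radical with probability one and the late phase is
conserved: Poisson(lambda * eps * m_i) with conservation factor eps << 1.
theta (= theta_II) is estimated by maximizing the mixture log-likelihood over
(theta, alpha, m1, m2, d_e), with pi_R fixed at its scheme value and eps
fixed (default 0.1, configurable).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import gammainc, gammaln
from scipy.stats import gamma as gamma_dist

from .type1_model import (
    DivergenceEstimate,
    SitePosteriorProfile,
    _boundary_pvalue,
    _hessian_se_theta,
)

__all__ = [
    "AAGroupScheme",
    "DEFAULT_SCHEME",
    "EarlyChangeProfile",
    "Type2Params",
    "classify_change",
    "scheme_radical_fraction",
    "early_profile",
    "discrete_gamma_rates",
    "type2_site_likelihoods",
    "fit_type2",
    "type2_posteriors",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class AAGroupScheme:
    """Partition of the 20 amino acids into physicochemical groups."""

    groups: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        all_letters = [l for g in self.groups.values() for l in g]
        if sorted(all_letters) != sorted(AA20):
            raise ValueError("groups must partition the 20 amino-acid letters")

    def group_of(self, aa: str) -> str:
        aa = aa.upper()
        for name, members in self.groups.items():
            if aa in members:
                return name
        raise KeyError(f"{aa!r} is not a standard amino-acid letter")


DEFAULT_SCHEME = AAGroupScheme(
    {
        "positive": frozenset("KRH"),
        "negative": frozenset("DE"),
        "hydrophilic": frozenset("STNQCGP"),
        "hydrophobic": frozenset("AILMFWVY"),
    }
)


def classify_change(a: str, b: str, scheme: AAGroupScheme = DEFAULT_SCHEME) -> str:
    """Classify the replacement a -> b: 'identical', 'conserved' or 'radical'."""
    ga, gb = scheme.group_of(a), scheme.group_of(b)
    if a.upper() == b.upper():
        return "identical"
    return "conserved" if ga == gb else "radical"


def scheme_radical_fraction(scheme: AAGroupScheme = DEFAULT_SCHEME) -> float:
    """Fraction of the 190 unordered heterotypic pairs that are radical."""
    pairs = list(itertools.combinations(AA20, 2))
    radical = sum(1 for a, b in pairs if classify_change(a, b, scheme) == "radical")
    return radical / len(pairs)


@dataclass
class EarlyChangeProfile:
    """Per-site early-phase change class with ancestral provenance."""

    classes: np.ndarray  # '<U1': 'N' | 'C' | 'R'
    a1: np.ndarray
    a2: np.ndarray
    tie: np.ndarray  # True where either cluster root state was ambiguous

    def __post_init__(self) -> None:
        bad = set(np.unique(self.classes)) - {"N", "C", "R"}
        if bad:
            raise ValueError(f"invalid class labels: {sorted(bad)}")

    @property
    def n_sites(self) -> int:
        return self.classes.size

    def counts(self) -> dict[str, int]:
        return {c: int((self.classes == c).sum()) for c in "NCR"}


def early_profile(table, scheme: AAGroupScheme = DEFAULT_SCHEME) -> EarlyChangeProfile:
    """Classify the inter-cluster ancestral change at every usable site."""
    a1 = np.asarray(table.data["a1"], dtype="<U1")
    a2 = np.asarray(table.data["a2"], dtype="<U1")
    tie = table.data["tie1"].to_numpy() | table.data["tie2"].to_numpy()
    code = {"identical": "N", "conserved": "C", "radical": "R"}
    classes = np.array(
        [code[classify_change(x, y, scheme)] for x, y in zip(a1, a2)],
        dtype="<U1",
    )
    return EarlyChangeProfile(classes, a1, a2, tie)


@dataclass
class Type2Params:
    theta: float
    alpha: float
    m1: float
    m2: float
    d_e: float
    pi_r: float = 137.0 / 190.0
    epsilon: float = 0.1
    n_categories: int = 8

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta < 1.0):
            raise ValueError(f"theta must be in [0, 1), got {self.theta}")
        if min(self.alpha, self.m1, self.m2, self.d_e) <= 0:
            raise ValueError("alpha, m1, m2 and d_e must be > 0")
        if not (0.0 < self.pi_r < 1.0):
            raise ValueError("pi_r must be in (0, 1)")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


def discrete_gamma_rates(alpha: float, k: int = 8) -> np.ndarray:
    """Means of K equal-probability categories of gamma(alpha, rate alpha).

    Category means preserve the overall mean of 1 exactly:
    mean_j = K * [P(alpha+1, alpha*b_{j+1}) - P(alpha+1, alpha*b_j)] with P
    the regularized lower incomplete gamma and b_j the quantile boundaries.
    """
    if alpha <= 0 or k < 1:
        raise ValueError("alpha > 0 and k >= 1 required")
    edges = gamma_dist.ppf(np.arange(k + 1) / k, a=alpha, scale=1.0 / alpha)
    edges[0], edges[-1] = 0.0, np.inf
    upper = gammainc(alpha + 1, alpha * edges[1:])
    lower = gammainc(alpha + 1, alpha * edges[:-1])
    return k * (upper - lower)


_CLASS_CODE = {"N": 0, "C": 1, "R": 2}


def _poisson_logpmf(x: np.ndarray, mu: np.ndarray) -> np.ndarray:
    mu = np.maximum(mu, 1e-300)
    return x * np.log(mu) - mu - gammaln(x + 1)


def type2_site_likelihoods(
    classes: np.ndarray, x1: np.ndarray, x2: np.ndarray, params: Type2Params
) -> tuple[np.ndarray, np.ndarray]:
    """Site likelihoods (f0, f1) over the joint (class, x1, x2) outcome."""
    code = np.array([_CLASS_CODE.get(c, -1) for c in classes])
    if np.any(code < 0):
        raise ValueError("classes must be drawn from {'N', 'C', 'R'}")
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    lam = discrete_gamma_rates(params.alpha, params.n_categories)  # (K,)

    # class probability given rate category, F0
    p_change = -np.expm1(-lam * params.d_e)  # (K,)
    class_p = np.stack(
        [1.0 - p_change, p_change * (1 - params.pi_r), p_change * params.pi_r]
    )  # (3, K)
    log_class0 = np.log(np.maximum(class_p[code], 1e-300))  # (n, K)

    late0 = (
        _poisson_logpmf(x1[:, None], lam[None, :] * params.m1)
        + _poisson_logpmf(x2[:, None], lam[None, :] * params.m2)
    )  # (n, K)
    f0 = np.mean(np.exp(log_class0 + late0), axis=1)

    late1 = (
        _poisson_logpmf(x1[:, None], lam[None, :] * params.epsilon * params.m1)
        + _poisson_logpmf(x2[:, None], lam[None, :] * params.epsilon * params.m2)
    )
    f1 = np.where(code == 2, np.mean(np.exp(late1), axis=1), 0.0)
    return f0, f1


def _loglik2(v: np.ndarray, classes, x1, x2, w, pi_r, epsilon, k) -> float:
    theta, alpha, m1, m2, d_e = v
    p = Type2Params(min(theta, 1 - 1e-12), alpha, m1, m2, d_e,
                    pi_r=pi_r, epsilon=epsilon, n_categories=k)
    f0, f1 = type2_site_likelihoods(classes, x1, x2, p)
    mix = (1.0 - theta) * f0 + theta * f1
    return float(np.sum(w * np.log(np.maximum(mix, 1e-300))))


_BOUNDS2 = [(0.0, 0.999), (0.05, 99.0), (1e-4, 100.0), (1e-4, 100.0), (1e-3, 20.0)]


def fit_type2(
    profile: EarlyChangeProfile,
    table,
    pi_r: float | None = None,
    epsilon: float = 0.1,
    n_categories: int = 8,
    scheme: AAGroupScheme = DEFAULT_SCHEME,
    min_sites: int = 50,
) -> tuple[DivergenceEstimate, Type2Params]:
    """Fit the type-II mixture to the early-change profile and count table.

    pi_R defaults to the scheme's neutral radical fraction (137/190 for the
    four-group scheme) rather than being estimated; eps is the fixed late-phase
    conservation factor of the divergent state.
    """
    if pi_r is None:
        pi_r = scheme_radical_fraction(scheme)
    classes = profile.classes
    x1 = np.asarray(table.x1, dtype=int)
    x2 = np.asarray(table.x2, dtype=int)
    n = classes.size
    if n != x1.size:
        raise ValueError("profile and count table cover different site sets")
    if n < min_sites:
        warnings.warn(f"only {n} usable sites; estimates may be unstable")

    n_r = int((classes == "R").sum())
    if n_r == 0:
        # no radical early change anywhere: the divergent state has zero support
        est, params = _fit_null_only(classes, x1, x2, pi_r, epsilon, n_categories)
        est.notes = "no radical sites: theta fixed at 0 (no identifiable signal)"
        return est, params

    # aggregate identical (class, x1, x2) triples
    trip = np.stack([np.vectorize(_CLASS_CODE.get)(classes), x1, x2], axis=1)
    uniq, w = np.unique(trip, axis=0, return_counts=True)
    uc = np.array(["NCR"[i] for i in uniq[:, 0]], dtype="<U1")
    ux1, ux2, w = uniq[:, 1], uniq[:, 2], w.astype(float)

    frac_n = max(float((classes == "N").mean()), 1e-3)
    d_e0 = max(-np.log(frac_n), 1e-2)
    m1_0 = max(float(np.mean(x1)), 1e-3)
    m2_0 = max(float(np.mean(x2)), 1e-3)

    def nll(v: np.ndarray) -> float:
        return -_loglik2(v, uc, ux1, ux2, w, pi_r, epsilon, n_categories)

    seeds = []
    for th in (0.05, 0.15, 0.3, 0.5, 0.75):
        for al in (0.3, 0.7, 1.5, 4.0):
            seeds.append(np.array([th, al, m1_0, m2_0, d_e0]))
    seeds.sort(key=nll)
    best = None
    for s in seeds[:3]:
        res = optimize.minimize(nll, s, method="L-BFGS-B", bounds=_BOUNDS2,
                                options={"maxiter": 500, "ftol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("type-II optimizer failed to converge")
    theta_hat, alpha_hat, m1_hat, m2_hat, de_hat = best.x
    loglik = -best.fun

    def nll_null(v: np.ndarray) -> float:
        return -_loglik2(np.concatenate([[0.0], v]), uc, ux1, ux2, w,
                         pi_r, epsilon, n_categories)

    res0 = optimize.minimize(
        nll_null, best.x[1:], method="L-BFGS-B", bounds=_BOUNDS2[1:],
        options={"maxiter": 500, "ftol": 1e-12},
    )
    loglik_null = -res0.fun
    lrt = max(0.0, 2.0 * (loglik - loglik_null))
    p = _boundary_pvalue(lrt)

    boundary = bool(theta_hat <= 1e-6)
    se = _hessian_se_theta(nll, best.x, _BOUNDS2)
    notes = f"pi_R fixed at {pi_r:.4f}; epsilon fixed at {epsilon}"
    if boundary:
        notes += "; theta at boundary 0, SE one-sided"
        theta_hat = 0.0

    params = Type2Params(
        float(theta_hat), float(alpha_hat), float(m1_hat), float(m2_hat),
        float(de_hat), pi_r=pi_r, epsilon=epsilon, n_categories=n_categories,
    )
    est = DivergenceEstimate(
        model="type-II",
        theta_hat=float(theta_hat),
        se_theta=se,
        nuisance={
            "alpha": float(alpha_hat), "m1": float(m1_hat),
            "m2": float(m2_hat), "d_e": float(de_hat),
            "pi_r": pi_r, "epsilon": epsilon,
        },
        loglik=loglik,
        loglik_null=loglik_null,
        lrt=lrt,
        p_value=p,
        n_sites=int(n),
        boundary=boundary,
        notes=notes,
    )
    return est, params


def _fit_null_only(classes, x1, x2, pi_r, epsilon, k):
    frac_n = max(float((classes == "N").mean()), 1e-3)
    d_e0 = max(-np.log(frac_n), 1e-2)
    start = np.array([1.0, max(x1.mean(), 1e-3), max(x2.mean(), 1e-3), d_e0])

    def nll_null(v):
        return -_loglik2(np.concatenate([[0.0], v]), classes, x1, x2,
                         np.ones(classes.size), pi_r, epsilon, k)

    res = optimize.minimize(nll_null, start, method="L-BFGS-B",
                            bounds=_BOUNDS2[1:], options={"maxiter": 500})
    alpha_hat, m1_hat, m2_hat, de_hat = res.x
    params = Type2Params(0.0, float(alpha_hat), float(m1_hat), float(m2_hat),
                         float(de_hat), pi_r=pi_r, epsilon=epsilon, n_categories=k)
    est = DivergenceEstimate(
        model="type-II", theta_hat=0.0, se_theta=0.0,
        nuisance={"alpha": float(alpha_hat), "m1": float(m1_hat),
                  "m2": float(m2_hat), "d_e": float(de_hat),
                  "pi_r": pi_r, "epsilon": epsilon},
        loglik=-res.fun, loglik_null=-res.fun, lrt=0.0, p_value=1.0,
        n_sites=int(classes.size), boundary=True,
    )
    return est, params


def type2_posteriors(
    profile: EarlyChangeProfile, table, params: Type2Params
) -> SitePosteriorProfile:
    """Posterior probability Q_II(k) that each site is type-II divergent."""
    x1 = np.asarray(table.x1, dtype=int)
    x2 = np.asarray(table.x2, dtype=int)
    f0, f1 = type2_site_likelihoods(profile.classes, x1, x2, params)
    th = params.theta
    denom = (1.0 - th) * f0 + th * f1
    q = np.where(denom > 0, th * f1 / np.maximum(denom, 1e-300), 0.0)
    if "reference_position" in table.data:
        positions = table.data["reference_position"].to_numpy()
    else:
        positions = np.arange(1, x1.size + 1)
    return SitePosteriorProfile("type-II", positions, np.clip(q, 0.0, 1.0))
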