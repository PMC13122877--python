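"""REML variance components and BLUP breeding values for the animal model.

The individual-tree model is ``y = X b + W a + e`` with ``a ~ N(0, s2a K)``
and ``e ~ N(0, s2e I)``, where K is any additive relationship matrix: the
pedigree A (ABLUP) or the genomic G (GBLUP). The engine eigendecomposes K
over the phenotyped individuals, which turns the restricted likelihood into
a cheap function of the variance components: univariate REML reduces to a
one-dimensional profile search in the variance ratio, and the bivariate
model (2x2 genetic and residual covariances with unstructured correlations)
to a six-parameter bounded derivative-free maximization over 2x2 blocks.

Predictions for unphenotyped individuals (the cross-validation mechanism)
and prediction-error variances come from the mixed-model equations at the
REML estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .containers import RelationshipMatrix

__all__ = [
    "ModelFit",
    "BivariateFit",
    "reml_univariate",
    "heritability_se",
    "reml_bivariate",
    "phenotypic_correlation",
    "lrt_correlation",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class ModelFit:
    """Univariate REML fit: variance components, h2 and (G)EBVs."""

    kind: str  # "GBLUP" or "ABLUP" by relationship-matrix kind
    sigma2_a: float
    sigma2_e: float
    h2: float
    h2_se: float
    beta: float
    ebv: pd.Series
    se_ebv: pd.Series
    loglik: float
    n_obs: int
    converged: bool = True
    _rotated: tuple | None = field(default=None, repr=False)


@dataclass
class BivariateFit:
    """Bivariate REML fit with unstructured genetic/residual correlations."""

    kind: str
    Va: np.ndarray
    Ve: np.ndarray
    r_a: float
    r_e: float
    r_p: float
    loglik: float
    n_obs: int
    converged: bool = True
    r_a_se: float = float("nan")


# ---------------------------------------------------------------------------
# univariate
# ---------------------------------------------------------------------------

def _rotate(y_obs: np.ndarray, K_obs: np.ndarray):
    d, U = np.linalg.eigh(K_obs)
    if d.min() <= 1e-10:
        raise ValueError(
            "relationship matrix is not positive definite over the phenotyped "
            "individuals; blend it (tune_g) before fitting"
        )
    return d, U.T @ y_obs, U.T @ np.ones(len(y_obs)), U


def _reml_ll_components(
    sa2: float, se2: float, d: np.ndarray, yt: np.ndarray, xt: np.ndarray
) -> float:
    """Restricted log-likelihood at variance components (sa2, se2)."""
    v = sa2 * d + se2
    if np.any(v <= 0):
        return -np.inf
    w = 1.0 / v
    xwx = float(np.sum(xt**2 * w))
    beta = float(np.sum(xt * w * yt)) / xwx
    r = yt - xt * beta
    quad = float(np.sum(r**2 * w))
    n_p = len(yt) - 1
    return -0.5 * (n_p * _LOG2PI + float(np.sum(np.log(v))) + np.log(xwx) + quad)


def _profile_ll(theta: float, d, yt, xt) -> tuple[float, float, float]:
    """Profile REML over the ratio lam = sa2/se2; returns (ll, sa2, se2)."""
    lam = np.exp(theta)
    v = lam * d + 1.0
    w = 1.0 / v
    xwx = float(np.sum(xt**2 * w))
    beta = float(np.sum(xt * w * yt)) / xwx
    r = yt - xt * beta
    n_p = len(yt) - 1
    se2 = float(np.sum(r**2 * w)) / n_p
    ll = -0.5 * (
        n_p * _LOG2PI
        + n_p * np.log(se2)
        + float(np.sum(np.log(v)))
        + np.log(xwx)
        + n_p
    )
    return ll, lam * se2, se2


def reml_univariate(
    y: pd.Series,
    K: RelationshipMatrix,
    min_obs: int = 30,
    theta_bounds: tuple[float, float] = (-12.0, 12.0),
) -> ModelFit:
    """Fit the intercept-only animal model by REML and predict all EBVs.

    ``y`` is indexed by individual id; NaN entries are treated as
    unphenotyped and receive predictions through K (the CV masking
    mechanism). Deterministic given inputs.
    """
    y = y.reindex(K.ids)
    obs = np.isfinite(y.to_numpy(dtype=float))
    y_obs = y.to_numpy(dtype=float)[obs]
    n_obs = int(obs.sum())
    if n_obs < min_obs:
        raise ValueError(f"need at least {min_obs} phenotyped individuals, got {n_obs}")
    if np.var(y_obs) == 0.0:
        raise ValueError("zero phenotypic variance")

    K_obs = K.values[np.ix_(obs, obs)]
    d, yt, xt, _ = _rotate(y_obs, K_obs)

    # coarse grid then bounded refinement in the log variance ratio
    grid = np.linspace(theta_bounds[0], theta_bounds[1], 61)
    lls = np.array([_profile_ll(t, d, yt, xt)[0] for t in grid])
    t0 = grid[np.argmax(lls)]
    lo = max(theta_bounds[0], t0 - 0.5)
    hi = min(theta_bounds[1], t0 + 0.5)
    res = optimize.minimize_scalar(
        lambda t: -_profile_ll(t, d, yt, xt)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    theta = float(res.x)
    ll, sa2, se2 = _profile_ll(theta, d, yt, xt)

    h2 = sa2 / (sa2 + se2)
    h2_se = _h2_se_numeric(sa2, se2, d, yt, xt)

    beta, ebv, se_ebv = _mme_solve(y.to_numpy(dtype=float), obs, K, sa2, se2)
    kind = "GBLUP" if K.kind.startswith("G") else "ABLUP"
    return ModelFit(
        kind=kind,
        sigma2_a=sa2,
        sigma2_e=se2,
        h2=h2,
        h2_se=h2_se,
        beta=beta,
        ebv=pd.Series(ebv, index=K.ids, name="ebv"),
        se_ebv=pd.Series(se_ebv, index=K.ids, name="se_ebv"),
        loglik=ll,
        n_obs=n_obs,
        converged=bool(res.success),
        _rotated=(d, yt, xt),
    )


def _mme_solve(
    y_all: np.ndarray,
    obs: np.ndarray,
    K: RelationshipMatrix,
    sa2: float,
    se2: float,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mixed-model equations: intercept, EBVs and prediction-error SEs."""
    N = K.n
    try:
        cf = linalg.cho_factor(K.values)
        Kinv = linalg.cho_solve(cf, np.eye(N))
    except linalg.LinAlgError as exc:
        raise ValueError(
            "relationship matrix not invertible; blend it (tune_g) first"
        ) from exc
    lam = se2 / max(sa2, 1e-12 * (sa2 + se2))
    n_obs = int(obs.sum())
    C = np.zeros((N + 1, N + 1))
    C[0, 0] = n_obs
    zt1 = obs.astype(float)
    C[0, 1:] = zt1
    C[1:, 0] = zt1
    C[1:, 1:] = np.diag(zt1) + lam * Kinv
    rhs = np.zeros(N + 1)
    rhs[0] = np.nansum(np.where(obs, y_all, 0.0))
    rhs[1:] = np.where(obs, np.nan_to_num(y_all), 0.0)
    Cinv = np.linalg.inv(C)
    sol = Cinv @ rhs
    beta = float(sol[0])
    ebv = sol[1:]
    pev = se2 * np.diag(Cinv)[1:]
    return beta, ebv, np.sqrt(np.clip(pev, 0.0, None))


def _h2_se_numeric(sa2, se2, d, yt, xt) -> float:
    """Delta-method SE of h2 from the numerical REML Hessian."""
    try:
        H = _hessian_ll(sa2, se2, d, yt, xt)
        cov = np.linalg.inv(-H)
        tot = sa2 + se2
        grad = np.array([se2, -sa2]) / tot**2
        var_h2 = float(grad @ cov @ grad)
        if var_h2 < 0:
            raise np.linalg.LinAlgError
        return float(np.sqrt(var_h2))
    except np.linalg.LinAlgError:
        warnings.warn("singular REML Hessian; h2 SE undefined", stacklevel=2)
        return float("nan")


def _hessian_ll(sa2, se2, d, yt, xt) -> np.ndarray:
    f = lambda p: _reml_ll_components(p[0], p[1], d, yt, xt)
    p0 = np.array([sa2, se2])
    h = np.maximum(1e-5 * np.abs(p0), 1e-10)
    H = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            pp = p0.copy(); pp[i] += h[i]; pp[j] += h[j]
            pm = p0.copy(); pm[i] += h[i]; pm[j] -= h[j]
            mp = p0.copy(); mp[i] -= h[i]; mp[j] += h[j]
            mm = p0.copy(); mm[i] -= h[i]; mm[j] -= h[j]
            H[i, j] = (f(pp) - f(pm) - f(mp) + f(mm)) / (4.0 * h[i] * h[j])
    return 0.5 * (H + H.T)


def heritability_se(fit: ModelFit) -> float:
    """Delta-method standard error of h2 (inverse numerical Hessian)."""
    if fit._rotated is None:
        raise ValueError("fit does not carry rotated data")
    d, yt, xt = fit._rotated
    return _h2_se_numeric(fit.sigma2_a, fit.sigma2_e, d, yt, xt)


# ---------------------------------------------------------------------------
# bivariate
# ---------------------------------------------------------------------------

_R_BOUND = 0.999


def _bivariate_negll(
    params: np.ndarray,
    d: np.ndarray,
    yt: np.ndarray,  # (n, 2) rotated phenotypes
    xt: np.ndarray,
    fix_ra: float | None,
    fix_re: float | None,
) -> float:
    """Negative restricted log-likelihood of the 2-trait model.

    Parameter vector: [log sa1, log sa2, z_ra, log se1, log se2, z_re] with
    correlations mapped through tanh; fixed correlations drop out of the
    vector.
    """
    k = 0
    sa1 = np.exp(params[k]); k += 1
    sa2 = np.exp(params[k]); k += 1
    if fix_ra is None:
        ra = _R_BOUND * np.tanh(params[k]); k += 1
    else:
        ra = fix_ra
    se1 = np.exp(params[k]); k += 1
    se2 = np.exp(params[k]); k += 1
    if fix_re is None:
        re = _R_BOUND * np.tanh(params[k]); k += 1
    else:
        re = fix_re

    ca = ra * np.sqrt(sa1 * sa2)
    ce = re * np.sqrt(se1 * se2)
    # per-eigenvalue 2x2 covariance blocks V_k = d_k * Va + Ve
    v11 = sa1 * d + se1
    v22 = sa2 * d + se2
    v12 = ca * d + ce
    det = v11 * v22 - v12**2
    if np.any(det <= 0) or np.any(v11 <= 0) or np.any(v22 <= 0):
        return 1e30
    i11 = v22 / det
    i22 = v11 / det
    i12 = -v12 / det

    y1, y2 = yt[:, 0], yt[:, 1]
    x2 = xt**2
    M = np.array(
        [
            [np.sum(x2 * i11), np.sum(x2 * i12)],
            [np.sum(x2 * i12), np.sum(x2 * i22)],
        ]
    )
    b = np.array(
        [
            np.sum(xt * (i11 * y1 + i12 * y2)),
            np.sum(xt * (i12 * y1 + i22 * y2)),
        ]
    )
    q = float(np.sum(i11 * y1**2 + 2.0 * i12 * y1 * y2 + i22 * y2**2))
    sign, logdet_m = np.linalg.slogdet(M)
    if sign <= 0:
        return 1e30
    beta = np.linalg.solve(M, b)
    quad = q - float(b @ beta)
    n_p = 2 * len(d) - 2
    ll = -0.5 * (
        n_p * _LOG2PI + float(np.sum(np.log(det))) + logdet_m + quad
    )
    return -ll


def reml_bivariate(
    y1: pd.Series,
    y2: pd.Series,
    K: RelationshipMatrix,
    fix_ra: float | None = None,
    fix_re: float | None = None,
    maxiter: int = 4000,
) -> BivariateFit:
    """Bivariate REML with per-trait intercepts and correlations in (-1, 1).

    Individuals with both traits observed enter the likelihood. ``fix_ra`` /
    ``fix_re`` pin the genetic / residual correlation (used by the
    likelihood-ratio tests of the correlations).
    """
    y1 = y1.reindex(K.ids)
    y2 = y2.reindex(K.ids)
    both = np.isfinite(y1.to_numpy(float)) & np.isfinite(y2.to_numpy(float))
    if both.sum() < 30:
        raise ValueError("need at least 30 individuals with both traits observed")
    Y = np.column_stack([y1.to_numpy(float)[both], y2.to_numpy(float)[both]])
    K_obs = K.values[np.ix_(both, both)]
    d, U = np.linalg.eigh(K_obs)
    if d.min() <= 1e-10:
        raise ValueError("relationship matrix not positive definite; tune_g first")
    yt = U.T @ Y
    xt = U.T @ np.ones(both.sum())

    # warm start from the univariate fits
    starts = []
    for j in range(2):
        dd, yy, xx, _ = _rotate(Y[:, j], K_obs)
        grid = np.linspace(-8, 8, 33)
        lls = [_profile_ll(t, dd, yy, xx)[0] for t in grid]
        _, sa, se = _profile_ll(grid[int(np.argmax(lls))], dd, yy, xx)
        starts.append((max(sa, 1e-8), max(se, 1e-8)))
    # start correlations at (a damped) sample correlation of the phenotypes
    r0 = float(np.clip(np.corrcoef(Y[:, 0], Y[:, 1])[0, 1], -0.95, 0.95))
    z0 = np.arctanh(r0 / _R_BOUND)
    p0 = [np.log(starts[0][0]), np.log(starts[1][0])]
    if fix_ra is None:
        p0.append(z0)
    p0 += [np.log(starts[0][1]), np.log(starts[1][1])]
    if fix_re is None:
        p0.append(z0)
    p0 = np.array(p0)

    opts = {"maxiter": maxiter, "maxfev": maxiter, "xatol": 1e-8, "fatol": 1e-10}
    res = optimize.minimize(
        _bivariate_negll, p0, args=(d, yt, xt, fix_ra, fix_re),
        method="Nelder-Mead", options=opts,
    )
    # restart from the optimum until the restricted likelihood stabilizes
    for _ in range(3):
        res2 = optimize.minimize(
            _bivariate_negll, res.x, args=(d, yt, xt, fix_ra, fix_re),
            method="Nelder-Mead", options=opts,
        )
        improved = res.fun - res2.fun
        res = res2
        if improved < 1e-8:
            break
    p = res.x
    k = 0
    sa1 = float(np.exp(p[k])); k += 1
    sa2 = float(np.exp(p[k])); k += 1
    if fix_ra is None:
        ra = float(_R_BOUND * np.tanh(p[k])); k += 1
    else:
        ra = float(fix_ra)
    se1 = float(np.exp(p[k])); k += 1
    se2 = float(np.exp(p[k])); k += 1
    re = float(_R_BOUND * np.tanh(p[k])) if fix_re is None else float(fix_re)

    Va = np.array(
        [[sa1, ra * np.sqrt(sa1 * sa2)], [ra * np.sqrt(sa1 * sa2), sa2]]
    )
    Ve = np.array(
        [[se1, re * np.sqrt(se1 * se2)], [re * np.sqrt(se1 * se2), se2]]
    )
    rp = phenotypic_correlation_components(ra, re, sa1, sa2, se1, se2)
    ra_se = _ra_se_numeric(p, d, yt, xt, fix_ra, fix_re)
    kind = "GBLUP" if K.kind.startswith("G") else "ABLUP"
    if not res.success:
        warnings.warn(
            f"bivariate REML did not fully converge (message: {res.message})",
            stacklevel=2,
        )
    return BivariateFit(
        kind=kind,
        Va=Va,
        Ve=Ve,
        r_a=ra,
        r_e=re,
        r_p=rp,
        loglik=-float(res.fun),
        n_obs=int(both.sum()),
        converged=bool(res.success),
        r_a_se=ra_se,
    )


def _ra_se_numeric(p, d, yt, xt, fix_ra, fix_re) -> float:
    """Delta-method SE of r_a from the numerical Hessian in the working scale."""
    if fix_ra is not None:
        return float("nan")
    try:
        npar = len(p)
        h = np.maximum(1e-4 * np.abs(p), 1e-6)
        f = lambda q: -_bivariate_negll(q, d, yt, xt, fix_ra, fix_re)
        H = np.zeros((npar, npar))
        for i in range(npar):
            for j in range(i, npar):
                pp = p.copy(); pp[i] += h[i]; pp[j] += h[j]
                pm = p.copy(); pm[i] += h[i]; pm[j] -= h[j]
                mp = p.copy(); mp[i] -= h[i]; mp[j] += h[j]
                mm = p.copy(); mm[i] -= h[i]; mm[j] -= h[j]
                H[i, j] = H[j, i] = (f(pp) - f(pm) - f(mp) + f(mm)) / (
                    4.0 * h[i] * h[j]
                )
        cov = np.linalg.inv(-H)
        z_idx = 2  # position of z_ra in the full vector
        var_z = cov[z_idx, z_idx]
        if var_z < 0:
            return float("nan")
        # d ra / d z = bound * sech^2(z)
        deriv = _R_BOUND * (1.0 - np.tanh(p[z_idx]) ** 2)
        return float(np.sqrt(var_z) * abs(deriv))
    except np.linalg.LinAlgError:
        return float("nan")


def phenotypic_correlation_components(
    r_a: float, r_e: float, s2a_i: float, s2a_j: float, s2e_i: float, s2e_j: float
) -> float:
    """Phenotypic correlation from genetic/residual components.

    r_p = (r_a sqrt(s2a_i s2a_j) + r_e sqrt(s2e_i s2e_j))
          / sqrt((s2a_i + s2e_i)(s2a_j + s2e_j)).
    """
    for v in (s2a_i, s2a_j, s2e_i, s2e_j):
        if v <= 0:
            raise ValueError("variance components must be positive")
    num = r_a * np.sqrt(s2a_i * s2a_j) + r_e * np.sqrt(s2e_i * s2e_j)
    den = np.sqrt((s2a_i + s2e_i) * (s2a_j + s2e_j))
    return float(num / den)


def phenotypic_correlation(fit: BivariateFit) -> float:
    """Phenotypic correlation implied by a bivariate fit's components."""
    return phenotypic_correlation_components(
        fit.r_a, fit.r_e, fit.Va[0, 0], fit.Va[1, 1], fit.Ve[0, 0], fit.Ve[1, 1]
    )


def lrt_correlation(
    full: BivariateFit, constrained: BivariateFit, df: int, tol: float = 1e-4
) -> float:
    """Likelihood-ratio p-value for nested correlation hypotheses.

    df = 1 tests r_a = 0; df = 2 tests r_a = r_e = 0. The statistic
    2 (lL_full - lL_constrained) is floored at zero; a constrained
    likelihood exceeding the full one beyond tolerance signals an optimizer
    failure and raises.
    """
    if df not in (1, 2):
        raise ValueError("df must be 1 or 2")
    delta = full.loglik - constrained.loglik
    if delta < -tol:
        raise ValueError(
            f"constrained log-likelihood exceeds full by {-delta:.3g}; "
            "refit (optimizer failure)"
        )
    stat = max(0.0, 2.0 * delta)
    return float(stats.chi2.sf(stat, df))
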