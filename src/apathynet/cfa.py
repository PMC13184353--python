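"""Confirmatory factor analysis of the a-priori three-factor AMI model.

The model: each retained item loads on exactly one of the Behavioural,
Social and Emotional factors; factor variances fixed to 1, loadings free,
factor correlations free, residual variances free, no residual covariances.
Estimation minimises the ML discrepancy

    F = ln det(Sigma) + tr(S Sigma^-1) - ln det(S) - p

by quasi-Newton with an analytic gradient.  The fit is computed on the
correlation matrix; because the model family is closed under diagonal
rescaling, the minimised discrepancy (and hence the chi-square) is identical
to the covariance-metric fit and the solution is already standardised.

chi2 = n * F_min (multiplier n, matching the convention of the SEM software
family the indices come from; switchable to n - 1).  Fit indices follow the
standard definitions: CFI, TLI against the independence baseline, RMSEA with
a 90% CI by noncentral-chi-square root finding, and SRMR over the
correlation-metric residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .scales import CohortDataset, builtin_scale

__all__ = [
    "CFAModelSpec",
    "CFAFit",
    "default_ami_spec",
    "model_df",
    "cfa_fit",
    "cfa_fit_corr",
    "fit_indices",
]

#: Residual variances are bounded below at this floor (Heywood guard).
RESIDUAL_FLOOR = 0.001


@dataclass(frozen=True)
class CFAModelSpec:
    """Factor labels, item -> factor map, and the exclusion set."""

    factors: tuple[str, ...]
    indicator_of: dict[str, str]
    excluded_items: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for item, f in self.indicator_of.items():
            if f not in self.factors:
                raise ValueError(f"item {item!r} mapped to unknown factor {f!r}")
        counts = {f: 0 for f in self.factors}
        for item in self.retained_items:
            counts[self.indicator_of[item]] += 1
        low = [f for f, c in counts.items() if c < 3]
        if low:
            raise ValueError(f"factors with fewer than 3 indicators: {low}")

    @property
    def retained_items(self) -> tuple[str, ...]:
        return tuple(i for i in self.indicator_of if i not in self.excluded_items)

    @property
    def n_factors(self) -> int:
        return len(self.factors)


def default_ami_spec(excluded: tuple[str, ...] = ("AMI-2", "AMI-6", "AMI-8")) -> CFAModelSpec:
    """The a-priori three-factor AMI model with the standard exclusions.

    AMI-2, AMI-6 and AMI-8 are dropped for low indicator reliability (the
    exclusion set is configuration, not computed), leaving 15 indicators.
    """
    ami = builtin_scale("AMI")
    return CFAModelSpec(
        factors=("Behavioural", "Social", "Emotional"),
        indicator_of={item: ami.domain_of[item] for item in ami.items},
        excluded_items=frozenset(excluded),
    )


def model_df(spec: CFAModelSpec, p: int | None = None) -> int:
    """Model-test degrees of freedom: p(p+1)/2 minus free parameters.

    Free parameters: p loadings + p residual variances + f(f-1)/2 factor
    covariances (factor variances are fixed at 1).
    """
    if p is None:
        p = len(spec.retained_items)
    f = spec.n_factors
    free = 2 * p + f * (f - 1) // 2
    df = p * (p + 1) // 2 - free
    if df < 0:
        raise ValueError(f"model is under-identified: df = {df} < 0")
    return df


@dataclass
class CFAFit:
    """A fitted CFA: standardised solution, model test and fit indices."""

    loadings: pd.Series  # standardised lambda per retained item
    factor_corr: pd.DataFrame
    residuals: pd.Series  # standardised residual variances
    chi2: float
    df: int
    p: float
    baseline_chi2: float
    baseline_df: int
    cfi: float
    tli: float
    rmsea: float
    rmsea_ci90: tuple[float, float]
    srmr: float
    n: int
    converged: bool
    f_min: float


def _unpack(x: np.ndarray, p: int, f: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lam = x[:p]
    theta = x[p : 2 * p]
    phi = np.eye(f)
    iu = np.triu_indices(f, 1)
    phi[iu] = x[2 * p :]
    phi[(iu[1], iu[0])] = x[2 * p :]
    return lam, theta, phi


def _discrepancy(x, R, factor_idx, p, f, logdet_R):
    lam, theta, phi = _unpack(x, p, f)
    L = np.zeros((p, f))
    L[np.arange(p), factor_idx] = lam
    sigma = L @ phi @ L.T
    sigma[np.diag_indices_from(sigma)] += theta
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return 1e10, np.zeros_like(x)
    sigma_inv = np.linalg.inv(sigma)
    F = logdet + float(np.sum(sigma_inv * R)) - logdet_R - p
    G = sigma_inv @ (sigma - R) @ sigma_inv
    g_lam = 2.0 * (G @ L @ phi)[np.arange(p), factor_idx]
    g_theta = np.diag(G).copy()
    LGL = L.T @ G @ L
    iu = np.triu_indices(f, 1)
    g_phi = 2.0 * LGL[iu]
    return F, np.concatenate([g_lam, g_theta, g_phi])


def cfa_fit_corr(
    R: np.ndarray,
    n: int,
    spec: CFAModelSpec,
    items: tuple[str, ...] | None = None,
    chi2_multiplier: str = "n",
    max_restarts: int = 5,
) -> CFAFit:
    """Fit the CFA to a correlation matrix of the retained items.

    ``R`` must be ordered like ``spec.retained_items`` (or ``items``).  On
    non-convergence the optimiser is restarted from jittered start values
    (seeded, deterministic) before raising.
    """
    R = np.asarray(R, dtype=float)
    items = tuple(items) if items is not None else spec.retained_items
    p = len(items)
    if R.shape != (p, p):
        raise ValueError(f"R shape {R.shape} does not match {p} retained items")
    if n <= p:
        raise ValueError("need more complete cases than items")
    f = spec.n_factors
    factor_idx = np.array([spec.factors.index(spec.indicator_of[i]) for i in items])
    sign, logdet_R = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("sample correlation matrix is not positive definite")

    # start values: loading from mean within-factor correlation, phi from
    # cross-factor correlations scaled by the start loadings
    lam0 = np.zeros(p)
    mean_r = np.zeros((f, f))
    for a in range(f):
        for b in range(f):
            ia, ib = np.flatnonzero(factor_idx == a), np.flatnonzero(factor_idx == b)
            block = R[np.ix_(ia, ib)]
            if a == b:
                off = block[~np.eye(len(ia), dtype=bool)]
                mean_r[a, a] = float(off.mean()) if off.size else 0.25
            else:
                mean_r[a, b] = float(block.mean())
    for i in range(p):
        lam0[i] = np.sqrt(np.clip(mean_r[factor_idx[i], factor_idx[i]], 0.04, 0.81))
    theta0 = 1.0 - lam0**2
    iu = np.triu_indices(f, 1)
    phi0 = np.clip(
        mean_r[iu] / np.sqrt(np.maximum(mean_r[np.diag_indices(f)][iu[0]], 0.04)
                             * np.maximum(mean_r[np.diag_indices(f)][iu[1]], 0.04)),
        -0.8, 0.8,
    )
    x0 = np.concatenate([lam0, theta0, phi0])
    bounds = [(-2.0, 2.0)] * p + [(RESIDUAL_FLOOR, 10.0)] * p + [(-0.99, 0.99)] * (f * (f - 1) // 2)

    rng = np.random.default_rng(2 * p + f)  # deterministic restart jitter
    best = None
    converged = False
    for attempt in range(max_restarts):
        start = x0 if attempt == 0 else x0 + rng.normal(0, 0.05 * (attempt), size=x0.size)
        start = np.clip(start, [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(
            _discrepancy,
            start,
            args=(R, factor_idx, p, f, logdet_R),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-9},
        )
        if best is None or res.fun < best.fun:
            best = res
        if np.linalg.norm(res.jac, ord=np.inf) <= 1e-6 or res.success:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"CFA did not converge after {max_restarts} restarts; "
            f"final gradient norm {np.linalg.norm(best.jac):.2e}"
        )
    lam, theta, phi = _unpack(best.x, p, f)
    if np.any(theta <= RESIDUAL_FLOOR * 1.01):
        warnings.warn(
            "Heywood case: residual variance bounded at the 0.001 floor for "
            f"items {[items[i] for i in np.flatnonzero(theta <= RESIDUAL_FLOOR * 1.01)]}",
            stacklevel=2,
        )
    # sign convention: flip factors so the mean loading is positive
    for a in range(f):
        sel = factor_idx == a
        if lam[sel].mean() < 0:
            lam[sel] = -lam[sel]
            others = np.arange(f) != a
            phi[a, others] = -phi[a, others]
            phi[others, a] = -phi[others, a]

    # standardise (implied variances may drift slightly from 1)
    L = np.zeros((p, f))
    L[np.arange(p), factor_idx] = lam
    sigma = L @ phi @ L.T + np.diag(theta)
    sd = np.sqrt(np.diag(sigma))
    lam_std = lam / sd
    theta_std = theta / sd**2

    F_min = float(best.fun)
    mult = n if chi2_multiplier == "n" else n - 1
    chi2 = max(mult * F_min, 0.0)
    df = model_df(spec, p)
    pval = float(stats.chi2.sf(chi2, df)) if df > 0 else float("nan")
    baseline_chi2 = max(mult * (-logdet_R), 0.0)
    baseline_df = p * (p - 1) // 2
    cfi, tli, rmsea, ci, srmr = fit_indices(
        chi2, df, baseline_chi2, baseline_df, n, S=R, sigma=sigma
    )
    return CFAFit(
        loadings=pd.Series(lam_std, index=list(items)),
        factor_corr=pd.DataFrame(phi, index=list(spec.factors), columns=list(spec.factors)),
        residuals=pd.Series(theta_std, index=list(items)),
        chi2=chi2,
        df=df,
        p=pval,
        baseline_chi2=baseline_chi2,
        baseline_df=baseline_df,
        cfi=cfi,
        tli=tli,
        rmsea=rmsea,
        rmsea_ci90=ci,
        srmr=srmr,
        n=n,
        converged=converged,
        f_min=F_min,
    )


def cfa_fit(data, spec: CFAModelSpec, chi2_multiplier: str = "n") -> CFAFit:
    """Fit the CFA to a cohort dataset (listwise complete cases) or DataFrame."""
    if isinstance(data, CohortDataset):
        ds = data.complete_cases()
        frame = ds.responses
    else:
        frame = pd.DataFrame(data).dropna()
    items = [i for i in spec.retained_items if i in frame.columns]
    if len(items) != len(spec.retained_items):
        missing = set(spec.retained_items) - set(items)
        raise ValueError(f"data lacks retained items: {sorted(missing)}")
    X = frame.loc[:, items].to_numpy(dtype=float)
    R = np.corrcoef(X, rowvar=False)
    return cfa_fit_corr(R, X.shape[0], spec, items=tuple(items), chi2_multiplier=chi2_multiplier)


def _rmsea_ci(chi2: float, df: int, n: int, level: float = 0.90) -> tuple[float, float]:
    """90% RMSEA CI by root-finding the noncentral-chi-square coverage."""
    alpha = (1.0 - level) / 2.0
    upper_target, lower_target = alpha, 1.0 - alpha

    def bound(target: float) -> float:
        # find nc >= 0 with P(X_{df, nc} <= chi2) = target
        if stats.ncx2.cdf(chi2, df, 0.0) <= target:
            return 0.0
        hi = max(chi2, df, 1.0)
        while stats.ncx2.cdf(chi2, df, hi) > target:
            hi *= 2.0
            if hi > 1e8:
                break
        nc = optimize.brentq(lambda l: stats.ncx2.cdf(chi2, df, l) - target, 0.0, hi, xtol=1e-6)
        return nc

    lo = np.sqrt(bound(lower_target) / (df * n))
    hi = np.sqrt(bound(upper_target) / (df * n))
    return float(lo), float(hi)


def fit_indices(
    chi2: float,
    df: int,
    baseline_chi2: float,
    baseline_df: int,
    n: int,
    S: np.ndarray | None = None,
    sigma: np.ndarray | None = None,
) -> tuple[float, float, float, tuple[float, float], float]:
    """CFI, TLI, RMSEA (with 90% CI) and SRMR from the model and baseline tests.

    SRMR needs the sample matrix ``S`` and the implied matrix ``sigma``;
    residuals are taken on the correlation metric over i <= j.  With df = 0
    the RMSEA and TLI are undefined and reported as NaN.
    """
    excess = max(chi2 - df, 0.0)
    excess_b = max(baseline_chi2 - baseline_df, 0.0)
    denom = max(excess_b, excess)
    cfi = 1.0 - (excess / denom if denom > 0 else 0.0)
    if df > 0 and baseline_df > 0:
        rat_b = baseline_chi2 / baseline_df
        rat = chi2 / df
        tli = (rat_b - rat) / (rat_b - 1.0) if rat_b != 1.0 else float("nan")
    else:
        tli = float("nan")
    if df > 0:
        rmsea = float(np.sqrt(excess / (df * n)))
        ci = _rmsea_ci(chi2, df, n)
    else:
        rmsea = float("nan")
        ci = (float("nan"), float("nan"))
    if S is not None and sigma is not None:
        S = np.asarray(S, dtype=float)
        sigma = np.asarray(sigma, dtype=float)
        ds = np.sqrt(np.diag(S))
        dm = np.sqrt(np.diag(sigma))
        S_std = S / np.outer(ds, ds)
        M_std = sigma / np.outer(dm, dm)
        iu = np.triu_indices(S.shape[0])
        srmr = float(np.sqrt(np.mean((S_std[iu] - M_std[iu]) ** 2)))
    else:
        srmr = float("nan")
    return float(cfi), float(tli), rmsea, ci, srmr
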