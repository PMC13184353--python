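"""Exploratory factor analysis of the combined item battery.

Implements the classical common-factor pipeline used on the 60-item
AMI + AES + DAS battery: Kaiser-Meyer-Olkin sampling adequacy, Bartlett's
test of sphericity, factor retention by Kaiser's criterion (eigenvalues of
the item correlation matrix > 1), maximum-likelihood extraction via the
concentrated likelihood over uniquenesses (Joreskog), varimax and promax
rotation, and the factor-purity index

    purity_i = lambda_{i,designated}^2 / h_i^2,

the share of an item's communality attributable to its designated factor.
Items are correlated with product-moment correlations on the 0-4 scores;
rank-based correlations are reserved for the symptom networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FactorSolution",
    "PurityTable",
    "EFAReport",
    "kmo_overall",
    "sampling_adequacy_label",
    "bartlett_sphericity",
    "kaiser_nfactors",
    "extract_ml",
    "extract_principal_axis",
    "rotate",
    "varimax",
    "promax",
    "factor_purity",
    "compare_purity",
    "tucker_congruence",
    "match_factors",
    "run_efa",
]

#: Residual-variance floor applied when ML extraction drifts into a Heywood case.
HEYWOOD_FLOOR = 0.005


@dataclass
class FactorSolution:
    """A factor solution: loadings, factor correlations, communalities, fit."""

    pattern: np.ndarray  # items x k loadings (pattern matrix after rotation)
    factor_corr: np.ndarray  # k x k, identity for orthogonal solutions
    communality: np.ndarray  # per item, sum of squared loadings
    eigenvalues: np.ndarray  # of the item correlation matrix, descending
    method: str
    rotation: str
    item_ids: tuple[str, ...]
    uniqueness: np.ndarray | None = None
    fit: tuple[float, float, float] | None = None  # (chi2, df, p) for ML

    @property
    def n_factors(self) -> int:
        return self.pattern.shape[1]


@dataclass
class PurityTable:
    """Per-item factor purity and per-factor summaries."""

    per_item: pd.DataFrame  # item, primary_factor, purity
    per_factor: pd.DataFrame  # factor, mean_purity, sem, n_items
    excluded: tuple[str, ...] = ()


def _ensure_invertible(R: np.ndarray) -> np.ndarray:
    """Ridge-regularise a (near-)singular correlation matrix and renormalise."""
    eigmin = np.linalg.eigvalsh(R).min()
    if eigmin < 1e-10:
        warnings.warn(
            "correlation matrix is singular or nearly so; applying ridge "
            "regularisation (R + 1e-6 I, renormalised)",
            stacklevel=3,
        )
        p = R.shape[0]
        R = (R + 1e-6 * np.eye(p)) / (1.0 + 1e-6)
    return R


def kmo_overall(R: np.ndarray) -> float:
    """Kaiser-Meyer-Olkin measure of sampling adequacy (overall).

    KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2) over i != j, where q are
    the anti-image partial correlations q_ij = -s_ij / sqrt(s_ii s_jj) with
    S = R^-1.  Near-singular input is ridge-regularised (with a warning).
    """
    R = np.asarray(R, dtype=float)
    R = _ensure_invertible(R)
    S = np.linalg.inv(R)
    d = np.sqrt(np.diag(S))
    Q = -S / np.outer(d, d)
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = np.sum(R[off] ** 2)
    q2 = np.sum(Q[off] ** 2)
    return float(r2 / (r2 + q2))


def sampling_adequacy_label(kmo: float) -> str:
    """Kaiser's verbal labels for the overall KMO value."""
    bands = [(0.9, "marvellous"), (0.8, "meritorious"), (0.7, "middling"),
             (0.6, "mediocre"), (0.5, "miserable")]
    for cut, label in bands:
        if kmo >= cut:
            return label
    return "unsuitable"


def bartlett_sphericity(R: np.ndarray, n: int) -> tuple[float, int, float]:
    """Bartlett's test that the correlation matrix is the identity.

    chi2 = -(n - 1 - (2p + 5)/6) ln det R with df = p(p - 1)/2.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("correlation matrix has non-positive determinant")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), pval


def kaiser_nfactors(eigenvalues: np.ndarray) -> int:
    """Kaiser's criterion: number of eigenvalues strictly greater than 1."""
    return int(np.sum(np.asarray(eigenvalues) > 1.0))


def ml_df(p: int, k: int) -> int:
    """Degrees of freedom of the ML factor-model test: ((p-k)^2 - (p+k))/2."""
    return ((p - k) ** 2 - (p + k)) // 2


def _canonical_loadings(R: np.ndarray, psi: np.ndarray, k: int) -> np.ndarray:
    """Conditional ML loadings at fixed uniquenesses, canonical orientation."""
    d = 1.0 / np.sqrt(psi)
    Rstar = R * np.outer(d, d)
    vals, vecs = np.linalg.eigh(Rstar)
    order = np.argsort(vals)[::-1]
    gam = vals[order][:k]
    V = vecs[:, order][:, :k]
    lam = np.sqrt(psi)[:, None] * V * np.sqrt(np.maximum(gam - 1.0, 0.0))
    # sign convention: largest-|loading| element of each column positive
    for j in range(k):
        i = np.argmax(np.abs(lam[:, j]))
        if lam[i, j] < 0:
            lam[:, j] = -lam[:, j]
    return lam


def _ml_objective(z: np.ndarray, R: np.ndarray, k: int) -> tuple[float, np.ndarray]:
    psi = np.exp(z)
    d = 1.0 / np.sqrt(psi)
    Rstar = R * np.outer(d, d)
    vals = np.linalg.eigvalsh(Rstar)[::-1]
    tail = vals[k:]
    F = float(np.sum(tail - np.log(tail) - 1.0))
    # envelope gradient: dF/dpsi_i = [Sigma^-1 (Sigma - R) Sigma^-1]_ii
    lam = _canonical_loadings(R, psi, k)
    sigma = lam @ lam.T + np.diag(psi)
    sigma_inv = np.linalg.inv(sigma)
    G = sigma_inv @ (sigma - R) @ sigma_inv
    return F, np.diag(G) * psi


def extract_ml(R: np.ndarray, k: int, n: int) -> FactorSolution:
    """Maximum-likelihood factor extraction from a correlation matrix.

    Minimises F = ln det(Sigma) + tr(R Sigma^-1) - ln det(R) - p over
    Sigma = Lambda Lambda' + diag(psi) via the concentrated likelihood in the
    uniquenesses.  Returns loadings in the canonical orientation (the factor
    axes that diagonalise Lambda' Psi^-1 Lambda) plus the Bartlett-corrected
    chi-square model test:

        chi2 = (n - 1 - (2p + 5)/6 - 2k/3) F_min,
        df = ((p - k)^2 - (p + k)) / 2.

    Uniquenesses that hit the Heywood floor (0.005) are reported with a
    warning.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if k >= p:
        raise ValueError("k must be smaller than the number of items")
    eigenvalues = np.sort(np.linalg.eigvalsh(R))[::-1]
    psi0 = (1.0 - 0.5 * k / p) / np.diag(np.linalg.inv(_ensure_invertible(R)))
    psi0 = np.clip(psi0, 0.05, 0.95)
    res = optimize.minimize(
        _ml_objective,
        np.log(psi0),
        args=(R, k),
        jac=True,
        method="L-BFGS-B",
        bounds=[(np.log(HEYWOOD_FLOOR), 0.0)] * p,
        options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-8},
    )
    if not res.success and res.fun > 1e-6:
        # L-BFGS-B occasionally reports failure at a flat optimum; only a
        # genuinely unconverged fit (non-trivial discrepancy) is an error
        if np.linalg.norm(res.jac) > 1e-4:
            raise RuntimeError(f"ML extraction did not converge: {res.message}")
    psi = np.exp(res.x)
    if np.any(psi <= HEYWOOD_FLOOR * 1.01):
        warnings.warn(
            "Heywood case: uniqueness bounded at the 0.005 floor for items "
            f"{list(np.flatnonzero(psi <= HEYWOOD_FLOOR * 1.01))}",
            stacklevel=2,
        )
    lam = _canonical_loadings(R, psi, k)
    F_min = float(res.fun)
    df = ml_df(p, k)
    mult = n - 1 - (2 * p + 5) / 6.0 - 2 * k / 3.0
    chi2 = max(mult * F_min, 0.0)
    pval = float(stats.chi2.sf(chi2, df)) if df > 0 else float("nan")
    return FactorSolution(
        pattern=lam,
        factor_corr=np.eye(k),
        communality=np.sum(lam**2, axis=1),
        eigenvalues=eigenvalues,
        method="ml",
        rotation="none",
        item_ids=tuple(f"item{i + 1}" for i in range(p)),
        uniqueness=psi,
        fit=(chi2, float(df), pval),
    )


def extract_principal_axis(R: np.ndarray, k: int, max_iter: int = 200, tol: float = 1e-8) -> FactorSolution:
    """Iterated principal-axis factoring (no chi-square model test)."""
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    eigenvalues = np.sort(np.linalg.eigvalsh(R))[::-1]
    h2 = 1.0 - 1.0 / np.diag(np.linalg.inv(_ensure_invertible(R)))
    for _ in range(max_iter):
        Rh = R.copy()
        Rh[np.diag_indices_from(Rh)] = h2
        vals, vecs = np.linalg.eigh(Rh)
        order = np.argsort(vals)[::-1][:k]
        lam = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
        h2_new = np.sum(lam**2, axis=1)
        if np.max(np.abs(h2_new - h2)) < tol:
            h2 = h2_new
            break
        h2 = h2_new
    for j in range(k):
        i = np.argmax(np.abs(lam[:, j]))
        if lam[i, j] < 0:
            lam[:, j] = -lam[:, j]
    return FactorSolution(
        pattern=lam,
        factor_corr=np.eye(k),
        communality=h2,
        eigenvalues=eigenvalues,
        method="paf",
        rotation="none",
        item_ids=tuple(f"item{i + 1}" for i in range(p)),
        uniqueness=1.0 - h2,
        fit=None,
    )


def varimax(loadings: np.ndarray, normalize: bool = True, tol: float = 1e-10, max_iter: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation (Kaiser row-normalised by default).

    Returns (rotated loadings, rotation matrix T) with L_rot = L @ T.
    """
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if normalize:
        h = np.sqrt(np.sum(L**2, axis=1))
        h[h == 0] = 1.0
        L = L / h[:, None]
    T = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        LR = L @ T
        B = L.T @ (LR**3 - LR @ np.diag(np.sum(LR**2, axis=0)) / p)
        U, s, Vt = np.linalg.svd(B)
        T = U @ Vt
        d = np.sum(s)
        if d_old != 0 and d / d_old < 1 + tol:
            break
        d_old = d
    LR = L @ T
    if normalize:
        LR = LR * h[:, None]
    return LR, T


def promax(loadings: np.ndarray, power: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Promax oblique rotation (varimax target raised to ``power``).

    Returns (pattern matrix, factor correlation matrix Phi).  The pattern and
    Phi satisfy pattern @ Phi @ pattern.T = L @ L.T (common part preserved).
    """
    X, _ = varimax(loadings)
    P = X * np.abs(X) ** (power - 1)  # element-wise, sign preserved
    L, *_ = np.linalg.lstsq(X, P, rcond=None)
    # rescale columns so the implied factor correlation has unit diagonal
    L = L * np.sqrt(np.diag(np.linalg.inv(L.T @ L)))
    pattern = X @ L
    phi = np.linalg.inv(L.T @ L)
    return pattern, phi


def _fix_signs(L: np.ndarray, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Reflect factors so each column's dominant loading is positive."""
    L = L.copy()
    phi = phi.copy()
    for j in range(L.shape[1]):
        if L[np.argmax(np.abs(L[:, j])), j] < 0:
            L[:, j] = -L[:, j]
            others = np.arange(phi.shape[0]) != j
            phi[j, others] = -phi[j, others]
            phi[others, j] = -phi[others, j]
    return L, phi


def rotate(sol: FactorSolution, method: str = "promax", promax_power: int = 4) -> FactorSolution:
    """Rotate an unrotated solution; varimax keeps Phi = I, promax frees it."""
    if sol.n_factors < 2:
        warnings.warn("single-factor solution: rotation is the identity", stacklevel=2)
        return replace(sol, rotation=f"{method} (identity, k=1)")
    if method == "varimax":
        L, _ = varimax(sol.pattern)
        phi = np.eye(sol.n_factors)
    elif method == "promax":
        L, phi = promax(sol.pattern, power=promax_power)
    else:
        raise ValueError(f"unknown rotation {method!r}")
    L, phi = _fix_signs(L, phi)
    return replace(
        sol,
        pattern=L,
        factor_corr=phi,
        communality=np.sum(L**2, axis=1),
        rotation=method,
    )


def factor_purity(
    pattern: np.ndarray,
    assignment: dict[int, int] | list[int] | None = None,
    item_ids: tuple[str, ...] | None = None,
) -> PurityTable:
    """Factor purity per item: squared designated loading over communality.

    ``assignment`` maps item index -> designated factor index; by default the
    designated factor is the argmax-|loading| factor.  Items with zero
    communality are flagged and excluded from the per-factor means.
    """
    L = np.asarray(pattern, dtype=float)
    p, k = L.shape
    if item_ids is None:
        item_ids = tuple(f"item{i + 1}" for i in range(p))
    sq = L**2
    h2 = sq.sum(axis=1)
    if assignment is None:
        designated = np.argmax(np.abs(L), axis=1)
    elif isinstance(assignment, dict):
        designated = np.array([assignment[i] for i in range(p)])
    else:
        designated = np.asarray(assignment, dtype=int)
    excluded = [item_ids[i] for i in range(p) if h2[i] <= 1e-12]
    purity = np.full(p, np.nan)
    ok = h2 > 1e-12
    purity[ok] = sq[np.arange(p), designated][ok] / h2[ok]
    per_item = pd.DataFrame(
        {"item": item_ids, "primary_factor": designated, "purity": purity}
    )
    rows = []
    for f in range(k):
        vals = purity[(designated == f) & ok]
        sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
        rows.append({
            "factor": f,
            "mean_purity": float(vals.mean()) if len(vals) else float("nan"),
            "sem": sem,
            "n_items": int(len(vals)),
        })
    return PurityTable(per_item=per_item, per_factor=pd.DataFrame(rows), excluded=tuple(excluded))


def _welch_one_sided(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Welch's t of mean(x) > mean(y) with Welch-Satterthwaite df.

    Zero-variance groups get a 1e-12 variance floor so degenerate inputs
    produce a finite statistic rather than 0/0.
    """
    nx, ny = len(x), len(y)
    vx = max(float(np.var(x, ddof=1)), 1e-12)
    vy = max(float(np.var(y, ddof=1)), 1e-12)
    se2 = vx / nx + vy / ny
    t = (float(np.mean(x)) - float(np.mean(y))) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = float(stats.t.sf(t, df))
    return t, df, p


def compare_purity(purity: PurityTable, focal_factor: int) -> dict:
    """One-way ANOVA over factor groups plus the planned one-sided Welch test
    of the focal factor's mean purity against all remaining items pooled."""
    per = purity.per_item.dropna(subset=["purity"])
    groups = []
    skipped = []
    for f, sub in per.groupby("primary_factor"):
        if len(sub) < 2:
            skipped.append(int(f))
            continue
        groups.append(sub["purity"].to_numpy())
    if skipped:
        warnings.warn(f"factor groups with < 2 items excluded from ANOVA: {skipped}", stacklevel=2)
    if len(groups) < 2:
        raise ValueError("need at least two factor groups with >= 2 items")
    if all(np.ptp(g) == 0 for g in groups) and np.ptp(np.concatenate(groups)) == 0:
        F, p_anova = 0.0, 1.0
        df_between, df_within = len(groups) - 1, sum(len(g) for g in groups) - len(groups)
    else:
        F, p_anova = stats.f_oneway(*groups)
        df_between = len(groups) - 1
        df_within = sum(len(g) for g in groups) - len(groups)
    focal = per.loc[per["primary_factor"] == focal_factor, "purity"].to_numpy()
    rest = per.loc[per["primary_factor"] != focal_factor, "purity"].to_numpy()
    t, df_w, p_welch = _welch_one_sided(focal, rest)
    return {
        "anova": {"F": float(F), "df": (df_between, df_within), "p": float(p_anova)},
        "welch": {"t": float(t), "df": float(df_w), "p": float(p_welch)},
    }


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker's congruence coefficient between two loading columns."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def match_factors(pattern: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Align recovered factors with target columns by greedy |congruence|.

    Returns (reordered sign-flipped pattern, column permutation, per-factor
    congruence after matching).  Used by recovery tests; the analysis itself
    never needs a factor order.
    """
    P = np.asarray(pattern, dtype=float)
    T = np.asarray(target, dtype=float)
    k = T.shape[1]
    C = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            C[i, j] = tucker_congruence(T[:, i], P[:, j])
    perm = np.full(k, -1)
    used: set[int] = set()
    for _ in range(k):
        masked = np.abs(C).copy()
        masked[[i for i in range(k) if perm[i] >= 0], :] = -1
        masked[:, list(used)] = -1
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        perm[i] = j
        used.add(j)
    aligned = P[:, perm].copy()
    congr = np.zeros(k)
    for i in range(k):
        c = tucker_congruence(T[:, i], aligned[:, i])
        if c < 0:
            aligned[:, i] = -aligned[:, i]
            c = -c
        congr[i] = c
    return aligned, perm, congr


@dataclass
class EFAReport:
    """Everything the exploratory stage reports for one battery."""

    kmo: float
    kmo_label: str
    bartlett: tuple[float, int, float]
    eigenvalues: np.ndarray
    n_factors: int
    solution: FactorSolution
    purity: PurityTable
    n: int


def run_efa(
    dataset,
    k: int | None = None,
    rotation: str = "promax",
    promax_power: int = 4,
    method: str = "ml",
) -> EFAReport:
    """Full exploratory pipeline on a cohort dataset (listwise complete cases).

    Correlates items with product-moment correlations, checks KMO/Bartlett,
    retains factors by Kaiser's criterion unless ``k`` is given, extracts by
    ML, rotates, and scores per-item factor purity against the argmax
    designation.
    """
    ds = dataset.complete_cases()
    X = ds.responses.to_numpy(dtype=float)
    n = X.shape[0]
    R = np.corrcoef(X, rowvar=False)
    kmo = kmo_overall(R)
    bart = bartlett_sphericity(R, n)
    eigenvalues = np.sort(np.linalg.eigvalsh(R))[::-1]
    if k is None:
        k = kaiser_nfactors(eigenvalues)
    if method == "ml":
        sol = extract_ml(R, k, n)
    elif method == "paf":
        sol = extract_principal_axis(R, k)
    else:
        raise ValueError(f"unknown extraction method {method!r}")
    sol = replace(sol, item_ids=ds.scale.items)
    if k >= 2:
        sol = rotate(sol, method=rotation, promax_power=promax_power)
    purity = factor_purity(sol.pattern, item_ids=ds.scale.items)
    return EFAReport(
        kmo=kmo,
        kmo_label=sampling_adequacy_label(kmo),
        bartlett=bart,
        eigenvalues=eigenvalues,
        n_factors=k,
        solution=sol,
        purity=purity,
        n=n,
    )
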