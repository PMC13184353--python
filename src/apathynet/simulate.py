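"""Synthetic questionnaire cohorts from a correlated latent-factor model.

Continuous item responses follow the common-factor model

    y = Lambda f + eps,   f ~ N(0, Phi),   eps ~ N(0, diag(theta)),

with ``theta_i = 1 - (Lambda Phi Lambda')_ii`` so each continuous response is
standardised.  Ordinal 0-4 responses are produced by cutting each item's
continuous response at per-item thresholds; the default thresholds are the
standard-normal quintiles, giving equal 20% category probabilities and
mid-scale item means.  Ages and cohort/assessment-mode labels are attached so
every downstream stage (factor analysis, symptom networks, lifespan scans) is
testable without any external data.

Non-stationary lifespan structure is obtained by mixing age-band-specific
factor models at the participant level: each participant's responses are drawn
from the model of the band their age falls in, so every age window has a
well-defined generating model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .scales import DOMAINS, CohortDataset, ScaleDefinition

__all__ = [
    "SpecError",
    "FactorModelSpec",
    "CohortSimSpec",
    "default_thresholds",
    "implied_correlation",
    "planted_module_spec",
    "scale_factor_spec",
    "simulate_continuous",
    "simulate_cohort",
    "stack_cohorts",
]


class SpecError(ValueError):
    """Invalid factor-model or simulation specification."""


def default_thresholds(n_items: int, n_categories: int = 5) -> np.ndarray:
    """Standard-normal equal-probability cut-points, one row per item."""
    probs = np.arange(1, n_categories) / n_categories
    return np.tile(stats.norm.ppf(probs), (n_items, 1))


@dataclass
class FactorModelSpec:
    """Loadings, inter-factor correlations and discretisation thresholds.

    ``loadings`` is items x factors (typically simple structure with
    primary loadings 0.4-0.8), ``factor_corr`` a unit-diagonal PSD matrix,
    ``thresholds`` an items x (categories-1) strictly increasing cut-point
    table.  Residual variances are derived, not stored:
    ``theta_i = 1 - (Lambda Phi Lambda')_ii``.
    """

    loadings: np.ndarray
    factor_corr: np.ndarray
    thresholds: np.ndarray
    item_ids: tuple[str, ...]
    domain_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.factor_corr = np.asarray(self.factor_corr, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        p, k = self.loadings.shape
        if len(self.item_ids) != p:
            raise SpecError("item_ids length must match loadings rows")
        if self.factor_corr.shape != (k, k):
            raise SpecError("factor_corr shape must match loadings columns")
        if not np.allclose(self.factor_corr, self.factor_corr.T):
            raise SpecError("factor_corr must be symmetric")
        if not np.allclose(np.diag(self.factor_corr), 1.0):
            raise SpecError("factor_corr must have unit diagonal")
        if np.linalg.eigvalsh(self.factor_corr).min() < -1e-10:
            raise SpecError("factor_corr must be positive semidefinite")
        if self.thresholds.ndim != 2 or self.thresholds.shape[0] != p:
            raise SpecError("thresholds must be items x cut-points")
        if np.any(np.diff(self.thresholds, axis=1) <= 0):
            raise SpecError("thresholds must be strictly increasing per item")
        if np.any(self.residual_var <= 0):
            raise SpecError(
                "communalities reach or exceed 1 (Heywood by construction); "
                "reduce loadings or factor correlations"
            )

    @property
    def n_items(self) -> int:
        return self.loadings.shape[0]

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    @property
    def residual_var(self) -> np.ndarray:
        common = self.loadings @ self.factor_corr @ self.loadings.T
        return 1.0 - np.diag(common)


def implied_correlation(model: FactorModelSpec) -> np.ndarray:
    """Population correlation of the continuous responses: LPL' + diag(theta)."""
    R = model.loadings @ model.factor_corr @ model.loadings.T
    R[np.diag_indices_from(R)] = 1.0
    return R


def planted_module_spec(
    k_modules: int,
    items_per_module: int,
    within_load: float,
    between_corr: float,
    item_ids: tuple[str, ...] | None = None,
    module_domains: tuple[str, ...] | None = None,
    thresholds: np.ndarray | None = None,
) -> FactorModelSpec:
    """Block simple structure: each module's items load ``within_load`` on one
    factor; factors are equicorrelated at ``between_corr``."""
    if not 0 < within_load < 1:
        raise SpecError("within_load must lie strictly between 0 and 1")
    if not -1 < between_corr < 1:
        raise SpecError("between_corr must be a valid correlation")
    p = k_modules * items_per_module
    lam = np.zeros((p, k_modules))
    for m in range(k_modules):
        lam[m * items_per_module : (m + 1) * items_per_module, m] = within_load
    phi = np.full((k_modules, k_modules), between_corr)
    np.fill_diagonal(phi, 1.0)
    if item_ids is None:
        item_ids = tuple(f"M{m + 1}-{j + 1}" for m in range(k_modules) for j in range(items_per_module))
    if module_domains is None:
        module_domains = tuple(DOMAINS[m % len(DOMAINS)] for m in range(k_modules))
    domain_of = {
        item_ids[m * items_per_module + j]: module_domains[m]
        for m in range(k_modules)
        for j in range(items_per_module)
    }
    if thresholds is None:
        thresholds = default_thresholds(p)
    return FactorModelSpec(lam, phi, thresholds, tuple(item_ids), domain_of)


def scale_factor_spec(
    scale: ScaleDefinition,
    within_load: float = 0.7,
    between_corr: float = 0.3,
    loadings_by_domain: dict[str, float] | None = None,
    merge_domains: dict[str, str] | None = None,
) -> FactorModelSpec:
    """One factor per a-priori domain of ``scale``; each item loads on its
    domain's factor (item order preserved, so blocks interleave like the AMI).

    ``merge_domains`` maps a domain onto another's factor (e.g. Social ->
    Behavioural) to build negative-control models in which two a-priori
    domains share one generating factor; ``loadings_by_domain`` overrides the
    loading per a-priori domain.
    """
    factor_of_domain: dict[str, int] = {}
    for item in scale.items:
        dom = scale.domain_of[item]
        target = (merge_domains or {}).get(dom, dom)
        if target not in factor_of_domain:
            factor_of_domain[target] = len(factor_of_domain)
    k = len(factor_of_domain)
    p = scale.n_items
    lam = np.zeros((p, k))
    for i, item in enumerate(scale.items):
        dom = scale.domain_of[item]
        target = (merge_domains or {}).get(dom, dom)
        load = (loadings_by_domain or {}).get(dom, within_load)
        lam[i, factor_of_domain[target]] = load
    phi = np.full((k, k), between_corr)
    np.fill_diagonal(phi, 1.0)
    return FactorModelSpec(
        lam, phi, default_thresholds(p), scale.items, dict(scale.domain_of)
    )


@dataclass
class CohortSimSpec:
    """How to draw one cohort: size, age law, generating model(s), seed.

    ``model`` is either a single :class:`FactorModelSpec` or a list of
    ``(age_lo, age_hi, model)`` bands partitioning ``[age_min, age_max]``;
    each participant's responses are drawn from the band their age falls in
    (upper bound inclusive for the last band).
    """

    n: int
    model: FactorModelSpec | list[tuple[float, float, FactorModelSpec]]
    cohort_label: str = "HC"
    age_min: float = 16.0
    age_max: float = 90.0
    age_weights: dict[int, float] | None = None
    mode_probs: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise SpecError("n must be at least 1")
        if isinstance(self.model, list):
            bands = sorted(self.model, key=lambda b: b[0])
            if bands[0][0] > self.age_min or bands[-1][1] < self.age_max:
                raise SpecError("age bands must cover the age range")
            for (_, hi), (lo, _) in zip([b[:2] for b in bands], [b[:2] for b in bands[1:]]):
                if hi != lo:
                    raise SpecError("age bands must partition the age range")
            self.model = bands

    def band_model(self, age: float) -> FactorModelSpec:
        if not isinstance(self.model, list):
            return self.model
        for lo, hi, m in self.model:
            if lo <= age < hi:
                return m
        return self.model[-1][2]


def _draw_continuous(model: FactorModelSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    f = rng.multivariate_normal(
        np.zeros(model.n_factors), model.factor_corr, size=n, method="cholesky"
    )
    eps = rng.standard_normal((n, model.n_items)) * np.sqrt(model.residual_var)
    return f @ model.loadings.T + eps


def simulate_continuous(model: FactorModelSpec, n: int, seed: int) -> np.ndarray:
    """Standardised continuous responses (no discretisation), n x items."""
    return _draw_continuous(model, n, np.random.default_rng(seed))


def _discretise(y: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    # response = number of cut-points the continuous value exceeds
    return (y[:, :, None] > thresholds[None, :, :]).sum(axis=2)


def simulate_cohort(spec: CohortSimSpec) -> CohortDataset:
    """Draw one cohort; deterministic given ``spec.seed``.

    Sub-streams for ages, modes and responses are spawned from one seeded
    generator, so partial re-runs with the same spec reproduce exactly.
    """
    root = np.random.SeedSequence(spec.seed)
    rng_age, rng_mode, rng_resp = (np.random.default_rng(s) for s in root.spawn(3))

    if spec.age_weights:
        ages_levels = np.array(sorted(spec.age_weights))
        w = np.array([spec.age_weights[a] for a in ages_levels], dtype=float)
        ages = rng_age.choice(ages_levels, size=spec.n, p=w / w.sum()).astype(float)
    else:
        ages = rng_age.uniform(spec.age_min, spec.age_max, size=spec.n)

    if spec.mode_probs:
        labels = sorted(spec.mode_probs)
        pr = np.array([spec.mode_probs[m] for m in labels], dtype=float)
        modes = rng_mode.choice(labels, size=spec.n, p=pr / pr.sum())
    else:
        modes = np.full(spec.n, "unknown", dtype=object)

    some_model = spec.band_model(float(ages[0]))
    responses = np.zeros((spec.n, some_model.n_items), dtype=int)
    if isinstance(spec.model, list):
        # draw band by band so each window's generating model is well-defined
        for lo, hi, model in spec.model:
            last = model is spec.model[-1][2]
            sel = (ages >= lo) & ((ages <= hi) if last else (ages < hi))
            if sel.any():
                y = _draw_continuous(model, int(sel.sum()), rng_resp)
                responses[sel] = _discretise(y, model.thresholds)
        items = spec.model[0][2].item_ids
        domain_of = spec.model[0][2].domain_of
    else:
        y = _draw_continuous(spec.model, spec.n, rng_resp)
        responses = _discretise(y, spec.model.thresholds)
        items = spec.model.item_ids
        domain_of = spec.model.domain_of

    n_cat = some_model.thresholds.shape[1] + 1
    scale = ScaleDefinition(
        name="custom",
        items=tuple(items),
        domain_of=dict(domain_of),
        response_min=0,
        response_max=n_cat - 1,
    )
    ids = [f"{spec.cohort_label}-{i + 1:06d}" for i in range(spec.n)]
    resp = pd.DataFrame(responses.astype(float), index=ids, columns=list(items))
    mask = pd.DataFrame(False, index=ids, columns=list(items))
    return CohortDataset(
        participant_ids=ids,
        cohort=np.full(spec.n, spec.cohort_label, dtype=object),
        age=ages,
        mode=np.asarray(modes, dtype=object),
        responses=resp,
        missing_mask=mask,
        scale=scale,
    )


def stack_cohorts(datasets: list[CohortDataset]) -> CohortDataset:
    """Concatenate cohorts that share a scale into one dataset."""
    first = datasets[0]
    for ds in datasets[1:]:
        if ds.scale.items != first.scale.items:
            raise SpecError("cohorts must share the same scale to be stacked")
    return CohortDataset(
        participant_ids=[p for ds in datasets for p in ds.participant_ids],
        cohort=np.concatenate([np.asarray(ds.cohort) for ds in datasets]),
        age=np.concatenate([np.asarray(ds.age) for ds in datasets]),
        mode=np.concatenate([np.asarray(ds.mode) for ds in datasets]),
        responses=pd.concat([ds.responses for ds in datasets], axis=0),
        missing_mask=pd.concat([ds.missing_mask for ds in datasets], axis=0),
        scale=first.scale,
        reverse_applied=first.reverse_applied,
    )
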