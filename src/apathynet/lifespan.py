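"""Lifespan trajectory of the symptom-network module structure.

The scan slides a 10-year age window in 1-year steps across a cohort's age
range.  Participants are weighted by a Gaussian kernel centred on the window
(sigma = 5 years) and truncated at the window edges (+/- 5 years), which
reconciles the finite window with the kernel width.  Windows whose Kish
effective sample size (sum w)^2 / sum w^2 falls below 30 are excluded.  In
each included window the weighted absolute-Spearman network is rebuilt, the
modal partition over Louvain restarts is found, and each module is
summarised (dominant a-priori domain, purity, central node).  A domain is
"present" at an age iff some module's modal domain equals it.

Module purities across windows feed a two-way fixed-effects ANOVA
(Group x Domain, Type II sums of squares, appropriate because cohorts
contribute unequal window counts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import (
    ModuleSummary,
    PartitionCensus,
    SymptomNetwork,
    effective_n,
    spearman_network,
    stable_partition,
    summarise_modules,
)
from .scales import CohortDataset

__all__ = [
    "WindowSpec",
    "LifespanTrajectory",
    "window_weights",
    "effective_n",
    "weighted_spearman_network",
    "lifespan_scan",
    "lifespan_scan_by_cohort",
    "purity_anova",
    "mode_sensitivity",
]


@dataclass
class WindowSpec:
    """Sliding-window geometry: centers, width, kernel sigma, ESS floor."""

    centers: np.ndarray
    width: float = 10.0
    sigma: float = 5.0
    min_ess: float = 30.0
    truncate: bool = True

    def __post_init__(self) -> None:
        if self.width <= 0 or self.sigma <= 0 or self.min_ess <= 0:
            raise ValueError("width, sigma and min_ess must be positive")
        self.centers = np.asarray(self.centers, dtype=float)

    @classmethod
    def from_ages(cls, ages: np.ndarray, step: float = 1.0, **kwargs) -> "WindowSpec":
        """Integer-year centers spanning the observed age range."""
        lo = float(np.ceil(np.min(ages)))
        hi = float(np.floor(np.max(ages)))
        return cls(centers=np.arange(lo, hi + step / 2, step), **kwargs)


def window_weights(ages: np.ndarray, center: float, spec: WindowSpec) -> np.ndarray:
    """Gaussian kernel weights, zero outside the +/- width/2 window."""
    ages = np.asarray(ages, dtype=float)
    w = np.exp(-((ages - center) ** 2) / (2.0 * spec.sigma**2))
    if spec.truncate:
        w = np.where(np.abs(ages - center) <= spec.width / 2.0, w, 0.0)
    return w


def weighted_spearman_network(ds: CohortDataset, weights: np.ndarray) -> SymptomNetwork:
    """Weighted Spearman network: mid-ranks over in-window participants, then
    weighted Pearson on the rank columns.  Uniform weights reproduce the
    unweighted network exactly."""
    ess = effective_n(weights)
    if ess < 3:
        raise ValueError(f"effective sample size {ess:.1f} < 3; window too sparse")
    return spearman_network(ds, weights=weights)


@dataclass
class LifespanTrajectory:
    """Scan output: long-format module table plus per-window details.

    ``table`` has one row per (center, module) for included windows and a
    single row with ``included = False`` (no partition) for excluded ones.
    """

    cohort: str
    table: pd.DataFrame
    windows: dict[float, tuple[PartitionCensus, list[ModuleSummary]]] = field(default_factory=dict)
    spec: WindowSpec | None = None

    def included_centers(self) -> np.ndarray:
        t = self.table
        return np.sort(t.loc[t["included"], "center"].unique())

    def domain_presence(self, domain: str) -> pd.Series:
        """Per included center: does some module have this modal domain?"""
        t = self.table[self.table["included"]]
        return t.groupby("center")["modal_domain"].agg(lambda s: (s == domain).any())

    def purity_records(self) -> pd.DataFrame:
        """Long-format (group, domain, center, purity) rows for the ANOVA."""
        t = self.table[self.table["included"]]
        return t[["cohort", "modal_domain", "center", "purity"]].rename(
            columns={"cohort": "group", "modal_domain": "domain"}
        ).reset_index(drop=True)


def lifespan_scan(
    ds: CohortDataset,
    spec: WindowSpec | None = None,
    domain_of: dict[str, str] | None = None,
    n_restarts: int = 1000,
    seed: int = 0,
) -> LifespanTrajectory:
    """Slide the Gaussian window across the cohort's age range.

    Per center: kernel weights -> ESS gate -> weighted network -> modal
    partition over ``n_restarts`` Louvain restarts -> module summaries.
    Restart sub-seeds are derived per center from ``seed``, so the whole scan
    is reproducible.
    """
    if spec is None:
        spec = WindowSpec.from_ages(ds.age)
    cohort = str(ds.cohort[0]) if ds.n_participants else "?"
    center_seeds = np.random.SeedSequence(seed).generate_state(len(spec.centers))
    rows: list[dict] = []
    windows: dict[float, tuple[PartitionCensus, list[ModuleSummary]]] = {}
    for center, cseed in zip(spec.centers, center_seeds):
        w = window_weights(ds.age, center, spec)
        ess = effective_n(w)
        if ess < spec.min_ess:
            rows.append({
                "cohort": cohort, "center": float(center), "ess": ess,
                "included": False, "module": np.nan, "modal_domain": None,
                "purity": np.nan, "central_node": None, "n_members": np.nan,
                "modal_share": np.nan,
            })
            continue
        net = weighted_spearman_network(ds, w)
        census = stable_partition(net, n_restarts=n_restarts, seed=int(cseed))
        modules = summarise_modules(net, census.modal, domain_of)
        windows[float(center)] = (census, modules)
        for mi, mod in enumerate(modules):
            rows.append({
                "cohort": cohort, "center": float(center), "ess": ess,
                "included": True, "module": mi, "modal_domain": mod.modal_domain,
                "purity": mod.purity, "central_node": mod.central_node,
                "n_members": len(mod.members), "modal_share": census.modal_share,
            })
    return LifespanTrajectory(cohort=cohort, table=pd.DataFrame(rows), windows=windows, spec=spec)


def lifespan_scan_by_cohort(
    ds: CohortDataset,
    spec: WindowSpec | None = None,
    domain_of: dict[str, str] | None = None,
    n_restarts: int = 1000,
    seed: int = 0,
) -> dict[str, LifespanTrajectory]:
    """Run the scan separately for each cohort label in the dataset."""
    out: dict[str, LifespanTrajectory] = {}
    for gi, group in enumerate(pd.unique(np.asarray(ds.cohort))):
        sub = ds.subset(np.asarray(ds.cohort) == group)
        sub_spec = spec if spec is not None else WindowSpec.from_ages(sub.age)
        out[str(group)] = lifespan_scan(
            sub, sub_spec, domain_of, n_restarts=n_restarts, seed=seed + gi
        )
    return out


def purity_anova(records: pd.DataFrame) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA of module purity on Group and Domain.

    ``records`` needs columns ``group``, ``domain``, ``purity`` (long format,
    one row per detected module).  Type II sums of squares are used because
    window counts differ between cohorts.  Crossed cells with no data drop
    the interaction term (with a warning); a completely constant response
    returns zero F throughout.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = records.dropna(subset=["purity"]).copy()
    if df.empty:
        raise ValueError("no purity records")
    cells = df.groupby(["group", "domain"], observed=True).size().unstack(fill_value=0)
    full_grid = (cells.to_numpy() > 0).all()
    if not full_grid:
        warnings.warn("empty Group x Domain cells: interaction term dropped", stacklevel=2)
    if np.ptp(df["purity"].to_numpy()) == 0:
        effects = ["C(group)", "C(domain)"] + (["C(group):C(domain)"] if full_grid else [])
        return pd.DataFrame(
            {"F": 0.0, "p": 1.0, "df": np.nan, "sum_sq": 0.0}, index=effects
        )
    formula = "purity ~ C(group) * C(domain)" if full_grid else "purity ~ C(group) + C(domain)"
    model = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(columns={"PR(>F)": "p"})
    return table


def mode_sensitivity(
    ds: CohortDataset,
    domain_of: dict[str, str] | None = None,
    n_restarts: int = 1000,
    seed: int = 0,
    min_n: int = 30,
) -> dict:
    """Re-run the network pipeline per assessment mode and compare partitions.

    Returns per-mode (census, module summaries) plus an agreement report
    between the first two modes: adjusted Rand index of the modal partitions
    and a per-item concordance table (modules aligned by maximal overlap).
    Modes with fewer than ``min_n`` participants are skipped with a warning.
    """
    from sklearn.metrics import adjusted_rand_score

    modes = [m for m in pd.unique(np.asarray(ds.mode)) if m != "unknown"]
    if len(modes) < 2:
        raise ValueError("mode metadata must distinguish at least 2 assessment modes")
    per_mode: dict[str, dict] = {}
    for mi, mode in enumerate(modes):
        sel = np.asarray(ds.mode) == mode
        if sel.sum() < min_n:
            warnings.warn(f"mode {mode!r} has n={int(sel.sum())} < {min_n}; skipped", stacklevel=2)
            continue
        sub = ds.subset(sel)
        net = spearman_network(sub)
        census = stable_partition(net, n_restarts=n_restarts, seed=seed + mi)
        per_mode[str(mode)] = {
            "n": int(sel.sum()),
            "census": census,
            "modules": summarise_modules(net, census.modal, domain_of),
        }
    report = {"modes": per_mode, "agreement": None}
    if len(per_mode) >= 2:
        (ma, ra), (mb, rb) = list(per_mode.items())[:2]
        la = np.asarray(ra["census"].modal.labels)
        lb = np.asarray(rb["census"].modal.labels)
        ari = float(adjusted_rand_score(la, lb))
        # align b's modules onto a's by maximal member overlap
        mapping: dict[int, int] = {}
        for cb in range(lb.max() + 1):
            overlap = [np.sum((lb == cb) & (la == ca)) for ca in range(la.max() + 1)]
            mapping[cb] = int(np.argmax(overlap))
        items = ds.scale.items
        per_item = pd.DataFrame({
            "item": items,
            f"module_{ma}": la,
            f"module_{mb}": lb,
            "concordant": [mapping[int(b)] == int(a) for a, b in zip(la, lb)],
        })
        report["agreement"] = {
            "mode_pair": (ma, mb),
            "ari": ari,
            "identical": bool((la == lb).all()),
            "per_item": per_item,
        }
    return report
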