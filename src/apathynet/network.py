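"""Symptom networks: absolute-Spearman edges, modularity, Louvain, stability.

Items are nodes; edges are weighted by the absolute Spearman rank
correlation between item responses (robust to the skewed, discrete
distributions Likert items produce).  Community structure is found by
maximising the standard weighted modularity

    Q = (1/2m) sum_ij [A_ij - k_i k_j / (2m)] delta(c_i, c_j)

with a Louvain-style algorithm: greedy local moves over a seeded random
node order, repeated until no move improves Q, followed by community
aggregation and further local-move rounds (a single-level variant without
aggregation is available).  Because the greedy result depends on the node
order,
the algorithm is restarted many times and the most frequent canonical
partition -- the modal partition -- is the one analysed; its restart share
measures partition stability.

Community detection always runs on the full weight matrix; the |rho| >= 0.1
sparsification exists only for export and visualisation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .scales import CohortDataset

__all__ = [
    "SymptomNetwork",
    "Partition",
    "PartitionCensus",
    "ModuleSummary",
    "spearman_network",
    "modularity",
    "louvain_once",
    "stable_partition",
    "summarise_modules",
    "between_domain_connectivity",
    "sparse_edges",
    "apriori_partition",
    "to_graphml",
]

logger = logging.getLogger(__name__)


@dataclass
class SymptomNetwork:
    """Item nodes with |Spearman| weights; the signed matrix is kept for export."""

    items: tuple[str, ...]
    domain_of: dict[str, str]
    W: np.ndarray  # symmetric, non-negative, zero diagonal
    signed_R: np.ndarray  # signed Spearman matrix, unit diagonal
    n_effective: float

    def __post_init__(self) -> None:
        p = len(self.items)
        if self.W.shape != (p, p):
            raise ValueError("weight matrix shape must match items")
        if not np.allclose(self.W, self.W.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(self.W) != 0):
            raise ValueError("weight matrix must have zero diagonal")
        if np.any(self.W < 0) or np.any(self.W > 1 + 1e-12):
            raise ValueError("weights must lie in [0, 1]")

    @property
    def n_items(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class Partition:
    """Canonical community assignment: ids numbered by first appearance."""

    labels: tuple[int, ...]

    @classmethod
    def from_labels(cls, labels) -> "Partition":
        seen: dict[int, int] = {}
        canon = []
        for raw in labels:
            if raw not in seen:
                seen[raw] = len(seen)
            canon.append(seen[raw])
        return cls(tuple(canon))

    @property
    def n_communities(self) -> int:
        return max(self.labels) + 1 if self.labels else 0

    def members(self, c: int) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.labels) == c)


@dataclass
class PartitionCensus:
    """Frequency census of canonical partitions over random restarts."""

    counts: dict[tuple[int, ...], int]
    modal: Partition
    modal_share: float
    n_restarts: int
    q_of: dict[tuple[int, ...], float] = field(default_factory=dict)


@dataclass
class ModuleSummary:
    """One detected module: members, dominant domain, purity, central node."""

    members: tuple[str, ...]
    modal_domain: str
    purity: float
    central_node: str
    intra_strengths: dict[str, float]


def _weighted_pearson(Z: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted product-moment correlation of columns; zero-variance -> NaN row/col."""
    sw = w.sum()
    mu = (w @ Z) / sw
    Zc = Z - mu
    C = Zc.T @ (Zc * w[:, None])
    v = np.diag(C).copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        R = C / np.sqrt(np.outer(v, v))
    R[v <= 0, :] = np.nan
    R[:, v <= 0] = np.nan
    return R


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average", axis=0)


def spearman_matrix(
    responses: pd.DataFrame,
    missing_mask: pd.DataFrame | None = None,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Signed Spearman correlation matrix with optional participant weights.

    Mid-ranks are used throughout.  With no missing data every item is
    ranked once over the participants carrying positive weight and a weighted
    Pearson correlation is taken on the rank columns; uniform weights reduce
    this exactly to the unweighted Spearman matrix.  With missing data the
    correlation is pairwise-complete: ranks are recomputed within each item
    pair's jointly observed participants.
    """
    X = responses.to_numpy(dtype=float)
    n, p = X.shape
    obs = (
        ~missing_mask.to_numpy(dtype=bool)
        if missing_mask is not None
        else ~np.isnan(X)
    )
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    active = w > 0
    if obs[active].all():
        Xa = X[active]
        R = _weighted_pearson(_rank(Xa), w[active])
    else:
        R = np.full((p, p), np.nan)
        np.fill_diagonal(R, 1.0)
        for i in range(p):
            for j in range(i + 1, p):
                sel = active & obs[:, i] & obs[:, j]
                if sel.sum() < 3:
                    continue
                zi = _rank(X[sel, i])
                zj = _rank(X[sel, j])
                R[i, j] = R[j, i] = _weighted_pearson(
                    np.column_stack([zi, zj]), w[sel]
                )[0, 1]
    return R


def effective_n(weights: np.ndarray) -> float:
    """Kish effective sample size (sum w)^2 / sum w^2; 0 for all-zero weights."""
    w = np.asarray(weights, dtype=float)
    s = w.sum()
    if s <= 0:
        return 0.0
    return float(s**2 / np.sum(w**2))


def spearman_network(
    ds: CohortDataset,
    weights: np.ndarray | None = None,
) -> SymptomNetwork:
    """Absolute-Spearman symptom network from a cohort dataset.

    Constant items (zero rank variance among the weighted participants) get
    all their edges set to 0, with a warning.
    """
    R = spearman_matrix(ds.responses, ds.missing_mask, weights)
    bad = np.isnan(R).any(axis=0)
    if bad.any():
        warnings.warn(
            "items with zero rank variance or insufficient pairwise data; "
            f"their edges are set to 0: {[ds.scale.items[i] for i in np.flatnonzero(bad)]}",
            stacklevel=2,
        )
        R = np.where(np.isnan(R), 0.0, R)
        np.fill_diagonal(R, 1.0)
    W = np.abs(R).copy()
    np.fill_diagonal(W, 0.0)
    W = np.clip((W + W.T) / 2.0, 0.0, 1.0)
    ess = effective_n(weights) if weights is not None else float(ds.n_participants)
    return SymptomNetwork(
        items=ds.scale.items,
        domain_of=dict(ds.scale.domain_of),
        W=W,
        signed_R=R,
        n_effective=ess,
    )


def modularity(net: SymptomNetwork, part: Partition) -> float:
    """Exact weighted modularity of a partition (A = W, k = strength)."""
    W = net.W
    two_m = W.sum()
    if two_m <= 0:
        raise ValueError("network has no edge weight (m = 0)")
    k = W.sum(axis=0)
    labels = np.asarray(part.labels)
    Q = 0.0
    for c in range(part.n_communities):
        sel = labels == c
        Q += W[np.ix_(sel, sel)].sum() / two_m - (k[sel].sum() / two_m) ** 2
    return float(Q)


def _local_moves(A: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    """Greedy local-move phase on a (possibly aggregated) weight matrix.

    Self-loop weights are allowed: they travel with the node, so they cancel
    out of every move comparison.  Returns (labels, any_move_made).
    """
    n = A.shape[0]
    two_m = A.sum()
    m = two_m / 2.0
    k = A.sum(axis=0)  # strength, self-loop counted once (consistent with 2m)
    labels = np.arange(n)
    sigma_tot = k.copy()
    off = A.copy()
    np.fill_diagonal(off, 0.0)
    moved_ever = False
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            c0 = labels[i]
            sigma_tot[c0] -= k[i]
            s = np.bincount(labels, weights=off[i], minlength=n)
            gains = s / m - k[i] * sigma_tot / (2.0 * m * m)
            # candidates: communities i connects to, its current one, and one
            # empty community (isolating i can be the best move)
            empty = np.flatnonzero(sigma_tot == 0)
            cand = np.flatnonzero((s > 0) | (np.arange(n) == c0))
            if empty.size and empty[0] not in cand:
                cand = np.sort(np.append(cand, empty[0]))
            best_gain = -np.inf
            best_c = c0
            for c in cand:  # ascending -> lowest id wins ties
                if gains[c] > best_gain + 1e-12:
                    best_gain = gains[c]
                    best_c = c
            if best_gain < gains[c0] + 1e-12:
                best_c = c0  # staying is never worse than an equal move
            labels[i] = best_c
            sigma_tot[best_c] += k[i]
            if best_c != c0:
                improved = True
                moved_ever = True
    return labels, moved_ever


def louvain_once(net: SymptomNetwork, seed: int = 0, single_level: bool = False) -> Partition:
    """One seeded Louvain run: greedy local moves, then community aggregation.

    Each node is moved to the community with maximal positive modularity
    gain (ties broken by the lowest community id); sweeps repeat until no
    move improves Q.  The converged communities are then contracted into
    super-nodes (edge weights summed, within-community weight becoming a
    self-loop) and the local-move phase repeats on the reduced graph, until a
    level makes no move.  ``single_level=True`` skips the aggregation phase
    and returns the first-level labelling directly (it can stall in local
    optima that a community-level merge would escape).
    """
    n = net.n_items
    if n < 2 or net.W.sum() <= 0:
        return Partition.from_labels([0] * n)
    rng = np.random.default_rng(seed)
    A = net.W.copy()
    node_of_item = np.arange(n)  # item -> current super-node
    while True:
        labels, moved = _local_moves(A, rng)
        # compact labels and project down to the original items
        _, compact = np.unique(labels, return_inverse=True)
        node_of_item = compact[node_of_item]
        if single_level or not moved or len(set(compact)) == A.shape[0]:
            break
        c = compact.max() + 1
        M = np.zeros((A.shape[0], c))
        M[np.arange(A.shape[0]), compact] = 1.0
        A = M.T @ A @ M  # aggregated graph; diagonal holds internal weight
    return Partition.from_labels(node_of_item)


def stable_partition(net: SymptomNetwork, n_restarts: int = 1000, seed: int = 0) -> PartitionCensus:
    """Restart census: run Louvain ``n_restarts`` times with derived sub-seeds
    and return the modal canonical partition.

    Frequency ties are broken by higher modularity, then by lexicographic
    canonical form.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be at least 1")
    sub_seeds = np.random.SeedSequence(seed).generate_state(n_restarts)
    counts: dict[tuple[int, ...], int] = {}
    q_of: dict[tuple[int, ...], float] = {}
    for s in sub_seeds:
        part = louvain_once(net, seed=int(s))
        key = part.labels
        counts[key] = counts.get(key, 0) + 1
        if key not in q_of:
            q_of[key] = modularity(net, part)
    modal_key = min(counts, key=lambda key: (-counts[key], -q_of[key], key))
    return PartitionCensus(
        counts=counts,
        modal=Partition(modal_key),
        modal_share=counts[modal_key] / n_restarts,
        n_restarts=n_restarts,
        q_of=q_of,
    )


def summarise_modules(
    net: SymptomNetwork,
    part: Partition,
    domain_of: dict[str, str] | None = None,
) -> list[ModuleSummary]:
    """Per-module summaries: members, modal a-priori domain, purity, central node.

    The central node maximises intra-modular strength (sum of weights to
    co-members; ties go to the first item in scale order, logged).  The modal
    domain is the most common member domain; a count tie is resolved by the
    central node's domain.
    """
    domain_of = domain_of or net.domain_of
    labels = np.asarray(part.labels)
    out: list[ModuleSummary] = []
    for c in range(part.n_communities):
        idx = np.flatnonzero(labels == c)
        members = tuple(net.items[i] for i in idx)
        sub = net.W[np.ix_(idx, idx)]
        strengths = sub.sum(axis=0)
        best = np.flatnonzero(strengths == strengths.max())
        if len(best) > 1:
            logger.info("central-node tie in module %d; first in item order chosen", c)
        central = members[best[0]]
        doms = [domain_of[it] for it in members]
        counts = pd.Series(doms).value_counts()
        top = counts[counts == counts.max()].index.tolist()
        modal_domain = domain_of[central] if len(top) > 1 and domain_of[central] in top else top[0]
        purity = counts[modal_domain] / len(members)
        out.append(
            ModuleSummary(
                members=members,
                modal_domain=modal_domain,
                purity=float(purity),
                central_node=central,
                intra_strengths=dict(zip(members, strengths)),
            )
        )
    return out


def between_domain_connectivity(
    net: SymptomNetwork, domain_of: dict[str, str] | None = None
) -> pd.Series:
    """Per item, the mean |Spearman| weight to items of other a-priori domains."""
    domain_of = domain_of or net.domain_of
    doms = np.array([domain_of[i] for i in net.items])
    if len(set(doms)) < 2:
        raise ValueError("between-domain connectivity needs at least 2 domains")
    vals = {}
    for i, item in enumerate(net.items):
        other = doms != doms[i]
        vals[item] = float(net.W[i, other].mean())
    return pd.Series(vals, name="between_domain_connectivity")


def sparse_edges(net: SymptomNetwork, threshold: float = 0.1) -> pd.DataFrame:
    """Edges with |rho| >= threshold, carrying the sign of the raw correlation.

    Export/visualisation only: community detection always uses the full W.
    """
    rows = []
    p = net.n_items
    for i in range(p):
        for j in range(i + 1, p):
            if net.W[i, j] >= threshold:
                rho = net.signed_R[i, j]
                rows.append({
                    "source": net.items[i],
                    "target": net.items[j],
                    "weight": float(net.W[i, j]),
                    "rho": float(rho),
                    "sign": "positive" if rho >= 0 else "negative",
                })
    return pd.DataFrame(rows, columns=["source", "target", "weight", "rho", "sign"])


def apriori_partition(net: SymptomNetwork, domain_of: dict[str, str] | None = None) -> Partition:
    """The fixed partition given by the items' a-priori domains."""
    domain_of = domain_of or net.domain_of
    doms = [domain_of[i] for i in net.items]
    order: dict[str, int] = {}
    for d in doms:
        order.setdefault(d, len(order))
    return Partition.from_labels([order[d] for d in doms])


def to_graphml(
    net: SymptomNetwork,
    path,
    partition: Partition | None = None,
    threshold: float = 0.1,
) -> None:
    """Write the sparsified network as GraphML with node and edge attributes."""
    import networkx as nx

    g = nx.Graph()
    bdc = between_domain_connectivity(net) if len(set(net.domain_of.values())) >= 2 else None
    for i, item in enumerate(net.items):
        attrs = {"domain": net.domain_of[item]}
        if bdc is not None:
            attrs["between_domain_connectivity"] = float(bdc[item])
        if partition is not None:
            attrs["module"] = int(partition.labels[i])
        g.add_node(item, **attrs)
    for _, row in sparse_edges(net, threshold).iterrows():
        g.add_edge(row["source"], row["target"], weight=row["weight"], rho=row["rho"], sign=row["sign"])
    nx.write_graphml(g, path)
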