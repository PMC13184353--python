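"""Shared fixtures: planted factor models, simulated cohorts, brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import apathynet as an
from apathynet.network import Partition, SymptomNetwork, modularity


@pytest.fixture(scope="session")
def ami_scale():
    return an.builtin_scale("AMI")


@pytest.fixture(scope="session")
def planted3(ami_scale):
    """AMI-shaped 3-factor model: domain blocks, loadings 0.7, phi 0.3."""
    return an.scale_factor_spec(ami_scale, within_load=0.7, between_corr=0.3)


@pytest.fixture(scope="session")
def cohort3_4000(planted3):
    return an.simulate_cohort(an.CohortSimSpec(n=4000, model=planted3, seed=11))


@pytest.fixture(scope="session")
def spec5_60():
    """60-item 5-block simple structure, loadings 0.7, phi 0.3."""
    return an.planted_module_spec(5, 12, 0.7, 0.3)


@pytest.fixture(scope="session")
def cohort5_5000(spec5_60):
    return an.simulate_cohort(an.CohortSimSpec(n=5000, model=spec5_60, seed=13))


def set_partitions(n: int):
    """All set partitions of range(n) as label vectors (restricted growth strings)."""
    def rec(i, labels, k):
        if i == n:
            yield tuple(labels)
            return
        for c in range(k + 1):
            labels.append(c)
            yield from rec(i + 1, labels, max(k, c + 1))
            labels.pop()

    yield from rec(0, [], 0)


def exhaustive_max_modularity(net: SymptomNetwork) -> tuple[float, Partition]:
    """Brute-force maximum-modularity partition (feasible for <= 9 nodes)."""
    best_q, best_p = -np.inf, None
    for labels in set_partitions(net.n_items):
        part = Partition.from_labels(labels)
        q = modularity(net, part)
        if q > best_q:
            best_q, best_p = q, part
    return best_q, best_p


def toy_network(W: np.ndarray, domains: list[str] | None = None) -> SymptomNetwork:
    """Wrap a weight matrix as a SymptomNetwork with dummy items."""
    p = W.shape[0]
    items = tuple(f"N{i}" for i in range(p))
    if domains is None:
        domains = ["Behavioural"] * p
    signed = W.copy()
    np.fill_diagonal(signed, 1.0)
    return SymptomNetwork(
        items=items,
        domain_of=dict(zip(items, domains)),
        W=W,
        signed_R=signed,
        n_effective=float(p),
    )


def two_triangles() -> SymptomNetwork:
    """Two disconnected unit-weight triangles (known max-Q partition, Q = 0.5)."""
    W = np.zeros((6, 6))
    for a, b in itertools.combinations(range(3), 2):
        W[a, b] = W[b, a] = 1.0
        W[a + 3, b + 3] = W[b + 3, a + 3] = 1.0
    return toy_network(W)


def random_connected_network(rng: np.random.Generator, n: int) -> SymptomNetwork:
    """Random weighted graph with noisy planted blocks, guaranteed connected.

    Mirrors the structure symptom networks actually show: a few strongly
    intra-connected groups with weaker, noisy links between them.
    """
    n_blocks = int(rng.integers(2, 4))
    blocks = rng.integers(0, n_blocks, size=n)
    W = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            if blocks[a] == blocks[b]:
                w = rng.uniform(0.4, 1.0)
            else:
                w = rng.uniform(0.0, 0.35) if rng.random() < 0.7 else 0.0
            W[a, b] = W[b, a] = w
    order = rng.permutation(n)
    for a, b in zip(order[:-1], order[1:]):
        if W[a, b] == 0:
            W[a, b] = W[b, a] = rng.uniform(0.05, 0.2)
    return toy_network(W)
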