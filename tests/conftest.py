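"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from eabspread.geo_network import DistanceMatrix, Location, pairwise_matrix
from eabspread.synthetic import NetworkSpec, generate_city_network


def haversine_km(lat1, lon1, lat2, lon2, radius_km=6371.0088):
    """Independent haversine distance oracle (numerically stable form)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlmb = math.radians(lon2) - math.radians(lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2) ** 2
    return radius_km * 2 * math.asin(min(1.0, math.sqrt(a)))


def enumerate_spread_probability(F: np.ndarray, seed_idx: int, n_steps: int) -> np.ndarray:
    """Brute-force oracle for the yearly transfer process.

    Each year every ordered pair (i, j), i != j, gets an independent
    Bernoulli transfer opportunity with probability F[i, j]; city j becomes
    infested the following year if any currently infested i succeeds, and
    infested cities stay infested.  Enumerates all coin outcomes exactly,
    so it is only usable for tiny networks/horizons.
    """
    n = F.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    marginal = np.zeros(n)
    coins_per_year = len(pairs)
    for outcome in itertools.product((0, 1), repeat=coins_per_year * n_steps):
        prob = 1.0
        for k, success in enumerate(outcome):
            p = F[pairs[k % coins_per_year]]
            prob *= p if success else 1.0 - p
        state = np.zeros(n, dtype=bool)
        state[seed_idx] = True
        for step in range(n_steps):
            new = state.copy()
            for k in range(coins_per_year):
                if outcome[step * coins_per_year + k]:
                    i, j = pairs[k]
                    if state[i]:
                        new[j] = True
            state = new
        marginal += prob * state
    return marginal


def random_distance_matrix(rng: np.random.Generator, n: int) -> DistanceMatrix:
    """Random symmetric zero-diagonal matrix from random points on a plane."""
    pts = rng.uniform(0, 500, size=(n, 2))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(ids=tuple(f"x{i}" for i in range(n)), d=d)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def triangle_locations():
    """Three equator cities at lon 0, 1, 2 degrees."""
    return [
        Location("a", "A", "X", "R1", 0.0, 0.0),
        Location("b", "B", "X", "R1", 0.0, 1.0),
        Location("c", "C", "Y", "R2", 0.0, 2.0),
    ]


@pytest.fixture
def small_network():
    """Deterministic 40-city clustered network with its distance matrix."""
    net = generate_city_network(NetworkSpec(n_cities=40, seed=7))
    return net, pairwise_matrix(net)
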