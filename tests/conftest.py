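"""Shared fixtures: reference models and helpers for oracle comparisons."""

import numpy as np
import pytest
from fractions import Fraction

import burstq as bq


@pytest.fixture(scope="session")
def telegraph_exact():
    """Exact-arithmetic telegraph arrival transform (alpha=1/4, beta=1, k_m=2)
    — the reference parameter set of the signature protocols."""
    params = bq.TelegraphParameters(Fraction(1, 4), Fraction(1), Fraction(2))
    return params, bq.telegraph_arrival_transform(params)


@pytest.fixture(scope="session")
def fig4_chain():
    """Activation chain of the multi-step promoter used in the burst-size
    estimation protocol (forward 1, .5, .25, .75; backward .1, .2, .5)."""
    return bq.chain_activation_transform((1.0, 0.5, 0.25, 0.75), (0.1, 0.2, 0.5))


def random_poisson_null_model(rng):
    """A random Poisson-arrival + conditional-geometric-burst model (the null
    class of the non-Poisson signatures)."""
    kb = rng.uniform(0.2, 5.0)
    mu_m = rng.uniform(0.2, 3.0)
    mu_p = mu_m * rng.uniform(0.005, 0.2)
    mb = rng.uniform(1.0, 15.0)
    pb = rng.uniform(0.2, 10.0)
    arrival = bq.exponential_transform(kb)
    burst = bq.BurstDistribution.conditional_geometric_from_mean(mb)
    protein = bq.BurstDistribution.geometric_from_mean(pb)
    return arrival, burst, protein, mu_m, mu_p


def random_telegraph_exact(rng):
    """Random telegraph parameters as exact rationals (for closed-form
    cross-checks at machine precision)."""
    frac = lambda lo, hi: Fraction(int(rng.integers(lo, hi)), int(rng.integers(8, 40)))
    alpha = frac(1, 30)
    beta = frac(1, 60)
    km = frac(5, 200)
    mb = 1 + Fraction(int(rng.integers(0, 120)), 10)
    kp = frac(1, 40)
    return alpha, beta, km, mb, kp
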