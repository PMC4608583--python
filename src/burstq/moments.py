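"""Exact steady-state moments for bursty gene expression.

The copy-number process (molecules arriving in i.i.d. batches on a renewal
event stream, each molecule decaying independently at rate ``mu``) is the
infinite-server batch queue GI^X/M/inf.  Its steady-state factorial moments
obey a triangular recursion in the Laplace transform ``f_L`` of the
interarrival law.  With ``t_j = f_L(j mu) / (1 - f_L(j mu))``, batch factorial
moments ``b_k`` and arrival rate ``k_b``:

``e_0 = 1``
``e_j = t_j * sum_{i<j} C(j, i) b_{j-i} e_i``
``m_k = (k_b / (k mu)) * sum_{j<k} C(k, j) b_{k-j} e_j``

Orders 1 and 2 reduce to the familiar mean ``m_1 = k_b b_1 / mu`` (Little's
law) and Fano factor ``F = 1 + (b_1/2)(K_g(mu) - 1) + b_2/(2 b_1)`` where
``K_g`` is the gestation factor; order 3 yields the skewness combination

``nu_3 / m_1 = 1 + m_1 b_1 K_1 + 2 b_1^2 K_2 + b_2 K_3 + b_3 / (3 b_1)``

with ``K_1 = K_g(2mu) - K_g(mu)``,
``K_2 = (K_g(mu) - 1)(3/b_1 + K_g(2mu) - 1)/4`` and
``K_3 = 3/(2 b_1) + (K_g(mu) + K_g(2mu))/2 - 1``.

Proteins in the burst limit (``mu_m >> mu_p``) are the same queue driven by
the compound burst moments ``A_k^p`` at decay rate ``mu_p``.  Beyond the
burst limit the finite mRNA lifetime is absorbed by rescaling: the excess
noise ``CV^2 - 1/<p_s>`` picks up a factor ``1/(1 + mu_p/mu_m)`` and, inside
the skewness formula, ``A_2 -> A_2 / (1 + mu_p/mu_m)`` and
``A_3 -> A_3 / [(1 + mu_p/mu_m)(1 + 2 mu_p/mu_m)]``; this reproduces the
exact two-stage results of the constitutive model and is a controlled
approximation for promoter-switching schemes.

All arithmetic is generic, so Fraction-valued inputs give exact rational
moments (used by the signature cross-checks).
"""

from __future__ import annotations

import math
import numbers
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Union

from .bursts import BurstDistribution, CompoundBurst
from .laplace import ArrivalProcess, InvalidModelError, RationalLaplaceTransform

__all__ = [
    "MomentSet",
    "GestationFactors",
    "gestation_factor",
    "steady_state_factorial_moments",
    "higher_factorial_moments",
    "mrna_moments",
    "protein_moments",
    "production_rate_from_means",
]


def _exact(x):
    if isinstance(x, numbers.Integral):
        return Fraction(x)
    return x


def _arrival(a) -> RationalLaplaceTransform:
    return a.interarrival if isinstance(a, ArrivalProcess) else a


@dataclass(frozen=True)
class MomentSet:
    """First moments of a steady-state copy-number distribution.

    ``third_central`` is ``nu_3 = gamma sigma^3``; the dimensionless skewness
    and the combination ``gamma sigma^3 / mean`` used throughout the moment
    formulas are exposed as properties.  ``se`` optionally carries bootstrap
    standard errors for empirical sets (keys ``mean``, ``variance``, ``fano``,
    ``skew_combination``, ``third_central``, ``fourth_central``).
    """

    mean: object
    variance: object
    third_central: object = None
    fourth_central: object = None
    se: Optional[dict] = None
    n_samples: Optional[int] = None
    degenerate: bool = False

    def __post_init__(self):
        if self.variance < 0:
            raise InvalidModelError("variance must be nonnegative")

    @property
    def fano(self):
        return self.variance / self.mean

    @property
    def skewness(self):
        """Conventional skewness ``nu_3 / sigma^3`` (None when undefined)."""
        if self.third_central is None or self.degenerate:
            return None
        return self.third_central / self.variance ** Fraction(3, 2) if isinstance(
            self.variance, Fraction
        ) else self.third_central / self.variance ** 1.5

    @property
    def skew_combination(self):
        """``gamma sigma^3 / mean = nu_3 / mean`` — the combination the
        steady-state skewness formula is written in."""
        if self.third_central is None:
            return None
        return self.third_central / self.mean

    def as_float(self) -> "MomentSet":
        f = lambda v: None if v is None else float(v)
        return MomentSet(
            float(self.mean), float(self.variance), f(self.third_central),
            f(self.fourth_central), self.se, self.n_samples, self.degenerate,
        )

    def raw_moments(self, order: int = 3):
        """``E[N^k]`` for k = 1..order (from the central moments)."""
        m = self.mean
        out = [m, self.variance + m * m]
        if order >= 3:
            if self.third_central is None:
                raise ValueError("third moment unavailable")
            out.append(self.third_central + 3 * m * out[1] - 2 * m ** 3)
        if order >= 4:
            if self.fourth_central is None:
                raise ValueError("fourth moment unavailable")
            out.append(self.fourth_central + 4 * m * out[2] - 6 * m * m * out[1] + 3 * m ** 4)
        return out[:order]

    def factorial_moments(self, order: int = 3):
        """Steady-state factorial moments ``E[N(N-1)...]`` for k = 1..order."""
        raw = self.raw_moments(order)
        out = [raw[0]]
        if order >= 2:
            out.append(raw[1] - raw[0])
        if order >= 3:
            out.append(raw[2] - 3 * raw[1] + 2 * raw[0])
        if order >= 4:
            out.append(raw[3] - 6 * raw[2] + 11 * raw[1] - 6 * raw[0])
        return out


@dataclass(frozen=True)
class GestationFactors:
    """``K_g`` evaluated at ``mu`` and ``2 mu`` plus the derived combinations
    entering the skewness formula (``b1`` is the mean batch size)."""

    kg_mu: object
    kg_2mu: object
    b1: object

    @property
    def K1(self):
        return self.kg_2mu - self.kg_mu

    @property
    def K2(self):
        return (self.kg_mu - 1) * (3 / _exact(self.b1) + self.kg_2mu - 1) / 4

    @property
    def K3(self):
        return 3 / (2 * _exact(self.b1)) + (self.kg_mu + self.kg_2mu) / 2 - 1


def gestation_factor(arrival, mu):
    """``K_g(mu) = 1 + 2 [f_L(mu)/(1 - f_L(mu)) - k_b/mu]``; equals 1 for
    Poisson arrivals at every rate."""
    if mu <= 0:
        raise InvalidModelError("mu must be positive")
    return _arrival(arrival).gestation_factor(mu)


def steady_state_factorial_moments(arrival, batch_factorial_moments, mu, order: int = 3):
    """The batch-renewal recursion; returns ``[m_1, ..., m_order]``."""
    if not 1 <= order <= 4:
        raise ValueError("order must be in 1..4")
    f = _arrival(arrival)
    mu = _exact(mu)
    if mu <= 0:
        raise InvalidModelError("mu must be positive")
    b = list(batch_factorial_moments) + [0] * 4
    kb = f.mean_rate
    t = [None]
    for j in range(1, order):
        fj = f(j * mu)
        if fj >= 1:
            raise InvalidModelError("recursion divergence: f_L(k mu) >= 1")
        t.append(f.odds(j * mu))
    e = [1]
    for j in range(1, order):
        acc = 0
        for i in range(j):
            acc += math.comb(j, i) * b[j - i - 1] * e[i]
        e.append(t[j] * acc)
    out = []
    for k in range(1, order + 1):
        acc = 0
        for j in range(k):
            acc += math.comb(k, j) * b[k - j - 1] * e[j]
        out.append(kb / (k * mu) * acc)
    return out


def higher_factorial_moments(arrival, burst: BurstDistribution, mu, order: int = 4):
    """Steady-state factorial moments for a named burst distribution."""
    return steady_state_factorial_moments(
        arrival, burst.factorial_moments(order), mu, order
    )


def _central_from_factorial(m):
    """(mean, variance, nu3[, nu4]) from factorial moments m_1.. ."""
    m1 = m[0]
    raw2 = m[1] + m1
    var = raw2 - m1 * m1
    out = [m1, var]
    if len(m) >= 3:
        raw3 = m[2] + 3 * m[1] + m1
        out.append(raw3 - 3 * raw2 * m1 + 2 * m1 ** 3)
    if len(m) >= 4:
        raw4 = m[3] + 6 * m[2] + 7 * m[1] + m1
        out.append(raw4 - 4 * raw3 * m1 + 6 * raw2 * m1 * m1 - 3 * m1 ** 4)
    return out


def mrna_moments(arrival, mrna_burst: BurstDistribution, mu_m, order: int = 3) -> MomentSet:
    """Steady-state mRNA moments: mean ``k_b <m_b>/mu_m``, Fano
    ``1 + (<m_b>/2)(K_g(mu_m) - 1) + <m_b(m_b-1)>/(2 <m_b>)``, and the exact
    third (and optionally fourth) moments from the recursion."""
    fm = higher_factorial_moments(arrival, mrna_burst, mu_m, order)
    cen = _central_from_factorial(fm)
    return MomentSet(*cen[:2], *(cen[2:3] or [None]), *(cen[3:4] or [None]))


def protein_moments(
    arrival,
    compound: CompoundBurst,
    mu_m,
    mu_p,
    mode: str = "scaled",
    order: int = 3,
) -> MomentSet:
    """Steady-state protein moments.

    ``mode="burst_limit"`` treats protein bursts as instantaneous (exact for
    ``mu_m >> mu_p``); ``mode="scaled"`` applies the finite-lifetime scaling
    of the burst parameters and is the default.
    """
    if mode not in ("burst_limit", "scaled"):
        raise ValueError("mode must be 'burst_limit' or 'scaled'")
    if mu_m <= 0 or mu_p <= 0:
        raise InvalidModelError("decay rates must be positive")
    mu_p = _exact(mu_p)
    mu_m = _exact(mu_m)
    A = compound.factorial_moments(4)
    if mode == "burst_limit":
        fm = steady_state_factorial_moments(arrival, A, mu_p, order)
        cen = _central_from_factorial(fm)
        return MomentSet(*cen[:2], *(cen[2:3] or [None]), *(cen[3:4] or [None]))
    x = mu_p / mu_m
    f = _arrival(arrival)
    kb = f.mean_rate
    A1, A2, A3 = A[0], A[1], A[2]
    mean = kb * A1 / mu_p
    # variance: scale the whole excess-noise bracket by 1/(1+x)
    var_bl = _central_from_factorial(
        steady_state_factorial_moments(arrival, A, mu_p, 2)
    )[1]
    var = mean + (var_bl - mean) / (1 + x)
    third = None
    if order >= 3:
        K = GestationFactors(f.gestation_factor(mu_p), f.gestation_factor(2 * mu_p), A1)
        A2s = A2 / (1 + x)
        A3s = A3 / ((1 + x) * (1 + 2 * x))
        skc = 1 + mean * A1 * K.K1 + 2 * A1 ** 2 * K.K2 + A2s * K.K3 + A3s / (3 * A1)
        third = skc * mean
    return MomentSet(mean, var, third, None)


def production_rate_from_means(mean_m, mean_p, mu_m, mu_p):
    """Infer ``b/<m_b> = (mu_p/mu_m)(<p_s>/<m_s>)`` and hence the protein
    production rate ``k_p = mu_m * (b/<m_b>)``; valid for arbitrary arrival
    processes because the means follow from Little's law alone."""
    if mean_m <= 0:
        raise InvalidModelError("mRNA mean must be positive")
    if mean_p <= 0 or mu_m <= 0 or mu_p <= 0:
        raise InvalidModelError("inputs must be positive")
    ratio = (mu_p / mu_m) * (mean_p / mean_m)
    return ratio, ratio * mu_m
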