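"""Burst-size distributions and their factorial moments.

A transcriptional burst delivers a random number of mRNAs; each mRNA then
yields a random number of proteins.  The moment formulas consume only the
factorial moments ``<X>, <X(X-1)>, <X(X-1)(X-2)>, ...`` of the batch law, so
every distribution here exposes exact closed-form factorial moments.

Two geometric conventions coexist in the bursting literature and both are
provided under explicit names:

* ``geometric_from_mean(m)`` — support {0, 1, 2, ...}, variance m(1+m).
* ``conditional_geometric_from_mean(m)`` — support {1, 2, ...} (a burst makes
  at least one mRNA), variance m(m-1).  At m = 1 it degenerates to exactly one
  mRNA per event, which unifies single-mRNA arrivals and bursty arrivals in
  one family.

The number of proteins made by all mRNAs of one burst is the compound random
variable with pgf ``A^p(z) = A^m(a^p(z))``; `compose` carries its factorial
moments ``A_k^p`` through the Bell-polynomial chain rule.
"""

from __future__ import annotations

import math
import numbers
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np

from .laplace import InvalidModelError

__all__ = ["BurstDistribution", "CompoundBurst", "compose", "factorial_moments"]

#: tail mass below which empirical pmfs are truncated for moment sums
EMPIRICAL_TAIL_TOL = 1e-12


def _exact(x):
    if isinstance(x, numbers.Integral):
        return Fraction(x)
    return x


@dataclass(frozen=True)
class BurstDistribution:
    """A batch-size law identified by ``kind`` plus its parameters.

    Construct through the classmethods; the generic constructor is only for
    ``empirical_pmf`` round-trips.
    """

    kind: str
    mean: object = None
    r: object = None
    p: object = None
    pmf: Optional[tuple] = None

    # -- constructors --------------------------------------------------------

    @classmethod
    def unit(cls) -> "BurstDistribution":
        """Exactly one molecule per event (no bursting)."""
        return cls(kind="unit", mean=1)

    @classmethod
    def geometric_from_mean(cls, mean) -> "BurstDistribution":
        """Geometric on {0,1,2,...}: ``P(n) = m^n / (1+m)^(n+1)``."""
        if mean < 0:
            raise InvalidModelError("geometric mean must be >= 0")
        return cls(kind="geometric", mean=_exact(mean))

    @classmethod
    def conditional_geometric_from_mean(cls, mean) -> "BurstDistribution":
        """Geometric conditioned on n >= 1: ``P(n) = (1-p)^(n-1) p`` with
        ``p = 1/mean``; variance ``mean (mean - 1)``."""
        if mean < 1:
            raise InvalidModelError("conditional geometric mean must be >= 1")
        return cls(kind="conditional_geometric", mean=_exact(mean))

    @classmethod
    def negative_binomial(cls, r, p) -> "BurstDistribution":
        """``P(n) = C(n+r-1, n) p^n (1-p)^r`` on {0,1,2,...}; r = 1 recovers
        the geometric law."""
        if not (0 < p < 1) or r < 1:
            raise InvalidModelError("need 0 < p < 1 and r >= 1")
        r, p = _exact(r), _exact(p)
        return cls(kind="negative_binomial", mean=r * p / (1 - p), r=r, p=p)

    @classmethod
    def empirical(cls, pmf: Sequence[float]) -> "BurstDistribution":
        arr = np.asarray(pmf, dtype=float)
        if np.any(arr < 0) or abs(arr.sum() - 1.0) > 1e-9:
            raise InvalidModelError("pmf must be nonnegative and sum to 1")
        mean = float(np.dot(np.arange(arr.size), arr))
        return cls(kind="empirical_pmf", mean=mean, pmf=tuple(arr))

    # -- moments -------------------------------------------------------------

    @property
    def variance(self):
        m = self.mean
        if self.kind == "unit":
            return 0
        if self.kind == "geometric":
            return m * (1 + m)
        if self.kind == "conditional_geometric":
            return m * (m - 1)
        if self.kind == "negative_binomial":
            return self.mean / (1 - self.p)
        b1, b2 = self.factorial_moment(1), self.factorial_moment(2)
        return b2 + b1 - b1 * b1

    def factorial_moment(self, order: int):
        """``E[X (X-1) ... (X-order+1)]``, exact for the parametric kinds."""
        if order == 0:
            return 1
        if order < 0:
            raise ValueError("order must be >= 0")
        m = self.mean
        if self.kind == "unit":
            return 1 if order == 1 else 0
        if self.kind == "geometric":
            self._check_order(order)
            return math.factorial(order) * m ** order
        if self.kind == "conditional_geometric":
            self._check_order(order)
            return math.factorial(order) * m * (m - 1) ** (order - 1)
        if self.kind == "negative_binomial":
            self._check_order(order)
            q = self.p / (1 - self.p)
            out = q ** order
            for j in range(order):
                out = out * (self.r + j)
            return out
        if self.kind == "empirical_pmf":
            arr = np.asarray(self.pmf)
            keep = np.cumsum(arr[::-1])[::-1] > EMPIRICAL_TAIL_TOL
            n = np.arange(arr.size, dtype=float)
            w = np.ones_like(n)
            for j in range(order):
                w = w * (n - j)
            return float(np.dot(np.where(keep, arr, 0.0), np.clip(w, 0, None)))
        raise InvalidModelError(f"unknown burst kind {self.kind!r}")

    @staticmethod
    def _check_order(order):
        if order > 4:
            raise ValueError("closed-form kinds provide factorial moments up to order 4")

    def factorial_moments(self, max_order: int):
        return [self.factorial_moment(k) for k in range(1, max_order + 1)]

    # -- sampling (host-side reference; the SSA has its own inlined samplers)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "unit":
            return np.ones(size, dtype=np.int64)
        if self.kind == "geometric":
            return rng.geometric(1.0 / (1.0 + float(self.mean)), size) - 1
        if self.kind == "conditional_geometric":
            return rng.geometric(1.0 / float(self.mean), size)
        if self.kind == "negative_binomial":
            return rng.negative_binomial(float(self.r), 1.0 - float(self.p), size)
        if self.kind == "empirical_pmf":
            return rng.choice(len(self.pmf), size=size, p=np.asarray(self.pmf))
        raise InvalidModelError(f"unknown burst kind {self.kind!r}")


def factorial_moments(d: BurstDistribution, max_order: int):
    """Module-level alias for :meth:`BurstDistribution.factorial_moments`."""
    return d.factorial_moments(max_order)


@dataclass(frozen=True)
class CompoundBurst:
    """Protein output of one transcriptional burst: the sum over the burst's
    mRNAs of i.i.d. per-mRNA protein bursts."""

    mrna_burst: BurstDistribution
    per_mrna_protein_burst: BurstDistribution
    _A: tuple = field(default=None, compare=False)

    @property
    def A(self) -> tuple:
        return self._A

    def factorial_moment(self, order: int):
        if order == 0:
            return 1
        return self._A[order - 1]

    def factorial_moments(self, max_order: int):
        return list(self._A[:max_order])

    @property
    def mean(self):
        return self._A[0]

    @property
    def is_geometric(self) -> bool:
        """True when the compound is itself geometric (conditional-geometric
        mRNA bursts composed with geometric protein bursts)."""
        return (
            self.mrna_burst.kind in ("conditional_geometric", "unit")
            and self.per_mrna_protein_burst.kind == "geometric"
        )


def compose(mrna_burst: BurstDistribution, protein_burst: BurstDistribution) -> CompoundBurst:
    """Factorial moments ``A_k^p`` of the compound protein burst, k = 1..4.

    Faà di Bruno for ``A^p(z) = A^m(a^p(z))`` at ``z = 1`` in terms of the
    component factorial moments (``B`` = mRNA, ``g`` = per-mRNA protein):

    ``A_1 = B_1 g_1``
    ``A_2 = B_2 g_1^2 + B_1 g_2``
    ``A_3 = B_3 g_1^3 + 3 B_2 g_1 g_2 + B_1 g_3``
    ``A_4 = B_4 g_1^4 + B_3 6 g_1^2 g_2 + B_2 (4 g_1 g_3 + 3 g_2^2) + B_1 g_4``
    """
    B = [mrna_burst.factorial_moment(k) for k in range(1, 5)]
    g = [protein_burst.factorial_moment(k) for k in range(1, 5)]
    A1 = B[0] * g[0]
    A2 = B[1] * g[0] ** 2 + B[0] * g[1]
    A3 = B[2] * g[0] ** 3 + 3 * B[1] * g[0] * g[1] + B[0] * g[2]
    A4 = (
        B[3] * g[0] ** 4
        + 6 * B[2] * g[0] ** 2 * g[1]
        + B[1] * (4 * g[0] * g[2] + 3 * g[1] ** 2)
        + B[0] * g[3]
    )
    for k, a in enumerate((A1, A2, A3, A4), start=1):
        if a < 0:
            raise InvalidModelError(f"compound factorial moment A_{k} negative")
    return CompoundBurst(mrna_burst, protein_burst, _A=(A1, A2, A3, A4))
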