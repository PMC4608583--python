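"""Laplace-domain models of waiting times between production events.

Renewal arrival processes are represented by the Laplace transform of their
interarrival-time density.  For promoter-driven transcription these transforms
are rational functions of the Laplace variable ``s`` (phase-type waiting
times), so we store them as a pair of real polynomial coefficient vectors with
the constant terms normalised to 1.  This representation supports

* exact evaluation of the transform and of the gestation factor
  ``K_g(mu) = 1 + 2 [ f_L(mu)/(1 - f_L(mu)) - k_b/mu ]`` without the
  catastrophic cancellation that a naive evaluation suffers near ``s = 0``,
* the promoter-to-arrival conversion
  ``f_L(s) = k_m / (k_m + s + (1 - g_L(s)) beta)`` mapping the OFF->ON
  activation waiting time ``g(t)`` to the waiting time between successive
  production events (the state after every production event is ON, so those
  waiting times are i.i.d. and the event stream is renewal),
* inversion to the time domain by partial fractions over the denominator
  roots.

All coefficient arithmetic is generic: `fractions.Fraction` inputs stay exact
through every operation, which the moment pipeline uses for closed-form
cross-checks.
"""

from __future__ import annotations

import math
import numbers
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np

__all__ = [
    "InvalidModelError",
    "RationalLaplaceTransform",
    "ArrivalProcess",
    "TelegraphParameters",
    "exponential_transform",
    "erlang_transform",
    "hypoexponential_transform",
    "telegraph_arrival_transform",
    "chain_activation_transform",
    "f_from_g",
    "mean_arrival_rate",
    "invert_to_density",
    "survival_values",
]

#: absolute tolerance on f_L(0) = 1 when validating external coefficient input
NORMALISATION_TOL = 1e-10

#: pole-clustering tolerance used to detect repeated denominator roots during
#: partial-fraction inversion
POLE_CLUSTER_TOL = 1e-8


class InvalidModelError(ValueError):
    """Raised when a waiting-time or kinetic model violates its invariants."""


# ----------------------------------------------------------------------------
# generic polynomial helpers (ascending coefficients, Fraction-safe)
# ----------------------------------------------------------------------------

def _trim(coeffs):
    c = list(coeffs)
    while len(c) > 1 and c[-1] == 0:
        c.pop()
    return tuple(c)


def _poly_eval(coeffs, s):
    out = coeffs[-1]
    for c in reversed(coeffs[:-1]):
        out = out * s + c
    return out


def _poly_add(a, b):
    n = max(len(a), len(b))
    a = tuple(a) + (0,) * (n - len(a))
    b = tuple(b) + (0,) * (n - len(b))
    return _trim(x + y for x, y in zip(a, b))


def _poly_scale(a, k):
    return _trim(c * k for c in a)


def _poly_shift(a):
    """Multiply by s (prepend a zero coefficient)."""
    return (0,) + tuple(a)


def _as_exact(x):
    """Promote ints to Fraction so mixed arithmetic stays exact when possible."""
    if isinstance(x, numbers.Integral):
        return Fraction(x)
    return x


@dataclass(frozen=True)
class RationalLaplaceTransform:
    """A normalised rational Laplace transform ``f_L(s) = N(s) / D(s)``.

    Coefficients are ascending; ``numer[0] == denom[0] == 1`` so that
    ``f_L(0) = 1`` holds exactly (normalisation of the underlying density).
    The denominator degree strictly exceeds the numerator degree.
    """

    numer: tuple = (1,)
    denom: tuple = (1, 1)
    label: str = field(default="rational", compare=False)

    def __post_init__(self):
        numer = _trim(self.numer)
        denom = _trim(self.denom)
        if numer[0] == 0 or denom[0] == 0:
            raise InvalidModelError("transform has vanishing constant term")
        # external input may arrive un-normalised; rescale so f_L(0) = 1
        if numer[0] != 1 or denom[0] != 1:
            ratio = float(numer[0]) / float(denom[0])
            if abs(ratio - 1.0) > NORMALISATION_TOL:
                raise InvalidModelError(
                    f"transform not normalised: f_L(0) = {ratio!r}"
                )
            numer = tuple(c / numer[0] for c in numer)
            denom = tuple(c / denom[0] for c in denom)
        if len(denom) <= len(numer):
            raise InvalidModelError(
                "denominator degree must strictly exceed numerator degree"
            )
        object.__setattr__(self, "numer", numer)
        object.__setattr__(self, "denom", denom)
        if self.mean_interarrival <= 0:
            raise InvalidModelError("mean interarrival time must be positive")

    # -- evaluation ----------------------------------------------------------

    def __call__(self, s):
        return _poly_eval(self.numer, s) / _poly_eval(self.denom, s)

    @property
    def survival_poly(self):
        """``Q(s) = (D(s) - N(s)) / s`` so that ``1 - f_L(s) = s Q(s)/D(s)``.

        Exact polynomial division: the constant terms cancel identically.
        """
        diff = _poly_add(self.denom, _poly_scale(self.numer, -1))
        if diff[0] != 0:
            raise InvalidModelError("constant terms must cancel in D - N")
        return _trim(diff[1:]) if len(diff) > 1 else (0,)

    @property
    def mean_interarrival(self):
        """``E[T] = -f_L'(0) = Q(0)``."""
        return self.survival_poly[0]

    @property
    def mean_rate(self):
        """Mean event rate ``1 / E[T]``."""
        return 1 / _as_exact(self.mean_interarrival)

    def odds(self, s):
        """``f_L(s) / (1 - f_L(s)) = N(s) / (s Q(s))`` — stable for small s."""
        q = _poly_eval(self.survival_poly, s)
        den = s * q
        if den == 0:
            raise InvalidModelError("f_L(s) = 1: degenerate interarrival mass")
        return _poly_eval(self.numer, s) / den

    # -- gestation factor ----------------------------------------------------

    @property
    def _excess_poly(self):
        """``R(s) = (N(s) - Q(s)/Q(0)) / s``; again an exact division."""
        q = self.survival_poly
        q0 = _as_exact(q[0])
        diff = _poly_add(self.numer, _poly_scale(q, -1 / q0))
        if len(diff) == 1 and diff[0] == 0:
            return (0,)
        if abs(float(diff[0])) > NORMALISATION_TOL:
            raise InvalidModelError("inconsistent normalisation in R(s)")
        rest = diff[1:] if len(diff) > 1 else (0,)
        return _trim(rest)

    def gestation_factor(self, mu):
        """``K_g(mu) = 1 + 2 R(mu) / Q(mu)``.

        Algebraically identical to ``1 + 2[f/(1-f) - k_b/mu]`` but free of the
        ``O(1/mu)`` cancellation, so it is accurate down to ``mu = 0`` (where
        it returns ``(CV_T^2 + 1)/2``-type information about the interarrival
        law).
        """
        if mu < 0:
            raise InvalidModelError("K_g is defined for rates mu >= 0")
        q = _poly_eval(self.survival_poly, mu)
        if q == 0:
            raise InvalidModelError("denominator of K_g vanished")
        return 1 + 2 * _poly_eval(self._excess_poly, mu) / q

    def gestation_factor_slope0(self):
        """``d K_g / d mu`` at ``mu = 0`` (needed for burst-limit statistics)."""
        q = self.survival_poly
        r = self._excess_poly
        q0, q1 = _as_exact(q[0]), (q[1] if len(q) > 1 else 0)
        r0, r1 = r[0], (r[1] if len(r) > 1 else 0)
        return 2 * (r1 * q0 - r0 * q1) / (q0 * q0)

    # -- conversions ---------------------------------------------------------

    def as_float(self) -> "RationalLaplaceTransform":
        return RationalLaplaceTransform(
            tuple(float(c) for c in self.numer),
            tuple(float(c) for c in self.denom),
            label=self.label,
        )


@dataclass(frozen=True)
class TelegraphParameters:
    """Two-state promoter: OFF -> ON at ``on_rate`` (alpha), ON -> OFF at
    ``off_rate`` (beta), production at ``transcription_rate`` (k_m) while ON."""

    on_rate: float
    off_rate: float
    transcription_rate: float

    def __post_init__(self):
        if not (self.on_rate > 0 and self.off_rate > 0 and self.transcription_rate > 0):
            raise InvalidModelError("telegraph rates must be strictly positive")


@dataclass(frozen=True)
class ArrivalProcess:
    """A renewal stream of (burst) arrival events."""

    interarrival: RationalLaplaceTransform

    @property
    def mean_rate(self):
        return self.interarrival.mean_rate

    def gestation_factor(self, mu):
        return self.interarrival.gestation_factor(mu)


# ----------------------------------------------------------------------------
# constructors
# ----------------------------------------------------------------------------

def exponential_transform(rate) -> RationalLaplaceTransform:
    """Poisson arrivals: ``f_L(s) = rate / (rate + s)``."""
    if rate <= 0:
        raise InvalidModelError("rate must be positive")
    return RationalLaplaceTransform((1,), (1, 1 / _as_exact(rate)), label="exponential")


def erlang_transform(shape: int, stage_rate) -> RationalLaplaceTransform:
    """Erlang(shape) waiting time: ``(rate/(rate+s))^shape``."""
    if shape < 1:
        raise InvalidModelError("shape must be >= 1")
    lam = _as_exact(stage_rate)
    denom = (1,)
    for _ in range(shape):
        denom = _poly_add(denom, _poly_shift(_poly_scale(denom, 1 / lam)))
    return RationalLaplaceTransform((1,), denom, label=f"erlang{shape}")


def hypoexponential_transform(rates: Sequence) -> RationalLaplaceTransform:
    """Sum of independent exponentials with distinct (or equal) rates."""
    denom = (1,)
    for r in rates:
        if r <= 0:
            raise InvalidModelError("rates must be positive")
        denom = _poly_add(denom, _poly_shift(_poly_scale(denom, 1 / _as_exact(r))))
    return RationalLaplaceTransform((1,), denom, label="hypoexponential")


def telegraph_arrival_transform(params: TelegraphParameters) -> RationalLaplaceTransform:
    """Waiting time between successive production events of a two-state
    promoter, started in the ON state:

    ``f_L(s) = k_m (alpha + s) / [ k_m (alpha + s) + s (alpha + beta + s) ]``.

    Valid both for single-mRNA production and for batch firing at rate
    ``k_m`` while ON — the inter-event law is the same.
    """
    a = _as_exact(params.on_rate)
    b = _as_exact(params.off_rate)
    km = _as_exact(params.transcription_rate)
    numer = (1, 1 / a)
    denom = (1, (km + a + b) / (km * a), 1 / (km * a))
    return RationalLaplaceTransform(numer, denom, label="telegraph")


def chain_activation_transform(forward_rates: Sequence, backward_rates: Sequence = ()) -> RationalLaplaceTransform:
    """First-passage waiting time of a promoter activation chain.

    The inactive promoter walks ``D_0 -> D_1 -> ... -> D_K -> ON`` with
    forward rates ``alpha_1..alpha_{K+1}`` and optional backward rates
    ``beta_1..beta_K`` (``D_j -> D_{j-1}``).  Returns the Laplace transform of
    the first-passage time from ``D_0`` to ON, computed exactly with Fraction
    linear algebra on the transient generator.
    """
    import sympy as sp

    k = len(forward_rates)
    if k == 0:
        raise InvalidModelError("need at least one forward rate")
    if len(backward_rates) >= k:
        raise InvalidModelError("too many backward rates for the chain length")
    s = sp.Symbol("s")
    n = k  # transient states D_0..D_{k-1}
    T = sp.zeros(n, n)
    for i, a in enumerate(forward_rates):
        a = sp.nsimplify(a, rational=True)
        if i + 1 < n:
            T[i, i + 1] += a
        T[i, i] -= a
    for i, b in enumerate(backward_rates):
        b = sp.nsimplify(b, rational=True)
        T[i + 1, i] += b
        T[i + 1, i + 1] -= b
    absorb = sp.zeros(n, 1)
    absorb[n - 1, 0] = sp.nsimplify(forward_rates[-1], rational=True)
    e0 = sp.zeros(1, n)
    e0[0, 0] = 1
    gl = sp.cancel((e0 * (s * sp.eye(n) - T).inv() * absorb)[0, 0])
    num, den = sp.fraction(sp.together(gl))
    pnum = sp.Poly(num, s).all_coeffs()[::-1]
    pden = sp.Poly(den, s).all_coeffs()[::-1]
    c0 = pnum[0]

    def _frac(c):
        r = sp.Rational(c / c0)
        return Fraction(int(r.p), int(r.q))

    numer = tuple(_frac(c) for c in pnum)
    denom = tuple(_frac(c) for c in pden)
    return RationalLaplaceTransform(numer, denom, label="chain")


# ----------------------------------------------------------------------------
# operations
# ----------------------------------------------------------------------------

def f_from_g(g: RationalLaplaceTransform, k_m, beta) -> RationalLaplaceTransform:
    """Convert an activation waiting time ``g`` into the production-event
    waiting time ``f_L(s) = k_m / (k_m + s + (1 - g_L(s)) beta)``.

    With ``1 - g_L = s Q_g / D_g`` this reduces to the rational canonical form
    ``N_f = D_g`` and ``D_f = D_g + s (D_g + beta Q_g) / k_m``.
    """
    if k_m <= 0 or beta <= 0:
        raise InvalidModelError("k_m and beta must be strictly positive")
    k_m = _as_exact(k_m)
    beta = _as_exact(beta)
    dg = g.denom
    qg = g.survival_poly
    inner = _poly_add(dg, _poly_scale(qg, beta))
    denom = _poly_add(dg, _poly_shift(_poly_scale(inner, 1 / k_m)))
    return RationalLaplaceTransform(dg, denom, label="f_from_g")


def mean_arrival_rate(f: RationalLaplaceTransform):
    """``k_b = 1 / E[T]`` with ``E[T] = -f_L'(0)`` taken exactly."""
    et = f.mean_interarrival
    if et <= 0:
        raise InvalidModelError("mean interarrival must be positive")
    return 1 / _as_exact(et)


def _partial_fraction_terms(numer, denom):
    """Residue expansion of numer/denom (ascending float coeffs).

    Returns a list of ``(residue, pole, power)`` with ``power >= 1`` such that
    the inverse transform is ``sum r * t^(power-1)/(power-1)! * exp(pole t)``.
    """
    from scipy import signal

    b = np.array([float(c) for c in reversed(numer)])
    a = np.array([float(c) for c in reversed(denom)])
    if not (np.all(np.isfinite(b)) and np.all(np.isfinite(a))):
        raise InvalidModelError("non-finite transform coefficients")
    r, p, k = signal.residue(b, a, tol=POLE_CLUSTER_TOL, rtype="avg")
    if k.size and np.any(np.abs(k) > 1e-12):
        raise InvalidModelError("transform is not strictly proper")
    terms = []
    i = 0
    while i < len(p):
        j = i
        while j + 1 < len(p) and abs(p[j + 1] - p[i]) <= POLE_CLUSTER_TOL * max(1.0, abs(p[i])):
            j += 1
        for power, idx in enumerate(range(i, j + 1), start=1):
            terms.append((r[idx], p[i], power))
        i = j + 1
    return terms


def invert_to_density(f: RationalLaplaceTransform, t_grid) -> np.ndarray:
    """Invert ``f_L`` to the time-domain density on ``t_grid``.

    Partial-fraction expansion over the (possibly complex, possibly repeated)
    denominator roots; residual imaginary parts below tolerance are discarded.
    """
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < 0):
        raise InvalidModelError("t_grid must be nonnegative")
    terms = _partial_fraction_terms(f.numer, f.denom)
    vals = np.zeros(t.shape, dtype=complex)
    for r, p, power in terms:
        vals += r * t ** (power - 1) / math.factorial(power - 1) * np.exp(p * t)
    out = vals.real
    max_imag = float(np.max(np.abs(vals.imag))) if t.size else 0.0
    if max_imag > 1e-8 * max(1.0, float(np.max(np.abs(out)))):
        raise InvalidModelError(f"partial-fraction inversion left imaginary residue {max_imag}")
    return out


def survival_values(f: RationalLaplaceTransform, t_grid) -> np.ndarray:
    """``S(t) = P(T > t)``, inverted from ``(1 - f_L(s))/s = Q(s)/D(s)``."""
    t = np.asarray(t_grid, dtype=float)
    terms = _partial_fraction_terms(f.survival_poly, f.denom)
    vals = np.zeros(t.shape, dtype=complex)
    for r, p, power in terms:
        vals += r * t ** (power - 1) / math.factorial(power - 1) * np.exp(p * t)
    return vals.real
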