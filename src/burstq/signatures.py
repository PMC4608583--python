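"""Moment-based signatures of non-Poisson burst arrival and non-geometric
burst-size distributions.

All four statistics are combinations of experimentally measurable steady-state
moments, built so that a reference model class pins their value:

* ``D_m = [gamma_m sigma_m^3/<m_s>] / [3(F_m-1){1 + (2/3)(F_m-1)} + 1] - 1``
  vanishes for Poisson burst arrival with conditional-geometric mRNA bursts.
* ``D_p`` is the protein analogue; the finite protein lifetime enters through
  the curvature factor ``(mu_m + mu_p)/(mu_m + 2 mu_p)``.
* ``D_mp = F_m/(mu_m <m_s>) - (mu_m + mu_p)(F_p - 1)/(mu_m mu_p <p_s>)``
  equals ``[K_g(mu_m) - K_g(mu_p)]/(2 k_b)`` and therefore vanishes for
  Poisson arrivals with *arbitrary* mRNA burst distributions; it needs no
  third moments.
* ``G_m`` combines mRNA moments measured at two degradation rates ``mu_m``
  and ``2 mu_m`` (same burst process) and equals 1 for conditional-geometric
  bursts under any renewal arrival process:

  ``G_m = [gamma sigma^3/<m_s> - 1 - 2 F_m(2mu)(<m_s> - 1)]
          / [F_m(mu)(1 - 2<m_s> + 2 F_m(2mu)) - 1]``.

For the two-state telegraph scheme firing conditional-geometric batches at
rate ``k_m`` while ON, the statistics have exact closed forms (functions of
``alpha, beta, k_m, <m_b>, k_p``) which `telegraph_closed_forms` evaluates;
the module's analytic pipeline reproduces them to rounding error, and
bootstrap confidence intervals are provided for empirical inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .laplace import InvalidModelError, TelegraphParameters
from .moments import MomentSet

__all__ = [
    "UndefinedSignatureError",
    "RatePairingWarning",
    "SignatureReport",
    "signature_Dm",
    "signature_Dp",
    "signature_Dmp",
    "signature_Gm",
    "telegraph_closed_forms",
    "signatures_from_samples",
]

#: null values of the four statistics under Poisson arrival + (conditional-)
#: geometric bursts
NULL_VALUES = {"D_m": 0.0, "D_p": 0.0, "D_mp": 0.0, "G_m": 1.0}

#: relative tolerance of the factor-of-two degradation-rate pairing check
PAIRING_REL_TOL = 0.1


class UndefinedSignatureError(InvalidModelError):
    """A signature's denominator is degenerate for the supplied moments."""


class RatePairingWarning(UserWarning):
    """The two mRNA moment sets are inconsistent with a halved decay rate."""


def _skc(ms: MomentSet):
    v = ms.skew_combination
    if v is None:
        raise UndefinedSignatureError("third moment required but unavailable")
    return v


def signature_Dm(moments_m: MomentSet):
    """Non-Poisson arrival signature from mRNA moments alone."""
    F = moments_m.fano
    den = 3 * (F - 1) * (1 + (F - 1) * 2 / 3) + 1
    if den <= 0:
        raise UndefinedSignatureError(f"D_m denominator nonpositive ({float(den)})")
    return _skc(moments_m) / den - 1


def signature_Dp(moments_p: MomentSet, mu_m, mu_p):
    """Non-Poisson arrival signature from protein moments alone."""
    if mu_m <= 0 or mu_p <= 0:
        raise InvalidModelError("decay rates must be positive")
    F = moments_p.fano
    curv = (mu_m + mu_p) / (mu_m + 2 * mu_p)
    den = 3 * (F - 1) * (1 + curv * (F - 1) * 2 / 3) + 1
    if den <= 0:
        raise UndefinedSignatureError(f"D_p denominator nonpositive ({float(den)})")
    return _skc(moments_p) / den - 1


def signature_Dmp(moments_m: MomentSet, moments_p: MomentSet, mu_m, mu_p):
    """Joint mRNA/protein signature; no third moments, no burst-shape
    assumption.  Equals ``[K_g(mu_m) - K_g(mu_p)]/(2 k_b)`` (units of time)."""
    if mu_m <= 0 or mu_p <= 0:
        raise InvalidModelError("decay rates must be positive")
    Fm = moments_m.fano
    Fp = moments_p.fano
    return Fm / (mu_m * moments_m.mean) - (mu_m + mu_p) * (Fp - 1) / (
        mu_m * mu_p * moments_p.mean
    )


def signature_Gm(moments_at_mu: MomentSet, moments_at_2mu: MomentSet):
    """Non-geometric-burst signature from mRNA moments at ``mu_m`` and
    ``2 mu_m``.

    The pairing requirement (doubled degradation rate, unchanged burst
    process) is checked through the means — halving the mRNA lifetime must
    halve the mean — and violations raise :class:`RatePairingWarning`.
    """
    m1, m2 = moments_at_mu.mean, moments_at_2mu.mean
    if abs(float(m2 - m1 / 2)) > PAIRING_REL_TOL * float(m1) / 2:
        warnings.warn(
            f"means {float(m1):g} and {float(m2):g} are inconsistent with a "
            "doubled degradation rate; G_m protocol violated",
            RatePairingWarning,
        )
    F1 = moments_at_mu.fano
    F2 = moments_at_2mu.fano
    num = _skc(moments_at_mu) - 1 - 2 * F2 * (m1 - 1)
    den = F1 * (1 - 2 * m1 + 2 * F2) - 1
    if den == 0:
        raise UndefinedSignatureError("G_m denominator vanished")
    return num / den


def telegraph_closed_forms(params: TelegraphParameters, mb_mean, k_p=None,
                           mu_m=1.0, mu_p=None):
    """Exact telegraph-model signatures (conditional-geometric batches of mean
    ``mb_mean`` fired at rate ``k_m`` while ON).

    Returns ``(D_m, D_p, D_mp)``.  ``D_m`` and ``D_p`` are dimensionless and
    evaluated with rates expressed in units of ``mu_m``; ``D_p`` is the
    burst-limit (``mu_p -> 0``) closed form and needs ``k_p``.  ``D_mp``
    (units of time) is exact for any ``mu_m, mu_p`` and needs ``mu_p``.
    ``D_p``/``D_mp`` are None when their extra rate is not supplied.
    """
    a = params.on_rate / mu_m
    b = params.off_rate / mu_m
    km = params.transcription_rate / mu_m
    m = mb_mean
    theta = (a + b) * (a + b + 1)
    dm = (
        2 * km * b * ((1 - m) * theta - (1 + a) * (a + b) * m * km)
        / ((2 + a + b) * (theta + b * km) * ((2 * m - 1) * theta + 2 * km * m * b))
    )
    dp = None
    if k_p is not None:
        kp = k_p / mu_m
        psi = km * b + (a + b) ** 2
        dp = (
            -2 * m ** 2 * km ** 2 * kp ** 2 * a * b
            / ((a + b) ** 4 + 3 * m * kp * (a + b) ** 2 * psi + 2 * m ** 2 * kp ** 2 * psi ** 2)
        )
    dmp = None
    if mu_p is not None:
        al, be = params.on_rate, params.off_rate
        dmp = be * (mu_p - mu_m) / (al * (al + be + mu_m) * (al + be + mu_p))
    return dm, dp, dmp


@dataclass
class SignatureReport:
    """Signature values with optional bootstrap confidence intervals."""

    values: dict
    ci: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)
    inputs: dict = field(default_factory=dict)
    null_values: dict = field(default_factory=lambda: dict(NULL_VALUES))

    def excludes_null(self, name: str) -> Optional[bool]:
        """True/False when a CI is available, else None."""
        if name not in self.ci or self.ci[name] is None:
            return None
        lo, hi = self.ci[name]
        null = self.null_values[name]
        return bool(null < lo or null > hi)

    def to_dict(self):
        return {
            "values": {k: (None if v is None else float(v)) for k, v in self.values.items()},
            "ci": {k: (None if v is None else [float(v[0]), float(v[1])])
                   for k, v in self.ci.items()},
            "null_values": self.null_values,
            "null_excluded": {k: self.excludes_null(k) for k in self.values},
            "flags": list(self.flags),
            "inputs": self.inputs,
        }


def _try(report, name, func):
    try:
        report.values[name] = float(func())
    except (UndefinedSignatureError, InvalidModelError) as exc:
        report.values[name] = None
        report.flags.append(f"{name}: {exc}")


def signatures_from_samples(
    mrna=None,
    protein=None,
    mrna_2mu=None,
    mu_m=None,
    mu_p=None,
    n_boot: int = 2000,
    seed: int = 0,
) -> SignatureReport:
    """Compute every signature the supplied count data allows, with seeded
    nonparametric bootstrap percentile CIs.

    ``mrna``/``protein`` are steady-state count vectors (paired samples may be
    passed but are resampled independently); ``mrna_2mu`` are mRNA counts
    measured at the doubled degradation rate for ``G_m``.
    """
    from .simulate import empirical_moments

    report = SignatureReport(values={}, inputs={
        "mu_m": mu_m, "mu_p": mu_p, "n_boot": n_boot, "seed": seed,
        "n_mrna": None if mrna is None else int(len(mrna)),
        "n_protein": None if protein is None else int(len(protein)),
        "n_mrna_2mu": None if mrna_2mu is None else int(len(mrna_2mu)),
    })
    ms = None if mrna is None else empirical_moments(mrna, n_boot=0)
    ps = None if protein is None else empirical_moments(protein, n_boot=0)
    ms2 = None if mrna_2mu is None else empirical_moments(mrna_2mu, n_boot=0)
    if ms is not None:
        _try(report, "D_m", lambda: signature_Dm(ms))
    if ps is not None and mu_m is not None and mu_p is not None:
        _try(report, "D_p", lambda: signature_Dp(ps, mu_m, mu_p))
    if ms is not None and ps is not None and mu_m is not None and mu_p is not None:
        _try(report, "D_mp", lambda: signature_Dmp(ms, ps, mu_m, mu_p))
    if ms is not None and ms2 is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("always")
            _try(report, "G_m", lambda: signature_Gm(ms, ms2))
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        draws = {k: [] for k in report.values}
        arrays = {"mrna": mrna, "protein": protein, "mrna_2mu": mrna_2mu}
        arrays = {k: np.asarray(v) for k, v in arrays.items() if v is not None}
        for _ in range(n_boot):
            res = {k: v[rng.integers(0, v.size, v.size)] for k, v in arrays.items()}
            bms = empirical_moments(res["mrna"], n_boot=0) if "mrna" in res else None
            bps = empirical_moments(res["protein"], n_boot=0) if "protein" in res else None
            bms2 = empirical_moments(res["mrna_2mu"], n_boot=0) if "mrna_2mu" in res else None
            for name in draws:
                try:
                    if name == "D_m":
                        draws[name].append(signature_Dm(bms))
                    elif name == "D_p":
                        draws[name].append(signature_Dp(bps, mu_m, mu_p))
                    elif name == "D_mp":
                        draws[name].append(signature_Dmp(bms, bps, mu_m, mu_p))
                    elif name == "G_m":
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore", RatePairingWarning)
                            draws[name].append(signature_Gm(bms, bms2))
                except (UndefinedSignatureError, InvalidModelError):
                    continue
        for name, vals in draws.items():
            if len(vals) >= max(20, n_boot // 2):
                lo, hi = np.percentile(vals, [2.5, 97.5])
                report.ci[name] = (float(lo), float(hi))
            else:
                report.ci[name] = None
                if report.values.get(name) is not None:
                    report.flags.append(f"{name}: bootstrap mostly undefined")
    return report
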