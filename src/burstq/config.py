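"""Configuration schema: declarative YAML/JSON blocks for arrival models,
burst distributions and kinetic schemes.

Block reference (all keys lowercase):

arrival:
  kind: exponential | telegraph | erlang | hypoexponential | rational | from_g
  exponential:      {rate}
  telegraph:        {on_rate, off_rate, transcription_rate}
  erlang:           {shape, stage_rate}
  hypoexponential:  {rates: [..]}
  rational:         {numer: [1, a1, ...], denom: [1, b1, ...]}
  from_g:           {g: <arrival block>, k_m, beta}

burst:
  kind: unit | geometric | conditional_geometric | negative_binomial | empirical_pmf
  geometric / conditional_geometric: {mean}
  negative_binomial: {r, p}
  empirical_pmf:     {pmf: [..]}

scheme:
  kind: telegraph | activation_chain | matrix
  telegraph:        {alpha, beta, k_m, mu_m, [burst], [k_p], [mu_p]}
  activation_chain: {forward_rates, [backward_rates], off_rate, k_m, mu_m,
                     [burst], [k_p], [mu_p]}
  matrix:           {transition_rates, active_state, k_m, mu_m, ...}
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional

from . import __version__
from .bursts import BurstDistribution
from .laplace import (
    InvalidModelError,
    RationalLaplaceTransform,
    TelegraphParameters,
    erlang_transform,
    exponential_transform,
    f_from_g,
    hypoexponential_transform,
    telegraph_arrival_transform,
)
from .simulate import ExtrinsicNoiseSpec, PromoterScheme

__all__ = ["RunConfig", "load_config", "build_arrival", "build_burst",
           "build_scheme", "provenance"]

WORKFLOWS = ("moments", "simulate", "estimate", "signatures", "reproduce-figure")


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InvalidModelError("config must be a mapping")
    return cfg


def build_arrival(block: dict) -> RationalLaplaceTransform:
    kind = block.get("kind")
    if kind == "exponential":
        return exponential_transform(block["rate"])
    if kind == "telegraph":
        return telegraph_arrival_transform(TelegraphParameters(
            block["on_rate"], block["off_rate"], block["transcription_rate"]))
    if kind == "erlang":
        return erlang_transform(int(block["shape"]), block["stage_rate"])
    if kind == "hypoexponential":
        return hypoexponential_transform(block["rates"])
    if kind == "rational":
        return RationalLaplaceTransform(tuple(block["numer"]), tuple(block["denom"]))
    if kind == "from_g":
        return f_from_g(build_arrival(block["g"]), block["k_m"], block["beta"])
    raise InvalidModelError(f"unknown arrival kind {kind!r}")


def build_burst(block: dict) -> BurstDistribution:
    kind = block.get("kind")
    if kind == "unit":
        return BurstDistribution.unit()
    if kind == "geometric":
        return BurstDistribution.geometric_from_mean(block["mean"])
    if kind == "conditional_geometric":
        return BurstDistribution.conditional_geometric_from_mean(block["mean"])
    if kind == "negative_binomial":
        return BurstDistribution.negative_binomial(block["r"], block["p"])
    if kind == "empirical_pmf":
        return BurstDistribution.empirical(block["pmf"])
    raise InvalidModelError(f"unknown burst kind {kind!r}")


def build_scheme(block: dict) -> PromoterScheme:
    kind = block.get("kind")
    burst = build_burst(block["burst"]) if "burst" in block else None
    common = dict(mu_m=block["mu_m"], batch=burst,
                  k_p=block.get("k_p", 0.0), mu_p=block.get("mu_p", 0.0))
    if kind == "telegraph":
        return PromoterScheme.telegraph(block["alpha"], block["beta"],
                                        block["k_m"], **common)
    if kind == "activation_chain":
        return PromoterScheme.activation_chain(
            tuple(block["forward_rates"]), block["off_rate"], block["k_m"],
            backward_rates=tuple(block.get("backward_rates", ())), **common)
    if kind == "matrix":
        return PromoterScheme(tuple(map(tuple, block["transition_rates"])),
                              int(block["active_state"]), block["k_m"], **common)
    raise InvalidModelError(f"unknown scheme kind {kind!r}")


def build_extrinsic(block: Optional[dict]) -> Optional[ExtrinsicNoiseSpec]:
    if block is None:
        return None
    return ExtrinsicNoiseSpec(block["mean_km"], block["sd_km"])


@dataclass
class RunConfig:
    """A validated workflow configuration."""

    workflow: str
    seed: Optional[int] = None
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        wf = cfg.get("workflow")
        if wf not in WORKFLOWS:
            raise InvalidModelError(f"workflow must be one of {WORKFLOWS}")
        seed = cfg.get("seed")
        if wf in ("simulate", "estimate", "reproduce-figure") and seed is None:
            raise InvalidModelError(f"workflow {wf!r} requires an explicit seed")
        return cls(workflow=wf, seed=seed, raw=dict(cfg))


def provenance(cfg: dict, seed=None) -> dict:
    """Reproducibility header attached to every CLI output."""
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    return {"config_sha256": digest, "seed": seed, "package": f"burstq {__version__}"}
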