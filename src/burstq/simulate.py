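"""Exact stochastic simulation of promoter-driven gene expression.

The simulator is the package's independent oracle: it runs the Gillespie
algorithm on an arbitrary multi-state promoter scheme (a continuous-time
Markov chain over promoter states, one production-competent state emitting
either single mRNAs or batches at rate ``k_m``, first-order mRNA/protein
decay, optional per-mRNA translation) and returns steady-state count samples,
an event log of production times for interarrival analysis, and time-weighted
promoter occupancies.

Sampling protocol: trajectories are burned in for ``10 x`` the slowest
relaxation timescale (the largest of ``1/mu_m``, ``1/mu_p`` when proteins are
simulated, and the reciprocal of the smallest promoter switching rate) and
then sampled at a spacing of ``5 x`` that timescale; both are overridable.
Extrinsic noise redraws the transcription rate once per replicate ("cell")
from a log-normal law with specified mean and standard deviation.

Reproducibility: a single integer seed is expanded into independent
per-replicate streams with `numpy.random.SeedSequence`, so identical
(scheme, seed) pairs give bit-identical event sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .bursts import BurstDistribution
from .laplace import InvalidModelError
from .moments import MomentSet

__all__ = [
    "PromoterScheme",
    "ExtrinsicNoiseSpec",
    "SimulationOutput",
    "simulate",
    "empirical_moments",
    "interarrival_log",
]

_BATCH_KINDS = {"unit": 0, "geometric": 1, "conditional_geometric": 2, "negative_binomial": 3}


@dataclass(frozen=True)
class PromoterScheme:
    """A kinetic scheme: promoter CTMC + production + decay rates.

    ``transition_rates[i, j]`` is the rate of switching from promoter state
    ``i`` to ``j``.  Production happens only in ``active_state``: single
    mRNAs at rate ``k_m`` when ``batch`` is None, otherwise batches drawn
    from ``batch``.  Set ``k_p = mu_p = 0`` to simulate mRNA only.
    """

    transition_rates: tuple
    active_state: int
    k_m: float
    mu_m: float
    batch: Optional[BurstDistribution] = None
    k_p: float = 0.0
    mu_p: float = 0.0
    state_names: Optional[tuple] = None

    def __post_init__(self):
        R = np.asarray(self.transition_rates, dtype=float)
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise InvalidModelError("transition_rates must be a square matrix")
        if np.any(R < 0) or np.any(np.diag(R) != 0):
            raise InvalidModelError("rates must be >= 0 with zero diagonal")
        if not (0 <= self.active_state < R.shape[0]):
            raise InvalidModelError("active_state out of range")
        if self.k_m <= 0 or self.mu_m <= 0 or self.k_p < 0 or self.mu_p < 0:
            raise InvalidModelError("invalid production/decay rates")
        if self.k_p > 0 and self.mu_p <= 0:
            raise InvalidModelError("translation requires mu_p > 0")
        if self.batch is not None and self.batch.kind not in _BATCH_KINDS:
            raise InvalidModelError(f"unsupported batch kind {self.batch.kind!r} in SSA")
        # active state must be reachable in the embedded chain
        reach = {0}
        frontier = [0]
        while frontier:
            i = frontier.pop()
            for j in np.nonzero(R[i] > 0)[0]:
                if j not in reach:
                    reach.add(int(j))
                    frontier.append(int(j))
        if self.active_state not in reach:
            raise InvalidModelError("active state unreachable from state 0")
        object.__setattr__(self, "transition_rates", tuple(map(tuple, R)))

    # -- common schemes ------------------------------------------------------

    @classmethod
    def telegraph(cls, alpha, beta, k_m, mu_m, batch=None, k_p=0.0, mu_p=0.0):
        """Two-state random telegraph model: OFF --alpha--> ON --beta--> OFF."""
        R = [[0.0, alpha], [beta, 0.0]]
        return cls(tuple(map(tuple, R)), 1, k_m, mu_m, batch, k_p, mu_p,
                   state_names=("OFF", "ON"))

    @classmethod
    def activation_chain(cls, forward_rates, off_rate, k_m, mu_m,
                         backward_rates=(), batch=None, k_p=0.0, mu_p=0.0):
        """OFF chain ``D_0 -> ... -> D_K -> ON`` (forward/backward rates) with
        the ON state switching back to ``D_0`` at ``off_rate``."""
        n = len(forward_rates) + 1
        R = np.zeros((n, n))
        for i, a in enumerate(forward_rates):
            R[i, i + 1] = a
        for i, b in enumerate(backward_rates):
            R[i + 1, i] = b
        R[n - 1, 0] = off_rate
        return cls(tuple(map(tuple, R)), n - 1, k_m, mu_m, batch, k_p, mu_p)

    @property
    def n_states(self):
        return len(self.transition_rates)

    def slowest_timescale(self) -> float:
        R = np.asarray(self.transition_rates)
        rates = [self.mu_m]
        if self.k_p > 0:
            rates.append(self.mu_p)
        pos = R[R > 0]
        if pos.size:
            rates.append(float(pos.min()))
        return 1.0 / min(rates)

    def ctmc_stationary(self) -> np.ndarray:
        """Stationary distribution of the promoter CTMC (for validation)."""
        R = np.asarray(self.transition_rates, dtype=float)
        Q = R - np.diag(R.sum(axis=1))
        A = np.vstack([Q.T, np.ones(self.n_states)])
        b = np.zeros(self.n_states + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        return pi


@dataclass(frozen=True)
class ExtrinsicNoiseSpec:
    """Cell-to-cell variability of the transcription rate: ``k_m`` is redrawn
    once per replicate from a log-normal law with mean ``mean_km`` and
    standard deviation ``sd_km``."""

    mean_km: float
    sd_km: float

    def __post_init__(self):
        if self.mean_km <= 0 or self.sd_km < 0:
            raise InvalidModelError("need mean_km > 0 and sd_km >= 0")

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.sd_km == 0:
            return np.full(size, self.mean_km)
        s2 = math.log1p((self.sd_km / self.mean_km) ** 2)
        mu = math.log(self.mean_km) - s2 / 2
        return rng.lognormal(mu, math.sqrt(s2), size)


@dataclass
class SimulationOutput:
    """Steady-state samples plus provenance and (optionally) the event log."""

    mrna: np.ndarray
    protein: Optional[np.ndarray]
    replicate: np.ndarray
    occupancy: np.ndarray
    seed: int
    scheme: PromoterScheme
    event_times: list = field(default_factory=list)
    event_sizes: list = field(default_factory=list)
    km_draws: Optional[np.ndarray] = None

    def to_frame(self):
        import pandas as pd

        data = {"replicate": self.replicate, "mrna": self.mrna}
        if self.protein is not None:
            data["protein"] = self.protein
        return pd.DataFrame(data)

    def events_frame(self):
        import pandas as pd

        rep = np.concatenate(
            [np.full(len(t), i) for i, t in enumerate(self.event_times)]
        ) if self.event_times else np.empty(0, int)
        times = np.concatenate(self.event_times) if self.event_times else np.empty(0)
        sizes = np.concatenate(self.event_sizes) if self.event_sizes else np.empty(0, int)
        return pd.DataFrame({"replicate": rep, "time": times, "size": sizes})


@njit(cache=True)
def _ssa_core(R, out_rates, active, km, batch_kind, bp1, bp2, kp, mum, mup,
              burnin, spacing, n_samples, seed, max_events):
    np.random.seed(seed)
    n_states = R.shape[0]
    samples_m = np.zeros(n_samples, dtype=np.int64)
    samples_p = np.zeros(n_samples, dtype=np.int64)
    occupancy = np.zeros(n_states)
    ev_times = np.empty(max_events)
    ev_sizes = np.zeros(max_events, dtype=np.int64)
    n_events = 0
    state = 0
    nm = 0
    npr = 0
    t = 0.0
    next_sample = burnin
    collected = 0
    want_events = max_events > 0
    while True:
        if collected >= n_samples and (not want_events or n_events >= max_events):
            break
        r_switch = out_rates[state]
        r_prod = km if state == active else 0.0
        r_mdec = nm * mum
        r_tl = nm * kp
        r_pdec = npr * mup
        total = r_switch + r_prod + r_mdec + r_tl + r_pdec
        if total <= 0.0:
            # absorbing quiet stretch cannot happen for irreducible schemes,
            # but guard against an infinite loop anyway
            t = next_sample
        dt = np.random.exponential(1.0 / total) if total > 0.0 else 0.0
        # record any sample times crossed by this waiting interval
        while collected < n_samples and next_sample <= t + dt:
            samples_m[collected] = nm
            samples_p[collected] = npr
            collected += 1
            next_sample += spacing
        if t + dt > burnin:
            lo = t if t > burnin else burnin
            occupancy[state] += t + dt - lo
        t += dt
        u = np.random.random() * total
        if u < r_switch:
            # promoter jump
            target = 0
            acc = 0.0
            for j in range(n_states):
                acc += R[state, j]
                if u < acc:
                    target = j
                    break
            state = target
        elif u < r_switch + r_prod:
            size = 1
            if batch_kind == 1:      # geometric on {0,1,...} with mean bp1
                size = np.random.geometric(1.0 / (1.0 + bp1)) - 1
            elif batch_kind == 2:    # conditional geometric, mean bp1 >= 1
                size = np.random.geometric(1.0 / bp1)
            elif batch_kind == 3:    # negative binomial, r = bp1, p = bp2
                size = 0
                for _ in range(int(bp1)):
                    size += np.random.geometric(1.0 - bp2) - 1
            nm += size
            if want_events and t > burnin and n_events < max_events:
                ev_times[n_events] = t
                ev_sizes[n_events] = size
                n_events += 1
        elif u < r_switch + r_prod + r_mdec:
            nm -= 1
        elif u < r_switch + r_prod + r_mdec + r_tl:
            npr += 1
        else:
            npr -= 1
    return samples_m, samples_p, occupancy, ev_times[:n_events], ev_sizes[:n_events]


def simulate(
    scheme: PromoterScheme,
    n_samples: int,
    seed: int,
    extrinsic: Optional[ExtrinsicNoiseSpec] = None,
    n_replicates: int = 1,
    burnin: Optional[float] = None,
    spacing: Optional[float] = None,
    record_events: int = 0,
) -> SimulationOutput:
    """Run the Gillespie algorithm and collect ``n_samples`` steady-state
    samples in total, split over ``n_replicates`` independent cells.

    ``record_events`` > 0 additionally logs (up to that many, per replicate)
    production event times after burn-in for interarrival analysis.
    """
    if n_samples < 1 and record_events <= 0:
        raise InvalidModelError("nothing to simulate")
    if extrinsic is not None and n_replicates < 2 and extrinsic.sd_km > 0:
        raise InvalidModelError("extrinsic noise needs many replicates (cells)")
    tau = scheme.slowest_timescale()
    burnin = 10.0 * tau if burnin is None else float(burnin)
    spacing = 5.0 * tau if spacing is None else float(spacing)
    R = np.asarray(scheme.transition_rates, dtype=float)
    out_rates = R.sum(axis=1)
    batch_kind = 0
    bp1 = bp2 = 0.0
    if scheme.batch is not None:
        batch_kind = _BATCH_KINDS[scheme.batch.kind]
        if batch_kind in (1, 2):
            bp1 = float(scheme.batch.mean)
        elif batch_kind == 3:
            bp1, bp2 = float(scheme.batch.r), float(scheme.batch.p)

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n_replicates, dtype=np.uint32)
    rng = np.random.default_rng(ss.spawn(1)[0])
    km_draws = None
    if extrinsic is not None:
        km_draws = extrinsic.draw(rng, n_replicates)

    per = [n_samples // n_replicates] * n_replicates
    for i in range(n_samples % n_replicates):
        per[i] += 1

    all_m, all_p, all_rep = [], [], []
    occupancy = np.zeros(scheme.n_states)
    ev_t, ev_s = [], []
    for i in range(n_replicates):
        km_i = float(km_draws[i]) if km_draws is not None else scheme.k_m
        m, p, occ, et, es = _ssa_core(
            R, out_rates, scheme.active_state, km_i, batch_kind, bp1, bp2,
            scheme.k_p, scheme.mu_m, scheme.mu_p,
            burnin, spacing, per[i], int(child_seeds[i]), int(record_events),
        )
        all_m.append(m)
        all_p.append(p)
        all_rep.append(np.full(per[i], i))
        occupancy += occ
        if record_events:
            ev_t.append(et)
            ev_s.append(es)
    protein = np.concatenate(all_p) if scheme.k_p > 0 else None
    return SimulationOutput(
        mrna=np.concatenate(all_m),
        protein=protein,
        replicate=np.concatenate(all_rep),
        occupancy=occupancy / max(occupancy.sum(), 1e-300),
        seed=seed,
        scheme=scheme,
        event_times=ev_t,
        event_sizes=ev_s,
        km_draws=km_draws,
    )


def empirical_moments(samples, n_boot: int = 500, seed: int = 0) -> MomentSet:
    """Sample mean/variance/third/fourth central moments with nonparametric
    bootstrap standard errors."""
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise InvalidModelError("need at least 2 samples")
    degenerate = bool(np.all(x == x[0]))

    def stats(v):
        m = v.mean()
        d = v - m
        return m, np.mean(d ** 2), np.mean(d ** 3), np.mean(d ** 4)

    mean, var, nu3, nu4 = stats(x)
    se = None
    if n_boot > 0 and not degenerate:
        rng = np.random.default_rng(seed)
        boots = np.empty((n_boot, 5))
        for b in range(n_boot):
            v = x[rng.integers(0, x.size, x.size)]
            mb, vb, n3b, n4b = stats(v)
            boots[b] = (mb, vb, n3b, n4b, n3b / mb if mb != 0 else np.nan)
        sd = boots.std(axis=0, ddof=1)
        se = {
            "mean": sd[0], "variance": sd[1], "third_central": sd[2],
            "fourth_central": sd[3], "skew_combination": sd[4],
            "fano": float(np.std(boots[:, 1] / boots[:, 0], ddof=1)),
        }
    return MomentSet(
        mean=mean, variance=var,
        third_central=None if degenerate else nu3,
        fourth_central=None if degenerate else nu4,
        se=se, n_samples=int(x.size), degenerate=degenerate,
    )


def interarrival_log(output: SimulationOutput) -> np.ndarray:
    """Waiting times between consecutive production events, pooled across
    replicates (each replicate's log is post burn-in, i.e. stationary)."""
    if not output.event_times:
        raise InvalidModelError("simulation was run without event recording")
    gaps = [np.diff(t) for t in output.event_times if len(t) >= 2]
    return np.concatenate(gaps) if gaps else np.empty(0)
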