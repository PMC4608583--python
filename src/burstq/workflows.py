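"""End-to-end study protocols: analytic predictions against the simulation
oracle, at desk scale.

Each function reproduces one of the package's reference experiments and
returns a tidy comparison table.  They are used both by the command line
(``burstq reproduce-figure``) and by the validation suite; sample sizes are
arguments so the suite can run them at full or reduced scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bursts import BurstDistribution, compose
from .inference import (
    burst_size_from_phi,
    extrinsic_noise_sweep,
    find_inflexion,
    sequence_size,
    two_state_sequence_size,
)
from .laplace import TelegraphParameters, chain_activation_transform, f_from_g, telegraph_arrival_transform
from .moments import mrna_moments, protein_moments
from .signatures import signatures_from_samples, telegraph_closed_forms
from .simulate import PromoterScheme, empirical_moments, simulate

__all__ = ["reproduce_figure", "two_stage_sweep", "burst_size_table",
           "extrinsic_noise_table", "telegraph_signature_table"]

#: reference parameter sets for the bundled protocols
TWO_STAGE_PARAMS = dict(alpha=0.5, beta=0.25, k_m=2.0, mb=5.0, k_p=0.5, mu_p=0.01)
SEQUENCE_SIZE_PARAMS = dict(
    forward_rates=(1.0, 0.5, 0.25, 0.75), backward_rates=(0.1, 0.2, 0.5),
    k_m=500.0, betas=(50.0, 100.0, 200.0))
EXTRINSIC_PARAMS = dict(forward_rates=(1.0, 0.5), beta=50.0, k_m=500.0, mu_m=1.0)
SIGNATURE_PARAMS = dict(alpha=0.25, k_m=2.0, mb=5.0, k_p=0.5, mu_m=1.0, mu_p=0.01)


def two_stage_sweep(seed: int, ratios=(1, 5, 10, 50), n_per_ratio: int = 25_000,
                    n_boot: int = 300) -> pd.DataFrame:
    """Protein variance and third central moment across the mRNA/protein
    lifetime ratio: finite-lifetime-scaled analytics vs the exact simulator.

    Telegraph promoter (alpha = 0.5, beta = 0.25) firing conditional-geometric
    batches (mean 5) at rate k_m = 2, translation k_p = 0.5; mu_p = 0.01 is
    held fixed (slow protein turnover, consistent with the package's other
    telegraph protocols) and mu_m = ratio * mu_p.  Samples are taken 1.5
    protein lifetimes apart — residual autocorrelation is mild and the
    bootstrap treats samples as exchangeable.
    """
    P = TWO_STAGE_PARAMS
    burst = BurstDistribution.conditional_geometric_from_mean(P["mb"])
    arrival = telegraph_arrival_transform(
        TelegraphParameters(P["alpha"], P["beta"], P["k_m"]))
    rows = []
    for i, ratio in enumerate(ratios):
        mu_m = ratio * P["mu_p"]
        protein = BurstDistribution.geometric_from_mean(P["k_p"] / mu_m)
        comp = compose(burst, protein)
        ana = protein_moments(arrival, comp, mu_m, P["mu_p"], mode="scaled").as_float()
        scheme = PromoterScheme.telegraph(
            P["alpha"], P["beta"], P["k_m"], mu_m, batch=burst,
            k_p=P["k_p"], mu_p=P["mu_p"])
        sim_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % 2**31)
        out = simulate(scheme, n_per_ratio, seed=sim_seed,
                       spacing=1.5 / P["mu_p"])
        emp = empirical_moments(out.protein, n_boot=n_boot, seed=sim_seed + 1)
        rows.append({
            "ratio": ratio, "mu_m": mu_m,
            "variance_analytic": ana.variance, "variance_sim": emp.variance,
            "variance_se": emp.se["variance"],
            "nu3_analytic": ana.third_central, "nu3_sim": emp.third_central,
            "nu3_se": emp.se["third_central"],
            "mean_analytic": ana.mean, "mean_sim": emp.mean,
            "mean_se": emp.se["mean"],
        })
    return pd.DataFrame(rows)


def burst_size_table(betas=None) -> pd.DataFrame:
    """Sequence-size burst-size estimation for the multi-step activation
    scheme (forward rates 1, 0.5, 0.25, 0.75; backslips 0.1, 0.2, 0.5;
    k_m = 500) across OFF rates beta, against the exact value 1 + k_m/beta.

    Three routes per beta: the exact value, the two-state bursty-limit chain
    (closed-form phi -> inflexion -> 2 phi), and the full-scheme chain (exact
    activation transform g -> f -> phi -> inflexion -> 2 phi).
    """
    S = SEQUENCE_SIZE_PARAMS
    betas = S["betas"] if betas is None else betas
    g = chain_activation_transform(S["forward_rates"], S["backward_rates"])
    rows = []
    for beta in betas:
        exact = 1.0 + S["k_m"] / beta
        curve2 = two_state_sequence_size(S["k_m"], beta)
        find_inflexion(curve2)
        f = f_from_g(g, S["k_m"], beta)
        curve_full = sequence_size(f.as_float())
        find_inflexion(curve_full)
        rows.append({
            "beta": beta, "exact_burst_size": exact,
            "two_state_estimate": burst_size_from_phi(curve2),
            "two_state_tau_x": curve2.tau_x,
            "full_scheme_estimate": burst_size_from_phi(curve_full),
            "full_scheme_tau_x": curve_full.tau_x,
        })
    return pd.DataFrame(rows)


def extrinsic_noise_table(seed: int, sigma_fracs=(0.0, 0.2, 0.5, 1.0),
                          n_cells: int = 20_000, samples_per_cell: int = 4,
                          n_boot: int = 8) -> pd.DataFrame:
    """Burst-size estimation error under extrinsic noise for the two-step
    activation scheme (alpha_1 = 1, alpha_2 = 0.5, beta = 50, <k_m> = 500,
    mu_m = 1); sigma_km = fraction * <k_m>."""
    E = EXTRINSIC_PARAMS
    scheme = PromoterScheme.activation_chain(
        E["forward_rates"], E["beta"], E["k_m"], E["mu_m"])
    sigmas = [f * E["k_m"] for f in sigma_fracs]
    table = extrinsic_noise_sweep(scheme, sigmas, seed=seed, n_cells=n_cells,
                                  samples_per_cell=samples_per_cell, n_boot=n_boot)
    table.insert(0, "sigma_frac", list(sigma_fracs))
    table["true_burst_size"] = 1.0 + E["k_m"] / E["beta"]
    return table


def telegraph_signature_table(seed: int, betas=(0.5, 1.0, 2.0),
                              n_samples: int = 30_000, n_boot: int = 400,
                              include_protein: bool = True) -> pd.DataFrame:
    """Non-Poisson signatures for the telegraph batch scheme (alpha = 0.25,
    k_m = 2, <m_b> = 5, k_p = 0.5, mu_m = 1, mu_p = 0.01) across beta:
    closed forms, the analytic moment pipeline, and SSA estimates with
    bootstrap CIs."""
    G = SIGNATURE_PARAMS
    burst = BurstDistribution.conditional_geometric_from_mean(G["mb"])
    rows = []
    for i, beta in enumerate(betas):
        params = TelegraphParameters(G["alpha"], beta, G["k_m"])
        arrival = telegraph_arrival_transform(params)
        dm_cf, dp_cf, dmp_cf = telegraph_closed_forms(
            params, G["mb"], k_p=G["k_p"], mu_m=G["mu_m"], mu_p=G["mu_p"])
        from .signatures import signature_Dm, signature_Dmp

        ms = mrna_moments(arrival, burst, G["mu_m"]).as_float()
        protein = BurstDistribution.geometric_from_mean(G["k_p"] / G["mu_m"])
        ps = protein_moments(arrival, compose(burst, protein),
                             G["mu_m"], G["mu_p"], mode="scaled").as_float()
        dm_pipe = signature_Dm(ms)
        dmp_pipe = signature_Dmp(ms, ps, G["mu_m"], G["mu_p"])
        scheme = PromoterScheme.telegraph(
            G["alpha"], beta, G["k_m"], G["mu_m"], batch=burst,
            k_p=G["k_p"] if include_protein else 0.0,
            mu_p=G["mu_p"] if include_protein else 0.0)
        sim_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % 2**31)
        out = simulate(scheme, n_samples, seed=sim_seed)
        rep = signatures_from_samples(
            mrna=out.mrna, protein=out.protein,
            mu_m=G["mu_m"], mu_p=G["mu_p"], n_boot=n_boot, seed=sim_seed + 1)
        row = {
            "beta": beta,
            "Dm_closed_form": dm_cf, "Dm_pipeline": dm_pipe,
            "Dm_sim": rep.values.get("D_m"),
            "Dm_ci_lo": (rep.ci.get("D_m") or (np.nan, np.nan))[0],
            "Dm_ci_hi": (rep.ci.get("D_m") or (np.nan, np.nan))[1],
            "Dmp_closed_form": dmp_cf, "Dmp_pipeline": dmp_pipe,
            "Dmp_sim": rep.values.get("D_mp"),
            "Dp_closed_form": dp_cf,
        }
        rows.append(row)
    return pd.DataFrame(rows)


def reproduce_figure(tag: str, seed: int, scale: float = 1.0):
    """Dispatch a named protocol at desk scale; ``scale`` multiplies the
    default sample sizes."""
    if tag == "fig2":
        return two_stage_sweep(seed, n_per_ratio=max(1000, int(25_000 * scale)))
    if tag == "fig4":
        return burst_size_table()
    if tag == "fig5":
        return extrinsic_noise_table(seed, n_cells=max(2000, int(20_000 * scale)))
    if tag == "fig6":
        return telegraph_signature_table(seed, n_samples=max(2000, int(30_000 * scale)))
    raise ValueError("tag must be one of fig2, fig4, fig5, fig6")
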