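"""Steady-state moment engine: reductions, printed-formula transcriptions,
and simulation cross-checks."""

import math
from fractions import Fraction

import numpy as np
import pytest

import burstq as bq
from burstq.moments import GestationFactors, _central_from_factorial


def mrna_noise_cv2(kg_mu, ms_mean, mu_m, kb, mb_mean, mb_var):
    """Literal transcription of the printed mRNA noise formula:
    CV^2 = 1/<m_s> + mu_m/k_b + (mu_m/2k_b)[Kg - 1 + var/mean^2 - (1+1/mean)]."""
    return (1 / ms_mean + mu_m / kb + mu_m / (2 * kb) * (
        kg_mu - 1 + mb_var / mb_mean ** 2 - (1 + 1 / mb_mean)))


def protein_noise_cv2(kg_mu, ps_mean, mu_p, kb, mb_mean, mb_var, pb_mean, pb_var):
    """Literal transcription of the printed protein noise formula (burst
    limit): note the mRNA bracket sign is -(1 - 1/<m_b>) here."""
    return (1 / ps_mean + mu_p / kb + mu_p / (2 * kb) * (
        kg_mu - 1 + mb_var / mb_mean ** 2 - (1 - 1 / mb_mean)
        + (pb_var / pb_mean ** 2 - (1 + 1 / pb_mean)) / mb_mean))


class TestGestationFactor:
    def test_poisson_is_one_at_every_rate(self):
        f = bq.exponential_transform(Fraction(7, 3))
        for mu in (Fraction(1, 10), Fraction(1), Fraction(9)):
            assert bq.gestation_factor(f, mu) == 1

    def test_telegraph_reduces_to_one_as_beta_vanishes(self):
        vals = []
        for beta in (1e-3, 1e-5, 1e-7):
            f = bq.telegraph_arrival_transform(bq.TelegraphParameters(0.25, beta, 2.0))
            vals.append(float(f.gestation_factor(1.0)))
        assert abs(vals[-1] - 1.0) < 1e-5
        assert abs(vals[0] - 1.0) > abs(vals[-1] - 1.0)

    def test_telegraph_value_against_closed_form_and_mc(self, telegraph_exact):
        params, f = telegraph_exact
        a, b, km = params.on_rate, params.off_rate, params.transcription_rate
        # closed form: 1 + 2 k_m beta / ((alpha+beta+mu)(alpha+beta))
        assert f.gestation_factor(1) == 1 + 2 * km * b / ((a + b + 1) * (a + b))
        # Monte-Carlo Laplace functional of simulated interarrivals
        scheme = bq.PromoterScheme.telegraph(0.25, 1.0, 2.0, 1.0)
        out = bq.simulate(scheme, 10, seed=31, record_events=40000)
        w = bq.interarrival_log(out)
        lap = np.exp(-1.0 * w)
        se = lap.std() / math.sqrt(lap.size)
        assert abs(lap.mean() - float(f(1.0))) < 3 * se

    def test_degenerate_transform_rejected(self):
        f = bq.exponential_transform(1.0)
        with pytest.raises(bq.InvalidModelError):
            f.odds(0.0)


class TestMrnaMoments:
    def test_poisson_unit_bursts_is_poisson_law(self):
        kb, mu = Fraction(3), Fraction(2)
        ms = bq.mrna_moments(bq.exponential_transform(kb), bq.BurstDistribution.unit(), mu)
        assert ms.mean == kb / mu
        assert ms.fano == 1
        assert ms.third_central == ms.mean  # Poisson: nu3 = mean

    def test_poisson_conditional_geometric_fano_is_burst_mean(self):
        mb = Fraction(6)
        ms = bq.mrna_moments(
            bq.exponential_transform(Fraction(1)),
            bq.BurstDistribution.conditional_geometric_from_mean(mb), Fraction(1))
        assert ms.fano == mb

    def test_printed_noise_formula_transcription(self, telegraph_exact):
        _, f = telegraph_exact
        mb = Fraction(5)
        burst = bq.BurstDistribution.conditional_geometric_from_mean(mb)
        mu = Fraction(1)
        ms = bq.mrna_moments(f, burst, mu)
        cv2 = mrna_noise_cv2(f.gestation_factor(mu), ms.mean, mu, f.mean_rate,
                      mb, burst.variance)
        assert ms.variance / ms.mean ** 2 == cv2

    def test_printed_skewness_formula_transcription(self, telegraph_exact):
        # gamma sigma^3/mean = 1 + <m_s><m_b>K1 + 2<m_b>^2 K2
        #                      + (var + mean^2 - mean) K3 + b3/(3<m_b>)
        _, f = telegraph_exact
        mb = Fraction(5)
        burst = bq.BurstDistribution.conditional_geometric_from_mean(mb)
        mu = Fraction(1)
        ms = bq.mrna_moments(f, burst, mu)
        K = GestationFactors(f.gestation_factor(mu), f.gestation_factor(2 * mu), mb)
        skc = (1 + ms.mean * mb * K.K1 + 2 * mb ** 2 * K.K2
               + burst.factorial_moment(2) * K.K3
               + burst.factorial_moment(3) / (3 * mb))
        assert ms.skew_combination == skc

    def test_telegraph_full_momentset_matches_ssa(self):
        burst = bq.BurstDistribution.conditional_geometric_from_mean(5.0)
        scheme = bq.PromoterScheme.telegraph(0.25, 1.0, 2.0, 1.0, batch=burst)
        out = bq.simulate(scheme, 60_000, seed=13)
        emp = bq.empirical_moments(out.mrna, n_boot=250, seed=1)
        f = bq.telegraph_arrival_transform(bq.TelegraphParameters(0.25, 1.0, 2.0))
        ana = bq.mrna_moments(f, burst, 1.0, order=4).as_float()
        for field in ("mean", "variance", "third_central", "fourth_central"):
            z = (getattr(emp, field) - getattr(ana, field)) / emp.se[field]
            assert abs(z) < 3.5, f"{field}: z={z:.2f}"


class TestProteinMoments:
    def test_scaled_converges_to_burst_limit(self, telegraph_exact):
        _, f = telegraph_exact
        comp = bq.compose(bq.BurstDistribution.conditional_geometric_from_mean(5.0),
                          bq.BurstDistribution.geometric_from_mean(2.0))
        mu_p = 0.01
        for mu_m, tol in ((1.0, 0.03), (100.0, 3e-4), (10000.0, 3e-6)):
            bl = bq.protein_moments(f, comp, mu_m, mu_p, mode="burst_limit")
            sc = bq.protein_moments(f, comp, mu_m, mu_p, mode="scaled")
            assert float(sc.variance / bl.variance) == pytest.approx(1.0, abs=tol)
            assert float(sc.third_central / bl.third_central) == pytest.approx(1.0, abs=tol)

    def test_printed_protein_noise_transcription(self, telegraph_exact):
        _, f = telegraph_exact
        mb, pb = Fraction(5), Fraction(5, 2)
        mrna = bq.BurstDistribution.conditional_geometric_from_mean(mb)
        prot = bq.BurstDistribution.geometric_from_mean(pb)
        comp = bq.compose(mrna, prot)
        mu_p = Fraction(1, 100)
        ps = bq.protein_moments(f, comp, Fraction(1), mu_p, mode="burst_limit")
        cv2 = protein_noise_cv2(f.gestation_factor(mu_p), ps.mean, mu_p, f.mean_rate,
                      mb, mrna.variance, pb, prot.variance)
        assert ps.variance / ps.mean ** 2 == cv2

    def test_two_stage_constitutive_fano_is_exact(self):
        # Poisson transcription + geometric protein bursts: the scaled mode
        # must reproduce the classic exact result F_p = 1 + b/(1 + mu_p/mu_m)
        kb, mu_m, mu_p, pb = Fraction(2), Fraction(1), Fraction(1, 4), Fraction(3)
        comp = bq.compose(bq.BurstDistribution.unit(),
                          bq.BurstDistribution.geometric_from_mean(pb))
        ps = bq.protein_moments(bq.exponential_transform(kb), comp, mu_m, mu_p,
                                mode="scaled")
        assert ps.fano == 1 + pb / (1 + mu_p / mu_m)


class TestProductionRate:
    def test_direct_substitution(self):
        ratio, kp = bq.production_rate_from_means(10, 1000, 1.0, 0.01)
        assert ratio == pytest.approx(1.0)
        assert kp == pytest.approx(1.0)

    def test_arrival_process_invariance_analytic(self):
        # the mean-based estimator depends only on Little's law, so Poisson
        # and telegraph arrivals at matched means give identical k_p
        mb, pb, mu_m, mu_p = 5.0, 2.0, 1.0, 0.05
        comp = bq.compose(bq.BurstDistribution.conditional_geometric_from_mean(mb),
                          bq.BurstDistribution.geometric_from_mean(pb))
        burst = bq.BurstDistribution.conditional_geometric_from_mean(mb)
        out = {}
        for name, f in (("poisson", bq.exponential_transform(0.4)),
                        ("telegraph", bq.telegraph_arrival_transform(
                            bq.TelegraphParameters(0.25, 1.0, 2.0)))):
            ms = bq.mrna_moments(f, burst, mu_m)
            ps = bq.protein_moments(f, comp, mu_m, mu_p, mode="burst_limit")
            out[name] = bq.production_rate_from_means(ms.mean, ps.mean, mu_m, mu_p)[1]
        assert float(out["poisson"]) == pytest.approx(float(out["telegraph"]))
        assert float(out["poisson"]) == pytest.approx(pb * mu_m)

    def test_ssa_recovery_of_kp(self):
        kp = 0.5
        burst = bq.BurstDistribution.conditional_geometric_from_mean(5.0)
        scheme = bq.PromoterScheme.telegraph(0.5, 0.25, 2.0, 1.0, batch=burst,
                                             k_p=kp, mu_p=0.05)
        out = bq.simulate(scheme, 20_000, seed=8)
        em = bq.empirical_moments(out.mrna, n_boot=150, seed=2)
        ep = bq.empirical_moments(out.protein, n_boot=150, seed=3)
        _, kp_hat = bq.production_rate_from_means(em.mean, ep.mean, 1.0, 0.05)
        se = kp_hat * math.hypot(em.se["mean"] / em.mean, ep.se["mean"] / ep.mean)
        assert abs(kp_hat - kp) < 3 * se

    def test_zero_mean_rejected(self):
        with pytest.raises(bq.InvalidModelError):
            bq.production_rate_from_means(0, 10, 1, 1)


class TestFactorialRecursion:
    def test_orders_one_two_reproduce_mean_and_noise(self, telegraph_exact):
        _, f = telegraph_exact
        burst = bq.BurstDistribution.conditional_geometric_from_mean(Fraction(5))
        mu = Fraction(2, 3)
        m = bq.higher_factorial_moments(f, burst, mu, 2)
        assert m[0] == f.mean_rate * Fraction(5) / mu  # Little's law
        mean, var = _central_from_factorial(m)
        kg = f.gestation_factor(mu)
        assert var / mean == 1 + Fraction(5, 2) * (kg - 1) + burst.factorial_moment(2) / 10

    def test_poisson_reduction_matches_hand_forms(self):
        # for exponential interarrival all moments reduce to the K_g = 1
        # forms; nu3/mean = 1 + (3/2) b2/b1 + b3/(3 b1)
        kb, mu = Fraction(3, 2), Fraction(1, 2)
        burst = bq.BurstDistribution.negative_binomial(3, Fraction(2, 5))
        ms = bq.mrna_moments(bq.exponential_transform(kb), burst, mu)
        b1, b2, b3 = burst.factorial_moments(3)
        assert ms.skew_combination == 1 + Fraction(3, 2) * b2 / b1 + b3 / (3 * b1)

    def test_order_four_matches_ssa(self):
        # covered at telegraph parameters in TestMrnaMoments; here the
        # Erlang-arrival case exercises a different pole structure
        f = bq.f_from_g(bq.erlang_transform(2, 0.5), 5.0, 2.0)
        scheme = bq.PromoterScheme.activation_chain((0.5, 0.5), 2.0, 5.0, 1.0)
        out = bq.simulate(scheme, 50_000, seed=23)
        emp = bq.empirical_moments(out.mrna, n_boot=250, seed=4)
        m = bq.steady_state_factorial_moments(f, [1], 1.0, 4)
        cen = _central_from_factorial(m)
        for field, val in zip(("mean", "variance", "third_central", "fourth_central"), cen):
            z = (getattr(emp, field) - val) / emp.se[field]
            assert abs(z) < 3.5, f"{field}: z={z:.2f}"

    def test_recursion_divergence_error(self):
        f = bq.exponential_transform(1.0)
        with pytest.raises(bq.InvalidModelError):
            bq.steady_state_factorial_moments(f, [1], 0.0, 2)
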