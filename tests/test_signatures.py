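"""Noise signatures: null calibration, closed forms, detection."""

import warnings
from fractions import Fraction

import numpy as np
import pytest

import burstq as bq
from burstq.signatures import NULL_VALUES, RatePairingWarning, UndefinedSignatureError
from conftest import random_poisson_null_model


class TestNullConditions:
    def test_poisson_conditional_geometric_zeroes_Dm(self):
        f = bq.exponential_transform(Fraction(3, 2))
        b = bq.BurstDistribution.conditional_geometric_from_mean(Fraction(4))
        ms = bq.mrna_moments(f, b, Fraction(1))
        assert bq.signature_Dm(ms) == 0

    def test_poisson_geometric_compound_zeroes_Dp(self):
        f = bq.exponential_transform(Fraction(1))
        comp = bq.compose(bq.BurstDistribution.conditional_geometric_from_mean(Fraction(5)),
                          bq.BurstDistribution.geometric_from_mean(Fraction(2)))
        ps = bq.protein_moments(f, comp, Fraction(1), Fraction(1, 20), mode="scaled")
        assert bq.signature_Dp(ps, Fraction(1), Fraction(1, 20)) == 0

    def test_Dmp_null_holds_for_arbitrary_burst_distribution(self):
        # the joint signature needs no geometric assumption: negative binomial
        # mRNA bursts with Poisson arrivals still give exactly zero
        f = bq.exponential_transform(Fraction(2))
        nb = bq.BurstDistribution.negative_binomial(3, Fraction(1, 3))
        prot = bq.BurstDistribution.geometric_from_mean(Fraction(2))
        ms = bq.mrna_moments(f, nb, Fraction(1))
        ps = bq.protein_moments(f, bq.compose(nb, prot), Fraction(1), Fraction(1, 50),
                                mode="scaled")
        assert bq.signature_Dmp(ms, ps, Fraction(1), Fraction(1, 50)) == 0


class TestTelegraphClosedForms:
    def test_beta_zero_limit_vanishes(self):
        vals = []
        for beta in (1e-3, 1e-6):
            dm, dp, dmp = bq.telegraph_closed_forms(
                bq.TelegraphParameters(0.25, beta, 2.0), 5.0, k_p=0.5,
                mu_m=1.0, mu_p=0.01)
            vals.append((abs(dm), abs(dp), abs(dmp)))
        # all three statistics vanish linearly as beta -> 0 (Poisson limit)
        assert all(v < 1e-3 for v in vals[1])
        for a, b in zip(vals[0], vals[1]):
            assert 100 < a / b < 2000

    def test_fast_switching_limit_vanishes(self):
        dm, dp, _ = bq.telegraph_closed_forms(
            bq.TelegraphParameters(500.0, 500.0, 2.0), 5.0, k_p=0.5,
            mu_m=1.0, mu_p=0.01)
        assert abs(dm) < 1e-3 and abs(dp) < 1e-3

    def test_Dmp_zero_at_equal_decay_rates(self):
        _, _, dmp = bq.telegraph_closed_forms(
            bq.TelegraphParameters(0.25, 1.0, 2.0), 5.0, mu_m=1.0, mu_p=1.0)
        assert dmp == 0

    def test_Dmp_negative_when_protein_outlives_mrna(self):
        for beta in (0.25, 1.0, 4.0):
            _, _, dmp = bq.telegraph_closed_forms(
                bq.TelegraphParameters(0.25, beta, 2.0), 5.0, mu_m=1.0, mu_p=0.01)
            assert dmp < 0

    def test_Dmp_equals_gestation_factor_difference(self, telegraph_exact):
        # D_mp = [K_g(mu_m) - K_g(mu_p)] / (2 k_b), exactly
        params, f = telegraph_exact
        mu_m, mu_p = Fraction(1), Fraction(1, 100)
        _, _, dmp = bq.telegraph_closed_forms(
            bq.TelegraphParameters(0.25, 1.0, 2.0), 5.0, mu_m=1.0, mu_p=0.01)
        exact = (f.gestation_factor(mu_m) - f.gestation_factor(mu_p)) / (2 * f.mean_rate)
        assert dmp == pytest.approx(float(exact), rel=1e-12)


class TestGm:
    def test_conditional_geometric_invariant_under_arrival_process(self, telegraph_exact):
        # G_m = 1 for conditional-geometric bursts under Poisson, telegraph
        # and Erlang-gestation arrivals alike
        _, tele = telegraph_exact
        arrivals = [bq.exponential_transform(Fraction(2)), tele,
                    bq.f_from_g(bq.erlang_transform(2, Fraction(1, 2)),
                                Fraction(5), Fraction(2))]
        b = bq.BurstDistribution.conditional_geometric_from_mean(Fraction(7, 2))
        for f in arrivals:
            m1 = bq.mrna_moments(f, b, Fraction(1))
            m2 = bq.mrna_moments(f, b, Fraction(2))
            assert bq.signature_Gm(m1, m2) == 1

    def test_negative_binomial_bursts_deviate(self):
        f = bq.exponential_transform(Fraction(1))
        nb = bq.BurstDistribution.negative_binomial(2, Fraction(1, 2))
        m1 = bq.mrna_moments(f, nb, Fraction(1))
        m2 = bq.mrna_moments(f, nb, Fraction(2))
        assert abs(float(bq.signature_Gm(m1, m2)) - 1.0) > 0.1

    def test_rate_pairing_violation_warns(self):
        f = bq.exponential_transform(1.0)
        b = bq.BurstDistribution.conditional_geometric_from_mean(4.0)
        m1 = bq.mrna_moments(f, b, 1.0)
        m_wrong = bq.mrna_moments(f, b, 1.5)  # not a doubled rate
        with pytest.warns(RatePairingWarning):
            bq.signature_Gm(m1, m_wrong)


class TestUndefinedSignatures:
    def test_subpoissonian_denominator_flagged(self):
        ms = bq.MomentSet(mean=10.0, variance=4.0, third_central=1.0)
        with pytest.raises(UndefinedSignatureError):
            bq.signature_Dm(ms)

    def test_report_carries_flag_not_silence(self):
        rng = np.random.default_rng(3)
        # strongly sub-Poissonian counts: D_m undefined, reported as a flag
        counts = rng.integers(9, 12, 4000)
        rep = bq.signatures_from_samples(mrna=counts, n_boot=50, seed=1)
        assert rep.values["D_m"] is None
        assert any("D_m" in fl for fl in rep.flags)


class TestDetection:
    def test_bursty_telegraph_Dm_excludes_zero(self):
        burst = bq.BurstDistribution.conditional_geometric_from_mean(5.0)
        scheme = bq.PromoterScheme.telegraph(0.25, 1.0, 2.0, 1.0, batch=burst)
        out = bq.simulate(scheme, 20_000, seed=29)
        rep = bq.signatures_from_samples(mrna=out.mrna, n_boot=400, seed=7)
        assert rep.excludes_null("D_m") is True
        # point estimate should be near the analytic value
        f = bq.telegraph_arrival_transform(bq.TelegraphParameters(0.25, 1.0, 2.0))
        dm_true = float(bq.signature_Dm(bq.mrna_moments(f, burst, 1.0).as_float()))
        lo, hi = rep.ci["D_m"]
        assert lo < dm_true < hi

    def test_joint_Dmp_excludes_zero(self):
        burst = bq.BurstDistribution.conditional_geometric_from_mean(5.0)
        scheme = bq.PromoterScheme.telegraph(0.25, 1.0, 2.0, 1.0, batch=burst,
                                             k_p=0.5, mu_p=0.05)
        out = bq.simulate(scheme, 20_000, seed=31)
        rep = bq.signatures_from_samples(mrna=out.mrna, protein=out.protein,
                                         mu_m=1.0, mu_p=0.05, n_boot=400, seed=9)
        assert rep.excludes_null("D_mp") is True
        assert rep.values["D_mp"] < 0  # protein outlives mRNA here

    def test_poisson_arrival_data_does_not_exclude_null(self):
        # constitutive (birth-death) expression: unit bursts are the
        # conditional-geometric limit, so D_m must be consistent with 0
        scheme = bq.PromoterScheme((tuple([0.0]),), 0, 4.0, 1.0)
        out = bq.simulate(scheme, 20_000, seed=37)
        rep = bq.signatures_from_samples(mrna=out.mrna, n_boot=400, seed=11)
        assert rep.excludes_null("D_m") is False

    def test_report_json_roundtrip(self):
        rng = np.random.default_rng(6)
        rep = bq.signatures_from_samples(mrna=rng.poisson(8, 5000), n_boot=60, seed=2)
        d = rep.to_dict()
        assert set(d) >= {"values", "ci", "null_values", "flags"}
        assert d["null_values"] == NULL_VALUES


def test_null_calibration_random_models():
    """|D_m|, |D_p|, |D_mp| below 1e-10 and G_m = 1 for random
    Poisson-arrival + (conditional-)geometric-burst models."""
    rng = np.random.default_rng(2024)
    for _ in range(25):
        arrival, burst, protein, mu_m, mu_p = random_poisson_null_model(rng)
        ms = bq.mrna_moments(arrival, burst, mu_m)
        ps = bq.protein_moments(arrival, bq.compose(burst, protein), mu_m, mu_p,
                                mode="scaled")
        assert abs(bq.signature_Dm(ms)) < 1e-10
        assert abs(bq.signature_Dp(ps, mu_m, mu_p)) < 1e-10
        assert abs(bq.signature_Dmp(ms, ps, mu_m, mu_p)) < 1e-10
        ms2 = bq.mrna_moments(arrival, burst, 2 * mu_m)
        assert bq.signature_Gm(ms, ms2) == pytest.approx(1.0, abs=1e-10)
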