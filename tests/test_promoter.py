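import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import ks_1samp

from promsprt.promoter import (
    PromoterArchitecture,
    activation_probability,
    dwell_means,
    dwell_time_distribution,
    generator_matrix,
    hill_coefficient,
    hill_fit,
    residence_time_fractions,
    stationary_distribution,
)
from promsprt.simulate import simulate_trajectory, telegraph_trace

from conftest import random_architecture


class TestGenerator:
    def test_single_site_matrix(self):
        arch = PromoterArchitecture([0.02], [0.08])
        Q = generator_matrix(arch, 5.0)
        muL = 0.02 * 5.0
        assert np.allclose(Q, [[-muL, muL], [0.08, -0.08]])

    def test_rows_sum_to_zero(self, baseline_arch):
        Q = generator_matrix(baseline_arch, 5.6)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-14)

    def test_tridiagonal(self, baseline_arch):
        Q = generator_matrix(baseline_arch, 5.6)
        assert np.allclose(Q, np.triu(np.tril(Q, 1), -1))


class TestStationary:
    def test_single_site(self):
        arch = PromoterArchitecture([0.02], [0.08])
        pi = stationary_distribution(arch, 5.0)
        muL = 0.1
        assert np.allclose(pi, [0.08 / (muL + 0.08), muL / (muL + 0.08)])

    def test_six_site_full_occupancy_at_boundary(self, baseline_arch):
        """Half activation: P(all six bound) ~ 0.495 for the baseline rates."""
        pi = stationary_distribution(baseline_arch, 5.6)
        assert abs(pi[6] - 0.495) < 1e-3
        p = 0.124 / (0.124 + 0.0154)
        assert np.isclose(pi[6], p**6, rtol=1e-12)

    def test_detailed_balance(self, bursty_arch):
        L = 4.1
        pi = stationary_distribution(bursty_arch, L)
        for i in range(1, 7):
            assert np.isclose(
                pi[i] / pi[i - 1], bursty_arch.mu[i - 1] * L / bursty_arch.nu[i - 1]
            )

    def test_matches_gillespie_time_fractions(self, bursty_arch):
        run = simulate_trajectory(bursty_arch, 5.88, 30_000.0, seed=3)
        seg = np.diff(np.append(run.times, run.t_end))
        frac = np.bincount(run.states, weights=seg, minlength=7) / run.t_end
        pi = stationary_distribution(bursty_arch, 5.88)
        # binomial-ish SE on occupancy fractions given ~t_end/tau samples
        n_eff = run.times.size
        se = np.sqrt(pi * (1 - pi) / n_eff) * 3
        assert np.all(np.abs(frac - pi) < 5 * np.maximum(se, 2e-3))

    def test_zero_rate_restricts_to_closed_class(self):
        arch = PromoterArchitecture([0.02, 0.0], [0.08, 0.1])
        with pytest.warns(UserWarning):
            pi = stationary_distribution(arch, 5.0)
        assert pi[2] == 0.0
        assert np.isclose(pi.sum(), 1.0)


class TestActivation:
    def test_monotone_in_concentration(self, baseline_arch):
        Ls = np.geomspace(0.5, 50, 30)
        p = [activation_probability(baseline_arch, 6, L) for L in Ls]
        assert np.all(np.diff(p) > 0)

    def test_saturates_at_high_concentration(self, baseline_arch):
        assert activation_probability(baseline_arch, 6, 1e5) > 0.999

    def test_single_site_half_activation(self):
        arch = PromoterArchitecture([0.08 / 5.0], [0.08])
        assert np.isclose(activation_probability(arch, 1, 5.0), 0.5)

    def test_monotone_in_rates(self):
        rng = np.random.default_rng(11)
        arch = random_architecture(rng)
        base = activation_probability(arch, 3, 5.6)
        mu_up = list(arch.mu)
        mu_up[2] *= 1.05
        assert activation_probability(PromoterArchitecture(mu_up, arch.nu), 3, 5.6) >= base
        nu_up = list(arch.nu)
        nu_up[4] *= 1.05
        assert activation_probability(PromoterArchitecture(arch.mu, nu_up), 3, 5.6) <= base


class TestDwellTimes:
    def test_single_site_off_is_exponential(self):
        arch = PromoterArchitecture([0.02], [0.08])
        off = dwell_time_distribution(arch, 1, 5.0, "OFF")
        t = np.linspace(0, 50, 40)
        assert np.allclose(off.pdf(t), 0.1 * np.exp(-0.1 * t))

    def test_renewal_identity(self, baseline_arch, bursty_arch):
        """P_ON equals tau_on / (tau_on + tau_off) for any architecture."""
        rng = np.random.default_rng(5)
        archs = [baseline_arch, bursty_arch] + [random_architecture(rng) for _ in range(4)]
        for arch in archs:
            for k in (1, 3, 6):
                tau_on, tau_off = dwell_means(arch, k, 5.6)
                P = activation_probability(arch, k, 5.6)
                assert np.isclose(P, tau_on / (tau_on + tau_off), atol=1e-8)

    def test_pdfs_normalized(self, bursty_arch):
        for label in ("ON", "OFF"):
            law = dwell_time_distribution(bursty_arch, 2, 5.88, label)
            norm, _ = quad(law.pdf, 0, 400 * law.mean(), limit=300)
            assert abs(norm - 1.0) < 1e-8

    def test_episode_histogram_matches_phase_type(self, bursty_arch):
        """Simulated ON/OFF episode durations follow the phase-type laws."""
        run = simulate_trajectory(bursty_arch, 5.88, 40_000.0, seed=9)
        trace = telegraph_trace(run, 2)
        states, durs = trace.states, trace.durations
        if trace.censored_last:
            states, durs = states[:-1], durs[:-1]
        # drop the first (empty-start) episode: its entry law differs
        states, durs = states[1:], durs[1:]
        for label, s in (("ON", 1), ("OFF", 0)):
            law = dwell_time_distribution(bursty_arch, 2, 5.88, label)
            sample = durs[states == s]
            assert sample.size > 1500
            res = ks_1samp(sample, lambda t: np.asarray(law.cdf(t)))
            assert res.pvalue > 0.01

    def test_unreachable_class_raises(self):
        arch = PromoterArchitecture([0.02, 0.0], [0.08, 0.1])
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                dwell_time_distribution(arch, 2, 5.0, "ON")


class TestHill:
    def test_single_site_hill_is_one(self, single_site_arch):
        assert np.isclose(hill_coefficient(single_site_arch, 1), 1.0, atol=1e-4)

    def test_six_iid_sites_all_or_nothing(self, baseline_arch):
        """H = 4*6*p^6(1-p) at p = 2^(-1/6) for six i.i.d. sites, k = 6."""
        p = 2 ** (-1 / 6)
        expected = 4 * 6 * p**6 * (1 - p)
        assert np.isclose(hill_coefficient(baseline_arch, 6), expected, atol=2e-3)
        assert abs(hill_coefficient(baseline_arch, 6) - 1.31) < 0.01

    def test_fit_agrees_with_local_slope(self, baseline_arch):
        H_local = hill_coefficient(baseline_arch, 6)
        L_half = 5.6 * (0.495 / 0.5) ** 0  # boundary is ~half activation
        grid = np.geomspace(L_half / 4, L_half * 4, 25)
        H_fit = hill_fit(baseline_arch, 6, grid)
        assert abs(H_fit - H_local) / H_local < 0.2

    def test_error_when_never_half_active(self):
        arch = PromoterArchitecture([1e-9], [10.0])
        with pytest.raises(ValueError):
            hill_coefficient(arch, 1, L_lo=1.0, L_hi=10.0)


def test_residence_fractions_equal_stationary(baseline_arch):
    assert np.array_equal(
        residence_time_fractions(baseline_arch, 5.6),
        stationary_distribution(baseline_arch, 5.6),
    )


def test_diffusion_limit_check(baseline_arch):
    assert baseline_arch.respects_diffusion_limit()
    too_fast = PromoterArchitecture([1.0] * 6, [0.1] * 6)
    assert not too_fast.respects_diffusion_limit()
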