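import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import ks_1samp

from promsprt.embryo import BoundaryProblem
from promsprt.promoter import PromoterArchitecture
from promsprt.reduced import (
    EnhancerModel,
    TwoSiteCycleModel,
    _cycle_dwell_laws,
    _joint_dwell_laws,
    compare_k1_k2_cycles,
    cycle_decision_time,
    cycle_off_time_pdf,
    cycle_on_time_pdf,
    enhancer_promoter_decision,
    equilibrium_one_vs_two_sites,
    optimal_weak_second_site,
)
from promsprt.sprt import decision_statistics


class TestCycleDensities:
    @pytest.mark.parametrize("mu1,mu2", [(0.1, 0.05), (0.02, 0.3), (0.1, 0.1)])
    def test_off_density_normalized_with_stage_mean(self, mu1, mu2):
        L = 5.6
        norm, _ = quad(lambda t: cycle_off_time_pdf(mu1, mu2, L, t), 0, 5000)
        mean, _ = quad(lambda t: t * cycle_off_time_pdf(mu1, mu2, L, t), 0, 10000)
        assert abs(norm - 1.0) < 1e-7
        assert np.isclose(mean, 1 / (mu1 * L) + 1 / (mu2 * L), rtol=1e-6)

    def test_equal_rates_match_gamma(self):
        t = np.array([0.5, 3.0, 11.0])
        a = 0.08 * 5.6
        gamma = a * a * t * np.exp(-a * t)
        assert np.allclose(cycle_off_time_pdf(0.08, 0.08, 5.6, t), gamma)

    def test_on_density_stated_form(self):
        mu2, nu, L = 0.05, 0.3, 5.6
        t = np.linspace(0.1, 30, 20)
        a = mu2 * L
        expected = nu * a / (nu - a) * (np.exp(-a * t) - np.exp(-nu * t))
        assert np.allclose(cycle_on_time_pdf(mu2, nu, L, t), expected)

    def test_on_density_fast_unbinding_limit(self):
        """nu -> inf: ON time dominated by the second binding."""
        mu2, L = 0.05, 5.6
        t = np.linspace(0.5, 30, 10)
        approx = cycle_on_time_pdf(mu2, 1e4, L, t)
        assert np.allclose(approx, mu2 * L * np.exp(-mu2 * L * t), rtol=1e-2)

    def test_phase_type_matches_closed_form(self):
        model = TwoSiteCycleModel("all_or_nothing_k2", mu1=0.1, mu2=0.04, nu=0.3)
        on, off = _cycle_dwell_laws(model, 5.6)
        t = np.linspace(0.05, 40, 30)
        assert np.allclose(off.pdf(t), cycle_off_time_pdf(0.1, 0.04, 5.6, t), rtol=1e-9)


class TestCycleComparison:
    def test_equal_speed_on_locus(self):
        """Along L mu1 = nu the k=1 and k=2 rules decide equally fast."""
        L = 5.6
        for mu1 in (0.05, 0.2, 1.0):
            df = compare_k1_k2_cycles([mu1], [L * mu1], L=L)
            row = df.iloc[0]
            assert abs(row.T_k1 - row.T_k2) / row.T_k1 < 0.01

    def test_high_concentration_favors_all_or_nothing(self):
        df = compare_k1_k2_cycles([0.2], [0.02], L=5.6)  # L mu1 >> nu
        assert df.iloc[0].faster == "k2"

    def test_low_concentration_favors_one_or_more(self):
        df = compare_k1_k2_cycles([0.2], [11.2], L=5.6)  # L mu1 << nu
        assert df.iloc[0].faster == "k1"

    def test_k1_reduces_to_single_site_at_strong_first_binding(self):
        """mu1 L / nu -> infinity: deactivation carries no extra
        information and the k=1 cycle performs like one site."""
        L = 5.6
        problem = BoundaryProblem(L1=L, L2=0.95 * L, delta_x=np.nan, error_rate=0.05)
        k1 = TwoSiteCycleModel("one_or_more_k1", mu1=0.5, mu2=50.0, nu=0.05)
        ss = TwoSiteCycleModel("single_site", mu1=0.5, nu=0.05)
        t_k1 = cycle_decision_time(k1, problem, L).mean_time
        t_ss = cycle_decision_time(ss, problem, L).mean_time
        assert abs(t_k1 - t_ss) / t_ss < 0.05


class TestEquilibriumPhaseDiagram:
    def test_regimes_across_nu2(self):
        """Fast second unbinding collapses to one effective site; slow
        second unbinding at high L favors using both sites."""
        df = equilibrium_one_vs_two_sites(
            nu2_grid=[5.0, 0.02], L_grid=[30.0], n_starts=3, seed=1
        )
        regimes = dict(zip(df["nu2"], df["regime"]))
        assert regimes[5.0] == "one_site"
        assert regimes[0.02] == "two_site"

    def test_no_silent_failures(self):
        df = equilibrium_one_vs_two_sites([0.5], [5.0], n_starts=2, seed=2)
        assert set(df["regime"]).issubset({"one_site", "two_site", "failed"})
        assert (df["regime"] != "failed").all()


class TestWeakSecondSite:
    def test_weak_region_detection(self):
        """The optimum sits at the cap over most of the plane; interior
        optima, where present (slow unbinding, low concentration), are
        flagged.  The advantage of a weaker site is marginal under these
        conventions."""
        df = optimal_weak_second_site(L_grid=[0.3, 30.0], nu_grid=[0.05, 2.0])
        assert np.all(df["mu2_star"] <= 0.2 * (1 + 1e-6))
        at_cap = df[(df.L == 30.0)]
        assert (~at_cap["weak_site"]).all()

    def test_objective_continuous_and_monotone_toward_zero(self):
        """mu2 -> 0 blocks the cycle's deactivation path, so the decision
        time grows smoothly (roughly inverse in mu2) without jumps."""
        L = 5.6
        problem = BoundaryProblem(L1=L, L2=0.95 * L, delta_x=np.nan, error_rate=0.05)
        times = []
        for mu2 in (1e-3, 2e-3, 4e-3, 8e-3):
            m = TwoSiteCycleModel("one_or_more_k1", mu1=0.2, mu2=mu2, nu=0.5)
            times.append(cycle_decision_time(m, problem, L).mean_time)
        assert np.all(np.isfinite(times))
        assert np.all(np.diff(times) < 0)  # decreasing in mu2
        ratios = np.array(times[:-1]) / np.array(times[1:])
        assert np.all(ratios < 3.0)


class TestEnhancer:
    def test_always_on_enhancer_reduces_to_promoter(self, bursty_arch):
        problem = BoundaryProblem(L1=5.88, L2=5.32, delta_x=2.0, error_rate=0.32)
        enh = EnhancerModel(mu_e=0.0221, e_off=0.0)
        joint = enhancer_promoter_decision(bursty_arch, 2, enh, problem)
        alone = decision_statistics(bursty_arch, 2, problem)
        assert np.isclose(joint.mean_time, alone.mean_time, rtol=1e-6)

    def test_joint_dwell_renewal_identity(self, bursty_arch):
        enh = EnhancerModel(mu_e=0.0221, e_off=0.1)
        L = 5.88
        on, off = _joint_dwell_laws(bursty_arch, 2, enh, L)
        from promsprt.promoter import activation_probability

        p_prom = activation_probability(bursty_arch, 2, L)
        p_enh = enh.e_on(L) / (enh.e_on(L) + enh.e_off)
        P_joint = p_prom * p_enh
        assert np.isclose(on.mean() / (on.mean() + off.mean()), P_joint, atol=1e-8)

    def test_joint_dwell_matches_simulated_and_gate(self, bursty_arch):
        """ON episodes of the simulated promoter-AND-enhancer signal follow
        the product-chain phase-type law (flux entry on a non-birth-death
        chain)."""
        rng = np.random.default_rng(17)
        L, k = 5.88, 2
        enh = EnhancerModel(mu_e=0.0221, e_off=0.05)
        from promsprt.simulate import simulate_trajectory

        run = simulate_trajectory(bursty_arch, L, 30_000.0, seed=18)
        # independent enhancer telegraph on the same clock
        e_on = enh.e_on(L)
        t, s = 0.0, 1
        etimes, estates = [0.0], [1]
        while t < 30_000.0:
            t += rng.exponential(1.0 / (e_on if s == 0 else enh.e_off))
            s = 1 - s
            etimes.append(t)
            estates.append(s)
        # AND the two signals on the merged event grid
        times = np.unique(np.concatenate([run.times, etimes, [30_000.0]]))
        ip = np.searchsorted(run.times, times, side="right") - 1
        ie = np.searchsorted(etimes, times, side="right") - 1
        act = (run.states[ip] >= k) & (np.array(estates)[ie] == 1)
        seg = np.diff(times)
        # collapse to ON episode durations
        durs, cur = [], 0.0
        for a, d in zip(act[:-1], seg):
            if a:
                cur += d
            elif cur > 0:
                durs.append(cur)
                cur = 0.0
        durs = np.array(durs[1:])
        on, _ = _joint_dwell_laws(bursty_arch, k, enh, L)
        res = ks_1samp(durs, lambda x: np.asarray(on.cdf(x)))
        assert res.pvalue > 0.01
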