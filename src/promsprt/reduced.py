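"""Two-binding-site reduced models and the enhancer AND-gate extension.

Four minimal promoters isolate how activation rules shape decision speed:

* ``all_or_nothing_k2`` — out-of-equilibrium cycle 0 -> 1 -> 2 (bindings at
  mu1 L, mu2 L), gene ON in state 2, deactivation by unbinding of the whole
  complex at rate nu back to state 0.  OFF times are the convolution of two
  concentration-dependent exponentials; ON times are uninformative.
* ``one_or_more_k1`` — cycle where the first binding activates; ON times
  convolve the second binding (mu2 L) with the complex unbinding (nu), so
  deactivation times carry concentration information.
* ``equilibrium_k2``  — reversible two-site chain with all-or-nothing
  activation.
* ``single_site``     — the one-site equilibrium reference.

The enhancer extension multiplies the promoter chain by an independent
two-state enhancer; the gene is transcribed only when both are ON.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from .embryo import BoundaryProblem
from .phasetype import PhaseType, kl_divergence
from .promoter import PromoterArchitecture, stationary_distribution, _k_of
from .sprt import DecisionStatistics, mean_decision_time, wrong_decision_probability

__all__ = [
    "TwoSiteCycleModel",
    "EnhancerModel",
    "cycle_off_time_pdf",
    "cycle_on_time_pdf",
    "cycle_decision_time",
    "compare_k1_k2_cycles",
    "equilibrium_one_vs_two_sites",
    "optimal_weak_second_site",
    "enhancer_promoter_decision",
]

_VARIANTS = ("all_or_nothing_k2", "one_or_more_k1", "equilibrium_k2", "single_site")


@dataclass(frozen=True)
class TwoSiteCycleModel:
    """A reduced promoter variant with its rate parameters.

    mu1, mu2 in um^3 s^-1; nu (or nu1/nu2 for the equilibrium variant)
    in s^-1.  Which rates are meaningful depends on ``variant``.
    """

    variant: str
    mu1: float
    mu2: float = 0.0
    nu: float = 0.0
    nu1: float = 0.0
    nu2: float = 0.0

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}")
        for r in (self.mu1, self.mu2, self.nu, self.nu1, self.nu2):
            if r < 0:
                raise ValueError("rates must be nonnegative")


def cycle_off_time_pdf(mu1: float, mu2: float, L: float, t) -> np.ndarray:
    """OFF-time density of the all-or-nothing two-site cycle.

    Convolution of Exp(mu1 L) and Exp(mu2 L):
    P_OFF(t) = mu1 mu2 L / (mu2 - mu1) (exp(-mu1 L t) - exp(-mu2 L t));
    the equal-rate limit is the Gamma(2, mu L) density.
    """
    t = np.asarray(t, dtype=float)
    a, b = mu1 * L, mu2 * L
    if np.isclose(a, b, rtol=1e-9):
        return a * a * t * np.exp(-a * t)
    return a * b / (b - a) * (np.exp(-a * t) - np.exp(-b * t))


def cycle_on_time_pdf(mu2: float, nu: float, L: float, t) -> np.ndarray:
    """ON-time density of the one-or-more two-site cycle.

    P_ON(t) = nu mu2 L / (nu - mu2 L) (exp(-mu2 L t) - exp(-nu t));
    equal rates give the Gamma(2) limit.
    """
    t = np.asarray(t, dtype=float)
    a, b = mu2 * L, nu
    if np.isclose(a, b, rtol=1e-9):
        return a * a * t * np.exp(-a * t)
    return a * b / (b - a) * (np.exp(-a * t) - np.exp(-b * t))


def _hypoexp(rate1: float, rate2: float) -> PhaseType:
    """Phase-type form of the convolution of two exponentials."""
    return PhaseType(
        alpha=[1.0, 0.0], S=[[-rate1, rate1], [0.0, -rate2]]
    )


def _cycle_dwell_laws(model: TwoSiteCycleModel, L: float):
    """(P_ON, P_OFF) phase-type laws of a reduced model at concentration L."""
    v = model.variant
    if v == "all_or_nothing_k2":
        off = _hypoexp(model.mu1 * L, model.mu2 * L)
        on = PhaseType([1.0], [[-model.nu]])
    elif v == "one_or_more_k1":
        off = PhaseType([1.0], [[-model.mu1 * L]])
        on = _hypoexp(model.mu2 * L, model.nu)
    elif v == "single_site":
        off = PhaseType([1.0], [[-model.mu1 * L]])
        on = PhaseType([1.0], [[-model.nu]])
    elif v == "equilibrium_k2":
        arch = PromoterArchitecture([model.mu1, model.mu2], [model.nu1, model.nu2])
        from .promoter import dwell_time_distribution

        on = dwell_time_distribution(arch, 2, L, "ON")
        off = dwell_time_distribution(arch, 2, L, "OFF")
    else:  # pragma: no cover
        raise ValueError(v)
    return on, off


def cycle_decision_time(
    model: TwoSiteCycleModel, problem: BoundaryProblem, L: float | None = None
) -> DecisionStatistics:
    """Drift-diffusion decision statistics of a reduced model (D = V)."""
    L = problem.L2 if L is None else L
    on, off = _cycle_dwell_laws(model, L)
    on1, off1 = _cycle_dwell_laws(model, problem.L1)
    on2, off2 = _cycle_dwell_laws(model, problem.L2)
    V = (
        kl_divergence(off, off2)
        - kl_divergence(off, off1)
        + kl_divergence(on, on2)
        - kl_divergence(on, on1)
    ) / (on.mean() + off.mean())
    K = problem.K
    if V == 0:
        raise ValueError("zero drift: hypotheses indistinguishable for this model")
    return DecisionStatistics(
        V=V,
        D=abs(V),
        K=K,
        mean_time=mean_decision_time(V, abs(V), K),
        error_prob=wrong_decision_probability(V, abs(V), K),
        tau_on=on.mean(),
        tau_off=off.mean(),
    )


def compare_k1_k2_cycles(
    mu1_grid,
    nu_grid,
    L: float = 5.6,
    error_rate: float = 0.1,
    delta_rel: float = 0.05,
    mu2_factor: float = 0.5,
) -> pd.DataFrame:
    """Decision-time map of the k=1 vs k=2 cycle rules on a (mu1, nu) grid.

    mu2 is tied to mu1 (``mu2 = mu2_factor * mu1``); hypotheses are
    (L, (1-delta_rel) L) with truth L.  Along the locus L mu1 = nu the two
    rules perform at the same speed.
    """
    problem = BoundaryProblem(
        L1=L, L2=L * (1.0 - delta_rel), delta_x=np.nan, error_rate=error_rate
    )
    rows = []
    for mu1 in np.atleast_1d(mu1_grid):
        for nu in np.atleast_1d(nu_grid):
            m2 = TwoSiteCycleModel("all_or_nothing_k2", mu1=mu1, mu2=mu2_factor * mu1, nu=nu)
            m1 = TwoSiteCycleModel("one_or_more_k1", mu1=mu1, mu2=mu2_factor * mu1, nu=nu)
            t2 = cycle_decision_time(m2, problem, L).mean_time
            t1 = cycle_decision_time(m1, problem, L).mean_time
            rows.append((mu1, nu, t1, t2, "k1" if t1 < t2 else "k2"))
    return pd.DataFrame(rows, columns=["mu1", "nu", "T_k1", "T_k2", "faster"])


def equilibrium_one_vs_two_sites(
    nu2_grid,
    L_grid,
    error_rate: float = 0.05,
    delta_rel: float = 0.05,
    mu_cap: float = 5.0,
    nu1_cap: float = 5.0,
    n_starts: int = 4,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Where do two equilibrium sites beat one?  (phase diagram)

    At each (nu2, L) grid point, (mu1, mu2, nu1) are optimized for the
    fastest all-or-nothing two-site decision at the given error rate,
    subject to mu1, mu2 <= ``mu_cap`` um^3 s^-1 (diffusion-limited
    arrival) and nu1 <= ``nu1_cap`` s^-1.  The point is classified
    ``two_site`` when the optimal first unbinding rate stays away from
    zero, ``one_site`` when nu1* -> 0 (the promoter never fully empties,
    collapsing to a one-site switch).  Failed optimizations are flagged.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for nu2 in np.atleast_1d(nu2_grid):
        for L in np.atleast_1d(L_grid):
            problem = BoundaryProblem(
                L1=L, L2=L * (1.0 - delta_rel), delta_x=np.nan, error_rate=error_rate
            )

            def objective(theta):
                mu1, mu2, nu1 = np.exp(theta)
                if mu1 > mu_cap or mu2 > mu_cap or nu1 > nu1_cap:
                    return 1e12
                model = TwoSiteCycleModel(
                    "equilibrium_k2", mu1=mu1, mu2=mu2, nu1=nu1, nu2=nu2
                )
                try:
                    return cycle_decision_time(model, problem, L).mean_time
                except (ValueError, np.linalg.LinAlgError):
                    return 1e12

            best = None
            for _ in range(n_starts):
                theta0 = np.log(
                    [
                        mu_cap * rng.uniform(0.1, 1.0),
                        mu_cap * rng.uniform(0.1, 1.0),
                        np.exp(rng.uniform(np.log(1e-6), np.log(nu1_cap))),
                    ]
                )
                res = minimize(
                    objective, theta0, method="Nelder-Mead",
                    options={"maxfev": 250, "xatol": 1e-3, "fatol": 1e-3},
                )
                if best is None or res.fun < best.fun:
                    best = res
            ok = best is not None and best.fun < 1e11
            if not ok:
                rows.append((nu2, L, np.nan, np.nan, np.nan, np.nan, "failed"))
                continue
            mu1, mu2, nu1 = np.exp(best.x)
            # one-site collapse: emptying the promoter is negligible on the
            # cycle timescale
            regime = "one_site" if nu1 * best.fun < 1.0 or nu1 < 1e-3 else "two_site"
            rows.append((nu2, L, best.fun, mu1, mu2, nu1, regime))
    return pd.DataFrame(
        rows, columns=["nu2", "L", "mean_time", "mu1", "mu2", "nu1", "regime"]
    )


def optimal_weak_second_site(
    L_grid,
    nu_grid,
    mu1: float = 0.2,
    error_rate: float = 0.05,
    delta_rel: float = 0.05,
) -> pd.DataFrame:
    """Optimal ordered second binding rate mu2* <= mu1 for the k=1 cycle.

    Binding is ordered (the second site opens only after the first binds),
    so the diffusion limit gives 0 <= mu2 <= mu1.  A gray-stripe region of
    (L, nu) exists where the optimum is strictly interior: a weaker second
    site decides faster.
    """
    rows = []
    for L in np.atleast_1d(L_grid):
        problem = BoundaryProblem(
            L1=L, L2=L * (1.0 - delta_rel), delta_x=np.nan, error_rate=error_rate
        )
        for nu in np.atleast_1d(nu_grid):

            def objective(mu2):
                model = TwoSiteCycleModel("one_or_more_k1", mu1=mu1, mu2=mu2, nu=nu)
                return cycle_decision_time(model, problem, L).mean_time

            res = minimize_scalar(
                objective, bounds=(1e-6 * mu1, mu1), method="bounded",
                options={"xatol": 1e-4 * mu1},
            )
            mu2_star = float(res.x)
            # flag only clearly interior optima (beyond optimizer jitter)
            weak = mu2_star < 0.95 * mu1
            rows.append((L, nu, mu2_star, res.fun, weak))
    return pd.DataFrame(rows, columns=["L", "nu", "mu2_star", "mean_time", "weak_site"])


@dataclass(frozen=True)
class EnhancerModel:
    """Two-state enhancer switching independently of the promoter.

    ``mu_e`` is the ON-switch rate constant (um^3 s^-1; the ON rate at
    concentration L is mu_e * L, diffusion-limited for a one-site
    enhancer); ``e_off`` the OFF-switch rate (s^-1).
    """

    mu_e: float
    e_off: float

    def __post_init__(self) -> None:
        if self.mu_e < 0 or self.e_off < 0:
            raise ValueError("rates must be nonnegative")

    @classmethod
    def from_on_rate(cls, e_on: float, L_ref: float, e_off: float) -> "EnhancerModel":
        return cls(mu_e=e_on / L_ref, e_off=e_off)

    def e_on(self, L: float) -> float:
        return self.mu_e * L


def _joint_dwell_laws(arch, rule, enh: EnhancerModel, L: float):
    """ON/OFF dwell laws of the promoter x enhancer product chain.

    States are (i, s): promoter occupancy i in 0..N, enhancer s in {0, 1};
    the gene is ON iff i >= k and s = 1.  Entry laws are stationary
    flux-weighted (the product chain is not birth-death, so the entry
    distribution is genuinely spread over several states).
    """
    from .promoter import generator_matrix

    k = _k_of(rule)
    N = arch.N
    Qp = generator_matrix(arch, L)
    Qe = np.array([[-enh.e_on(L), enh.e_on(L)], [enh.e_off, -enh.e_off]])
    n_p, n_e = N + 1, 2
    Q = np.kron(Qp, np.eye(n_e)) + np.kron(np.eye(n_p), Qe)
    pi_p = stationary_distribution(arch, L)
    pe_on = enh.e_on(L) / (enh.e_on(L) + enh.e_off)
    pi = np.kron(pi_p, np.array([1.0 - pe_on, pe_on]))
    occ = np.repeat(np.arange(n_p), n_e)
    enh_state = np.tile(np.arange(n_e), n_p)
    inside_on = (occ >= k) & (enh_state == 1)

    def law(inside, label):
        outside = ~inside
        flux = pi[outside] @ Q[np.ix_(outside, inside)]
        total = flux.sum()
        if total <= 0:
            raise ValueError(f"{label} class unreachable")
        return PhaseType(
            alpha=flux / total, S=Q[np.ix_(inside, inside)], label=label
        )

    return law(inside_on, "ON"), law(~inside_on, "OFF")


def enhancer_promoter_decision(
    arch: PromoterArchitecture,
    rule,
    enh: EnhancerModel,
    problem: BoundaryProblem,
    L: float | None = None,
) -> DecisionStatistics:
    """SPRT statistics of the joint enhancer-promoter telegraph signal."""
    L = problem.L1 if L is None else L
    on, off = _joint_dwell_laws(arch, rule, enh, L)
    on1, off1 = _joint_dwell_laws(arch, rule, enh, problem.L1)
    on2, off2 = _joint_dwell_laws(arch, rule, enh, problem.L2)
    V = (
        kl_divergence(off, off2)
        - kl_divergence(off, off1)
        + kl_divergence(on, on2)
        - kl_divergence(on, on1)
    ) / (on.mean() + off.mean())
    K = problem.K
    return DecisionStatistics(
        V=V,
        D=abs(V),
        K=K,
        mean_time=mean_decision_time(V, abs(V), K) if V != 0 else np.inf,
        error_prob=wrong_decision_probability(V, abs(V), K) if V != 0 else 0.5,
        tau_on=on.mean(),
        tau_off=off.mean(),
    )
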