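"""Sequential probability ratio test on promoter telegraph traces.

The gene-activity signal is a sequence of alternating ON/OFF episodes.
Each completed episode of duration t multiplies the likelihood ratio
R = P(trace | L1)/P(trace | L2) by the ratio of the episode-duration
densities under the two hypothesized concentrations, so log R performs a
random walk that is absorbed at +K (decide L1, anterior) or -K (decide
L2, posterior).  For close hypotheses the walk is a drift-diffusion
process with drift V (a difference of Kullback-Leibler divergence rates)
and diffusivity D; the mean first-passage time and the absorption
probabilities are classical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .embryo import BoundaryProblem, EmbryoGradient, bcd_concentration
from .phasetype import PhaseType, episode_moments, kl_divergence
from .promoter import PromoterArchitecture, dwell_time_distribution, generator_matrix

__all__ = [
    "TelegraphTrace",
    "LikelihoodPath",
    "DecisionStatistics",
    "log_likelihood_path",
    "drift",
    "diffusivity",
    "mean_decision_time",
    "absorption_probability",
    "wrong_decision_probability",
    "decision_statistics",
    "error_and_time_profile",
    "error_profile_at_budget",
    "threshold_for_budget",
]

OFF, ON = 0, 1


@dataclass
class TelegraphTrace:
    """Alternating ON/OFF episodes of the gene-activity signal.

    states : 0/1 array (0 = OFF, 1 = ON), strictly alternating
    durations : positive episode durations (s)
    censored_last : final episode still in progress at observation end
    """

    states: np.ndarray
    durations: np.ndarray
    censored_last: bool = False

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)
        self.durations = np.asarray(self.durations, dtype=float)
        if self.states.shape != self.durations.shape:
            raise ValueError("states and durations must have equal length")
        if np.any(self.durations <= 0):
            raise ValueError("episode durations must be positive")
        if self.states.size and np.any(np.diff(self.states) == 0):
            raise ValueError("states must strictly alternate")
        if not np.all(np.isin(self.states, (OFF, ON))):
            raise ValueError("states must be 0 (OFF) or 1 (ON)")

    @property
    def J_plus(self) -> int:
        """Number of completed OFF->ON switches."""
        n_off = int(np.sum(self.states == OFF))
        if self.censored_last and self.states[-1] == OFF:
            n_off -= 1
        return n_off

    @property
    def J_minus(self) -> int:
        """Number of completed ON->OFF switches."""
        n_on = int(np.sum(self.states == ON))
        if self.censored_last and self.states[-1] == ON:
            n_on -= 1
        return n_on

    @property
    def total_time(self) -> float:
        return float(self.durations.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "episode_index": np.arange(self.states.size),
                "state": self.states,
                "duration_s": self.durations,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, censored_last: bool = False) -> "TelegraphTrace":
        df = df.sort_values("episode_index")
        return cls(
            states=df["state"].to_numpy(),
            durations=df["duration_s"].to_numpy(),
            censored_last=censored_last,
        )


@dataclass
class LikelihoodPath:
    """Log-likelihood ratio after each completed episode."""

    times: np.ndarray
    logR: np.ndarray

    @property
    def Q2(self) -> np.ndarray:
        """Posterior probability of hypothesis L2 (flat prior)."""
        return 1.0 / (1.0 + np.exp(self.logR))

    @property
    def Q1(self) -> np.ndarray:
        return 1.0 - self.Q2


@dataclass
class DecisionStatistics:
    """Drift-diffusion summary of one discrimination problem."""

    V: float
    D: float
    K: float
    mean_time: float
    error_prob: float
    tau_on: float
    tau_off: float


def _dwell_pair(arch, rule, L):
    on = dwell_time_distribution(arch, rule, L, "ON")
    off = dwell_time_distribution(arch, rule, L, "OFF")
    return on, off


def _empty_start_off(arch, rule, L) -> PhaseType:
    """OFF-episode law entered at the fully unbound state (mitotic reset)."""
    from .promoter import _k_of

    k = _k_of(rule)
    Q = generator_matrix(arch, L)
    alpha = np.zeros(k)
    alpha[0] = 1.0
    return PhaseType(alpha=alpha, S=Q[:k, :k], label="OFF")


def log_likelihood_path(
    trace: TelegraphTrace,
    arch: PromoterArchitecture,
    rule,
    L1: float,
    L2: float,
    start: str = "empty",
) -> LikelihoodPath:
    """Accumulate log R over the episodes of a telegraph trace.

    Each completed episode contributes the log-density ratio of its
    duration under the two hypotheses; a censored final episode
    contributes the survival-function ratio.  With ``start='empty'`` the
    first OFF episode is entered at the fully unbound state; with
    ``start='stationary'`` all episodes use the stationary-flux entry law.
    """
    on1, off1 = _dwell_pair(arch, rule, L1)
    on2, off2 = _dwell_pair(arch, rule, L2)
    laws = {ON: (on1, on2), OFF: (off1, off2)}
    inc = np.zeros(trace.states.size)
    for i, (s, d) in enumerate(zip(trace.states, trace.durations)):
        f1, f2 = laws[s]
        if i == 0 and s == OFF and start == "empty":
            f1 = _empty_start_off(arch, rule, L1)
            f2 = _empty_start_off(arch, rule, L2)
        censored = trace.censored_last and i == trace.states.size - 1
        if censored:
            inc[i] = f1.logsf(d) - f2.logsf(d)
        else:
            inc[i] = f1.logpdf(d) - f2.logpdf(d)
    return LikelihoodPath(times=np.cumsum(trace.durations), logR=np.cumsum(inc))


def drift(arch: PromoterArchitecture, rule, L: float, L1: float, L2: float) -> float:
    """Drift of log R per unit time for true concentration L.

    V = [D(Poff(.,L)||Poff(.,L2)) - D(Poff(.,L)||Poff(.,L1))
         + D(Pon(.,L)||Pon(.,L2)) - D(Pon(.,L)||Pon(.,L1))] / (tau_on + tau_off).
    """
    on, off = _dwell_pair(arch, rule, L)
    on1, off1 = (on, off) if L1 == L else _dwell_pair(arch, rule, L1)
    on2, off2 = (on, off) if L2 == L else _dwell_pair(arch, rule, L2)
    num = (
        kl_divergence(off, off2)
        - kl_divergence(off, off1)
        + kl_divergence(on, on2)
        - kl_divergence(on, on1)
    )
    return num / (on.mean() + off.mean())


def diffusivity(
    arch: PromoterArchitecture,
    rule,
    L: float,
    L1: float,
    L2: float,
    method: str = "analytic",
    **mc_kwargs,
) -> float:
    """Diffusivity of the log-likelihood random walk.

    method="identity"    returns D = V (exact for close hypotheses, the
                         Bayesian-update argument);
    method="analytic"    renewal-reward asymptotic variance rate,
                         D = Var(X - V tau_cycle) / (2 E[tau_cycle]) with X
                         the per-cycle log-likelihood increment, computed by
                         quadrature on the phase-type episode laws;
    method="montecarlo"  regression of Var[log R(t)] against 2t over a
                         simulated ensemble (see stochastic_sim); returns
                         the point estimate.
    """
    if method == "identity":
        return drift(arch, rule, L, L1, L2)
    if method == "analytic":
        return _diffusivity_analytic(arch, rule, L, L1, L2)
    if method == "montecarlo":
        from .simulate import diffusivity_montecarlo

        d, _ = diffusivity_montecarlo(arch, rule, L, L1, L2, **mc_kwargs)
        return d
    raise ValueError(f"unknown diffusivity method {method!r}")


def _vd_analytic(arch, rule, L, L1, L2, censor_at=None):
    """(V, D) via quadrature moments of the per-episode increments.

    ``censor_at`` right-censors episodes at a finite observation window
    (see :func:`promsprt.phasetype.episode_moments`).
    """
    on, off = _dwell_pair(arch, rule, L)
    on1, off1 = (on, off) if L1 == L else _dwell_pair(arch, rule, L1)
    on2, off2 = (on, off) if L2 == L else _dwell_pair(arch, rule, L2)
    mo = episode_moments(off, off1, off2, censor_at=censor_at)
    ma = episode_moments(on, on1, on2, censor_at=censor_at)
    tau = mo[3] + ma[3]
    V = (mo[0] + ma[0]) / tau
    var = 0.0
    for ex, ex2, ext, et, et2 in (mo, ma):
        var += (ex2 - ex * ex) - 2 * V * (ext - ex * et) + V * V * (et2 - et * et)
    return V, var / (2.0 * tau)


def _diffusivity_analytic(arch, rule, L, L1, L2):
    return _vd_analytic(arch, rule, L, L1, L2)[1]


def mean_decision_time(V: float, D: float, K: float) -> float:
    """Mean first-passage time of the drift-diffusion walk to +/-K.

    <T> = (K/V) tanh(V K / 2D); the V -> 0 limit is the diffusive K^2/(2D).
    With D = V this is K tanh(K/2)/V = (K/V)(1 - 2e).
    """
    if K < 0 or D <= 0:
        raise ValueError("need K >= 0 and D > 0")
    a = abs(V) * K / (2.0 * D)
    if a < 1e-8:
        return K * K / (2.0 * D)
    return (K / abs(V)) * np.tanh(a)


def absorption_probability(V: float, D: float, K: float) -> float:
    """Probability of first absorption at +K: e^(VK/D) / (1 + e^(VK/D))."""
    if D <= 0:
        raise ValueError("need D > 0")
    x = V * K / D
    return float(1.0 / (1.0 + np.exp(-x)))


def wrong_decision_probability(V: float, D: float, K: float) -> float:
    """Probability of absorbing at the boundary opposed to the drift."""
    return float(1.0 / (1.0 + np.exp(min(abs(V) * K / D, 700.0))))


def decision_statistics(
    arch: PromoterArchitecture,
    rule,
    problem: BoundaryProblem,
    L: float | None = None,
    method: str = "identity",
) -> DecisionStatistics:
    """Drift, diffusivity, mean decision time and error for one problem.

    ``L`` defaults to the anterior hypothesis L1 (a nucleus sitting at the
    border edge).  With ``method='identity'`` the decision time reduces to
    Eq. K(1-2e)/V.
    """
    L = problem.L1 if L is None else L
    if method == "identity":
        V = drift(arch, rule, L, problem.L1, problem.L2)
        D = abs(V)
    else:
        V, D = _vd_analytic(arch, rule, L, problem.L1, problem.L2)
    on, off = _dwell_pair(arch, rule, L)
    K = problem.K
    return DecisionStatistics(
        V=V,
        D=D,
        K=K,
        mean_time=mean_decision_time(V, D, K),
        error_prob=wrong_decision_probability(V, D, K),
        tau_on=on.mean(),
        tau_off=off.mean(),
    )


def _profile_point(arch, rule, problem, L):
    V, D = _vd_analytic(arch, rule, L, problem.L1, problem.L2)
    return V, D


def error_and_time_profile(
    arch: PromoterArchitecture,
    rule,
    grad: EmbryoGradient,
    problem: BoundaryProblem,
    positions: np.ndarray,
) -> pd.DataFrame:
    """Fixed-threshold SPRT error and mean time along the AP axis.

    At each position x the drift V(x) and diffusivity D(x) are evaluated
    at the local concentration; the wrong-boundary probability comes from
    the scale-function absorption formula and the mean time from the
    first-passage formula, both at the problem's threshold K.  Positions
    inside the border region are masked (NaN).
    """
    positions = np.asarray(positions, dtype=float)
    half = problem.delta_x / 2.0
    rows = []
    for x in positions:
        L = float(bcd_concentration(grad, x))
        if abs(x - grad.x0) < half:
            rows.append((x, L, np.nan, np.nan))
            continue
        V, D = _profile_point(arch, rule, problem, L)
        rows.append(
            (
                x,
                L,
                wrong_decision_probability(V, D, problem.K),
                mean_decision_time(V, D, problem.K),
            )
        )
    return pd.DataFrame(
        rows, columns=["position_EL", "concentration", "error_prob", "mean_time_s"]
    )


def threshold_for_budget(V: float, D: float, T_budget: float, K_max: float = 200.0) -> float:
    """Threshold K at which the mean decision time equals ``T_budget``."""
    f = lambda K: mean_decision_time(V, D, K) - T_budget
    if f(K_max) < 0:  # even a huge threshold decides faster than the budget
        return K_max
    return float(brentq(f, 1e-12, K_max, xtol=1e-10))


def error_profile_at_budget(
    arch: PromoterArchitecture,
    rule,
    grad: EmbryoGradient,
    problem: BoundaryProblem,
    positions: np.ndarray,
    T_budget: float = 270.0,
    border_mask_halfwidth: float | None = None,
) -> pd.DataFrame:
    """Error achievable per position when the mean decision time is fixed.

    For each nucleus the symmetric threshold K(x) is raised until the
    drift-diffusion mean decision time exhausts ``T_budget``; the error is
    the wrong-boundary absorption probability at that threshold.  Drift
    and diffusivity are right-censored at the observation window, so
    saturated nuclei far from the border (whose episodes outlast the
    window) correctly report near-zero error.

    This is the per-position error "for a given average decision time"
    used for embryo-wide error counts.  The masked neighbourhood of the
    boundary defaults to +/- delta_x (one full border width on each
    side): a nucleus within one internuclear distance of the border
    carries a concentration within the stated resolution of the
    hypotheses, so no readout can classify it reliably and either fate is
    taken as correct.  Pass ``border_mask_halfwidth=problem.delta_x / 2``
    to mask only the border region itself.
    """
    positions = np.asarray(positions, dtype=float)
    half = border_mask_halfwidth if border_mask_halfwidth is not None else problem.delta_x
    rows = []
    for x in positions:
        L = float(bcd_concentration(grad, x))
        if abs(x - grad.x0) < half:
            rows.append((x, L, np.nan, np.nan))
            continue
        V, D = _vd_analytic(arch, rule, L, problem.L1, problem.L2, censor_at=T_budget)
        K = threshold_for_budget(V, D, T_budget)
        rows.append((x, L, wrong_decision_probability(V, D, K), K))
    return pd.DataFrame(
        rows, columns=["position_EL", "concentration", "error_prob", "threshold_K"]
    )
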