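"""Promoter occupancy chain: stationary behaviour and dwell-time laws.

A promoter with N Bicoid-binding sites is an (N+1)-state birth-death chain
over the number of bound molecules.  Binding step i (state i-1 -> i) has
propensity ``mu[i-1] * L`` (mu in um^3 s^-1, L in molecules um^-3);
unbinding step i (state i -> i-1) has rate ``nu[i-1]`` (s^-1).  The gene is
ON when at least k sites are bound ("k-or-more" rule; k = N is
all-or-nothing, k = 1 is one-or-more).  The durations of contiguous ON and
OFF episodes are phase-type laws over the respective state classes, entered
through the stationary probability flux across the k-1 <-> k boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, curve_fit

from .phasetype import PhaseType

__all__ = [
    "MU_MAX",
    "DIFFUSION_LIMITED_ON_RATE",
    "PromoterArchitecture",
    "ActivationRule",
    "generator_matrix",
    "stationary_distribution",
    "activation_probability",
    "dwell_time_distribution",
    "dwell_means",
    "hill_coefficient",
    "hill_fit",
    "residence_time_fractions",
]

#: diffusion-limited arrival rate at one site at the boundary concentration
DIFFUSION_LIMITED_ON_RATE = 0.124  # s^-1 at L = 5.6 um^-3
#: the same limit as a rate constant per unit concentration
MU_MAX = DIFFUSION_LIMITED_ON_RATE / 5.6  # um^3 s^-1


@dataclass(frozen=True)
class PromoterArchitecture:
    """Per-step binding rate constants ``mu`` and unbinding rates ``nu``.

    ``mu[i-1]`` and ``nu[i-1]`` parameterize the i-th binding/unbinding
    step; both arrays have length N.  Concentration is kept out of ``mu``
    so one architecture can be evaluated at any L.
    """

    mu: tuple
    nu: tuple

    def __init__(self, mu, nu):
        mu = tuple(float(v) for v in np.atleast_1d(mu))
        nu = tuple(float(v) for v in np.atleast_1d(nu))
        if len(mu) != len(nu):
            raise ValueError("mu and nu must have equal length N")
        if any(v < 0 for v in mu) or any(v < 0 for v in nu):
            raise ValueError("rates must be nonnegative")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "nu", nu)

    @property
    def N(self) -> int:
        return len(self.mu)

    @classmethod
    def independent_sites(
        cls,
        N: int = 6,
        on_rate_per_site: float = DIFFUSION_LIMITED_ON_RATE,
        off_rate_per_site: float = 0.0154,
        L_ref: float = 5.6,
    ) -> "PromoterArchitecture":
        """N identical sites binding independently.

        ``on_rate_per_site`` is the per-site binding propensity at the
        reference concentration ``L_ref`` (figure captions quote
        "binding rate per site mu_max L"); the aggregate up-rate from
        state i-1 is (N-i+1) times the per-site rate, the aggregate
        down-rate from state i is i times the per-site unbinding rate.
        Site occupancies are then i.i.d. with p = muL/(muL + nu).
        """
        mu_site = on_rate_per_site / L_ref
        mu = [(N - i + 1) * mu_site for i in range(1, N + 1)]
        nu = [i * off_rate_per_site for i in range(1, N + 1)]
        return cls(mu, nu)

    def respects_diffusion_limit(self, mu_max: float = MU_MAX, rtol: float = 1e-9) -> bool:
        """Check mu[i] <= mu_max * (N+1-i) for every binding step i."""
        return all(
            m <= mu_max * (self.N + 1 - i) * (1 + rtol)
            for i, m in enumerate(self.mu, start=1)
        )


@dataclass(frozen=True)
class ActivationRule:
    """Gene is ON when at least ``k`` sites are bound."""

    k: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


def _k_of(rule) -> int:
    return rule.k if isinstance(rule, ActivationRule) else int(rule)


def generator_matrix(arch: PromoterArchitecture, L: float) -> np.ndarray:
    """Tridiagonal CTMC generator over occupancy states 0..N."""
    if L <= 0:
        raise ValueError("concentration must be positive")
    N = arch.N
    Q = np.zeros((N + 1, N + 1))
    for i in range(1, N + 1):
        Q[i - 1, i] = arch.mu[i - 1] * L
        Q[i, i - 1] = arch.nu[i - 1]
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    return Q


def stationary_distribution(arch: PromoterArchitecture, L: float) -> np.ndarray:
    """Stationary occupancy probabilities of the birth-death chain.

    Uses detailed balance P_i / P_{i-1} = mu[i] L / nu[i].  A zero rate
    splitting the chain is flagged and the distribution is restricted to
    the closed reachable class.
    """
    N = arch.N
    up = np.array(arch.mu) * L
    down = np.array(arch.nu)
    if np.all(up > 0) and np.all(down > 0):
        log_ratio = np.log(up) - np.log(down)
        logw = np.concatenate([[0.0], np.cumsum(log_ratio)])
        logw -= logw.max()
        w = np.exp(logw)
        return w / w.sum()
    # chain splits; find the closed class
    lo, hi = 0, N
    for i in range(N, 0, -1):  # nu[i-1]==0: states < i unreachable long-run
        if down[i - 1] == 0 and up[i - 1] > 0:
            lo = max(lo, i)
    for i in range(1, N + 1):  # mu[i-1]==0: states >= i unreachable
        if up[i - 1] == 0:
            hi = min(hi, i - 1)
    if lo > hi:
        raise ValueError("no closed communicating class (inconsistent zero rates)")
    warnings.warn(
        "zero rate splits the chain; stationary distribution restricted to "
        f"states {lo}..{hi}",
        stacklevel=2,
    )
    pi = np.zeros(N + 1)
    w = np.ones(hi - lo + 1)
    for j, i in enumerate(range(lo + 1, hi + 1), start=1):
        w[j] = w[j - 1] * up[i - 1] / down[i - 1]
    pi[lo : hi + 1] = w / w.sum()
    return pi


def activation_probability(arch: PromoterArchitecture, rule, L: float) -> float:
    """P_ON = sum of stationary probabilities of states with >= k bound."""
    k = _k_of(rule)
    return float(stationary_distribution(arch, L)[k:].sum())


def residence_time_fractions(arch: PromoterArchitecture, L: float) -> np.ndarray:
    """Long-run fraction of time per occupancy state (== stationary law)."""
    return stationary_distribution(arch, L)


def _entry_distribution(Q: np.ndarray, pi: np.ndarray, inside: np.ndarray) -> np.ndarray:
    """Stationary flux-weighted entry law into the state class ``inside``."""
    outside = ~inside
    flux = pi[outside] @ Q[np.ix_(outside, inside)]
    total = flux.sum()
    if total <= 0:
        raise ValueError("state class is unreachable from its complement")
    return flux / total


def dwell_time_distribution(
    arch: PromoterArchitecture, rule, L: float, label: str
) -> PhaseType:
    """Phase-type law of contiguous ON or OFF episode durations.

    OFF episodes live on states {0..k-1}, ON episodes on {k..N}; the entry
    distribution is the stationary probability flux across the k-1 <-> k
    boundary (renewal entry law; a point mass for birth-death chains).
    """
    k = _k_of(rule)
    N = arch.N
    if not 1 <= k <= N:
        raise ValueError("activation rule k must satisfy 1 <= k <= N")
    Q = generator_matrix(arch, L)
    pi = stationary_distribution(arch, L)
    states = np.arange(N + 1)
    if label.upper() == "OFF":
        inside = states < k
    elif label.upper() == "ON":
        inside = states >= k
    else:
        raise ValueError("label must be 'ON' or 'OFF'")
    if pi[inside].sum() <= 0 or pi[~inside].sum() <= 0:
        raise ValueError(f"{label} class unreachable at this concentration")
    alpha = _entry_distribution(Q, pi, inside)
    S = Q[np.ix_(inside, inside)]
    return PhaseType(alpha=alpha, S=S, label=label.upper())


def dwell_means(arch: PromoterArchitecture, rule, L: float) -> tuple[float, float]:
    """(tau_on, tau_off): mean ON and OFF episode durations."""
    on = dwell_time_distribution(arch, rule, L, "ON")
    off = dwell_time_distribution(arch, rule, L, "OFF")
    return on.mean(), off.mean()


def _half_activation_concentration(arch, rule, L_lo, L_hi):
    f = lambda logL: activation_probability(arch, rule, float(np.exp(logL))) - 0.5
    lo, hi = np.log(L_lo), np.log(L_hi)
    if f(lo) * f(hi) > 0:
        raise ValueError("activation probability does not cross 0.5 in range")
    return float(np.exp(brentq(f, lo, hi, xtol=1e-12)))


def hill_coefficient(
    arch: PromoterArchitecture,
    rule,
    L_lo: float = 1e-3,
    L_hi: float = 1e4,
) -> float:
    """Steepness of the activation curve: H = 4 dP_ON/dlnL at P_ON = 0.5.

    Exact for a true Hill function P = L^H/(L^H + L_half^H); the local
    log-slope avoids the window arbitrariness of a fit (see
    :func:`hill_fit` for the fit-based cross-check).
    """
    L_half = _half_activation_concentration(arch, rule, L_lo, L_hi)
    h = 1e-5
    p_hi = activation_probability(arch, rule, L_half * np.exp(h))
    p_lo = activation_probability(arch, rule, L_half * np.exp(-h))
    return float(4.0 * (p_hi - p_lo) / (2 * h))


def hill_fit(
    arch: PromoterArchitecture,
    rule,
    L_grid: np.ndarray,
) -> float:
    """Least-squares Hill-coefficient estimate over a concentration grid."""
    L_grid = np.asarray(L_grid, dtype=float)
    p = np.array([activation_probability(arch, rule, L) for L in L_grid])

    def hill(logL, H, logLh):
        return 1.0 / (1.0 + np.exp(-H * (logL - logLh)))

    H0 = max(hill_coefficient(arch, rule, L_grid.min() / 10, L_grid.max() * 10), 0.5)
    popt, _ = curve_fit(
        hill, np.log(L_grid), p, p0=[H0, float(np.log(L_grid.mean()))], maxfev=10000
    )
    return float(popt[0])
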