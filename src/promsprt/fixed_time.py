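"""Fixed-time (Berg-Purcell) readout benchmark.

Instead of deciding sequentially, a nucleus averages the gene-activity
indicator A(t) over a predetermined window T and thresholds the average.
The relative concentration resolution after time T follows from the
variance of the time average, Var[A_hat] = 2 tau_c Var[A] / T, mapped to
concentration units through the logarithmic sensitivity dP_ON/dlnL of the
activation curve.

Two variance conventions are provided:

``telegraph`` (default)
    two-state reduction of the activity signal,
    tau_c Var[A] = P^2 (1-P)^2 (tau_ON + tau_OFF);
``spectral``
    exact integrated autocovariance of the activity indicator from the
    occupancy-chain spectrum.

``half`` variants drop the factor 2 (one-sided correlation integral).
For a single site the paper-anchored baseline is Poisson arrival counting,
T = 1/(mu L delta^2).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .embryo import BoundaryProblem, EmbryoGradient, NucleiCensus, bcd_concentration
from .promoter import (
    PromoterArchitecture,
    activation_probability,
    dwell_means,
    generator_matrix,
    stationary_distribution,
    _k_of,
)

__all__ = [
    "single_site_fixed_time",
    "activity_correlation_time",
    "averaged_activity_variance_rate",
    "activity_sensitivity",
    "fixed_time_error_profile",
    "time_to_accuracy",
]


def single_site_fixed_time(delta_rel: float, on_rate: float) -> float:
    """Arrival-counting time for one diffusion-limited site (seconds).

    Counting binding events at rate ``on_rate`` for time T estimates the
    concentration with relative standard deviation 1/sqrt(on_rate T); a
    one-standard-deviation resolution of ``delta_rel`` therefore needs
    T = 1/(on_rate delta_rel^2).
    """
    if delta_rel <= 0:
        raise ValueError("delta_rel must be positive")
    if on_rate <= 0:
        raise ValueError("on_rate must be positive")
    return 1.0 / (on_rate * delta_rel**2)


def activity_correlation_time(arch: PromoterArchitecture, rule, L: float) -> float:
    """Integrated autocorrelation time of the ON indicator (seconds).

    tau_c = int_0^inf Corr[A(0), A(t)] dt, computed from the occupancy
    chain generator by solving the Poisson equation Q y = -(a - P) with
    pi y = 0; then int Cov dt = sum_i pi_i (a_i - P) y_i.
    """
    k = _k_of(rule)
    Q = generator_matrix(arch, L)
    pi = stationary_distribution(arch, L)
    a = (np.arange(arch.N + 1) >= k).astype(float)
    P = float(pi @ a)
    var = P * (1.0 - P)
    if var <= 0:
        return 0.0
    atil = a - P
    # bordered system enforcing pi @ y = 0 on the singular generator
    n = Q.shape[0]
    M = np.zeros((n + 1, n + 1))
    M[:n, :n] = Q
    M[:n, n] = 1.0  # Lagrange-style column (kernel direction)
    M[n, :n] = pi
    rhs = np.concatenate([-atil, [0.0]])
    y = np.linalg.solve(M, rhs)[:n]
    integral = float(pi @ (atil * y))
    return max(integral, 0.0) / var


def averaged_activity_variance_rate(
    arch: PromoterArchitecture,
    rule,
    L: float,
    convention: str = "telegraph",
) -> float:
    """c such that Var[time-averaged activity over T] = c / T.

    ``telegraph``: c = 2 P^2(1-P)^2 (tau_ON + tau_OFF); ``spectral``:
    c = 2 tau_c Var[A] with the exact integrated autocorrelation time.
    ``telegraph_half``/``spectral_half`` drop the factor 2.
    """
    base, _, half = convention.partition("_")
    factor = 1.0 if half == "half" else 2.0
    P = activation_probability(arch, rule, L)
    if base == "telegraph":
        tau_on, tau_off = dwell_means(arch, rule, L)
        c = (P * (1.0 - P)) ** 2 * (tau_on + tau_off)
    elif base == "spectral":
        tau_c = activity_correlation_time(arch, rule, L)
        c = tau_c * P * (1.0 - P)
    else:
        raise ValueError(f"unknown variance convention {convention!r}")
    return factor * c


def activity_sensitivity(arch: PromoterArchitecture, rule, L: float, h: float = 1e-5) -> float:
    """Logarithmic sensitivity dP_ON/dlnL at concentration L."""
    p_hi = activation_probability(arch, rule, L * np.exp(h))
    p_lo = activation_probability(arch, rule, L * np.exp(-h))
    return (p_hi - p_lo) / (2.0 * h)


def _z_of_error(e: float) -> float:
    """Gaussian deviate for a two-sided error level (e = 0.32 <-> ~1 sd)."""
    if not 0 < e < 1:
        raise ValueError("error level must lie in (0, 1)")
    return float(norm.isf(e / 2.0))


def time_to_accuracy(
    arch: PromoterArchitecture,
    rule,
    L: float,
    delta_rel: float,
    e: float = 0.32,
    convention: str = "telegraph",
) -> float:
    """Averaging time for a fixed-time decision at error level ``e``.

    Inverts the Gaussian error model: the time-averaged activity must
    resolve a relative concentration difference ``delta_rel`` with
    misclassification probability ``e``; at e = 0.32 the estimator
    standard deviation equals ``delta_rel`` (one-sigma correspondence).
    For a single site (N = 1) this reduces to arrival counting.
    """
    if arch.N == 1:
        t_single = single_site_fixed_time(delta_rel, arch.mu[0] * L)
        return t_single * (_z_of_error(e) / 1.0) ** 2
    c = averaged_activity_variance_rate(arch, rule, L, convention)
    sens = activity_sensitivity(arch, rule, L)
    if sens == 0:
        return np.inf
    sigma_target = delta_rel * abs(sens) / _z_of_error(e)
    return c / sigma_target**2


def fixed_time_error_profile(
    arch: PromoterArchitecture,
    rule,
    grad: EmbryoGradient,
    problem: BoundaryProblem,
    T: float,
    census: NucleiCensus | None = None,
    convention: str = "telegraph",
    error_space: str = "activity",
) -> pd.DataFrame:
    """Per-position fixed-time misclassification probability.

    At each position the time-averaged activity is Gaussian around
    P_ON(L(x)) with variance c/T; a nucleus errs when the average falls on
    the wrong side of the activity level of the *nearest* border
    hypothesis (anterior nuclei compare against L1, posterior against
    L2).  With ``error_space='loglik'`` the distance is measured in lnL
    units through the sensitivity map instead (singular where the
    activation curve saturates; positions with zero sensitivity report
    error 0.5).  Border positions are masked.
    """
    if T <= 0:
        raise ValueError("integration time must be positive")
    positions = (
        census.positions if census is not None else np.linspace(0.0, 100.0, 201)
    )
    half = problem.delta_x / 2.0
    P1 = activation_probability(arch, rule, problem.L1)
    P2 = activation_probability(arch, rule, problem.L2)
    rows = []
    for x in np.asarray(positions, dtype=float):
        L = float(bcd_concentration(grad, x))
        if abs(x - grad.x0) < half:
            rows.append((x, L, np.nan))
            continue
        c = averaged_activity_variance_rate(arch, rule, L, convention)
        sigma = np.sqrt(c / T)
        P = activation_probability(arch, rule, L)
        if error_space == "activity":
            dist = (P - P1) if x < grad.x0 else (P2 - P)
            err = float(norm.sf(dist / sigma)) if sigma > 0 else float(dist <= 0) * 1.0
        elif error_space == "loglik":
            sens = abs(activity_sensitivity(arch, rule, L))
            if sens == 0:
                err = 0.5
            else:
                target = problem.L1 if x < grad.x0 else problem.L2
                dist = abs(np.log(L / target))
                err = float(norm.sf(dist / (sigma / sens)))
        else:
            raise ValueError("error_space must be 'activity' or 'loglik'")
        rows.append((x, L, err))
    return pd.DataFrame(rows, columns=["position_EL", "concentration", "error_prob"])
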