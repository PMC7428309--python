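"""Search for the fastest decision-making promoter architectures.

The objective is the drift-diffusion mean decision time K(1-2e)/V for the
border discrimination problem, minimized over all binding/unbinding rates
(mu[1..N], nu[1..N]) subject to embryological constraints:

* half activation at the boundary concentration, P_ON(L0) = 0.5, enforced
  exactly by solving for the detailed-balance ratio of the activation
  step k in closed form;
* diffusion-limited binding, mu[i] <= mu_max (N+1-i);
* optionally a floor on the Hill coefficient of the activation curve,
  enforced by a smooth hinge penalty plus a feasibility filter.

Multi-start local minimization (log-space Nelder-Mead) with recorded
per-start seeds; the best feasible start wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .embryo import BoundaryProblem
from .promoter import (
    MU_MAX,
    PromoterArchitecture,
    activation_probability,
    hill_coefficient,
    stationary_distribution,
    _k_of,
)
from .sprt import drift, mean_decision_time

__all__ = ["SearchConstraints", "SearchResult", "optimize_architecture", "mutant_profiles"]


@dataclass(frozen=True)
class SearchConstraints:
    """Feasibility requirements for candidate architectures."""

    k: int = 1
    N: int = 6
    H_min: float = 0.0
    boundary_activation: float = 0.5
    activation_tol: float = 0.01
    hill_tol: float = 0.05
    mu_cap: float = MU_MAX
    L0: float = 5.6
    nu_bounds: tuple = (1e-4, 10.0)
    mu_floor: float = 1e-4

    def mu_caps(self) -> np.ndarray:
        return self.mu_cap * (self.N + 1 - np.arange(1, self.N + 1))


@dataclass
class SearchResult:
    """Best architecture found plus full optimizer provenance."""

    arch: PromoterArchitecture | None
    k: int
    mean_time: float
    hill: float
    boundary_activation: float
    feasible: bool
    n_starts: int
    seed: int | None
    start_records: list = field(default_factory=list)


def _solve_half_activation(mu, nu_other, cons: SearchConstraints):
    """Closed-form nu[k] giving the target boundary activation.

    With birth-death stationary weights a_i = prod_{j<=i} (mu_j L0/nu_j),
    P_ON/P_OFF = (sum_{i>=k} a_i)/(sum_{i<k} a_i) and every a_i with
    i >= k is proportional to r_k = mu_k L0/nu_k, so the activation
    constraint fixes r_k exactly.
    """
    k, N, L0, q = cons.k, cons.N, cons.L0, cons.boundary_activation
    r = np.empty(N)
    nu_full = np.empty(N)
    j = 0
    for i in range(N):
        if i == k - 1:
            nu_full[i] = np.nan  # placeholder
        else:
            nu_full[i] = nu_other[j]
            j += 1
    with np.errstate(divide="ignore"):
        # weights below the activation step
        a = 1.0  # a_0
        A = 1.0  # sum_{i<k} a_i
        for i in range(k - 1):
            a *= mu[i] * L0 / nu_full[i]
            A += a
        a_km1 = a  # a_{k-1}
        # weights above, computed with r_k = 1
        b = a_km1 * mu[k - 1] * L0  # a_k / (1/nu_k) ... tracked as a_k with nu_k=1
        B = b
        for i in range(k, N):
            b *= mu[i] * L0 / nu_full[i]
            B += b
    target_ratio = q / (1.0 - q)
    # P_ON/P_OFF = (B / nu_k) / A  =>  nu_k = B / (A * target_ratio)
    nu_k = B / (A * target_ratio)
    nu_full[k - 1] = nu_k
    return nu_full


def _build_arch(theta, cons: SearchConstraints):
    """Map unconstrained optimizer coordinates to a feasible architecture."""
    N, k = cons.N, cons.k
    caps = cons.mu_caps()
    lo_nu, hi_nu = cons.nu_bounds
    mu = np.exp(theta[:N])
    mu = np.clip(mu, cons.mu_floor, caps)
    nu_other = np.exp(theta[N:])
    nu_other = np.clip(nu_other, lo_nu, hi_nu)
    nu = _solve_half_activation(mu, nu_other, cons)
    # the eliminated rate must respect the same search box as the others
    if not np.all(np.isfinite(nu)) or not lo_nu <= nu[k - 1] <= hi_nu:
        return None
    return PromoterArchitecture(mu, nu)


def _objective(arch, cons: SearchConstraints, problem: BoundaryProblem):
    """Worst-side drift-diffusion decision time (D = V identity)."""
    K = problem.K
    times = []
    for L in (problem.L1, problem.L2):
        V = drift(arch, cons.k, L, problem.L1, problem.L2)
        correct = V > 0 if L == problem.L1 else V < 0
        if not correct or V == 0:
            return np.inf
        times.append(mean_decision_time(V, abs(V), K))
    return max(times)


def optimize_architecture(
    constraints: SearchConstraints,
    problem: BoundaryProblem,
    n_starts: int = 8,
    seed: int | None = None,
    maxfev: int = 400,
    penalty_weight: float = 500.0,
) -> SearchResult:
    """Multi-start constrained minimization of the mean decision time."""
    cons = constraints
    rng = np.random.default_rng(seed)
    N, k = cons.N, cons.k
    caps = cons.mu_caps()
    lo_nu, hi_nu = cons.nu_bounds
    n_free_nu = N - 1

    def penalized(theta):
        arch = _build_arch(theta, cons)
        if arch is None:
            return 1e12
        try:
            t = _objective(arch, cons, problem)
        except (ValueError, np.linalg.LinAlgError):
            return 1e12
        if not np.isfinite(t):
            return 1e12
        pen = 0.0
        if cons.H_min > 0:
            try:
                H = hill_coefficient(arch, k)
            except ValueError:
                return 1e12
            pen = penalty_weight * max(0.0, cons.H_min - H) ** 2
        return t * (1.0 + pen)

    # structured warm starts (binding at the diffusion limit, one common
    # unbinding scale) bracket the fast-toggling optima; the remaining
    # starts are log-uniform random.
    structured = [
        np.concatenate([np.log(caps), np.full(n_free_nu, np.log(c))])
        for c in (0.1, 0.3, 1.0, 3.0)
    ]

    records = []
    best = None
    for istart in range(n_starts):
        start_seed = int(rng.integers(2**31 - 1))
        r = np.random.default_rng(start_seed)
        if istart < len(structured):
            theta0 = structured[istart]
        else:
            theta0 = np.concatenate(
                [
                    r.uniform(np.log(caps) - 5.0, np.log(caps)),
                    r.uniform(np.log(lo_nu), np.log(hi_nu), n_free_nu),
                ]
            )
        res = minimize(
            penalized,
            theta0,
            method="Nelder-Mead",
            options={"maxfev": maxfev, "xatol": 1e-4, "fatol": 1e-4, "adaptive": True},
        )
        arch = _build_arch(res.x, cons)
        rec = {"seed": start_seed, "fun": float(res.fun), "nfev": int(res.nfev)}
        if arch is not None and np.isfinite(res.fun) and res.fun < 1e11:
            try:
                t = _objective(arch, cons, problem)
                H = hill_coefficient(arch, k) if cons.H_min > 0 else np.nan
            except (ValueError, np.linalg.LinAlgError):
                records.append(rec)
                continue
            feasible = (cons.H_min <= 0) or (H >= cons.H_min - cons.hill_tol)
            rec.update(
                {
                    "time": float(t),
                    "hill": float(H),
                    "feasible": feasible,
                    "mu": [float(v) for v in arch.mu],
                    "nu": [float(v) for v in arch.nu],
                }
            )
            if feasible and (best is None or t < best["time"]):
                best = {"arch": arch, "time": t, "hill": H}
        records.append(rec)

    if best is None:
        return SearchResult(
            arch=None,
            k=k,
            mean_time=np.inf,
            hill=np.nan,
            boundary_activation=np.nan,
            feasible=False,
            n_starts=n_starts,
            seed=seed,
            start_records=records,
        )
    arch = best["arch"]
    H = best["hill"] if cons.H_min > 0 else hill_coefficient(arch, k)
    return SearchResult(
        arch=arch,
        k=k,
        mean_time=best["time"],
        hill=float(H),
        boundary_activation=activation_probability(arch, k, cons.L0),
        feasible=True,
        n_starts=n_starts,
        seed=seed,
        start_records=records,
    )


def mutant_profiles(
    result_arch: PromoterArchitecture,
    rule,
    n_sites_list,
    grad,
    x_grid=None,
) -> dict:
    """Activation profiles of promoters with binding sites removed.

    Site removal truncates the occupancy chain at N' states keeping the
    remaining rates (the last binding steps are deleted).  For each mutant
    returns the P_ON(x) profile, the fraction active at the original
    boundary, and the shift of the half-activation point (%EL, positive =
    posterior).  A mutant whose remaining sites cannot satisfy the
    activation rule is reported never-active.
    """
    from .embryo import bcd_concentration

    k = _k_of(rule)
    if x_grid is None:
        x_grid = np.linspace(grad.x0 - 30.0, grad.x0 + 30.0, 121)
    x_grid = np.asarray(x_grid, dtype=float)
    out = {}
    for n_sites in n_sites_list:
        if not 1 <= n_sites <= result_arch.N:
            raise ValueError("n_sites must lie in 1..N")
        sub = PromoterArchitecture(result_arch.mu[:n_sites], result_arch.nu[:n_sites])
        if k > n_sites:
            prof = np.zeros_like(x_grid)
            out[n_sites] = {
                "positions": x_grid,
                "activation": prof,
                "fraction_at_boundary": 0.0,
                "boundary_shift_EL": np.nan,
                "never_active": True,
            }
            continue
        prof = np.array(
            [
                activation_probability(sub, k, float(bcd_concentration(grad, x)))
                for x in x_grid
            ]
        )
        frac0 = activation_probability(sub, k, float(bcd_concentration(grad, grad.x0)))
        # half-activation position: P_ON decreasing in x
        shift = np.nan
        if prof.max() >= 0.5 >= prof.min():
            x_half = float(np.interp(-0.5, -prof, x_grid))
            shift = x_half - grad.x0
        out[n_sites] = {
            "positions": x_grid,
            "activation": prof,
            "fraction_at_boundary": float(frac0),
            "boundary_shift_EL": shift,
            "never_active": False,
        }
    return out
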