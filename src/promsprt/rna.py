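"""Delayed RNA production / active degradation as a log-likelihood proxy.

The per-episode log-likelihood of the telegraph signal is asymptotically
linear in the episode duration (phase-type tails are exponential), with a
positive slope for ON episodes and a negative slope for OFF episodes.  A
molecular circuit can therefore approximate the SPRT statistic with RNA
copy number: produce at rate r_on while the gene has been continuously ON
for longer than a delay d_on, at basal rate r_b otherwise (reverting only
after the gene has been continuously OFF for d_off), and degrade at a
constant (zeroth-order, enzyme-saturated) rate r_deg.  The resulting
signed RNA level drifts up under the anterior hypothesis and down under
the posterior one; affine thresholds c1(t) > c2(t) turn it into a
sequential decision.

The delays implement continuous-residence filters: episodes shorter than
their delay never flip the production state, which reproduces the sign
structure of the episode log-likelihood (short ON episodes argue for the
lower concentration, short OFF episodes for the higher one).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .embryo import BoundaryProblem, EmbryoGradient, bcd_concentration
from .phasetype import PhaseType, _quad_grid
from .promoter import PromoterArchitecture, activation_probability
from .sprt import OFF, ON, TelegraphTrace, _dwell_pair

__all__ = [
    "RnaKineticParams",
    "RnaTrajectory",
    "episode_loglikelihood_curves",
    "rna_trajectory",
    "affine_thresholds",
    "rna_decision",
    "rna_ensemble",
    "neutral_level_path",
    "calibrate_thresholds",
    "select_rna_candidate",
    "mean_production_rate",
    "rna_profile_hill",
]


@dataclass(frozen=True)
class RnaKineticParams:
    """Kinetics of the RNA likelihood-proxy circuit (rates s^-1, delays s)."""

    r_on: float = 0.805
    r_b: float = 0.2
    r_deg: float = 0.5
    d_on: float = 0.047
    d_off: float = 1.6

    def __post_init__(self) -> None:
        if not self.r_on > self.r_b >= 0:
            raise ValueError("need r_on > r_b >= 0")
        if self.r_deg <= 0:
            raise ValueError("r_deg must be positive")
        if self.d_on < 0 or self.d_off < 0:
            raise ValueError("delays must be nonnegative")


@dataclass
class RnaTrajectory:
    """Piecewise-linear signed RNA level along a telegraph trace.

    ``times``/``levels`` are the breakpoints; slopes between breakpoints
    are either r_on - r_deg or r_b - r_deg.  The level is a likelihood
    proxy in signed accounting and may go negative.
    """

    times: np.ndarray
    levels: np.ndarray

    def level_at(self, t):
        return np.interp(t, self.times, self.levels)


def episode_loglikelihood_curves(
    arch: PromoterArchitecture,
    rule,
    problem: BoundaryProblem,
    t_grid: np.ndarray,
) -> pd.DataFrame:
    """Per-episode log-likelihood increments ell(t) for ON and OFF episodes.

    ell_state(t) = log p_state(t; L1) - log p_state(t; L2); asymptotically
    linear with slope equal to the difference of the dominant phase-type
    decay rates under the two hypotheses.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    on1, off1 = _dwell_pair(arch, rule, problem.L1)
    on2, off2 = _dwell_pair(arch, rule, problem.L2)
    return pd.DataFrame(
        {
            "t": t_grid,
            "ell_on": on1.logpdf(t_grid) - on2.logpdf(t_grid),
            "ell_off": off1.logpdf(t_grid) - off2.logpdf(t_grid),
        }
    )


def _production_segments(states, durations, params: RnaKineticParams):
    """Effective production-state segments after delay filtering.

    Yields (duration, active) pieces in trace order.  ``active`` means
    production at r_on.  The filter keeps a latent two-state memory:
    an ON episode shorter than d_on never activates production; an OFF
    episode shorter than d_off never deactivates it.
    """
    segs: list[tuple[float, bool]] = []
    active = False
    for s, d in zip(states, durations):
        if s == ON:
            if active:
                segs.append((d, True))
            elif d >= params.d_on:
                segs.append((params.d_on, False))
                segs.append((d - params.d_on, True))
                active = True
            else:
                segs.append((d, False))
        else:
            if not active:
                segs.append((d, False))
            elif d >= params.d_off:
                segs.append((params.d_off, True))
                segs.append((d - params.d_off, False))
                active = False
            else:
                segs.append((d, True))
    return segs


def rna_trajectory(trace: TelegraphTrace, params: RnaKineticParams) -> RnaTrajectory:
    """Deterministic signed RNA accounting along one telegraph trace."""
    segs = _production_segments(trace.states, trace.durations, params)
    times = [0.0]
    levels = [0.0]
    for d, active in segs:
        rate = (params.r_on if active else params.r_b) - params.r_deg
        times.append(times[-1] + d)
        levels.append(levels[-1] + rate * d)
    return RnaTrajectory(times=np.array(times), levels=np.array(levels))


def affine_thresholds(offset: float, slope: float, intercept: float = 0.0):
    """Convenience pair of affine thresholds intercept + slope t +/- offset."""
    c1 = lambda t: intercept + slope * np.asarray(t) + offset
    c2 = lambda t: intercept + slope * np.asarray(t) - offset
    return c1, c2


def rna_decision(traj: RnaTrajectory, c1, c2) -> tuple[int, float]:
    """First crossing of the thresholds c1(t) (anterior decision, +1) or
    c2(t) (posterior decision, -1).

    ``c1``/``c2`` are callables of time with c1(t) > c2(t) everywhere.
    Crossings are located on the trajectory breakpoints with linear
    interpolation in between (exact for affine thresholds).  Returns
    (decision, time); decision 0 with time NaN if no crossing occurs
    within the trajectory.
    """
    t = traj.times
    up = traj.levels - np.asarray(c1(t), dtype=float)
    dn = traj.levels - np.asarray(c2(t), dtype=float)
    if np.any(up >= dn):
        raise ValueError("need c1(t) > c2(t) for all t")
    for i in range(1, t.size):
        cand = []
        if up[i] >= 0 and up[i - 1] < 0:
            frac = -up[i - 1] / (up[i] - up[i - 1])
            cand.append((+1, t[i - 1] + frac * (t[i] - t[i - 1])))
        if dn[i] <= 0 and dn[i - 1] > 0:
            frac = dn[i - 1] / (dn[i - 1] - dn[i])
            cand.append((-1, t[i - 1] + frac * (t[i] - t[i - 1])))
        if i == 1:  # already outside the corridor at the start
            if up[0] >= 0:
                return +1, float(t[0])
            if dn[0] <= 0:
                return -1, float(t[0])
        if cand:
            cand.sort(key=lambda c: c[1])
            return cand[0][0], float(cand[0][1])
    return 0, float("nan")


def _sample_trace(arch, rule, L, n_cycles, rng) -> TelegraphTrace:
    on, off = _dwell_pair(arch, rule, L)
    d_off = off.sample(n_cycles, rng)
    d_on = on.sample(n_cycles, rng)
    durations = np.empty(2 * n_cycles)
    durations[0::2] = d_off
    durations[1::2] = d_on
    states = np.tile([OFF, ON], n_cycles)
    return TelegraphTrace(states=states, durations=durations)


def rna_ensemble(
    arch: PromoterArchitecture,
    rule,
    params: RnaKineticParams,
    problem: BoundaryProblem,
    offset: float,
    neutral=None,
    n_rep: int = 400,
    horizon: float = 1000.0,
    seed: int | np.random.Generator | None = None,
) -> dict:
    """Realized error and mean decision time of the RNA circuit.

    Symmetric thresholds ``neutral(t) +/- offset`` are applied to traces
    simulated under both hypotheses (truth L1 and truth L2); errors are
    wrong-side crossings, replicates without a crossing within
    ``horizon`` are censored and counted.  ``neutral`` defaults to the
    straight neutral drift line (see :func:`neutral_level_path` for the
    burn-in-aware alternative).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if neutral is None:
        s = neutral_slope(arch, rule, params, problem)
        neutral = lambda t: s * np.asarray(t)
    c1 = lambda t: neutral(t) + offset
    c2 = lambda t: neutral(t) - offset
    out = {"error": [], "time": [], "censored": 0}
    for truth, sign in ((problem.L1, +1), (problem.L2, -1)):
        on, off = _dwell_pair(arch, rule, truth)
        n_cycles = max(int(horizon / (on.mean() + off.mean()) * 1.5), 20)
        for _ in range(n_rep):
            trace = _sample_trace(arch, rule, truth, n_cycles, rng)
            traj = rna_trajectory(trace, params)
            dec, t = rna_decision(traj, c1, c2)
            if dec == 0 or t > horizon:
                out["censored"] += 1
                continue
            out["error"].append(dec != sign)
            out["time"].append(t)
    n = len(out["error"])
    return {
        "error_rate": float(np.mean(out["error"])) if n else np.nan,
        "mean_time": float(np.mean(out["time"])) if n else np.nan,
        "n_decided": n,
        "n_censored": out["censored"],
    }


def neutral_level_path(
    arch: PromoterArchitecture,
    rule,
    params: RnaKineticParams,
    problem: BoundaryProblem,
    horizon: float = 1000.0,
    n_rep: int = 100,
    n_grid: int = 50,
    seed: int | np.random.Generator | None = None,
):
    """Mean RNA-level path under the neutral (boundary) concentration.

    After the mitotic reset production starts basal, so the level departs
    from zero along a curved burn-in before settling onto the neutral
    drift line.  Decision thresholds run parallel to this empirical mean
    path (estimated once on a calibration ensemble and interpolated),
    which is the natural time-dependent threshold pair for the circuit.
    Returns a callable t -> mean level.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L0 = float(np.sqrt(problem.L1 * problem.L2))
    on, off = _dwell_pair(arch, rule, L0)
    n_cycles = max(int(horizon / (on.mean() + off.mean()) * 1.5), 20)
    grid = np.linspace(0.0, horizon, n_grid)
    acc = np.zeros_like(grid)
    for _ in range(n_rep):
        trace = _sample_trace(arch, rule, L0, n_cycles, rng)
        traj = rna_trajectory(trace, params)
        acc += traj.level_at(grid)
    mean_path = acc / n_rep
    tail_slope = (mean_path[-1] - mean_path[-2]) / (grid[-1] - grid[-2])

    def path(t):
        t = np.asarray(t, dtype=float)
        inside = np.interp(t, grid, mean_path)
        return np.where(t <= horizon, inside, mean_path[-1] + tail_slope * (t - horizon))

    return path


def neutral_slope(
    arch: PromoterArchitecture,
    rule,
    params: RnaKineticParams,
    problem: BoundaryProblem,
) -> float:
    """Drift of the RNA level at the boundary (geometric-mean) concentration.

    The decision thresholds run parallel to this neutral line so that the
    two hypotheses produce symmetric signed drifts.
    """
    L0 = float(np.sqrt(problem.L1 * problem.L2))
    return mean_production_rate(arch, rule, L0, params) - params.r_deg


def calibrate_thresholds(
    arch: PromoterArchitecture,
    rule,
    params: RnaKineticParams,
    problem: BoundaryProblem,
    target_error: float = 0.32,
    offsets=None,
    n_rep: int = 200,
    horizon: float = 1000.0,
    seed: int | np.random.Generator | None = None,
) -> dict:
    """Smallest symmetric offset meeting the target error on an ensemble."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    neutral = neutral_level_path(
        arch, rule, params, problem, horizon=horizon,
        n_rep=max(n_rep // 2, 50), seed=rng,
    )
    if offsets is None:
        offsets = np.geomspace(0.5, 30.0, 12)
    for offset in offsets:
        res = rna_ensemble(
            arch, rule, params, problem, offset, neutral, n_rep, horizon, rng
        )
        if np.isfinite(res["error_rate"]) and res["error_rate"] <= target_error:
            return {"offset": float(offset), "neutral": neutral, **res}
    return {"offset": float(offsets[-1]), "neutral": neutral, **res}


def select_rna_candidate(
    search_result,
    params: RnaKineticParams,
    problem: BoundaryProblem,
    target_error: float = 0.32,
    n_rep: int = 200,
    horizon: float = 1000.0,
    seed: int | np.random.Generator | None = None,
    max_candidates: int = 6,
) -> dict | None:
    """Pick the search candidate on which the RNA circuit decides fastest.

    The architecture search returns many near-optimal constraint-
    satisfying architectures; the circuit's fixed kinetics suit some
    better than others (its delays interact with the episode-duration
    statistics), so the circuit parameters-plus-architecture combination
    is selected jointly: each feasible candidate is threshold-calibrated
    to the target error and the one with the shortest realized mean
    decision time wins.  Returns None when no candidate reaches the
    target error.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cands, seen = [], set()
    for rec in sorted(
        (r for r in search_result.start_records if r.get("feasible")),
        key=lambda r: r["time"],
    ):
        key = round(rec["time"], 3)
        if key in seen:
            continue
        seen.add(key)
        cands.append(rec)
        if len(cands) >= max_candidates:
            break
    best = None
    for rec in cands:
        arch = PromoterArchitecture(rec["mu"], rec["nu"])
        cal = calibrate_thresholds(
            arch, search_result.k, params, problem,
            target_error=target_error, n_rep=n_rep, horizon=horizon, seed=rng,
        )
        if not np.isfinite(cal["error_rate"]) or cal["error_rate"] > target_error:
            continue
        if best is None or cal["mean_time"] < best["calibration"]["mean_time"]:
            best = {"arch": arch, "sprt_time": rec["time"], "calibration": cal}
    return best


# -- mean production and profile steepness ----------------------------------


def _partial_mean(law: PhaseType, upto: float) -> float:
    """E[min(T, upto)] = int_0^upto S(u) du by panel quadrature."""
    if upto <= 0:
        return 0.0
    nodes, weights = _quad_grid((law,), horizon_scales=1.0)
    keep = nodes < upto
    base = float(np.sum(weights[keep] * law.sf(nodes[keep])))
    # remainder of [0, upto] not covered by the law-scaled grid
    hi = nodes.max() if keep.any() else 0.0
    if upto > hi:
        gl_x, gl_w = np.polynomial.legendre.leggauss(32)
        mid, half = 0.5 * (upto + hi), 0.5 * (upto - hi)
        base += float(np.sum(half * gl_w * law.sf(mid + half * gl_x)))
    return base


def mean_production_rate(
    arch: PromoterArchitecture, rule, L: float, params: RnaKineticParams
) -> float:
    """Long-run mean RNA production rate under the delay-filtered telegraph.

    Renewal argument over ON/OFF cycles: with q_on = P(ON episode >= d_on)
    and q_off = P(OFF episode >= d_off), the probability that production
    is active at the start of an ON episode is
    pi_A = q_on (1-q_off) / (q_off + q_on (1-q_off)); active time per cycle
    follows from partial means of the dwell laws.
    """
    on, off = _dwell_pair(arch, rule, L)
    q_on = float(on.sf(params.d_on))
    q_off = float(off.sf(params.d_off))
    denom = q_off + q_on * (1.0 - q_off)
    pi_A = q_on * (1.0 - q_off) / denom if denom > 0 else 0.0
    e_on_full = on.mean()
    # E[(t - d_on)^+] = E[t] - E[min(t, d_on)]
    e_on_late = e_on_full - _partial_mean(on, params.d_on)
    active_on = pi_A * e_on_full + (1.0 - pi_A) * e_on_late
    p_active_at_on_end = pi_A + (1.0 - pi_A) * q_on
    active_off = p_active_at_on_end * _partial_mean(off, params.d_off)
    cycle = e_on_full + off.mean()
    frac = (active_on + active_off) / cycle
    return params.r_b + (params.r_on - params.r_b) * frac


def _hill_of_profile(L_vals: np.ndarray, f_vals: np.ndarray) -> float:
    """Hill steepness 4 dg/dlnL at half height of a normalized profile."""
    g = (f_vals - f_vals.min()) / (f_vals.max() - f_vals.min())
    lnL = np.log(L_vals)
    order = np.argsort(lnL)
    lnL, g = lnL[order], g[order]
    if not (g[0] < 0.5 < g[-1] or g[0] > 0.5 > g[-1]):
        raise ValueError("profile does not cross half height in range")
    # locate half crossing and central slope there
    ln_half = float(np.interp(0.5, g, lnL)) if g[0] < g[-1] else float(
        np.interp(0.5, g[::-1], lnL[::-1])
    )
    dg = np.gradient(g, lnL)
    slope = float(np.interp(ln_half, lnL, dg))
    return 4.0 * abs(slope)


def rna_profile_hill(
    grad: EmbryoGradient,
    arch: PromoterArchitecture,
    rule,
    params: RnaKineticParams,
    x_range: tuple[float, float] = (-15.0, 15.0),
    n_points: int = 61,
) -> dict:
    """Steepness of the mean RNA-production profile along the embryo.

    Returns the Hill coefficients of the normalized RNA-production
    profile and of the promoter-activity profile over the same positions
    (the delays filter short episodes asymmetrically along the gradient,
    which can steepen the RNA profile beyond the activity profile).
    """
    xs = grad.x0 + np.linspace(x_range[0], x_range[1], n_points)
    Ls = np.array([float(bcd_concentration(grad, x)) for x in xs])
    prod = np.array([mean_production_rate(arch, rule, L, params) for L in Ls])
    act = np.array([activation_probability(arch, rule, L) for L in Ls])
    return {
        "positions": xs,
        "concentrations": Ls,
        "production": prod,
        "activity": act,
        "hill_rna": _hill_of_profile(Ls, prod),
        "hill_activity": _hill_of_profile(Ls, act),
    }
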