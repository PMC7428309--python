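"""Exact stochastic simulation of promoter occupancy and SPRT ensembles.

Single trajectories are simulated event-by-event (Gillespie); decision-time
and diffusivity ensembles instead sample whole ON/OFF episodes from the
phase-type dwell laws, which is exact for the telegraph statistics (the
log-likelihood only sees episode durations) and vectorizes across
replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phasetype import PhaseType
from .promoter import PromoterArchitecture, dwell_time_distribution, generator_matrix
from .sprt import OFF, ON, TelegraphTrace, _dwell_pair, _empty_start_off

__all__ = [
    "SimulationRun",
    "BoundTimeSample",
    "FirstPassageEnsemble",
    "simulate_trajectory",
    "telegraph_trace",
    "sprt_first_passage_ensemble",
    "diffusivity_montecarlo",
    "sample_bound_times",
]


@dataclass
class SimulationRun:
    """One exact occupancy trajectory: event times and states after events."""

    seed: int | None
    times: np.ndarray  # event times, strictly increasing, times[0] = 0
    states: np.ndarray  # occupancy after each event; states[0] = initial
    t_end: float
    arch: PromoterArchitecture
    L: float

    def telegraph(self, rule) -> TelegraphTrace:
        return telegraph_trace(self, rule)


def simulate_trajectory(
    arch: PromoterArchitecture,
    L: float,
    t_end: float,
    seed: int | np.random.Generator | None = None,
    start_state: int = 0,
) -> SimulationRun:
    """Exact CTMC sample of the occupancy chain up to time ``t_end``."""
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    N = arch.N
    up = np.array(arch.mu) * L  # up[i]: rate i -> i+1
    down = np.array(arch.nu)  # down[i]: rate i+1 -> i
    t, s = 0.0, int(start_state)
    times, states = [0.0], [s]
    while True:
        r_up = up[s] if s < N else 0.0
        r_dn = down[s - 1] if s > 0 else 0.0
        total = r_up + r_dn
        if total == 0:
            break
        t += rng.exponential(1.0 / total)
        if t >= t_end:
            break
        s = s + 1 if rng.random() < r_up / total else s - 1
        times.append(t)
        states.append(s)
    return SimulationRun(
        seed=None if isinstance(seed, np.random.Generator) else seed,
        times=np.array(times),
        states=np.array(states),
        t_end=t_end,
        arch=arch,
        L=L,
    )


def telegraph_trace(run: SimulationRun, rule) -> TelegraphTrace:
    """Collapse an occupancy trajectory into alternating ON/OFF episodes."""
    from .promoter import _k_of

    k = _k_of(rule)
    activity = (run.states >= k).astype(int)
    # durations between events, last one truncated at t_end
    bounds = np.append(run.times, run.t_end)
    seg = np.diff(bounds)
    states, durations = [], []
    for a, d in zip(activity, seg):
        if d <= 0:
            continue
        if states and states[-1] == a:
            durations[-1] += d
        else:
            states.append(int(a))
            durations.append(float(d))
    return TelegraphTrace(
        states=np.array(states), durations=np.array(durations), censored_last=True
    )


@dataclass
class FirstPassageEnsemble:
    """Decision outcomes of an ensemble of SPRT first-passage runs."""

    times: np.ndarray  # decision times (s); NaN for censored replicates
    decisions: np.ndarray  # +1 (hit +K), -1 (hit -K), 0 censored
    overshoots: np.ndarray  # |log R| - K at the crossing episode
    K: float

    @property
    def n_censored(self) -> int:
        return int(np.sum(self.decisions == 0))

    def mean_time(self) -> float:
        ok = self.decisions != 0
        return float(np.nanmean(self.times[ok]))

    def error_rate(self, truth_sign: int = +1) -> float:
        ok = self.decisions != 0
        return float(np.mean(self.decisions[ok] == -truth_sign))


def sprt_first_passage_ensemble(
    arch: PromoterArchitecture,
    rule,
    L: float,
    L1: float,
    L2: float,
    K: float,
    n_rep: int,
    seed: int | np.random.Generator | None = None,
    start: str = "empty",
    max_cycles: int | None = None,
) -> FirstPassageEnsemble:
    """First crossing of +/-K of the episode-wise log-likelihood walk.

    Episodes are drawn from the true-concentration dwell laws; each
    completed episode adds the log-density ratio of its duration under
    (L1, L2).  The walk is checked at episode completions, so the crossing
    overshoots the boundary; the overshoot is recorded.  Replicates
    exceeding the safety horizon (``max_cycles``, default ~100x the
    expected number of cycles) are censored.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    on, off = _dwell_pair(arch, rule, L)
    on1, off1 = _dwell_pair(arch, rule, L1)
    on2, off2 = _dwell_pair(arch, rule, L2)
    off_first1 = _empty_start_off(arch, rule, L1) if start == "empty" else off1
    off_first2 = _empty_start_off(arch, rule, L2) if start == "empty" else off2
    off_first = _empty_start_off(arch, rule, L) if start == "empty" else off

    if max_cycles is None:
        from .phasetype import kl_divergence

        per_cycle = abs(
            kl_divergence(off, off2)
            - kl_divergence(off, off1)
            + kl_divergence(on, on2)
            - kl_divergence(on, on1)
        )
        expected = K / max(per_cycle, 1e-12)
        max_cycles = int(min(100 * max(expected, 10), 2_000_000))

    S = np.zeros(n_rep)
    t = np.zeros(n_rep)
    decided = np.zeros(n_rep, dtype=int)
    times = np.full(n_rep, np.nan)
    overshoot = np.zeros(n_rep)

    def _step(idx, law, law1, law2):
        d = law.sample(idx.size, rng)
        inc = law1.logpdf(d) - law2.logpdf(d)
        t[idx] += d
        S[idx] += inc
        crossed = np.abs(S[idx]) >= K
        hit = idx[crossed]
        decided[hit] = np.sign(S[hit]).astype(int)
        times[hit] = t[hit]
        overshoot[hit] = np.abs(S[hit]) - K

    cycle = 0
    state = OFF
    while cycle < max_cycles:
        idx = np.flatnonzero(decided == 0)
        if idx.size == 0:
            break
        if state == OFF:
            if cycle == 0:
                _step(idx, off_first, off_first1, off_first2)
            else:
                _step(idx, off, off1, off2)
            state = ON
        else:
            _step(idx, on, on1, on2)
            state = OFF
            cycle += 1
    return FirstPassageEnsemble(times=times, decisions=decided, overshoots=overshoot, K=K)


def diffusivity_montecarlo(
    arch: PromoterArchitecture,
    rule,
    L: float,
    L1: float,
    L2: float,
    n_traces: int = 2000,
    n_cycles: int = 200,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Diffusivity from the growth of Var[log R(t)] across an ensemble.

    Simulates ``n_traces`` telegraph traces of ``n_cycles`` ON/OFF cycles
    at the true concentration, evaluates log R at a fixed time grid and
    fits Var[log R(t)] = a + 2 D t by weighted least squares.  Returns
    (D, standard error of D from the variance-estimator noise).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    on, off = _dwell_pair(arch, rule, L)
    on1, off1 = _dwell_pair(arch, rule, L1)
    on2, off2 = _dwell_pair(arch, rule, L2)
    n_tot = n_traces * n_cycles
    d_off = off.sample(n_tot, rng).reshape(n_traces, n_cycles)
    d_on = on.sample(n_tot, rng).reshape(n_traces, n_cycles)
    inc = (off1.logpdf(d_off) - off2.logpdf(d_off)) + (on1.logpdf(d_on) - on2.logpdf(d_on))
    tau = d_off + d_on
    T = np.cumsum(tau, axis=1)
    logR = np.cumsum(inc, axis=1)
    t_total = (off.mean() + on.mean()) * n_cycles
    grid = np.linspace(0.2, 0.8, 7) * t_total
    var = np.empty(grid.size)
    for j, tg in enumerate(grid):
        idx = np.sum(T <= tg, axis=1)  # completed cycles by tg
        vals = np.where(idx > 0, logR[np.arange(n_traces), np.maximum(idx - 1, 0)], 0.0)
        var[j] = np.var(vals, ddof=1)
    # weighted fit: SE(var_j) ~ var_j sqrt(2/(n-1))
    w = 1.0 / (var * np.sqrt(2.0 / (n_traces - 1))) ** 2
    A = np.column_stack([np.ones_like(grid), 2.0 * grid])
    WA = A * w[:, None]
    coef, *_ = np.linalg.lstsq(WA.T @ A, WA.T @ var, rcond=None)
    cov = np.linalg.inv(WA.T @ A)
    return float(coef[1]), float(np.sqrt(cov[1, 1]))


@dataclass
class BoundTimeSample:
    """Per-molecule DNA-bound intervals."""

    durations: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.durations.mean())

    @property
    def median(self) -> float:
        return float(np.median(self.durations))


def sample_bound_times(
    arch: PromoterArchitecture,
    L: float,
    n_events: int,
    seed: int | np.random.Generator | None = None,
    selection: str = "uniform",
) -> BoundTimeSample:
    """Continuous DNA-bound times of individual Bicoid molecules.

    A molecule's bound time runs from its binding event to the unbinding
    event that removes it.  Binding sites are indistinguishable, so on an
    unbinding event the removed molecule is chosen uniformly among the
    currently bound ones (``selection='uniform'``) or last-in-first-out
    (``selection='lifo'``) to probe sensitivity to this bookkeeping.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if selection not in ("uniform", "lifo"):
        raise ValueError("selection must be 'uniform' or 'lifo'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    N = arch.N
    up = np.array(arch.mu) * L
    down = np.array(arch.nu)
    t, s = 0.0, 0
    bind_times: list[float] = []
    out: list[float] = []
    while len(out) < n_events:
        r_up = up[s] if s < N else 0.0
        r_dn = down[s - 1] if s > 0 else 0.0
        total = r_up + r_dn
        t += rng.exponential(1.0 / total)
        if rng.random() < r_up / total:
            s += 1
            bind_times.append(t)
        else:
            s -= 1
            j = rng.integers(len(bind_times)) if selection == "uniform" else -1
            out.append(t - bind_times.pop(j))
    return BoundTimeSample(durations=np.array(out))
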