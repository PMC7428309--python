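"""Phase-type distributions: absorption-time laws of finite Markov chains.

A contiguous OFF (or ON) episode of the promoter telegraph signal is the
time the occupancy chain spends inside the inactive (active) state class
before first exiting it.  Conditioned on the entry state, that time is
phase-type distributed: ``f(t) = alpha @ expm(S t) @ s`` where ``S`` is the
generator restricted to the transient class, ``alpha`` the entry
distribution and ``s = -S @ 1`` the exit-rate vector.

The chains here are tiny (at most ~14 states for the enhancer product
chain), so densities are evaluated through a cached eigendecomposition of
``S`` with an ``expm`` fallback for (near-)defective cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm, eig, inv

__all__ = ["PhaseType", "kl_divergence", "episode_moments"]

_TINY = 1e-300


@dataclass
class PhaseType:
    """Phase-type law with entry distribution ``alpha`` and sub-generator ``S``.

    Parameters
    ----------
    alpha : (m,) array
        Probability distribution over entry states; must sum to 1.
    S : (m, m) array
        Sub-generator over the transient class: nonnegative off-diagonal,
        row sums <= 0, and at least one strictly negative row sum so that
        absorption is certain.
    label : str, optional
        Free-text tag ("ON"/"OFF") used in reports.
    """

    alpha: np.ndarray
    S: np.ndarray
    label: str = ""
    _spec: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.S = np.atleast_2d(np.asarray(self.S, dtype=float))
        m = self.alpha.size
        if self.S.shape != (m, m):
            raise ValueError("alpha and S have inconsistent shapes")
        if not np.isclose(self.alpha.sum(), 1.0, atol=1e-10):
            raise ValueError("entry distribution must sum to 1")
        if np.any(self.alpha < -1e-12):
            raise ValueError("entry distribution must be nonnegative")
        rowsum = self.S.sum(axis=1)
        if np.any(rowsum > 1e-9):
            raise ValueError("sub-generator rows must sum to <= 0")
        ev = np.linalg.eigvals(self.S)
        if np.any(ev.real > 1e-9):
            raise ValueError("sub-generator must be stable (Re eig <= 0)")

    # -- spectral cache -----------------------------------------------------

    @property
    def m(self) -> int:
        return self.alpha.size

    @property
    def exit_rates(self) -> np.ndarray:
        return -self.S.sum(axis=1)

    def _spectral(self):
        """Cache (eigvals, pdf weights, sf weights) or None if defective."""
        if self._spec is None:
            lam, P = eig(self.S)
            # defective / ill-conditioned eigenbasis -> expm fallback
            if np.linalg.cond(P) > 1e10:
                self._spec = (None,)
            else:
                Pinv = inv(P)
                s = self.exit_rates
                w_pdf = (self.alpha @ P) * (Pinv @ s)
                w_sf = (self.alpha @ P) * (Pinv @ np.ones(self.m))
                self._spec = (lam, w_pdf, w_sf)
        return self._spec

    # -- densities ----------------------------------------------------------

    def pdf(self, t):
        t = np.asarray(t, dtype=float)
        spec = self._spectral()
        if spec[0] is not None:
            lam, w, _ = spec
            val = np.einsum("j,...j->...", w, np.exp(np.multiply.outer(t, lam)))
            out = np.maximum(val.real, 0.0)
        else:
            out = np.vectorize(self._pdf_expm)(t)
        return np.where(t < 0, 0.0, out)

    def _pdf_expm(self, t: float) -> float:
        return max(float(self.alpha @ expm(self.S * t) @ self.exit_rates), 0.0)

    def logpdf(self, t):
        return np.log(np.maximum(self.pdf(t), _TINY))

    def sf(self, t):
        """Survival function P(T > t)."""
        t = np.asarray(t, dtype=float)
        spec = self._spectral()
        if spec[0] is not None:
            lam, _, w = spec
            val = np.einsum("j,...j->...", w, np.exp(np.multiply.outer(t, lam)))
            out = np.clip(val.real, 0.0, 1.0)
        else:
            out = np.vectorize(
                lambda x: float(np.clip(self.alpha @ expm(self.S * x) @ np.ones(self.m), 0, 1))
            )(t)
        return np.where(t < 0, 1.0, out)

    def logsf(self, t):
        return np.log(np.maximum(self.sf(t), _TINY))

    def cdf(self, t):
        return 1.0 - self.sf(t)

    # -- moments ------------------------------------------------------------

    def mean(self) -> float:
        return float(-self.alpha @ np.linalg.solve(self.S, np.ones(self.m)))

    def moment(self, n: int) -> float:
        """Raw moment E[T^n] = n! * alpha (-S)^{-n} 1."""
        Sinv = np.linalg.inv(self.S)
        out = self.alpha.copy()
        for _ in range(n):
            out = -(out @ Sinv)
        return float(_factorial(n) * (out @ np.ones(self.m)))

    def var(self) -> float:
        m1 = self.mean()
        return self.moment(2) - m1 * m1

    # -- sampling -----------------------------------------------------------

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` absorption times by vectorized jump-chain simulation."""
        m = self.m
        state = rng.choice(m, size=n, p=np.clip(self.alpha, 0, None) / self.alpha.sum())
        t = np.zeros(n)
        active = np.ones(n, dtype=bool)
        out_rate = -np.diag(self.S)
        # jump probabilities: to state j with S[i,j]/out_rate[i]; absorb with
        # exit_rates[i]/out_rate[i]
        P = self.S / out_rate[:, None]
        np.fill_diagonal(P, 0.0)
        p_absorb = self.exit_rates / out_rate
        cum = np.cumsum(np.column_stack([P, p_absorb]), axis=1)
        while active.any():
            idx = np.flatnonzero(active)
            st = state[idx]
            t[idx] += rng.exponential(1.0 / out_rate[st])
            u = rng.random(idx.size)
            nxt = (u[:, None] < cum[st]).argmax(axis=1)
            absorbed = nxt == m
            active[idx[absorbed]] = False
            state[idx[~absorbed]] = nxt[~absorbed]
        return t


def _factorial(n: int) -> float:
    out = 1.0
    for i in range(2, n + 1):
        out *= i
    return out


# -- quadrature on episode laws ---------------------------------------------

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(32)


def _timescales(laws) -> tuple[float, float]:
    """Fastest and slowest decay timescales across a set of phase-type laws.

    Dwell laws of cooperative promoters mix decay rates spanning many
    decades (a short typical episode plus rare very long excursions), so
    quadrature grids must be anchored to the spectrum, not just the mean.
    """
    t_fast, t_slow = np.inf, 0.0
    for f in laws:
        rates = -np.linalg.eigvals(f.S).real
        rates = rates[rates > 0]
        t_fast = min(t_fast, float(1.0 / rates.max()))
        t_slow = max(t_slow, float(1.0 / rates.min()), f.mean())
    return t_fast, t_slow


def _quad_grid(laws, horizon_scales: float = 40.0):
    """Composite Gauss-Legendre nodes on geometric panels.

    Panels run from two decades below the fastest timescale out to
    ``horizon_scales`` slowest timescales (tail mass ~ exp(-40)).
    """
    t_fast, t_slow = _timescales(laws)
    lo = t_fast * 1e-2
    hi = t_slow * horizon_scales
    n_dec = np.log10(hi / lo)
    n_panels = max(int(np.ceil(3 * n_dec)), 4)
    edges = np.concatenate([[0.0], np.geomspace(lo, hi, n_panels)])
    a, b = edges[:-1], edges[1:]
    half = 0.5 * (b - a)
    mid = 0.5 * (b + a)
    nodes = (mid[:, None] + half[:, None] * _GL_NODES[None, :]).ravel()
    weights = (half[:, None] * _GL_WEIGHTS[None, :]).ravel()
    return nodes, weights


def kl_divergence(f: PhaseType, g: PhaseType, horizon_scales: float = 40.0) -> float:
    """Kullback-Leibler divergence D(f || g) between two phase-type laws.

    Spectrum-anchored composite Gauss-Legendre quadrature; the decision
    model needs absolute accuracy far below the drift scale, so the grid
    resolves every decay timescale of both laws.
    """
    nodes, weights = _quad_grid((f, g), horizon_scales)
    ft = f.pdf(nodes)
    ratio = f.logpdf(nodes) - g.logpdf(nodes)
    mask = ft > _TINY
    val = float(np.sum(weights[mask] * ft[mask] * ratio[mask]))
    if not np.isfinite(val):
        raise ValueError("divergent KL (density support mismatch)")
    return val


def episode_moments(
    f: PhaseType,
    f1: PhaseType,
    f2: PhaseType,
    horizon_scales: float = 40.0,
    censor_at: float | None = None,
):
    """Moments of the per-episode log-likelihood increment under truth ``f``.

    The increment for an episode of duration t is
    ``x(t) = log f1(t) - log f2(t)`` (hypothesis 1 over hypothesis 2).
    Returns ``(E[x], E[x^2], E[x t], E[t], E[t^2])``.

    With ``censor_at = T`` the episode is right-censored at T: durations
    count as min(t, T) and an episode still running at T contributes the
    survival-ratio evidence log S1(T) - log S2(T).  This yields the
    finite-observation-window drift and diffusivity, which stay
    well-behaved for architectures whose dwell laws have rare episodes
    far longer than the window (the uncensored renewal asymptotics would
    attribute enormous variance to events the window never completes).
    """
    nodes, weights = _quad_grid((f, f1, f2), horizon_scales)
    if censor_at is not None:
        keep = nodes < censor_at
        nodes, weights = nodes[keep], weights[keep]
    ft = f.pdf(nodes)
    x = f1.logpdf(nodes) - f2.logpdf(nodes)
    mask = ft > _TINY
    w = weights[mask] * ft[mask]
    xv, tv = x[mask], nodes[mask]
    if censor_at is not None:
        p_tail = float(f.sf(censor_at))
        if p_tail > 1e-15:
            x_tail = float(f1.logsf(censor_at) - f2.logsf(censor_at))
            w = np.append(w, p_tail)
            xv = np.append(xv, x_tail)
            tv = np.append(tv, censor_at)
    ex = float(np.sum(w * xv))
    ex2 = float(np.sum(w * xv * xv))
    ext = float(np.sum(w * xv * tv))
    et = float(np.sum(w * tv))
    et2 = float(np.sum(w * tv * tv))
    return ex, ex2, ext, et, et2
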