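"""Bicoid gradient geometry and embryo-wide error bookkeeping.

The anterior–posterior (AP) Bicoid profile is exponential,
``L(x) = L0 exp(-(x - x0)/lambda)`` with positions in percent egg length
(%EL).  The half-maximum *hunchback* expression point ``x0`` is the
reference origin; every computation depends only on ``x - x0``.  A nucleus
at position x must decide whether its local concentration is above the
anterior border-hypothesis concentration L1 or below the posterior one L2,
where L1 and L2 sit on either side of a border region of width ``delta_x``
within which either answer counts as correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "EmbryoGradient",
    "BoundaryProblem",
    "NucleiCensus",
    "bcd_concentration",
    "boundary_hypotheses",
    "decision_threshold",
    "threshold_to_error",
    "expected_error_nuclei",
]


@dataclass(frozen=True)
class EmbryoGradient:
    """Exponential Bicoid profile along the AP axis.

    L0 : concentration at the half-max *hb* point (molecules um^-3)
    x0 : boundary position (%EL); default 45 (half-max point sits ~5%EL
         anterior of mid-embryo)
    decay_length : gradient decay length (%EL)
    """

    L0: float = 5.6
    x0: float = 45.0
    decay_length: float = 20.0

    def __post_init__(self) -> None:
        if self.L0 <= 0:
            raise ValueError("L0 must be positive")
        if self.decay_length <= 0:
            raise ValueError("decay_length must be positive")

    def concentration(self, x):
        return bcd_concentration(self, x)

    def position_of(self, L):
        """Inverse profile: the position (%EL) where concentration is L."""
        return self.x0 - self.decay_length * np.log(np.asarray(L) / self.L0)


def bcd_concentration(grad: EmbryoGradient, x):
    """Bicoid concentration at position ``x`` (%EL); strictly decreasing."""
    x = np.asarray(x, dtype=float)
    return grad.L0 * np.exp(-(x - grad.x0) / grad.decay_length)


def decision_threshold(e: float) -> float:
    """Symmetric SPRT threshold K = log((1-e)/e) for error rate e."""
    if not 0 < e < 0.5:
        raise ValueError("error rate must lie in (0, 0.5)")
    return float(np.log((1.0 - e) / e))


def threshold_to_error(K: float) -> float:
    """Inverse of :func:`decision_threshold`: e = 1/(1+exp(K))."""
    return float(1.0 / (1.0 + np.exp(K)))


@dataclass(frozen=True)
class BoundaryProblem:
    """The two-hypothesis discrimination problem across the border region.

    L1/L2 are the concentrations at the anterior/posterior edges of the
    border of width ``delta_x`` (%EL); ``error_rate`` sets the threshold
    K = log((1-e)/e).
    """

    L1: float
    L2: float
    delta_x: float
    error_rate: float = 0.32

    def __post_init__(self) -> None:
        if not self.L1 > self.L2 > 0:
            raise ValueError("need L1 > L2 > 0")
        if not 0 < self.error_rate < 0.5:
            raise ValueError("error rate must lie in (0, 0.5)")

    @property
    def K(self) -> float:
        return decision_threshold(self.error_rate)

    @classmethod
    def from_gradient(
        cls, grad: EmbryoGradient, delta_x: float = 2.0, error_rate: float = 0.32
    ) -> "BoundaryProblem":
        L1, L2 = boundary_hypotheses(grad, delta_x)
        return cls(L1=L1, L2=L2, delta_x=delta_x, error_rate=error_rate)


def boundary_hypotheses(grad: EmbryoGradient, delta_x: float):
    """Concentrations (L1, L2) at the border edges x0 -/+ delta_x/2."""
    if delta_x < 0:
        raise ValueError("delta_x must be nonnegative")
    L1 = bcd_concentration(grad, grad.x0 - delta_x / 2.0)
    L2 = bcd_concentration(grad, grad.x0 + delta_x / 2.0)
    return float(L1), float(L2)


@dataclass(frozen=True)
class NucleiCensus:
    """Nuclei of one nuclear cycle, placed uniformly along the AP axis.

    Cycle c holds 2^(c-1) nuclei (yolk-nucleus losses neglected).
    """

    cycle: int = 11
    positions: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.cycle < 1:
            raise ValueError("cycle must be >= 1")
        if self.positions is None:
            n = self.n_nuclei
            # midpoint placement of n nuclei on [0, 100] %EL
            pos = (np.arange(n) + 0.5) * (100.0 / n)
            object.__setattr__(self, "positions", pos)
        else:
            pos = np.asarray(self.positions, dtype=float)
            if np.any((pos < 0) | (pos > 100)):
                raise ValueError("positions must lie in [0, 100] %EL")
            object.__setattr__(self, "positions", pos)

    @property
    def n_nuclei(self) -> int:
        return 2 ** (self.cycle - 1)


def expected_error_nuclei(
    error_profile: Callable[[np.ndarray], np.ndarray] | Sequence[float],
    census: NucleiCensus,
    border: tuple[float, float] | None = None,
) -> float:
    """Expected number of nuclei deciding their AP identity incorrectly.

    Sums the per-position error probability over the census positions,
    excluding nuclei inside the border interval ``border = (x_left,
    x_right)`` where either decision is correct.  For a spatially uniform
    error e_s this equals e_s * 2^(c-1) (minus the masked nuclei).
    """
    pos = np.asarray(census.positions, dtype=float)
    if pos.size == 0:
        return 0.0
    if border is not None:
        x_left, x_right = border
        mask = (pos < x_left) | (pos > x_right)
        pos = pos[mask]
    if callable(error_profile):
        err = np.asarray(error_profile(pos), dtype=float)
    else:
        err = np.asarray(error_profile, dtype=float)
        if border is not None:
            raise ValueError("pass a callable profile when masking a border")
    if err.shape != pos.shape:
        raise ValueError("error profile shape does not match positions")
    if np.any((err < 0) | (err > 1)):
        raise ValueError("error probabilities must lie in [0, 1]")
    return float(err.sum())
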