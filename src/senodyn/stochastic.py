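"""Non-hierarchical stochastic cancer model (the null hypothesis).

All tumor cells are equivalent: per generation a cancer cell (CC)
duplicates with probability ``p``, dies with probability ``q``, or turns
senescent by random mutation with probability ``alpha``; any remainder
stays quiescent.  Senescent cells die with probability ``d`` per
generation.  The mean counts follow::

    C(k+1) = (1 + p - q - alpha) * C(k)
    B(k+1) = (1 - d) * B(k) + alpha * C(k)

so the tumor progresses iff ``p - q - alpha > 0``.  Unlike the
hierarchical model, the senescent fraction here relaxes monotonically to a
steady state — it can never show the transient senescence peak seen in
long-term melanoma cultures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StochasticParams",
    "StochasticState",
    "NoSteadyStateError",
    "advance",
    "simulate",
    "closed_form",
    "steady_state_fractions",
]


class NoSteadyStateError(ValueError):
    """The population goes extinct; asymptotic fractions are undefined."""


@dataclass(frozen=True)
class StochasticParams:
    """Per-generation probabilities of the stochastic model.

    ``p_dup + p_die + p_sen`` may be below 1; the remainder quiesces
    (persists unchanged).  ``death_prob`` applies to senescent cells.
    """

    p_dup: float
    p_die: float = 0.0
    p_sen: float = 0.0
    death_prob: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_dup", "p_die", "p_sen", "death_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.p_dup + self.p_die + self.p_sen > 1.0 + 1e-12:
            raise ValueError("p_dup + p_die + p_sen must not exceed 1")

    @property
    def growth_factor(self) -> float:
        """Per-generation multiplier of the CC population, 1 + p - q - alpha."""
        return 1.0 + self.p_dup - self.p_die - self.p_sen


@dataclass(frozen=True)
class StochasticState:
    generation: int
    cc: float
    senescent: float

    def __post_init__(self) -> None:
        if self.cc < 0 or self.senescent < 0:
            raise ValueError("population counts must be non-negative")

    @property
    def total(self) -> float:
        return self.cc + self.senescent

    @property
    def senescent_fraction(self) -> float:
        tot = self.total
        return self.senescent / tot if tot > 0 else 0.0


def advance(state: StochasticState, params: StochasticParams) -> StochasticState:
    """One generation of the mean recursion."""
    return StochasticState(
        generation=state.generation + 1,
        cc=params.growth_factor * state.cc,
        senescent=(1.0 - params.death_prob) * state.senescent
        + params.p_sen * state.cc,
    )


def simulate(
    params: StochasticParams,
    k_max: int,
    c0: float = 1.0,
    b0: float = 0.0,
) -> list[StochasticState]:
    """Iterate the recursion, returning states for k = 0 .. k_max."""
    if k_max < 0:
        raise ValueError("k_max must be non-negative")
    states = [StochasticState(0, c0, b0)]
    for _ in range(k_max):
        states.append(advance(states[-1], params))
    return states


def closed_form(
    params: StochasticParams, k: int, c0: float = 1.0, b0: float = 0.0
) -> StochasticState:
    """Explicit solution of the recursion.

    ``C(k) = c0 g^k`` with ``g = 1 + p - q - alpha`` and
    ``B(k) = b0 (1-d)^k + alpha c0 (g^k - (1-d)^k) / (g - 1 + d)``,
    with the analytic limit when ``g = 1 - d``.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    g = params.growth_factor
    r = 1.0 - params.death_prob
    gk = g**k
    rk = r**k if (r > 0 or k > 0) else 1.0
    if r == 0.0:
        rk = 1.0 if k == 0 else 0.0
    if abs(g - r) < 1e-9:
        mid = 0.5 * (g + r)
        conv = k * mid ** max(k - 1, 0)
    else:
        conv = (gk - rk) / (g - r)
    return StochasticState(
        generation=k, cc=c0 * gk, senescent=b0 * rk + params.p_sen * c0 * conv
    )


def steady_state_fractions(params: StochasticParams) -> tuple[float, float]:
    """Large-k limits (cc_fraction, senescent_fraction) from a pure CC seed.

    In the regime ``p - q - alpha + d > 0`` (CCs outgrow the senescent
    decay) the limits are ``(p - q - alpha + d) / (p - q + d)`` and
    ``alpha / (p - q + d)``.  When senescent decay dominates and mutation
    keeps feeding the senescent pool, all cells end up senescent: (0, 1).
    Raises :class:`NoSteadyStateError` when the population dies out
    entirely and no fractions exist.
    """
    g = params.growth_factor
    r = 1.0 - params.death_prob
    alpha = params.p_sen
    if g > r:
        denom = g - r + alpha  # = p - q + d
        if denom <= 0:  # g > r forces denom > alpha >= 0; only alpha=0, g<=r left
            raise NoSteadyStateError("degenerate parameter set")
        return (g - r) / denom, alpha / denom
    # g <= r: the senescent pool decays no faster than CCs grow
    if alpha > 0.0:
        if g == 0.0 and r == 0.0:
            raise NoSteadyStateError("all cells die within one generation")
        return 0.0, 1.0
    # alpha == 0: senescent pool is never fed
    if g > 0.0:
        return 1.0, 0.0
    raise NoSteadyStateError("cancer cells die out and none turn senescent")
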