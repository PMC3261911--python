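"""Mean-field hierarchical cancer-stem-cell (CSC) growth model.

The model describes a tumor cell population organized hierarchically.
Cancer stem cells (CSCs) divide indefinitely: symmetrically into two CSCs
(probability ``p2``), symmetrically into two ordinary cancer cells (CCs,
probability ``p0``), or asymmetrically into one of each.  The mean kinetics
depend on these probabilities only through ``delta = p2 - p0``, the net
relative increase in CSC number per duplication.  CCs duplicate with unit
probability but carry an "age" (generations since their CSC ancestor) and
turn senescent once the age reaches ``n_senescence``.  Senescent cells no
longer divide and die with probability ``death_prob`` per generation.

Writing ``S(k)`` for the mean CSC count after ``k`` generations, ``C_i(k)``
for CCs of age ``i`` and ``B(k)`` for senescent cells, the per-generation
recursion is::

    S(k+1)   = (1 + delta) * S(k)
    C_1(k+1) = (1 - delta) * S(k)
    C_{i+1}(k+1) = 2 * C_i(k)          for i = 1 .. N-1
    B(k+1)   = (1 - d) * B(k) + C_N(k)

This module provides the recursion, its closed-form solutions for a
CSC-only seed and for a uniformly age-distributed CC seed, the asymptotic
senescent/CSC fractions, and the homeostatic (``delta = 0``, ``d = 0``)
special case describing mesenchymal stem cell cultures, whose cumulative
population doublings (CPD) grow linearly and then logarithmically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "HierarchicalParams",
    "PopulationState",
    "Trajectory",
    "advance_generation",
    "simulate_trajectory",
    "mixed_initial_state",
    "csc_seeded_solution",
    "cc_seeded_solution",
    "total_population",
    "asymptotic_fractions",
    "converged_senescent_fraction",
    "homeostatic_cpd",
]

_EPS_DEGENERATE = 1e-9  # switch to analytic limits near removable singularities


@dataclass(frozen=True)
class HierarchicalParams:
    """Parameter set of the hierarchical CSC model.

    Parameters
    ----------
    delta
        Net relative increase in CSC number per duplication,
        ``delta = p2 - p0``; in ``(-1, 1]``.  ``delta = 0`` is homeostasis
        (normal stem cells), ``delta > 0`` tumor growth.
    n_senescence
        Number of generations a CC divides before turning senescent (N >= 1).
    death_prob
        Probability per generation that a senescent cell dies, in [0, 1].
    division_rate
        Cell divisions per day (R > 0); maps generations to time, k = R * t.
    csc_fraction_0
        Initial fraction of CSCs in the population, in [0, 1].
    """

    delta: float
    n_senescence: int
    death_prob: float = 0.0
    division_rate: float = 1.0
    csc_fraction_0: float = 1.0

    def __post_init__(self) -> None:
        if not (-1.0 < self.delta <= 1.0):
            raise ValueError(f"delta must be in (-1, 1], got {self.delta}")
        if int(self.n_senescence) != self.n_senescence or self.n_senescence < 1:
            raise ValueError(
                f"n_senescence must be a positive integer, got {self.n_senescence}"
            )
        object.__setattr__(self, "n_senescence", int(self.n_senescence))
        if not (0.0 <= self.death_prob <= 1.0):
            raise ValueError(f"death_prob must be in [0, 1], got {self.death_prob}")
        if not self.division_rate > 0.0:
            raise ValueError(
                f"division_rate must be positive, got {self.division_rate}"
            )
        if not (0.0 <= self.csc_fraction_0 <= 1.0):
            raise ValueError(
                f"csc_fraction_0 must be in [0, 1], got {self.csc_fraction_0}"
            )

    @classmethod
    def from_division_probs(
        cls,
        p_sym_csc: float,
        p_sym_cc: float,
        n_senescence: int,
        death_prob: float = 0.0,
        division_rate: float = 1.0,
        csc_fraction_0: float = 1.0,
    ) -> "HierarchicalParams":
        """Build parameters from explicit division-type probabilities.

        ``p_sym_csc`` (two CSCs), ``p_sym_cc`` (two CCs) and the implied
        asymmetric probability ``1 - p_sym_csc - p_sym_cc`` must all lie in
        [0, 1]; the mean kinetics depend on them only through
        ``delta = p_sym_csc - p_sym_cc``.
        """
        for name, p in (("p_sym_csc", p_sym_csc), ("p_sym_cc", p_sym_cc)):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if p_sym_csc + p_sym_cc > 1.0 + 1e-12:
            raise ValueError("p_sym_csc + p_sym_cc must not exceed 1")
        return cls(
            delta=p_sym_csc - p_sym_cc,
            n_senescence=n_senescence,
            death_prob=death_prob,
            division_rate=division_rate,
            csc_fraction_0=csc_fraction_0,
        )


@dataclass(frozen=True)
class PopulationState:
    """Mean population vector at one generation.

    ``cc_by_age[i-1]`` holds CCs of age ``i`` (generations since the CSC
    they originated from), for ``i = 1 .. n_senescence``.
    """

    generation: int
    csc: float
    cc_by_age: np.ndarray
    senescent: float

    def __post_init__(self) -> None:
        cc = np.asarray(self.cc_by_age, dtype=float)
        object.__setattr__(self, "cc_by_age", cc)
        if self.generation < 0:
            raise ValueError("generation must be non-negative")
        if self.csc < 0 or self.senescent < 0 or np.any(cc < 0):
            raise ValueError("population counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.csc + self.cc_by_age.sum() + self.senescent)

    @property
    def senescent_fraction(self) -> float:
        tot = self.total
        return self.senescent / tot if tot > 0 else 0.0

    @property
    def csc_fraction(self) -> float:
        tot = self.total
        return self.csc / tot if tot > 0 else 0.0


@dataclass(frozen=True)
class Trajectory:
    """Time course of the population, one entry per generation."""

    times: np.ndarray
    generations: np.ndarray
    totals: np.ndarray
    cpd: np.ndarray
    senescent_fraction: np.ndarray
    csc_fraction: np.ndarray
    states: tuple[PopulationState, ...] = field(default=(), repr=False)

    def __len__(self) -> int:
        return len(self.generations)

    def to_frame(self):
        """Export as a pandas DataFrame (day, generation, total, cpd, fractions)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "day": self.times,
                "generation": self.generations,
                "total": self.totals,
                "cpd": self.cpd,
                "senescent_fraction": self.senescent_fraction,
                "csc_fraction": self.csc_fraction,
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _check_state(state: PopulationState, params: HierarchicalParams) -> None:
    if len(state.cc_by_age) != params.n_senescence:
        raise ValueError(
            f"cc_by_age has length {len(state.cc_by_age)}, "
            f"expected n_senescence = {params.n_senescence}"
        )


def advance_generation(
    state: PopulationState, params: HierarchicalParams
) -> PopulationState:
    """Apply the mean-field recursion for one generation.

    Each CSC yields on average ``1 + delta`` CSCs and ``1 - delta`` new
    age-1 CCs; CCs of age ``i < N`` double into age ``i + 1``; a CC of age
    ``N`` joins the senescent pool, which loses a fraction ``death_prob``
    per subsequent generation.
    """
    _check_state(state, params)
    delta, d = params.delta, params.death_prob
    cc = state.cc_by_age
    new_cc = np.empty_like(cc)
    new_cc[0] = (1.0 - delta) * state.csc
    new_cc[1:] = 2.0 * cc[:-1]
    return PopulationState(
        generation=state.generation + 1,
        csc=(1.0 + delta) * state.csc,
        cc_by_age=new_cc,
        senescent=(1.0 - d) * state.senescent + cc[-1],
    )


def mixed_initial_state(
    params: HierarchicalParams, scale: float = 1.0
) -> PopulationState:
    """Initial state with CSC fraction ``csc_fraction_0`` and the CC
    remainder spread uniformly over ages 1..N (no senescent cells)."""
    f = params.csc_fraction_0
    n = params.n_senescence
    return PopulationState(
        generation=0,
        csc=f * scale,
        cc_by_age=np.full(n, (1.0 - f) * scale / n),
        senescent=0.0,
    )


def simulate_trajectory(
    params: HierarchicalParams,
    init: PopulationState | None = None,
    k_max: int = 100,
    keep_states: bool = True,
) -> Trajectory:
    """Iterate the recursion ``k_max`` times from ``init``.

    ``init`` defaults to :func:`mixed_initial_state`.  Times are mapped as
    ``t = k / division_rate`` and CPD as ``log2(total / total(0))``.
    """
    if k_max < 0:
        raise ValueError("k_max must be non-negative")
    if init is None:
        init = mixed_initial_state(params)
    _check_state(init, params)

    states = [init]
    for _ in range(k_max):
        states.append(advance_generation(states[-1], params))

    totals = np.array([s.total for s in states])
    sen = np.array([s.senescent for s in states])
    csc = np.array([s.csc for s in states])
    gens = np.arange(init.generation, init.generation + k_max + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sen_frac = np.where(totals > 0, sen / totals, 0.0)
        csc_frac = np.where(totals > 0, csc / totals, 0.0)
        cpd = np.log2(totals / totals[0]) if totals[0] > 0 else np.zeros_like(totals)
    return Trajectory(
        times=gens / params.division_rate,
        generations=gens,
        totals=totals,
        cpd=cpd,
        senescent_fraction=sen_frac,
        csc_fraction=csc_frac,
        states=tuple(states) if keep_states else (),
    )


# ---------------------------------------------------------------------------
# Closed-form solutions.
#
# The vectorized helpers below evaluate the closed forms at (possibly
# real-valued) generation index k.  At integer k they reproduce the
# recursion exactly; between integers each population term is bridged
# geometrically (exponentials evaluated at real k), which for the
# homeostatic special case coincides with the exact continuous CPD formula.
# ---------------------------------------------------------------------------


def _pow(base: float, expo: np.ndarray) -> np.ndarray:
    """base ** expo with the convention 0**0 = 1, 0**positive = 0."""
    if base == 0.0:
        return np.where(np.asarray(expo) == 0.0, 1.0, 0.0)
    return np.power(base, expo)


def _csc_seeded_curves(
    delta: float, n: int, d: float, k: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(total, senescent, csc) for a unit CSC seed, vectorized over k >= 0."""
    k = np.asarray(k, dtype=float)
    a = 1.0 + delta
    r = 1.0 - d
    s = _pow(a, k)

    # CC total: (1-delta) * sum_{i=1}^{m} 2^{i-1} a^{k-i},  m = min(k, N)
    m = np.minimum(k, float(n))
    if abs(2.0 - a) < _EPS_DEGENERATE:
        cc = (1.0 - delta) * m * _pow(a, k - 1.0)
    else:
        cc = (1.0 - delta) * (np.power(2.0, m) * _pow(a, k - m) - _pow(a, k)) / (2.0 - a)

    # Senescent pool for k >= N: (1-delta) 2^{N-1} (a^j - r^j)/(a - r), j = k-N
    j = np.maximum(k - n, 0.0)
    if abs(a - r) < _EPS_DEGENERATE:  # delta + d -> 0: analytic limit
        core = j * _pow(0.5 * (a + r), np.maximum(j - 1.0, 0.0))
    else:
        core = (_pow(a, j) - _pow(r, j)) / (a - r)
    b = np.where(k >= n, (1.0 - delta) * 2.0 ** (n - 1.0) * core, 0.0)

    return s + cc + b, b, s


def _cc_seeded_curves(
    n: int, d: float, k: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(total, senescent) for a unit CC seed uniform over ages 1..N.

    Cohort bookkeeping: the cohort of initial age j (mass 1/N) doubles for
    N - j generations, converts to ``2^{N-j}/N`` senescent cells at
    generation N - j + 1, and then decays by (1 - d) per generation.
    """
    k = np.asarray(k, dtype=float)
    r = 1.0 - d
    dividing = np.where(k <= n, np.power(2.0, k) * (n - k) / n, 0.0)
    # senescent: sum over converted cohorts, M = min(N-1, k-1)
    big_m = np.minimum(float(n - 1), k - 1.0)
    expo = np.maximum(k - 1.0 - big_m, 0.0)  # = max(k - N, 0)
    b = np.where(
        k >= 1.0,
        (np.power(2.0, big_m + 1.0) * _pow(r, expo) - _pow(r, k)) / (n * (2.0 - r)),
        0.0,
    )
    return dividing + b, b


def csc_seeded_solution(params: HierarchicalParams, k: int) -> PopulationState:
    """Closed-form state at integer generation ``k`` for a unit CSC seed.

    ``S(k) = (1+delta)^k``; ``C_i(k) = (1-delta) 2^{i-1} (1+delta)^{k-i}``
    for ``i <= min(k, N)``; the senescent pool is the geometric sum of
    converted age-N cohorts decayed by ``(1-d)`` per generation.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    delta, n, d = params.delta, params.n_senescence, params.death_prob
    a, r = 1.0 + delta, 1.0 - d
    cc = np.zeros(n)
    imax = min(k, n)
    i = np.arange(1, imax + 1, dtype=float)
    cc[: int(imax)] = (1.0 - delta) * 2.0 ** (i - 1.0) * a ** (k - i)
    if k >= n:
        j = float(k - n)
        if abs(a - r) < _EPS_DEGENERATE:
            core = j * (0.5 * (a + r)) ** max(j - 1.0, 0.0)
        else:
            core = (_pow(a, np.array(j)) - _pow(r, np.array(j))) / (a - r)
        b = float((1.0 - delta) * 2.0 ** (n - 1.0) * core)
    else:
        b = 0.0
    return PopulationState(generation=k, csc=a**k, cc_by_age=cc, senescent=b)


def cc_seeded_solution(params: HierarchicalParams, k: int) -> PopulationState:
    """Closed-form state at integer ``k`` for a unit CC seed uniform over ages."""
    if k < 0:
        raise ValueError("k must be non-negative")
    n, d = params.n_senescence, params.death_prob
    r = 1.0 - d
    cc = np.zeros(n)
    # cohort of initial age j is at age j + k with mass 2^k / N while j + k <= N
    ages = np.arange(k + 1, n + 1)
    cc[ages - 1] = 2.0**k / n
    b = 0.0
    for jj in range(1, n + 1):  # cohort initial age jj converts at k = N - jj + 1
        kc = n - jj + 1
        if k >= kc:
            b += (2.0 ** (n - jj) / n) * r ** (k - kc)
    return PopulationState(generation=k, csc=0.0, cc_by_age=cc, senescent=b)


def total_population(params: HierarchicalParams, k) -> np.ndarray | float:
    """Total cell count at (real) generation index ``k``, unit initial scale.

    Linear superposition of the CSC-seeded and CC-seeded closed forms
    weighted by ``csc_fraction_0``; non-integer ``k`` is evaluated by the
    continuous (geometric-bridge) closed forms.
    """
    k_arr = np.asarray(k, dtype=float)
    if np.any(k_arr < 0):
        raise ValueError("generation index must be non-negative")
    f = params.csc_fraction_0
    tot_s, _, _ = _csc_seeded_curves(
        params.delta, params.n_senescence, params.death_prob, k_arr
    )
    tot_c, _ = _cc_seeded_curves(params.n_senescence, params.death_prob, k_arr)
    out = f * tot_s + (1.0 - f) * tot_c
    return out if np.ndim(k) else float(out)


def asymptotic_fractions(params: HierarchicalParams) -> tuple[float, float]:
    """Large-k limits of the senescent and CSC fractions (CSC-seeded).

    For ``delta + death_prob > 0`` the senescent fraction tends to
    ``(1 - delta) / (1 + delta + 2 d)`` — independent of N — and the CSC
    fraction to ``2 (delta + d) / (1 + delta + 2 d) * ((1 + delta)/2)^N``.
    For ``delta + d <= 0`` (including the homeostatic limit
    ``delta = 0, d = 0``) senescent cells take over: the limits are (1, 0).
    """
    delta, d, n = params.delta, params.death_prob, params.n_senescence
    if delta + d > 0.0:
        denom = 1.0 + delta + 2.0 * d
        sen = (1.0 - delta) / denom
        csc = 2.0 * (delta + d) / denom * ((1.0 + delta) / 2.0) ** n
        return sen, csc
    return 1.0, 0.0


def converged_senescent_fraction(
    params: HierarchicalParams,
    init: PopulationState | None = None,
    tol: float = 1e-13,
    max_iter: int = 10_000_000,
) -> tuple[float, int]:
    """Iterate the recursion (renormalized each step) until the senescent
    fraction changes by less than ``tol`` per generation.

    Renormalization leaves all fractions untouched (the recursion is
    linear) while avoiding overflow.  Returns (fraction, generations used).
    """
    if init is None:
        init = PopulationState(
            generation=0,
            csc=1.0,
            cc_by_age=np.zeros(params.n_senescence),
            senescent=0.0,
        )
    _check_state(init, params)
    delta, d, n = params.delta, params.death_prob, params.n_senescence
    # state vector [S, C_1..C_N, B]; tight loop, no dataclass churn
    x = np.empty(n + 2)
    x[0] = init.csc
    x[1 : n + 1] = init.cc_by_age
    x[n + 1] = init.senescent
    y = np.empty_like(x)
    prev = x[n + 1] / x.sum()
    hits = 0
    for it in range(1, max_iter + 1):
        y[0] = (1.0 + delta) * x[0]
        y[1] = (1.0 - delta) * x[0]
        y[2 : n + 1] = 2.0 * x[1:n]
        y[n + 1] = (1.0 - d) * x[n + 1] + x[n]
        y /= y.sum()
        frac = y[n + 1]
        x, y = y, x
        # the fraction is exactly flat for the first N generations, so ask
        # for a run of small changes past that transient
        hits = hits + 1 if abs(frac - prev) < tol else 0
        if hits >= 5 and it > n + 5:
            return float(frac), it
        prev = frac
    return float(prev), max_iter


def homeostatic_cpd(n_senescence: int, division_rate: float, t) -> np.ndarray | float:
    """CPD of the homeostatic special case (``delta = 0``, ``d = 0``,
    CSC-only seed), continuous in time.

    With ``k = division_rate * t``: CPD = k for k <= N, and
    ``N - 1 + log2(k - N + 2)`` beyond — exponential growth that crosses
    over to logarithmic flattening once the first CC cohorts senesce.
    """
    if not division_rate > 0:
        raise ValueError("division_rate must be positive")
    if int(n_senescence) != n_senescence or n_senescence < 1:
        raise ValueError("n_senescence must be a positive integer")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    k = division_rate * t_arr
    out = np.where(k <= n_senescence, k, (n_senescence - 1) + np.log2(np.maximum(k - n_senescence + 2, 1e-300)))
    return out if np.ndim(t) else float(out)
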