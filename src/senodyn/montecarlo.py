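"""Individual-based Monte-Carlo realizations of the branching processes.

Generation-synchronous sampling of the hierarchical CSC model and of the
stochastic null model with integer cell counts.  Used to validate the
mean-field recursions and to expose demographic noise (e.g. stochastic
loss of all CSCs, which the mean-field description cannot show).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import HierarchicalParams, PopulationState
from .stochastic import StochasticParams

__all__ = [
    "DivisionProbs",
    "EnsembleSummary",
    "simulate_realization",
    "simulate_stochastic_realization",
    "ensemble_summary",
    "stochastic_ensemble_summary",
]

DEFAULT_POPULATION_CAP = 10_000_000


@dataclass(frozen=True)
class DivisionProbs:
    """CSC division-type probabilities: two CSCs (``p_sym_csc``), two CCs
    (``p_sym_cc``) or one of each (the remainder).  Implied
    ``delta = p_sym_csc - p_sym_cc``."""

    p_sym_csc: float
    p_sym_cc: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_sym_csc <= 1.0 and 0.0 <= self.p_sym_cc <= 1.0):
            raise ValueError("division probabilities must be in [0, 1]")
        if self.p_sym_csc + self.p_sym_cc > 1.0 + 1e-12:
            raise ValueError("p_sym_csc + p_sym_cc must not exceed 1")

    @property
    def p_asym(self) -> float:
        return max(0.0, 1.0 - self.p_sym_csc - self.p_sym_cc)

    @property
    def delta(self) -> float:
        return self.p_sym_csc - self.p_sym_cc


@dataclass(frozen=True)
class Realization:
    """One stochastic realization: integer states plus a truncation flag."""

    states: tuple[PopulationState, ...]
    truncated: bool
    csc_extinct: bool  # True if the CSC lineage died out at some generation

    def __iter__(self):
        return iter(self.states)

    def __len__(self):
        return len(self.states)

    def __getitem__(self, i):
        return self.states[i]


@dataclass(frozen=True)
class EnsembleSummary:
    """Ensemble mean and standard-error trajectories per population class."""

    generations: np.ndarray
    mean_csc: np.ndarray
    mean_cc: np.ndarray
    mean_senescent: np.ndarray
    mean_total: np.ndarray
    se_csc: np.ndarray
    se_cc: np.ndarray
    se_senescent: np.ndarray
    se_total: np.ndarray
    n_runs: int
    seed: int
    n_truncated: int
    csc_extinction_fraction: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "generation": self.generations,
                "mean_csc": self.mean_csc,
                "mean_cc": self.mean_cc,
                "mean_senescent": self.mean_senescent,
                "mean_total": self.mean_total,
                "se_csc": self.se_csc,
                "se_cc": self.se_cc,
                "se_senescent": self.se_senescent,
                "se_total": self.se_total,
            }
        )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _check_integer_init(init: PopulationState) -> None:
    vals = np.concatenate(([init.csc], init.cc_by_age, [init.senescent]))
    if not np.allclose(vals, np.round(vals)):
        raise ValueError("Monte-Carlo initial counts must be integers")


def simulate_realization(
    probs: DivisionProbs,
    params: HierarchicalParams,
    init: PopulationState,
    k_max: int,
    seed,
    population_cap: int = DEFAULT_POPULATION_CAP,
) -> Realization:
    """One realization of the hierarchical branching process.

    Per generation each CSC independently draws its division type; each CC
    of age below N doubles into age + 1 with unit probability; age-N CCs
    join the senescent pool; each senescent cell dies with probability
    ``death_prob``.  Once the total population exceeds ``population_cap``
    the state is frozen and the run flagged truncated.
    """
    if len(init.cc_by_age) != params.n_senescence:
        raise ValueError("cc_by_age length must equal n_senescence")
    if k_max < 0:
        raise ValueError("k_max must be non-negative")
    _check_integer_init(init)
    rng = _as_rng(seed)
    p2, pa = probs.p_sym_csc, probs.p_asym
    n, d = params.n_senescence, params.death_prob

    s = int(round(init.csc))
    cc = np.round(np.asarray(init.cc_by_age, dtype=float)).astype(np.int64)
    b = int(round(init.senescent))
    states = [
        PopulationState(init.generation, float(s), cc.astype(float), float(b))
    ]
    truncated = False
    csc_extinct = s == 0
    for _ in range(k_max):
        if truncated:
            states.append(states[-1])
            continue
        n2 = rng.binomial(s, p2) if s > 0 else 0
        rem = s - n2
        if rem > 0 and p2 < 1.0:
            na = rng.binomial(rem, min(1.0, pa / (1.0 - p2)))
        else:
            na = 0
        n0 = rem - na
        new_s = 2 * n2 + na
        new_cc = np.empty_like(cc)
        new_cc[0] = 2 * n0 + na
        new_cc[1:] = 2 * cc[:-1]
        surv = rng.binomial(b, 1.0 - d) if (b > 0 and d > 0) else b
        new_b = surv + int(cc[-1])
        s, cc, b = new_s, new_cc, new_b
        csc_extinct = csc_extinct or s == 0
        if s + cc.sum() + b > population_cap:
            truncated = True
        states.append(
            PopulationState(
                states[-1].generation + 1, float(s), cc.astype(float), float(b)
            )
        )
    return Realization(tuple(states), truncated, csc_extinct)


def simulate_stochastic_realization(
    params: StochasticParams,
    c0: int,
    b0: int,
    k_max: int,
    seed,
    population_cap: int = DEFAULT_POPULATION_CAP,
) -> Realization:
    """One realization of the stochastic null model (no hierarchy).

    Each CC independently duplicates, dies, turns senescent, or quiesces;
    each senescent cell dies with probability ``death_prob``.  States are
    returned as :class:`PopulationState` with a single CC age slot.
    """
    if k_max < 0:
        raise ValueError("k_max must be non-negative")
    if c0 != int(c0) or b0 != int(b0):
        raise ValueError("initial counts must be integers")
    rng = _as_rng(seed)
    p, q, alpha, d = params.p_dup, params.p_die, params.p_sen, params.death_prob
    c, b = int(c0), int(b0)
    states = [PopulationState(0, 0.0, np.array([float(c)]), float(b))]
    truncated = False
    for k in range(k_max):
        if truncated:
            states.append(states[-1])
            continue
        n_dup = rng.binomial(c, p) if c > 0 else 0
        rem = c - n_dup
        if rem > 0 and p < 1.0:
            n_die = rng.binomial(rem, min(1.0, q / (1.0 - p)))
        else:
            n_die = 0
        rem -= n_die
        if rem > 0 and p + q < 1.0:
            n_sen = rng.binomial(rem, min(1.0, alpha / (1.0 - p - q)))
        else:
            n_sen = 0
        quiescent = rem - n_sen
        c = 2 * n_dup + quiescent
        surv = rng.binomial(b, 1.0 - d) if (b > 0 and d > 0) else b
        b = surv + n_sen
        if c + b > population_cap:
            truncated = True
        states.append(PopulationState(k + 1, 0.0, np.array([float(c)]), float(b)))
    return Realization(tuple(states), truncated, False)


def _summarize(
    runs: list[Realization], seed: int
) -> EnsembleSummary:
    n_runs = len(runs)
    k_len = len(runs[0])
    csc = np.array([[st.csc for st in r] for r in runs])
    cc = np.array([[st.cc_by_age.sum() for st in r] for r in runs])
    sen = np.array([[st.senescent for st in r] for r in runs])
    tot = csc + cc + sen

    def se(x):
        if n_runs < 2:
            return np.full(k_len, np.nan)
        return x.std(axis=0, ddof=1) / np.sqrt(n_runs)

    return EnsembleSummary(
        generations=np.array([st.generation for st in runs[0]]),
        mean_csc=csc.mean(axis=0),
        mean_cc=cc.mean(axis=0),
        mean_senescent=sen.mean(axis=0),
        mean_total=tot.mean(axis=0),
        se_csc=se(csc),
        se_cc=se(cc),
        se_senescent=se(sen),
        se_total=se(tot),
        n_runs=n_runs,
        seed=seed,
        n_truncated=sum(r.truncated for r in runs),
        csc_extinction_fraction=float(np.mean([r.csc_extinct for r in runs])),
    )


def ensemble_summary(
    probs: DivisionProbs,
    params: HierarchicalParams,
    init: PopulationState,
    k_max: int,
    n_runs: int,
    seed: int,
    population_cap: int = DEFAULT_POPULATION_CAP,
) -> EnsembleSummary:
    """Means and standard errors over independent seeded realizations.

    Per-realization RNG streams are spawned deterministically from the
    master seed, so two calls with the same seed are bit-identical; with
    ``n_runs = 1`` the mean equals that single realization and the SEs are
    flagged NaN.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    children = np.random.SeedSequence(seed).spawn(n_runs)
    runs = [
        simulate_realization(
            probs, params, init, k_max, np.random.default_rng(ss), population_cap
        )
        for ss in children
    ]
    return _summarize(runs, seed)


def stochastic_ensemble_summary(
    params: StochasticParams,
    c0: int,
    b0: int,
    k_max: int,
    n_runs: int,
    seed: int,
    population_cap: int = DEFAULT_POPULATION_CAP,
) -> EnsembleSummary:
    """Ensemble summary for the stochastic null model (CC counts reported
    in the ``cc`` class, CSC class identically zero)."""
    if n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    children = np.random.SeedSequence(seed).spawn(n_runs)
    runs = [
        simulate_stochastic_realization(
            params, c0, b0, k_max, np.random.default_rng(ss), population_cap
        )
        for ss in children
    ]
    return _summarize(runs, seed)
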