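"""Simulated drug treatments in the hierarchical CSC model.

Two therapeutic strategies are modelled as sustained parameter changes
from an onset generation:

* a senescence-inducing drug lowers the senescence generation N to
  ``n_treated`` (cells beyond the new limit convert to the senescent pool
  at the next step), and
* a death-inducing drug kills each CC with probability ``cc_death_prob``
  per generation before it divides, while CSCs are drug resistant.

In both cases the treated tumor stalls or shrinks only transiently: the
CSC compartment is untouched, its fraction rises in response, and growth
resumes at the untreated asymptotic rate ``1 + delta`` — the model's
statement that a therapy which spares CSCs fails in the long term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    HierarchicalParams,
    PopulationState,
    Trajectory,
    mixed_initial_state,
    simulate_trajectory,
)

__all__ = ["TreatmentSpec", "apply_treatment", "drug_induced_senescent_fraction"]


@dataclass(frozen=True)
class TreatmentSpec:
    """Specification of one sustained treatment.

    ``kind`` is 'senescence_inducing' (requires ``n_treated``) or
    'death_inducing' (requires ``cc_death_prob``); treatment starts at
    ``onset_generation`` and stays on.
    """

    kind: str
    onset_generation: int = 0
    n_treated: int | None = None
    cc_death_prob: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("senescence_inducing", "death_inducing"):
            raise ValueError(f"unknown treatment kind {self.kind!r}")
        if self.onset_generation < 0:
            raise ValueError("onset_generation must be non-negative")
        if self.kind == "senescence_inducing":
            if self.n_treated is None or self.n_treated < 1:
                raise ValueError("senescence_inducing requires n_treated >= 1")
            if self.cc_death_prob is not None:
                raise ValueError("cc_death_prob is not a senescence-drug field")
        else:
            if self.cc_death_prob is None or not (0.0 <= self.cc_death_prob <= 1.0):
                raise ValueError("death_inducing requires cc_death_prob in [0, 1]")
            if self.n_treated is not None:
                raise ValueError("n_treated is not a death-drug field")


def _advance_treated(
    state: PopulationState, params: HierarchicalParams, spec: TreatmentSpec
) -> PopulationState:
    """One generation under active treatment (state vector keeps length N)."""
    delta, d, n = params.delta, params.death_prob, params.n_senescence
    cc = state.cc_by_age
    new_cc = np.zeros_like(cc)
    if spec.kind == "senescence_inducing":
        n_eff = min(spec.n_treated, n)
        # ages below the new limit still double; everything at or past it senesces
        new_cc[0] = (1.0 - delta) * state.csc
        new_cc[1:n_eff] = 2.0 * cc[: n_eff - 1]
        converting = cc[n_eff - 1 :].sum()
        new_b = (1.0 - d) * state.senescent + converting
    else:
        pd_ = spec.cc_death_prob
        new_cc[0] = (1.0 - delta) * state.csc
        new_cc[1:] = 2.0 * (1.0 - pd_) * cc[:-1]
        new_b = (1.0 - d) * state.senescent + (1.0 - pd_) * cc[-1]
    return PopulationState(
        generation=state.generation + 1,
        csc=(1.0 + delta) * state.csc,
        cc_by_age=new_cc,
        senescent=new_b,
    )


def apply_treatment(
    params: HierarchicalParams,
    init: PopulationState | None,
    spec: TreatmentSpec,
    k_max: int,
) -> tuple[Trajectory, Trajectory]:
    """Simulate a treated and an untreated (control) trajectory.

    The control applies the unmodified recursion throughout; the treated
    trajectory switches to the drug-modified recursion from
    ``onset_generation`` on.  Returns (treated, control).
    """
    if init is None:
        init = mixed_initial_state(params)
    if spec.onset_generation > k_max:
        raise ValueError("onset_generation must not exceed k_max")
    control = simulate_trajectory(params, init, k_max)

    from .core import advance_generation

    states = [init]
    for k in range(k_max):
        if k >= spec.onset_generation:
            states.append(_advance_treated(states[-1], params, spec))
        else:
            states.append(advance_generation(states[-1], params))
    totals = np.array([s.total for s in states])
    sen = np.array([s.senescent for s in states])
    csc = np.array([s.csc for s in states])
    gens = np.arange(init.generation, init.generation + k_max + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sen_frac = np.where(totals > 0, sen / totals, 0.0)
        csc_frac = np.where(totals > 0, csc / totals, 0.0)
        cpd = np.where(
            totals > 0, np.log2(np.maximum(totals, 1e-300) / totals[0]), -np.inf
        )
    treated = Trajectory(
        times=gens / params.division_rate,
        generations=gens,
        totals=totals,
        cpd=cpd,
        senescent_fraction=sen_frac,
        csc_fraction=csc_frac,
        states=tuple(states),
    )
    return treated, control


def drug_induced_senescent_fraction(
    treated: Trajectory, control: Trajectory
) -> np.ndarray:
    """Excess senescent fraction attributable to the drug, per generation.

    For a growing tumor (delta > 0) under a senescence-inducing drug this
    difference decays back to zero: the asymptotic senescent fraction does
    not depend on the senescence generation, so drug-induced senescence is
    transient.  A sustained death-inducing drug, by contrast, permanently
    shifts the population composition (though never the growth rate).
    """
    if len(treated) != len(control):
        raise ValueError("trajectories must have equal length")
    return treated.senescent_fraction - control.senescent_fraction
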