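"""Model observables and least-squares fitting.

Converts the hierarchical model into the two experimental observables —
cumulative population doublings (CPD) and the senescent-cell fraction —
and implements the two fitting procedures used on stem-cell and melanoma
cultures:

* a two-parameter fit of the homeostatic CPD law (N, R) per donor, for
  mesenchymal stem cell growth curves, and
* a joint multi-curve fit in which two subpopulations (e.g. ABCG2+ and
  ABCG2- sorted melanoma cells) share the kinetic parameters
  (delta, N, d, R) and differ only by their initial CSC fraction, so that
  two growth curves and two senescence curves are fitted simultaneously in
  terms of six parameters (delta, N, d, R, f+, f-).

Fits use bounded least squares with seeded multi-start; N is treated as a
continuous parameter during optimization (round it for reporting).  The
parameter covariance is the Gauss-Newton approximation ``(J^T J)^{-1}``
scaled by the reduced chi-square, and t-statistics are estimate / SE.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .core import HierarchicalParams, _cc_seeded_curves, _csc_seeded_curves, homeostatic_cpd
from .datasets import GrowthDataset

__all__ = [
    "FitResult",
    "cpd_from_counts",
    "predict_curves",
    "multi_curve_objective",
    "fit_model",
    "fit_homeostatic",
    "initial_guess_from_data",
    "initial_condition_robustness",
    "steady_state_age_profile",
]

SHARED_PARAMS = ("delta", "n_senescence", "death_prob", "division_rate")

DEFAULT_BOUNDS = {
    "delta": (-0.9, 0.999),
    "n_senescence": (1.0, 500.0),
    "death_prob": (0.0, 1.0),
    "division_rate": (0.05, 5.0),
    "f": (0.0, 1.0),
}

_SD_FLOOR = 1e-6  # guard against zero-uncertainty points blowing up weights


def cpd_from_counts(x, x0) -> np.ndarray | float:
    """Cumulative population doublings, ``log2(x / x0)``."""
    x_arr, x0_arr = np.asarray(x, dtype=float), np.asarray(x0, dtype=float)
    if np.any(x_arr <= 0) or np.any(x0_arr <= 0):
        raise ValueError("cell counts must be positive")
    out = np.log2(x_arr / x0_arr)
    return out if (np.ndim(x) or np.ndim(x0)) else float(out)


def _model_curves(
    delta: float, n: float, d: float, rate: float, f: float, days: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(cpd, senescent_fraction) of the mixed-seed model at the given days.

    Evaluates the closed forms at real generation index ``k = rate * day``;
    ``n`` may be non-integer during optimization.
    """
    k = rate * np.asarray(days, dtype=float)
    tot_s, b_s, _ = _csc_seeded_curves(delta, n, d, k)
    if f < 1.0:
        tot_c, b_c = _cc_seeded_curves(n, d, k)
    else:
        tot_c = b_c = 0.0
    total = f * tot_s + (1.0 - f) * tot_c
    senescent = f * b_s + (1.0 - f) * b_c
    with np.errstate(divide="ignore", invalid="ignore"):
        cpd = np.log2(total)  # initial scale x0 = 1
        frac = np.where(total > 0, senescent / np.maximum(total, 1e-300), 0.0)
    return cpd, frac


def predict_curves(
    params: HierarchicalParams, days
) -> tuple[np.ndarray, np.ndarray]:
    """Model CPD and senescent fraction at the given observation days."""
    days_arr = np.asarray(days, dtype=float)
    if np.any(days_arr < 0):
        raise ValueError("days must be non-negative")
    return _model_curves(
        params.delta,
        params.n_senescence,
        params.death_prob,
        params.division_rate,
        params.csc_fraction_0,
        days_arr,
    )


def _param_names(datasets: Sequence[GrowthDataset]) -> tuple[str, ...]:
    return SHARED_PARAMS + tuple(f"f[{ds.label}]" for ds in datasets)


def _point_weights(
    ds: GrowthDataset, weights: dict | None
) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Per-point weights (1/sd when uncertainties are given, else unit),
    times any per-curve multiplier from ``weights`` (keys 'cpd'/'fraction')."""
    mult = weights or {}
    w_cpd = w_frac = None
    if ds.cpd is not None:
        base = (
            1.0 / np.maximum(ds.sd_cpd, _SD_FLOOR)
            if ds.sd_cpd is not None
            else np.ones_like(ds.cpd)
        )
        w_cpd = float(mult.get("cpd", 1.0)) * base
    if ds.senescent_fraction is not None:
        base = (
            1.0 / np.maximum(ds.sd_fraction, _SD_FLOOR)
            if ds.sd_fraction is not None
            else np.ones_like(ds.senescent_fraction)
        )
        w_frac = float(mult.get("fraction", 1.0)) * base
    return w_cpd, w_frac


def _stacked_residuals(
    full: dict, datasets: Sequence[GrowthDataset], weights: dict | None
) -> np.ndarray:
    res = []
    for ds in datasets:
        cpd_m, frac_m = _model_curves(
            full["delta"],
            full["n_senescence"],
            full["death_prob"],
            full["division_rate"],
            full[f"f[{ds.label}]"],
            ds.days,
        )
        w_cpd, w_frac = _point_weights(ds, weights)
        if ds.cpd is not None:
            res.append(w_cpd * (cpd_m - ds.cpd))
        if ds.senescent_fraction is not None:
            res.append(w_frac * (frac_m - ds.senescent_fraction))
    out = np.concatenate(res)
    return np.where(np.isfinite(out), out, 1e6)


def multi_curve_objective(
    free_params: Sequence[float],
    datasets: Sequence[GrowthDataset],
    weights: dict | None = None,
    fixed: dict | None = None,
) -> tuple[np.ndarray, float]:
    """Stacked weighted residuals and chi-square for the joint fit.

    ``free_params`` lists values for the non-fixed parameters in the order
    ``delta, n_senescence, death_prob, division_rate, f[label_1], ...``
    (skipping any parameter pinned via ``fixed``).  All datasets share the
    kinetic parameters and differ only in their initial CSC fraction.
    """
    if not datasets:
        raise ValueError("at least one dataset is required")
    if weights and all(v == 0 for v in weights.values()):
        raise ValueError("weights must not all be zero")
    fixed = fixed or {}
    names = [nm for nm in _param_names(datasets) if nm not in fixed]
    if len(free_params) != len(names):
        raise ValueError(
            f"expected {len(names)} free parameters ({names}), got {len(free_params)}"
        )
    full = dict(fixed)
    full.update(dict(zip(names, map(float, free_params))))
    residuals = _stacked_residuals(full, datasets, weights)
    return residuals, float(residuals @ residuals)


@dataclass
class FitResult:
    """Best-fit parameters with covariance-based uncertainties.

    ``parameters`` keeps the continuous optimizer estimates (round
    ``n_senescence`` for reporting); ``t_statistics`` are estimate / SE.
    """

    param_names: tuple[str, ...]
    parameters: dict
    stderr: dict
    covariance: np.ndarray
    t_statistics: dict
    chi2: float
    reduced_chi2: float
    n_points: int
    n_free: int
    success: bool
    message: str = ""
    flags: tuple[str, ...] = ()
    n_restarts: int = 1

    def to_dict(self) -> dict:
        return {
            "param_names": list(self.param_names),
            "parameters": {k: float(v) for k, v in self.parameters.items()},
            "stderr": {k: float(v) for k, v in self.stderr.items()},
            "t_statistics": {k: float(v) for k, v in self.t_statistics.items()},
            "covariance": np.asarray(self.covariance).tolist(),
            "chi2": float(self.chi2),
            "reduced_chi2": float(self.reduced_chi2),
            "n_points": self.n_points,
            "n_free": self.n_free,
            "success": self.success,
            "message": self.message,
            "flags": list(self.flags),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary(self) -> str:
        lines = [f"chi2 = {self.chi2:.6g}, reduced chi2 = {self.reduced_chi2:.4g} "
                 f"({self.n_points} points, {self.n_free} free parameters)"]
        for nm in self.param_names:
            if nm not in self.parameters:
                continue
            est, se, t = self.parameters[nm], self.stderr.get(nm, np.nan), self.t_statistics.get(nm, np.nan)
            note = ""
            if nm == "n_senescence":
                note = f"  (rounded: {round(est)})"
            lines.append(f"  {nm:>22s} = {est:.6g} +/- {se:.3g}  (t = {t:.3g}){note}")
        for fl in self.flags:
            lines.append(f"  flag: {fl}")
        return "\n".join(lines)


def _finish_fit(
    best, names, fixed, n_points, n_restarts, extra_flags=()
) -> FitResult:
    chi2 = float(2.0 * best.cost)
    n_free = len(names)
    dof = n_points - n_free
    red = chi2 / dof if dof > 0 else float("nan")
    jtj = best.jac.T @ best.jac
    try:
        cov_free = np.linalg.pinv(jtj) * (red if dof > 0 else 1.0)
    except np.linalg.LinAlgError:  # pragma: no cover
        cov_free = np.full((n_free, n_free), np.nan)
    params = dict(zip(names, map(float, best.x)))
    se = dict(zip(names, np.sqrt(np.maximum(np.diag(cov_free), 0.0))))
    tstat = {
        nm: (params[nm] / se[nm] if se[nm] > 0 else np.nan) for nm in names
    }
    params.update(fixed)
    flags = list(extra_flags)
    success = best.status > 0
    if not success:
        flags.append("optimizer did not report convergence")
    return FitResult(
        param_names=tuple(names) + tuple(fixed),
        parameters=params,
        stderr=se,
        covariance=cov_free,
        t_statistics=tstat,
        chi2=chi2,
        reduced_chi2=red,
        n_points=n_points,
        n_free=n_free,
        success=success,
        message=best.message,
        flags=tuple(flags),
        n_restarts=n_restarts,
    )


def initial_guess_from_data(datasets: Sequence[GrowthDataset]) -> dict:
    """Heuristic starting point read off the data.

    The early CPD slope approximates R (all cells still doubling), the late
    slope approximates ``R log2(1 + delta)``, and the day of the senescence
    peak approximates ``N / R``.
    """
    rate = 1.0
    slopes_early, slopes_late, peak_days = [], [], []
    for ds in datasets:
        if ds.cpd is not None and ds.days.size >= 4:
            ne = max(3, ds.days.size // 5)
            slopes_early.append(np.polyfit(ds.days[:ne], ds.cpd[:ne], 1)[0])
            slopes_late.append(np.polyfit(ds.days[-ne:], ds.cpd[-ne:], 1)[0])
        if ds.senescent_fraction is not None:
            peak_days.append(ds.days[int(np.argmax(ds.senescent_fraction))])
    if slopes_early:
        rate = float(np.clip(np.median(slopes_early), 0.1, 4.0))
    if slopes_late:
        ratio = np.clip(np.median(slopes_late) / rate, -0.5, 0.95)
        delta = float(np.clip(2.0**ratio - 1.0, -0.5, 0.9))
    else:
        delta = 0.1
    if peak_days:
        n0 = float(np.clip(rate * np.median(peak_days), 2.0, 450.0))
    else:
        n0 = float(np.clip(rate * np.median([ds.days[-1] for ds in datasets]) / 2, 2.0, 450.0))
    guess = {
        "delta": delta,
        "n_senescence": n0,
        "death_prob": 0.1,
        "division_rate": rate,
    }
    for ds in datasets:
        guess[f"f[{ds.label}]"] = 0.02
    return guess


def _bounds_for(names, bounds_override) -> tuple[np.ndarray, np.ndarray]:
    bounds_override = bounds_override or {}
    lo, hi = [], []
    for nm in names:
        key = "f" if nm.startswith("f[") else nm
        b = bounds_override.get(nm, bounds_override.get(key, DEFAULT_BOUNDS[key]))
        lo.append(b[0])
        hi.append(b[1])
    return np.asarray(lo), np.asarray(hi)


def _random_start(rng, names, lo, hi) -> np.ndarray:
    x = np.empty(len(names))
    for i, nm in enumerate(names):
        if nm.startswith("f[") or nm == "division_rate":
            # log-uniform for scale-like parameters
            a = max(lo[i], 1e-4)
            x[i] = np.exp(rng.uniform(np.log(a), np.log(max(hi[i], a * 1.01))))
        else:
            x[i] = rng.uniform(lo[i], hi[i])
    return np.clip(x, lo, hi)


def fit_model(
    datasets: Sequence[GrowthDataset],
    init_guess: dict | None = None,
    bounds: dict | None = None,
    weights: dict | None = None,
    fixed: dict | None = None,
    n_restarts: int = 16,
    seed: int = 0,
) -> FitResult:
    """Joint bounded least-squares fit of the hierarchical model.

    All datasets share (delta, N, d, R); each contributes its own initial
    CSC fraction ``f[label]``.  ``fixed`` pins parameters by name;
    ``bounds`` overrides the defaults per name (or 'f' for all fractions).
    Multi-start: the data-driven heuristic start plus ``n_restarts - 1``
    seeded random starts; the lowest chi-square wins.  Non-convergence is
    reported through ``success``/``flags``, never raised.
    """
    datasets = list(datasets)
    if not datasets:
        raise ValueError("at least one dataset is required")
    fixed = dict(fixed or {})
    names = [nm for nm in _param_names(datasets) if nm not in fixed]
    if not names:
        raise ValueError("no free parameters left to fit")
    lo, hi = _bounds_for(names, bounds)
    n_points = sum(ds.n_points for ds in datasets)

    def residuals(x):
        full = dict(fixed)
        full.update(dict(zip(names, x)))
        return _stacked_residuals(full, datasets, weights)

    starts = []
    base = dict(initial_guess_from_data(datasets))
    if init_guess:
        base.update(init_guess)
    starts.append(np.clip([base[nm] for nm in names], lo, hi))
    rng = np.random.default_rng(seed)
    for _ in range(max(0, n_restarts - 1)):
        starts.append(_random_start(rng, names, lo, hi))

    best = None
    for x0 in starts:
        try:
            res = least_squares(
                residuals, x0, bounds=(lo, hi), method="trf", x_scale="jac"
            )
        except Exception:  # noqa: BLE001 - a bad start must not kill the fit
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("all optimizer starts failed")

    flags = []
    for i, nm in enumerate(names):
        width = hi[i] - lo[i]
        if width > 0 and (
            best.x[i] <= lo[i] + 1e-9 * width or best.x[i] >= hi[i] - 1e-9 * width
        ):
            flags.append(f"{nm} at bound")
    return _finish_fit(best, names, fixed, n_points, len(starts), flags)


def fit_homeostatic(
    dataset: GrowthDataset,
    init_guess: dict | None = None,
    bounds: dict | None = None,
    n_restarts: int = 8,
    seed: int = 0,
) -> FitResult:
    """Two-parameter (N, R) fit of the homeostatic CPD law to one donor.

    Applied across donors of different ages this exposes the decline of N
    (generations before senescence) with donor age.  A fitted N pinned at
    its upper bound is flagged 'senescence not identifiable': the curve
    never flattens within the observation window.
    """
    if dataset.cpd is None:
        raise ValueError("fit_homeostatic needs a CPD curve")
    if dataset.cpd.size < 3:
        raise ValueError("fit_homeostatic needs at least 3 points")
    names = ["n_senescence", "division_rate"]
    lo, hi = _bounds_for(names, bounds)
    w = (
        1.0 / np.maximum(dataset.sd_cpd, _SD_FLOOR)
        if dataset.sd_cpd is not None
        else np.ones_like(dataset.cpd)
    )

    def residuals(x):
        model = homeostatic_cpd_continuous(x[0], x[1], dataset.days)
        return w * (model - dataset.cpd)

    slope = np.polyfit(dataset.days[:3], dataset.cpd[:3], 1)[0]
    base = {
        "n_senescence": float(np.clip(dataset.cpd.max(), lo[0] + 1, hi[0] - 1)),
        "division_rate": float(np.clip(slope, lo[1], hi[1])),
    }
    if init_guess:
        base.update(init_guess)
    starts = [np.clip([base[nm] for nm in names], lo, hi)]
    rng = np.random.default_rng(seed)
    for _ in range(max(0, n_restarts - 1)):
        starts.append(
            np.array(
                [rng.uniform(lo[0], hi[0]), np.exp(rng.uniform(np.log(max(lo[1], 1e-3)), np.log(hi[1])))]
            )
        )

    best = None
    for x0 in starts:
        res = least_squares(residuals, x0, bounds=(lo, hi), method="trf", x_scale="jac")
        if best is None or res.cost < best.cost:
            best = res
    flags = []
    crossover_k = best.x[1] * dataset.days[-1]  # generations observed
    if best.x[0] >= min(crossover_k, hi[0] - 1e-6 * (hi[0] - lo[0])):
        flags.append(
            "senescence not identifiable: fitted crossover lies outside the "
            "observation window (curve never flattens)"
        )
    return _finish_fit(best, names, {}, dataset.cpd.size, len(starts), flags)


def steady_state_age_profile(
    params: HierarchicalParams, n_ages: int | None = None
) -> np.ndarray:
    """Steady-state CC age distribution of the model with senescence
    generation ``n_ages`` (<= N), embedded in a length-N vector.

    In the growing regime the age-i cohort is proportional to
    ``2^{i-1} (1+delta)^{-i}``; normalized to unit mass.  A smaller
    ``n_ages`` describes cells sorted out of a younger parental culture.
    """
    n = params.n_senescence
    n_ages = n if n_ages is None else int(n_ages)
    if not (1 <= n_ages <= n):
        raise ValueError("n_ages must be in [1, n_senescence]")
    i = np.arange(1, n_ages + 1, dtype=float)
    profile = np.zeros(n)
    raw = 2.0 ** (i - 1.0) * (1.0 + params.delta) ** (-i)
    profile[:n_ages] = raw / raw.sum()
    return profile


def initial_condition_robustness(
    params: HierarchicalParams, days, n_init: int | None = None
) -> dict[str, float]:
    """Diagnostic: sensitivity of the predictions to the unobservable
    initial CC age distribution.

    Compares the uniform-age initialization (used by the closed forms)
    against the steady-state age profile of the same model with a smaller
    senescence generation ``n_init`` (default N // 10), emulating cells
    sorted from a younger culture.  Reports the largest absolute CPD and
    senescent-fraction differences over the observation days; a small CPD
    difference justifies fitting growth curves with the uniform-age
    closed form.
    """
    from .core import PopulationState, simulate_trajectory

    days_arr = np.asarray(days, dtype=float)
    k_max = int(np.ceil(params.division_rate * days_arr.max()))
    f, n = params.csc_fraction_0, params.n_senescence
    if n_init is None:
        n_init = max(1, n // 10)

    def curves(cc_profile):
        init = PopulationState(0, f, (1.0 - f) * cc_profile, 0.0)
        tr = simulate_trajectory(params, init, k_max, keep_states=False)
        k = params.division_rate * days_arr
        cpd = np.interp(k, tr.generations, tr.cpd)
        frac = np.interp(k, tr.generations, tr.senescent_fraction)
        return cpd, frac

    cpd_u, frac_u = curves(np.full(n, 1.0 / n))
    cpd_s, frac_s = curves(steady_state_age_profile(params, n_init))
    return {
        "max_cpd_difference": float(np.max(np.abs(cpd_u - cpd_s))),
        "max_fraction_difference": float(np.max(np.abs(frac_u - frac_s))),
        "final_fraction_difference": float(abs(frac_u[-1] - frac_s[-1])),
        "n_init": float(n_init),
    }


def homeostatic_cpd_continuous(n: float, rate: float, t) -> np.ndarray:
    """Homeostatic CPD with non-integer N allowed (optimizer relaxation)."""
    k = rate * np.asarray(t, dtype=float)
    return np.where(k <= n, k, (n - 1.0) + np.log2(np.maximum(k - n + 2.0, 1e-300)))
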