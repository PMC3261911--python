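"""Synthetic-data generators for every pipeline stage.

Emulates the statistical structure of long-term cell-culture experiments with known
ground truth:

* long-term melanoma cultures: two subpopulations (ABCG2+-like and
  ABCG2--like) identical except for their initial CSC fraction, observed
  twice weekly for ~140 days, with a senescence-fraction peak near day 90
  that is larger for the CSC-poor population;
* mesenchymal stem cell (MSC) cultures: homeostatic CPD curves that
  flatten once the culture senesces, with per-donor senescence generation;
* crystal-violet colony plates: disk colonies with exact ground-truth
  label maps and areas.

Noise models: Gaussian on CPD (cell-counting error) and, for the
senescence fraction, either binomial scoring of a fixed number of cells
(mechanistic default, 200 cells scored) or Gaussian.  All generators are
bit-reproducible given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import HierarchicalParams
from .datasets import GrowthDataset
from .fitting import homeostatic_cpd_continuous, predict_curves

__all__ = [
    "NoiseSpec",
    "ColonyPlacementError",
    "ColonyPlate",
    "default_schedule",
    "generate_growth_experiment",
    "generate_msc_experiment",
    "generate_msc_donor_panel",
    "generate_colony_image",
]

_FRACTION_SD_FLOOR = 5e-3  # keeps chi-square weights finite near 0 or 1


@dataclass(frozen=True)
class NoiseSpec:
    """Observation-noise model for generated datasets."""

    cpd_sd: float = 0.2
    fraction_mode: str = "binomial"
    fraction_sd: float = 0.02
    cells_scored: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cpd_sd < 0 or self.fraction_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.fraction_mode not in ("gaussian", "binomial"):
            raise ValueError("fraction_mode must be 'gaussian' or 'binomial'")
        if self.cells_scored < 1:
            raise ValueError("cells_scored must be at least 1")


def default_schedule(total_days: float = 140.0) -> np.ndarray:
    """Twice-weekly (alternating 3/4-day) observation days from day 0."""
    days = [0.0]
    gap = 3.0
    while days[-1] + gap <= total_days:
        days.append(days[-1] + gap)
        gap = 7.0 - gap
    return np.asarray(days)


def _noisy_fraction(
    frac_true: np.ndarray, noise: NoiseSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, int]:
    """(observed fraction, per-point sd, number of clipped points)."""
    if noise.fraction_mode == "binomial":
        n = noise.cells_scored
        obs = rng.binomial(n, np.clip(frac_true, 0.0, 1.0)) / n
        sd = np.sqrt(np.clip(frac_true * (1.0 - frac_true), 0.0, None) / n)
        return obs, np.maximum(sd, _FRACTION_SD_FLOOR), 0
    obs = frac_true + rng.normal(0.0, noise.fraction_sd, size=frac_true.shape)
    clipped = int(np.sum((obs < 0) | (obs > 1)))
    obs = np.clip(obs, 0.0, 1.0)
    sd = np.full_like(frac_true, max(noise.fraction_sd, _FRACTION_SD_FLOOR))
    return obs, sd, clipped


def generate_growth_experiment(
    true_params: HierarchicalParams,
    f_list: tuple[float, ...] = (0.05, 0.002),
    days: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec(),
    labels: tuple[str, ...] | None = None,
) -> list[GrowthDataset]:
    """Noisy CPD + senescence-fraction datasets for subpopulations that
    differ only in initial CSC fraction.

    With the defaults (f = 0.05 vs 0.002, N close to 90 R generations) the
    CSC-poor population shows the higher senescence peak between days 80
    and 100, mirroring ABCG2-sorted melanoma cultures.
    """
    if days is None:
        days = default_schedule()
    days = np.asarray(days, dtype=float)
    if labels is None:
        labels = tuple(f"f={f:g}" for f in f_list)
    if len(labels) != len(f_list):
        raise ValueError("labels must match f_list in length")
    rng = np.random.default_rng(noise.seed)
    out = []
    for f, label in zip(f_list, labels):
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"initial CSC fraction must be in [0, 1], got {f}")
        params = HierarchicalParams(
            delta=true_params.delta,
            n_senescence=true_params.n_senescence,
            death_prob=true_params.death_prob,
            division_rate=true_params.division_rate,
            csc_fraction_0=f,
        )
        cpd_true, frac_true = predict_curves(params, days)
        cpd_obs = cpd_true + (
            rng.normal(0.0, noise.cpd_sd, size=days.shape) if noise.cpd_sd > 0 else 0.0
        )
        frac_obs, sd_frac, n_clipped = (
            _noisy_fraction(frac_true, noise, rng)
            if _noise_active(noise)
            else (frac_true, None, 0)
        )
        out.append(
            GrowthDataset(
                label=label,
                days=days,
                cpd=cpd_obs,
                senescent_fraction=frac_obs,
                sd_cpd=np.full_like(days, noise.cpd_sd) if noise.cpd_sd > 0 else None,
                sd_fraction=sd_frac,
                meta={"f_true": f, "n_clipped": n_clipped, "seed": noise.seed},
            )
        )
    return out


def _noise_active(noise: NoiseSpec) -> bool:
    if noise.fraction_mode == "gaussian":
        return noise.fraction_sd > 0
    return noise.cells_scored < 10**9  # binomial scoring always adds noise


def generate_msc_experiment(
    n_senescence: int,
    division_rate: float,
    days: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec(),
    label: str = "MSC",
) -> GrowthDataset:
    """CPD-only homeostatic growth curve of one MSC donor."""
    if days is None:
        days = np.arange(0.0, 61.0, 2.5)
    days = np.asarray(days, dtype=float)
    rng = np.random.default_rng(noise.seed)
    cpd_true = homeostatic_cpd_continuous(float(n_senescence), division_rate, days)
    cpd_obs = cpd_true + (
        rng.normal(0.0, noise.cpd_sd, size=days.shape) if noise.cpd_sd > 0 else 0.0
    )
    return GrowthDataset(
        label=label,
        days=days,
        cpd=cpd_obs,
        sd_cpd=np.full_like(days, noise.cpd_sd) if noise.cpd_sd > 0 else None,
        meta={"n_true": n_senescence, "rate_true": division_rate, "seed": noise.seed},
    )


def generate_msc_donor_panel(
    n_values: tuple[int, ...],
    division_rate: float = 0.9,
    days: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec(),
) -> list[GrowthDataset]:
    """One homeostatic dataset per donor with per-donor senescence
    generation (e.g. decreasing N emulates increasing donor age)."""
    out = []
    for i, n in enumerate(n_values):
        spec = NoiseSpec(
            cpd_sd=noise.cpd_sd,
            fraction_mode=noise.fraction_mode,
            fraction_sd=noise.fraction_sd,
            cells_scored=noise.cells_scored,
            seed=noise.seed + i,
        )
        out.append(
            generate_msc_experiment(
                n, division_rate, days, spec, label=f"donor{i}(N={n})"
            )
        )
    return out


class ColonyPlacementError(RuntimeError):
    """Colonies could not be placed without overlap."""


@dataclass(frozen=True)
class ColonyPlate:
    """Synthetic crystal-violet plate with exact ground truth."""

    image: np.ndarray  # float intensities in [0, 1], colonies bright
    labels: np.ndarray  # int truth label map, 0 = background
    areas: np.ndarray  # pixel area per colony, index = label - 1
    centers: np.ndarray
    radii: np.ndarray

    @property
    def n_colonies(self) -> int:
        return len(self.areas)


def generate_colony_image(
    n_colonies: int,
    radius_range: tuple[float, float] = (4.0, 12.0),
    image_size: tuple[int, int] = (256, 256),
    seed: int = 0,
    allow_overlap: bool = False,
    noise_sd: float = 0.0,
    foreground: float = 0.85,
    background: float = 0.15,
    max_attempts: int = 10_000,
) -> ColonyPlate:
    """Disk colonies on a uniform background, with ground-truth labels.

    Without ``allow_overlap``, disks are rejection-sampled so that no two
    colonies touch even diagonally (centers at least ``r1 + r2 + 2`` px
    apart), guaranteeing that connected-component labeling recovers the
    exact colony count.
    """
    h, w = image_size
    rmin, rmax = radius_range
    if rmin <= 0 or rmax < rmin:
        raise ValueError("invalid radius_range")
    if 2 * rmax + 2 > min(h, w):
        raise ValueError("colonies do not fit in the image")
    rng = np.random.default_rng(seed)
    centers, radii = [], []
    attempts = 0
    while len(centers) < n_colonies:
        if attempts >= max_attempts:
            raise ColonyPlacementError(
                f"placed {len(centers)}/{n_colonies} colonies "
                f"in {max_attempts} attempts"
            )
        attempts += 1
        r = rng.uniform(rmin, rmax)
        cy = rng.uniform(r + 1, h - r - 1)
        cx = rng.uniform(r + 1, w - r - 1)
        if not allow_overlap:
            ok = all(
                np.hypot(cy - y0, cx - x0) >= r + r0 + 2.0
                for (y0, x0), r0 in zip(centers, radii)
            )
            if not ok:
                continue
        centers.append((cy, cx))
        radii.append(r)

    yy, xx = np.mgrid[0:h, 0:w]
    labels = np.zeros((h, w), dtype=np.int32)
    for i, ((cy, cx), r) in enumerate(zip(centers, radii), start=1):
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        labels[disk] = i
    image = np.where(labels > 0, foreground, background)
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, size=image.shape)
    areas = np.bincount(labels.ravel(), minlength=n_colonies + 1)[1:].astype(int)
    return ColonyPlate(
        image=image,
        labels=labels,
        areas=areas,
        centers=np.asarray(centers, dtype=float).reshape(-1, 2),
        radii=np.asarray(radii, dtype=float),
    )
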