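"""Synthetic data generators.

Three generators emulate the statistical structure of the experimental
inputs so every pipeline stage can be exercised end to end:

* :func:`generate_cohort` — cohorts of noisy sigmoid lacZ profiles whose
  per-embryo boundary positions are drawn from a configurable
  Normal(mean, sd), matching printed cohort summaries such as
  x = 0.291 +/- 0.071 (n = 35, no gal80) or x = 0.262 +/- 0.045 (n = 51,
  UASx5:gal80).
* :func:`generate_model_targets` — noiseless or noisy reporter profiles
  computed from a known parameter set, used as ground-truth targets for
  parameter-recovery tests of the fitting protocol.
* :func:`generate_embryo_image` — rotated elliptical "embryos" with a
  painted peripheral intensity band and known AP profile, the ground truth
  for the image-extraction stage.

All generators are pure functions of their configuration, including the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from galshuttle.fitting import THRESHOLD_2X, THRESHOLD_4X, FitTarget
from galshuttle.imaging import axial_ap_fraction
from galshuttle.model import (
    DosageConfig,
    ModelParameters,
    SpatialGrid,
    lacz_readout,
    solve_steady_state,
)
from galshuttle.stats import ANALYSIS_GRID, EmbryoProfile

__all__ = [
    "CohortConfig",
    "ImageConfig",
    "generate_cohort",
    "generate_model_targets",
    "generate_embryo_image",
    "axial_ap_fraction",
]


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of one synthetic embryo cohort.

    ``boundary_mean``/``boundary_sd`` describe the per-embryo boundary
    position x_L — the AP position where the normalized profile falls to
    ``crossing_level`` of its maximum (27% by default, matching the summary
    statistic used for four-copy-Gal4 cohorts).  The profile is a logistic
    ramp of width ``width`` EL; the two sides of one embryo share the
    boundary draw but receive independent noise.
    """

    n_embryos: int = 35
    boundary_mean: float = 0.291
    boundary_sd: float = 0.071
    width: float = 0.08
    crossing_level: float = 0.27
    amplitude: float = 1000.0
    amplitude_noise_sd: float = 0.05
    additive_noise_sd: float = 0.03
    baseline: float = 50.0
    genotype: str = "gal4x4"
    seed: int = 0

    def __post_init__(self):
        if self.n_embryos < 1:
            raise ValueError("n_embryos must be >= 1")
        if not (0.0 < self.boundary_mean < 1.0):
            raise ValueError("boundary_mean must be in (0, 1)")
        for name in ("boundary_sd", "amplitude_noise_sd", "additive_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.width <= 0:
            raise ValueError("width must be positive")
        if not (0.0 < self.crossing_level < 1.0):
            raise ValueError("crossing_level must be in (0, 1)")


def _logistic_offset(b: float, width: float, level: float) -> float:
    """Offset making the logistic ramp cross ``level`` of its in-domain
    maximum exactly at x = b.

    The curve is expit((b - x)/width + off); its maximum over [0, 1] sits at
    x = 0, so ``off`` solves expit(off) = level * expit(b/width + off).
    """
    def h(off):
        return expit(off) - level * expit(b / width + off)
    return brentq(h, -40.0, 40.0, xtol=1e-12)


def generate_cohort(config: CohortConfig,
                    grid: Optional[np.ndarray] = None) -> list[EmbryoProfile]:
    """Generate a cohort of two-sided noisy sigmoid profiles.

    Each embryo draws one boundary position
    ``b ~ Normal(boundary_mean, boundary_sd)`` (clipped to [0.05, 0.95]);
    both sides get intensity
    ``baseline + amplitude_i * logistic((b - x)/width + offset) + noise``
    where the offset places the ``crossing_level`` crossing of the
    normalized curve at ``b``, the per-side amplitude factor is lognormal
    with sd ``amplitude_noise_sd``, and the additive noise is Gaussian per
    grid point (sd relative to the amplitude).
    """
    if grid is None:
        grid = ANALYSIS_GRID
    rng = np.random.default_rng(config.seed)
    # a logistic ramp cannot fall to crossing_level of its maximum faster
    # than width*ln(1/level): clip boundary draws to the feasible range
    b_min = max(0.05, config.width * np.log(1.0 / config.crossing_level) + 1e-3)
    profiles = []
    for i in range(config.n_embryos):
        b = float(np.clip(rng.normal(config.boundary_mean, config.boundary_sd),
                          b_min, 0.95))
        off = _logistic_offset(b, config.width, config.crossing_level)
        shape = expit((b - grid) / config.width + off)
        for side in ("dorsal", "ventral"):
            amp = config.amplitude * np.exp(
                rng.normal(0.0, config.amplitude_noise_sd))
            noise = rng.normal(0.0, config.additive_noise_sd * config.amplitude,
                               size=grid.size)
            y = np.clip(config.baseline + amp * shape + noise, 0.0, None)
            profiles.append(EmbryoProfile(
                embryo_id=f"{config.genotype}_{i:03d}", side=side,
                ap=grid.copy(), intensity=y, genotype=config.genotype))
    return profiles


_SCENARIOS = {
    "control_4x": (0.0, "four", THRESHOLD_4X),
    "attenuation": (1.0, "four", THRESHOLD_4X),
    "control_2x": (0.0, "two", THRESHOLD_2X),
    "shuttling": (2.0, "two", THRESHOLD_2X),
}


def generate_model_targets(params: ModelParameters,
                           labels: Sequence[str] = tuple(_SCENARIOS),
                           noise_sd: float = 0.0, seed: int = 0,
                           q_2x: float = 0.35,
                           grid: Optional[SpatialGrid] = None) -> list[FitTarget]:
    """Model-generated fit targets for the standard dosage scenarios.

    Solves the steady state for each requested scenario with the given
    parameter set, applies the reporter readout, and (optionally) adds
    Gaussian noise clipped to the valid intensity range.
    """
    if grid is None:
        grid = SpatialGrid.uniform(201)
    rng = np.random.default_rng(seed)
    targets = []
    for label in labels:
        q_r, copies, threshold = _SCENARIOS[label]
        dosage = (DosageConfig.four_copy(q_r=q_r, q_2x=q_2x) if copies == "four"
                  else DosageConfig.two_copy(q_r=q_r, q_2x=q_2x))
        sol = solve_steady_state(params, dosage, grid, richardson=False)
        z = lacz_readout(sol, params)
        if noise_sd > 0:
            z = np.clip(z + rng.normal(0.0, noise_sd, size=z.size), 0.0, 1.05)
        targets.append(FitTarget(x=grid.x.copy(), y=z, label=label,
                                 dosage=dosage, threshold=threshold))
    return targets


def _default_peripheral(ap: np.ndarray) -> np.ndarray:
    return np.exp(-ap / 0.2)


@dataclass(frozen=True)
class ImageConfig:
    """Configuration of one synthetic mid-sagittal embryo image."""

    shape: tuple = (512, 768)
    center: tuple = (256.0, 384.0)
    semi_major: float = 300.0
    semi_minor: float = 120.0
    rotation: float = 0.0
    band_width: float = 12.0
    interior_level: float = 0.08
    peripheral_level: float = 1.0
    dorsal_profile: Callable[[np.ndarray], np.ndarray] = _default_peripheral
    ventral_profile: Callable[[np.ndarray], np.ndarray] = _default_peripheral
    noise_sd: float = 0.01
    n_bins: int = 200
    seed: int = 0

    def __post_init__(self):
        if not (self.semi_major >= self.semi_minor > 0):
            raise ValueError("need semi_major >= semi_minor > 0")
        if self.band_width <= 0:
            raise ValueError("band_width must be positive")


def _ellipse_frame(config: ImageConfig):
    h, w = config.shape
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    dy = rr - config.center[0]
    dx = cc - config.center[1]
    ct, st = np.cos(config.rotation), np.sin(config.rotation)
    # u along the major axis, v along the minor axis
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return u, v


def generate_embryo_image(config: ImageConfig) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a synthetic embryo image plus its ground-truth profiles.

    A filled rotated ellipse sits on a black background; a peripheral band
    of thickness ``band_width`` px just inside the outline carries the
    configured dorsal/ventral AP intensity functions (scaled by
    ``peripheral_level``) added on top of the uniform interior level — as
    in real embryos, where the nuclear-layer signal sits on cytoplasmic
    background — and Gaussian noise is added everywhere.  Returns the image
    and a table of exact AP-binned truth values (columns ``ap``,
    ``dorsal``, ``ventral``).
    """
    a, b = config.semi_major, config.semi_minor
    u, v = _ellipse_frame(config)
    rho2 = (u / a) ** 2 + (v / b) ** 2
    inside = rho2 <= 1.0
    # first-order distance to the ellipse outline: |F| / |grad F|
    grad = 2.0 * np.hypot(u / a**2, v / b**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        dist = np.where(grad > 0, np.abs(rho2 - 1.0) / grad, np.inf)
    band = inside & (dist <= config.band_width)

    img = np.zeros(config.shape, dtype=float)
    img[inside] = config.interior_level
    ap = axial_ap_fraction(u[band], v[band], a, b)
    dorsal = v[band] < 0  # image row axis points down: dorsal drawn on top
    vals = np.where(dorsal,
                    config.peripheral_level * config.dorsal_profile(ap),
                    config.peripheral_level * config.ventral_profile(ap))
    img[band] += vals
    rng = np.random.default_rng(config.seed)
    img = np.clip(img + rng.normal(0.0, config.noise_sd, size=img.shape), 0.0, None)

    centers = (np.arange(config.n_bins) + 0.5) / config.n_bins
    truth = pd.DataFrame({
        "ap": centers,
        "dorsal": config.peripheral_level * config.dorsal_profile(centers),
        "ventral": config.peripheral_level * config.ventral_profile(centers),
    })
    return img, truth
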