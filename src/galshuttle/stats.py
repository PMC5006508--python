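"""Expression-profile statistics for embryo cohorts.

Per-embryo lacZ intensity curves (intensity vs anterior-posterior fraction)
are normalized, registered by horizontal shift into a cohort-average
"canonical" profile, and summarized by the boundary position ``x_L`` — the AP
position where a normalized profile falls to a stated fraction (e.g. 27% or
31%) of its maximum.  Cohorts are compared pointwise with Welch two-sample
t-tests (reported as log10 p curves), and at the summary level with a Welch
t-test on boundary positions and a variance-ratio F-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.ndimage import uniform_filter1d
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

#: Common analysis grid: 0 to 1 EL in steps of 0.005.
ANALYSIS_GRID = np.round(np.arange(0, 201) * 0.005, 10)

__all__ = [
    "ANALYSIS_GRID",
    "EmbryoProfile",
    "CanonicalProfile",
    "SummaryStats",
    "BoundaryStat",
    "PointwiseTest",
    "normalize_profile",
    "build_canonical",
    "boundary_position",
    "pointwise_log10p",
    "summary_ttest",
    "variance_ftest",
    "cohort_boundary_stats",
    "read_profiles_csv",
    "write_profiles_csv",
]


@dataclass
class EmbryoProfile:
    """One dorsal or ventral intensity curve of a single embryo."""

    embryo_id: str
    side: str  # "dorsal" | "ventral"
    ap: np.ndarray
    intensity: np.ndarray
    genotype: str = ""

    def __post_init__(self):
        self.ap = np.asarray(self.ap, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.side not in ("dorsal", "ventral"):
            raise ValueError("side must be 'dorsal' or 'ventral'")
        if self.ap.ndim != 1 or self.ap.shape != self.intensity.shape:
            raise ValueError("ap and intensity must be 1-D arrays of equal length")
        if np.any(np.diff(self.ap) <= 0):
            raise ValueError("ap must be strictly increasing")
        if self.ap[0] < -1e-9 or self.ap[-1] > 1 + 1e-9:
            raise ValueError("ap must lie within [0, 1]")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")


@dataclass
class CanonicalProfile:
    """Aligned-and-averaged cohort profile."""

    x: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: int
    genotype: str = ""


@dataclass(frozen=True)
class SummaryStats:
    """Mean/SD/count of a per-embryo summary statistic (boundary position)."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass(frozen=True)
class BoundaryStat:
    """Boundary position x_L at a given fraction of maximal intensity."""

    x_L: float
    threshold: float


@dataclass
class PointwiseTest:
    """Pointwise Welch-t comparison of two cohorts along the AP axis."""

    x: np.ndarray
    p: np.ndarray
    log10_p: np.ndarray
    significant_intervals: list = field(default_factory=list)
    alpha: float = 0.05


def _smooth(y: np.ndarray, dx: float, window_el: float = 0.05) -> np.ndarray:
    w = max(1, int(round(window_el / dx)))
    if w % 2 == 0:
        w += 1
    return uniform_filter1d(y, size=w, mode="nearest")


def normalize_profile(profile: EmbryoProfile,
                      background_window: tuple[float, float] = (0.85, 0.95),
                      smooth_window_el: float = 0.05) -> EmbryoProfile:
    """Background-subtract and rescale one profile.

    The background is the mean intensity over the posterior window
    ``background_window`` (default 85-95% EL, beyond the expression domain).
    After subtraction the curve is rescaled so the maximum of a moving-average
    smoothed copy (window ``smooth_window_el`` of embryo length) equals 1,
    then clipped to nonnegative values.
    """
    y = profile.intensity
    if np.ptp(y) == 0:
        raise ValueError("constant profile has no dynamic range")
    mask = (profile.ap >= background_window[0]) & (profile.ap <= background_window[1])
    if not mask.any():
        raise ValueError("profile has no samples in the background window")
    background = float(y[mask].mean())
    y = y - background
    dx = float(np.median(np.diff(profile.ap)))
    peak = _smooth(y, dx, smooth_window_el).max()
    if peak <= 0:
        raise ValueError("no signal above background")
    y = np.clip(y / peak, 0.0, None)
    return EmbryoProfile(profile.embryo_id, profile.side, profile.ap.copy(), y,
                         profile.genotype)


def _resample(profile: EmbryoProfile, grid: np.ndarray, shift: float = 0.0) -> np.ndarray:
    """Profile values on ``grid`` after a horizontal shift (positive moves the
    curve posterior)."""
    return np.interp(grid - shift, profile.ap, profile.intensity)


def build_canonical(profiles: Sequence[EmbryoProfile],
                    grid: Optional[np.ndarray] = None, *,
                    max_shift: float = 0.1, tol: float = 0.001,
                    max_iter: int = 20,
                    fit_window: tuple[float, float] = (0.05, 0.95),
                    ) -> tuple[CanonicalProfile, np.ndarray]:
    """Iteratively align and average a cohort into a canonical profile.

    Each round averages the currently-aligned curves, then re-registers every
    curve to that template by the horizontal shift minimizing the sum of
    squared differences (bounded by ``max_shift`` EL, evaluated inside
    ``fit_window`` to avoid pole artifacts).  Shifts are re-centered to zero
    mean each round so the template cannot drift.  Iteration stops when no
    shift moves by more than ``tol`` EL (default 0.1% EL) or after
    ``max_iter`` rounds.

    Returns the canonical profile and the per-profile displacements
    (positive = the curve sits posterior of the canonical profile; aligning
    a curve means shifting it by minus its displacement).
    """
    if len(profiles) == 0:
        raise ValueError("need at least one profile")
    if grid is None:
        grid = ANALYSIS_GRID
    genotypes = {p.genotype for p in profiles}
    if len(genotypes) > 1:
        raise ValueError(f"profiles mix genotypes: {sorted(genotypes)}")
    shifts = np.zeros(len(profiles))
    window = (grid >= fit_window[0]) & (grid <= fit_window[1])
    for iteration in range(max_iter):
        curves = np.array([_resample(p, grid, s) for p, s in zip(profiles, shifts)])
        template = curves.mean(axis=0)
        new_shifts = np.empty_like(shifts)
        for i, p in enumerate(profiles):
            def sse(delta, p=p):
                resid = _resample(p, grid, delta)[window] - template[window]
                return float(resid @ resid)
            res = minimize_scalar(sse, bounds=(-max_shift, max_shift),
                                  method="bounded",
                                  options={"xatol": 1e-5})
            new_shifts[i] = res.x
        new_shifts -= new_shifts.mean()
        delta_max = np.abs(new_shifts - shifts).max()
        shifts = new_shifts
        if delta_max < tol:
            break
    curves = np.array([_resample(p, grid, s) for p, s in zip(profiles, shifts)])
    mean = curves.mean(axis=0)
    sd = curves.std(axis=0, ddof=1) if len(profiles) > 1 else np.zeros_like(mean)
    canon = CanonicalProfile(x=np.asarray(grid, float), mean=mean, sd=sd,
                             n=len(profiles), genotype=profiles[0].genotype)
    return canon, -shifts


ProfileLike = Union[EmbryoProfile, CanonicalProfile, tuple]


def _as_xy(obj: ProfileLike) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(obj, EmbryoProfile):
        return obj.ap, obj.intensity
    if isinstance(obj, CanonicalProfile):
        return obj.x, obj.mean
    x, y = obj
    return np.asarray(x, float), np.asarray(y, float)


def boundary_position(profile: ProfileLike, threshold: float = 0.27) -> BoundaryStat:
    """Locate x_L: where the profile falls to ``threshold`` of its maximum.

    Starting from the global maximum and moving posterior, the first downward
    crossing of ``threshold * max`` is located by linear interpolation
    between the bracketing nodes.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    x, y = _as_xy(profile)
    level = threshold * y.max()
    i0 = int(np.argmax(y))
    below = np.nonzero(y[i0:] < level)[0]
    if below.size == 0:
        raise ValueError(f"profile never falls below {threshold:.2f} of maximum")
    j = i0 + below[0]
    # interpolate between nodes j-1 (>= level) and j (< level)
    x_L = x[j - 1] + (level - y[j - 1]) * (x[j] - x[j - 1]) / (y[j] - y[j - 1])
    return BoundaryStat(x_L=float(x_L), threshold=threshold)


def pointwise_log10p(group_a: Sequence[EmbryoProfile],
                     group_b: Sequence[EmbryoProfile],
                     grid: Optional[np.ndarray] = None,
                     alpha: float = 0.05) -> PointwiseTest:
    """Pointwise Welch two-sample t-test between two cohorts.

    Both cohorts are resampled to the common grid; at every position the
    normalized intensities of group A are compared with group B by an
    unequal-variance (Welch) t-test.  Positions where both groups have zero
    variance are recorded as p = 1.  Also reports the contiguous AP intervals
    where p < ``alpha``.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 profiles per group")
    if grid is None:
        grid = ANALYSIS_GRID
    A = np.array([_resample(p, grid) for p in group_a])
    B = np.array([_resample(p, grid) for p in group_b])
    with np.errstate(divide="ignore", invalid="ignore"):
        result = sps.ttest_ind(A, B, axis=0, equal_var=False)
        p = np.asarray(result.pvalue)
    degenerate = (A.var(axis=0) == 0) & (B.var(axis=0) == 0)
    p = np.where(degenerate, 1.0, p)
    p = np.where(np.isnan(p), 1.0, p)
    with np.errstate(divide="ignore"):
        log10_p = np.log10(p)
    sig = p < alpha
    intervals = []
    in_run = False
    for i, flag in enumerate(sig):
        if flag and not in_run:
            start = grid[i]
            in_run = True
        elif not flag and in_run:
            intervals.append((float(start), float(grid[i - 1])))
            in_run = False
    if in_run:
        intervals.append((float(start), float(grid[-1])))
    return PointwiseTest(x=np.asarray(grid, float), p=p, log10_p=log10_p,
                         significant_intervals=intervals, alpha=alpha)


def summary_ttest(a: SummaryStats, b: SummaryStats) -> float:
    """Two-sided Welch t-test from summary statistics.

    Uses the Welch-Satterthwaite degrees of freedom.  Returns the two-sided
    p-value; degenerate input (both SDs zero, equal means) gives p = 1.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("need n >= 2 in both groups")
    if a.sd == 0 and b.sd == 0:
        return 1.0 if a.mean == b.mean else 0.0
    res = sps.ttest_ind_from_stats(a.mean, a.sd, a.n, b.mean, b.sd, b.n,
                                   equal_var=False)
    return float(res.pvalue)


def variance_ftest(a: SummaryStats, b: SummaryStats) -> float:
    """One-sided F-test for equality of variances.

    The larger sample variance goes in the numerator; returns the upper tail
    probability P(F >= s_max^2 / s_min^2) at the matching degrees of freedom.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("need n >= 2 in both groups")
    va, vb = a.sd**2, b.sd**2
    if min(va, vb) == 0:
        raise ValueError("zero variance in denominator")
    if va >= vb:
        F, dfn, dfd = va / vb, a.n - 1, b.n - 1
    else:
        F, dfn, dfd = vb / va, b.n - 1, a.n - 1
    return float(sps.f.sf(F, dfn, dfd))


def cohort_boundary_stats(profiles: Sequence[EmbryoProfile],
                          threshold: float = 0.27) -> SummaryStats:
    """Per-embryo boundary positions summarized as mean/SD/n.

    Profiles whose curve never falls below the threshold are excluded (with a
    warning counting them).
    """
    values = []
    skipped = 0
    for p in profiles:
        try:
            values.append(boundary_position(p, threshold).x_L)
        except ValueError:
            skipped += 1
    if skipped:
        logger.warning("%d of %d profiles had no %.0f%%-of-max crossing and were excluded",
                       skipped, len(profiles), 100 * threshold)
    if not values:
        raise ValueError("no profile crossed the threshold")
    arr = np.asarray(values)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return SummaryStats(mean=float(arr.mean()), sd=sd, n=arr.size)


def read_profiles_csv(path) -> list[EmbryoProfile]:
    """Read profiles from CSV with columns
    embryo_id, side, genotype, ap_fraction, intensity."""
    df = pd.read_csv(path)
    required = {"embryo_id", "side", "genotype", "ap_fraction", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"profiles CSV missing columns: {sorted(missing)}")
    profiles = []
    for (eid, side, gt), sub in df.groupby(["embryo_id", "side", "genotype"], sort=False):
        sub = sub.sort_values("ap_fraction")
        profiles.append(EmbryoProfile(str(eid), str(side),
                                      sub["ap_fraction"].to_numpy(),
                                      sub["intensity"].to_numpy(), str(gt)))
    return profiles


def write_profiles_csv(profiles: Iterable[EmbryoProfile], path) -> None:
    frames = []
    for p in profiles:
        frames.append(pd.DataFrame({
            "embryo_id": p.embryo_id, "side": p.side, "genotype": p.genotype,
            "ap_fraction": p.ap, "intensity": p.intensity,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
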