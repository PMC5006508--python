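"""Multi-regime fitting of the Gal4/Gal80 model to expression profiles.

The protocol mirrors how the network was interrogated experimentally:

1. *Control fit* — with no Gal80 (``q_r = 0``) the free-Gal4 gradient is
   analytic; only the gradient length scale and the reporter response
   (``lambda_g``, ``K_z``, ``n_z``) are fitted to the no-gal80 profile.
2. *Simultaneous fit* — holding the control parameters fixed, the feedback
   parameters are fitted jointly to the attenuation scenario
   (``q_r = 1, q_g = 1``) and the shuttling scenario
   (``q_r = 2, q_g = q_2x``).  Multistart optimization returns a *family*
   of acceptable parameter sets rather than a single optimum.
3. *Attenuation-only fit* — same, but fitted only to the attenuation
   scenario with the shuttling parameter pinned at ``chi = 0``.
4. *Gal3 prediction* — each family member is re-solved with a Gal3 stripe
   to ask whether a localized reporter increase requires shuttling.

The loss is unweighted least squares on normalized profiles over
``x in [0.05, 0.95]`` (pole artifacts excluded); optimization is bounded
least squares on log-transformed parameters from Latin-hypercube restarts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from galshuttle.model import (
    ConvergenceError,
    DosageConfig,
    ModelParameters,
    SpatialGrid,
    lacz_readout,
    solve_steady_state,
    solve_with_gal3,
    Gal3Config,
)
from galshuttle.stats import boundary_position

logger = logging.getLogger(__name__)

__all__ = [
    "FitTarget",
    "FitResult",
    "objective",
    "fit_control",
    "fit_simultaneous",
    "fit_attenuation_only",
    "predict_gal3",
    "Gal3Prediction",
    "CONTROL_BOUNDS",
    "FEEDBACK_BOUNDS",
]

#: Thresholds (fraction of maximal intensity) used for the boundary statistic
#: in the four-copy and two-copy Gal4 backgrounds.
THRESHOLD_4X = 0.27
THRESHOLD_2X = 0.31

_LABELS = ("control_4x", "control_2x", "attenuation", "shuttling")


@dataclass
class FitTarget:
    """A mean expression profile to be fitted under a known dosage scenario."""

    x: np.ndarray
    y: np.ndarray
    label: str
    dosage: DosageConfig
    threshold: float = THRESHOLD_4X

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.label not in _LABELS:
            raise ValueError(f"label must be one of {_LABELS}")
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if np.any((self.x < 0) | (self.x > 1)):
            raise ValueError("target coordinates must lie in [0, 1]")
        if np.any((self.y < -1e-9) | (self.y > 1.05)):
            raise ValueError("target intensities must lie in [0, 1.05]")


@dataclass
class FitResult:
    """One optimized parameter set."""

    params: ModelParameters
    dosage: DosageConfig
    objective: float
    seed: int
    converged: bool
    n_evaluations: int = 0
    x_L: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: getattr(self.params, k) for k in (
            "lambda_g", "lambda_r", "chi", "mu", "nu", "beta", "rho_c",
            "K_r", "n_r", "K_z", "n_z")}
        d.update(q_2x=self.dosage.q_2x, objective=self.objective,
                 seed=self.seed, converged=self.converged, x_L=self.x_L)
        return d


#: log-uniform multistart bounds for the control fit.
CONTROL_BOUNDS = {
    "lambda_g": (0.03, 0.5),
    "K_z": (0.1, 50.0),
    "n_z": (1.0, 6.0),
}

#: log-uniform multistart bounds for the feedback parameters.
FEEDBACK_BOUNDS = {
    "lambda_r": (0.01, 0.5),
    "chi": (0.1, 60.0),
    "mu": (0.1, 1e3),
    "nu": (1e-3, 10.0),
    "beta": (0.1, 10.0),
    "rho_c": (0.1, 10.0),
    "K_r": (0.002, 2.0),
    "n_r": (1.0, 8.0),
}

_FIT_WINDOW = (0.05, 0.95)
_PENALTY = 1e3


def _solver_cache():
    """Memoize solves and warm-start Newton from the last solution of the
    same dosage scenario, which makes the many nearby solves of an
    optimization trajectory cheap."""
    cache: dict = {}
    warm: dict = {}

    def solve(params: ModelParameters, dosage: DosageConfig, grid: SpatialGrid):
        key = (tuple(getattr(params, k) for k in (
            "lambda_g", "lambda_r", "chi", "mu", "nu", "beta", "rho_c",
            "K_r", "n_r", "K_z", "n_z")), dosage.q_g, dosage.q_r)
        if key not in cache:
            scenario = (dosage.q_g, dosage.q_r, grid.n_nodes)
            try:
                sol = solve_steady_state(params, dosage, grid, richardson=False,
                                         max_iter=100, initial=warm.get(scenario))
            except ConvergenceError:
                if scenario not in warm:
                    raise
                sol = solve_steady_state(params, dosage, grid, richardson=False,
                                         max_iter=100)  # cold retry
            warm[scenario] = np.concatenate([sol.g, sol.r, sol.c])
            cache[key] = sol
            if len(cache) > 32:
                cache.pop(next(iter(cache)))
        return cache[key]

    return solve


def _target_residuals(params: ModelParameters, target: FitTarget,
                      grid: SpatialGrid, solve) -> np.ndarray:
    sol = solve(params, target.dosage, grid)
    z = lacz_readout(sol, params)
    mask = (target.x >= _FIT_WINDOW[0]) & (target.x <= _FIT_WINDOW[1])
    z_at = np.interp(target.x[mask], grid.x, z)
    return (z_at - target.y[mask]) / np.sqrt(mask.sum())


def objective(params: ModelParameters, targets: Sequence[FitTarget],
              grid: Optional[SpatialGrid] = None) -> float:
    """Sum over targets of the mean squared profile mismatch.

    Solver non-convergence at a parameter point yields a large finite
    penalty so optimizers can move on.
    """
    if len(targets) == 0:
        raise ValueError("need at least one target")
    if grid is None:
        grid = SpatialGrid.uniform(201)
    solve = _solver_cache()
    total = 0.0
    for t in targets:
        try:
            res = _target_residuals(params, t, grid, solve)
        except (ConvergenceError, ValueError) as exc:
            logger.warning("objective penalty at %s: %s", t.label, exc)
            return _PENALTY
        total += float(res @ res)
    return total


def _lhs_starts(bounds: dict, n_starts: int, seed: int,
                center: Optional[dict] = None) -> np.ndarray:
    """Latin-hypercube starts in log space; the first start can be a given
    center point."""
    names = list(bounds)
    lo = np.log([bounds[k][0] for k in names])
    hi = np.log([bounds[k][1] for k in names])
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    X = qmc.scale(sampler.random(n_starts), lo, hi)
    if center is not None:
        X[0] = np.clip(np.log([center[k] for k in names]), lo, hi)
    return X


def _run_local(make_params: Callable[[np.ndarray], ModelParameters],
               targets: Sequence[FitTarget], x0: np.ndarray,
               lo: np.ndarray, hi: np.ndarray, grid: SpatialGrid,
               max_nfev: int = 120):
    """Bounded least squares on log-parameters; returns (x, cost, nfev)."""
    solve = _solver_cache()
    n_eval = [0]

    def residuals(xv):
        n_eval[0] += 1
        params = make_params(np.exp(xv))
        try:
            return np.concatenate([
                _target_residuals(params, t, grid, solve) for t in targets])
        except (ConvergenceError, ValueError):
            return np.full(sum(((t.x >= _FIT_WINDOW[0]) & (t.x <= _FIT_WINDOW[1])).sum()
                               for t in targets), np.sqrt(_PENALTY))

    res = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                        diff_step=1e-4, xtol=1e-10, ftol=1e-10, gtol=1e-10,
                        max_nfev=max_nfev)
    return res.x, 2.0 * res.cost, n_eval[0]


def fit_control(target: FitTarget, bounds: Optional[dict] = None,
                n_starts: int = 8, seed: int = 0,
                grid: Optional[SpatialGrid] = None,
                base_params: Optional[ModelParameters] = None) -> FitResult:
    """Fit the no-Gal80 control (``q_r = 0``): gradient scale and readout.

    Optimizes ``lambda_g``, ``K_z`` and ``n_z`` against a control profile;
    returns the best of ``n_starts`` Latin-hypercube restarts.  A result
    sitting on a bound (within 0.1% in log space) is logged as such.
    """
    if not target.label.startswith("control"):
        raise ValueError("control fit requires a control target")
    if target.dosage.q_r != 0:
        raise ValueError("control target must have q_r = 0")
    if grid is None:
        grid = SpatialGrid.uniform(201)
    if bounds is None:
        bounds = CONTROL_BOUNDS
    if base_params is None:
        base_params = ModelParameters()
    names = list(bounds)
    lo = np.log([bounds[k][0] for k in names])
    hi = np.log([bounds[k][1] for k in names])

    def make_params(vals):
        return replace(base_params, **dict(zip(names, vals)))

    starts = _lhs_starts(bounds, n_starts, seed)
    best = None
    for x0 in starts:
        try:
            x, cost, nev = _run_local(make_params, [target], x0, lo, hi, grid)
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("control restart failed: %s", exc)
            continue
        if best is None or cost < best[1]:
            best = (x, cost, nev)
    if best is None or best[1] >= _PENALTY:
        raise ConvergenceError("all control-fit restarts failed", np.inf)
    x, cost, nev = best
    at_bound = [names[i] for i in range(len(names))
                if x[i] - lo[i] < 1e-3 or hi[i] - x[i] < 1e-3]
    if at_bound:
        logger.warning("control fit hit bounds for: %s", ", ".join(at_bound))
    params = make_params(np.exp(x))
    return FitResult(params=params, dosage=target.dosage, objective=cost,
                     seed=seed, converged=True, n_evaluations=nev)


def _evaluate_xl(params: ModelParameters, dosage: DosageConfig,
                 threshold: float, grid: SpatialGrid) -> float:
    sol = solve_steady_state(params, dosage, grid, richardson=False)
    return boundary_position((grid.x, lacz_readout(sol, params)), threshold).x_L


def _family_select(results: list, factor: float) -> list:
    ok = [r for r in results if r is not None and r.objective < _PENALTY]
    if not ok:
        return []
    best = min(r.objective for r in ok)
    return sorted((r for r in ok if r.objective <= factor * best),
                  key=lambda r: r.objective)


def fit_simultaneous(attn_target: FitTarget, shut_target: FitTarget,
                     control_fit: FitResult, n_starts: int = 50, seed: int = 0,
                     grid: Optional[SpatialGrid] = None,
                     bounds: Optional[dict] = None,
                     family_factor: float = 2.0) -> list[FitResult]:
    """Joint fit of the feedback parameters to both dosage regimes.

    The control parameters (``lambda_g``, ``K_z``, ``n_z``, ``q_2x``) are
    frozen from ``control_fit``; the eight feedback parameters are free.
    Returns the family of restarts whose objective is within
    ``family_factor`` of the best *and* whose simulated boundary shifts have
    the observed regime directions (anterior at ``q_r=1, q_g=1``; posterior
    at ``q_r=2, q_g=q_2x``).  Raises if no restart satisfies both
    directions.
    """
    if grid is None:
        grid = SpatialGrid.uniform(201)
    if bounds is None:
        bounds = FEEDBACK_BOUNDS
    names = list(bounds)
    lo = np.log([bounds[k][0] for k in names])
    hi = np.log([bounds[k][1] for k in names])
    base = control_fit.params

    def make_params(vals):
        return replace(base, **dict(zip(names, vals)))

    targets = [attn_target, shut_target]
    starts = _lhs_starts(bounds, n_starts, seed)
    results: list[Optional[FitResult]] = []
    for i, x0 in enumerate(starts):
        try:
            x, cost, nev = _run_local(make_params, targets, x0, lo, hi, grid)
            params = make_params(np.exp(x))
            results.append(FitResult(params=params, dosage=shut_target.dosage,
                                     objective=cost, seed=seed, converged=True,
                                     n_evaluations=nev))
        except Exception as exc:
            logger.warning("simultaneous restart %d failed: %s", i, exc)
            results.append(None)
    family = _family_select(results, family_factor)
    # regime-direction filter against the Gal80-free controls
    q2x = shut_target.dosage.q_2x
    ctrl_attn = _evaluate_xl(base, DosageConfig.four_copy(q_2x=q2x),
                             attn_target.threshold, grid)
    ctrl_shut = _evaluate_xl(base, DosageConfig.two_copy(q_2x=q2x),
                             shut_target.threshold, grid)
    accepted = []
    for r in family:
        try:
            xl_a = _evaluate_xl(r.params, attn_target.dosage,
                                attn_target.threshold, grid)
            xl_s = _evaluate_xl(r.params, shut_target.dosage,
                                shut_target.threshold, grid)
        except (ConvergenceError, ValueError) as exc:
            logger.warning("family member rejected (diagnostics failed): %s", exc)
            continue
        r.x_L = {"attenuation": xl_a, "shuttling": xl_s,
                 "control_4x": ctrl_attn, "control_2x": ctrl_shut}
        if xl_a <= ctrl_attn and xl_s >= ctrl_shut:
            accepted.append(r)
    if not accepted:
        best = family[0] if family else None
        raise ConvergenceError(
            "no restart reproduces both regime directions; best objective "
            f"{best.objective if best else np.nan:.3e} with x_L {best.x_L if best else {}}",
            np.inf)
    logger.info("simultaneous fit: %d/%d restarts in family, best objective %.3e",
                len(accepted), n_starts, accepted[0].objective)
    return accepted


def fit_attenuation_only(attn_target: FitTarget, control_fit: FitResult,
                         n_starts: int = 50, seed: int = 0,
                         grid: Optional[SpatialGrid] = None,
                         bounds: Optional[dict] = None,
                         family_factor: float = 2.0) -> list[FitResult]:
    """Fit only the attenuation scenario with shuttling disabled (chi = 0).

    Every returned member has ``chi = 0``; the family is the set of restarts
    within ``family_factor`` of the best objective.  In this ablated model
    class the complex must behave like DNA-associated Gal4 — neither
    longer-ranged (``chi = 0``) nor longer-lived (``rho_c >= 1``) than free
    Gal4.  Without the lifetime constraint the optimizer escapes to
    storage-depot solutions (immobile but nearly undegraded complex) that
    hoard Gal4 and release it under perturbations, which is facilitated
    dispersal by another name.
    """
    if grid is None:
        grid = SpatialGrid.uniform(201)
    if bounds is None:
        bounds = {k: v for k, v in FEEDBACK_BOUNDS.items() if k != "chi"}
        bounds["rho_c"] = (1.0, FEEDBACK_BOUNDS["rho_c"][1])
    names = list(bounds)
    lo = np.log([bounds[k][0] for k in names])
    hi = np.log([bounds[k][1] for k in names])
    base = replace(control_fit.params, chi=0.0)

    def make_params(vals):
        return replace(base, **dict(zip(names, vals)))

    starts = _lhs_starts(bounds, n_starts, seed)
    results: list[Optional[FitResult]] = []
    for i, x0 in enumerate(starts):
        try:
            x, cost, nev = _run_local(make_params, [attn_target], x0, lo, hi, grid)
            params = make_params(np.exp(x))
            results.append(FitResult(params=params, dosage=attn_target.dosage,
                                     objective=cost, seed=seed, converged=True,
                                     n_evaluations=nev))
        except Exception as exc:
            logger.warning("attenuation-only restart %d failed: %s", i, exc)
            results.append(None)
    family = _family_select(results, family_factor)
    if not family:
        raise ConvergenceError("all attenuation-only restarts failed", np.inf)
    for r in family:
        try:
            r.x_L = {"attenuation": _evaluate_xl(r.params, attn_target.dosage,
                                                 attn_target.threshold, grid)}
        except (ConvergenceError, ValueError):
            pass
    logger.info("attenuation-only fit: family of %d, best objective %.3e",
                len(family), family[0].objective)
    return family


@dataclass
class Gal3Prediction:
    """Predicted reporter response of one family member to a Gal3 stripe."""

    x: np.ndarray
    lacz_gal3: np.ndarray
    lacz_base: np.ndarray
    within_domain_increase: float
    anterior_change: float
    error: Optional[str] = None


def predict_gal3(family: Sequence[FitResult], gal3: Gal3Config,
                 dosage: Optional[DosageConfig] = None,
                 grid: Optional[SpatialGrid] = None) -> list[Gal3Prediction]:
    """Predict the lacZ response to a Gal3 stripe for each family member.

    For every parameter set the model is solved with and without the stripe
    (default: in the shuttling scenario ``q_r=2, q_g=q_2x``), and the
    maximal reporter increase inside the stripe domain and the largest
    decrease anterior of it are reported.  Per-member solver failures are
    recorded, not raised.
    """
    if len(family) == 0:
        raise ValueError("family must be nonempty")
    if grid is None:
        grid = SpatialGrid.uniform(201)
    if dosage is None:
        dosage = DosageConfig.two_copy(q_r=2.0)
    x = grid.x
    dom = (x >= gal3.domain_start) & (x <= gal3.domain_end)
    ant = (x >= _FIT_WINDOW[0]) & (x < gal3.domain_start)
    out = []
    for r in family:
        try:
            base_sol = solve_steady_state(r.params, dosage, grid, richardson=False)
            z0 = lacz_readout(base_sol, r.params)
            g3_sol = solve_with_gal3(r.params, dosage, gal3, grid, richardson=False)
            z1 = lacz_readout(g3_sol, r.params)
        except (ConvergenceError, ValueError) as exc:
            logger.warning("gal3 prediction failed for a family member: %s", exc)
            out.append(Gal3Prediction(x=x, lacz_gal3=np.array([]),
                                      lacz_base=np.array([]),
                                      within_domain_increase=np.nan,
                                      anterior_change=np.nan, error=str(exc)))
            continue
        delta = z1 - z0
        out.append(Gal3Prediction(
            x=x, lacz_gal3=z1, lacz_base=z0,
            within_domain_increase=float(delta[dom].max()),
            anterior_change=float(delta[ant].min())))
    return out
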