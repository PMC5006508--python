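"""Steady-state reaction-diffusion model of the Gal4/Gal80 negative-feedback network.

The model describes three species on the anterior-posterior (AP) axis of the
early Drosophila embryo, with position ``x`` measured as fraction of embryo
length (0 = anterior pole):

* ``g`` — free Gal4, supplied by a constant flux at the anterior pole,
* ``r`` — Gal80, produced where Gal4 signaling is high,
* ``c`` — the Gal4/Gal80 complex.

At steady state each species diffuses, decays, and exchanges through a
reversible binding reaction with forward rate ``mu`` and affinity ``nu``::

    0 = lambda_g**2 * g_xx - g - mu*(g*r - nu*c)
    0 = lambda_r**2 * r_xx - r - beta*mu*(g*r - nu*c) + q_r * f_r(g)
    0 = lambda_c**2 * c_xx - rho_c*c + mu*(g*r - nu*c)

with no-flux boundaries everywhere except a constant influx ``q_g`` of free
Gal4 at ``x = 0``.  Gal80 production ``f_r(g)`` is a Hill function of free
Gal4.  The key regime switch is the shuttling parameter ``chi``: the complex
is not DNA-bound and can therefore disperse Gal4 farther than free
(DNA-binding) Gal4 travels on its own.  ``chi`` measures that range
enhancement, ``lambda_c**2 = lambda_g**2 * rho_c * (1 + chi)``, so the
complex's decay range is ``lambda_g * sqrt(1 + chi)``; with ``chi = 0``
facilitated transport is disabled whatever the complex's lifetime.

An optional fourth species models a Gal3 stripe that sequesters Gal80
(releasing Gal4 from the complex), used to probe whether shuttling is
necessary and sufficient for a localized boost in reporter output.

The nonlinear boundary-value problem is discretized with second-order central
finite differences (flux boundary via ghost nodes) and solved by damped
Newton iteration; by default the solve is repeated on a doubled grid and
Richardson-extrapolated, giving fourth-order-accurate fields on the requested
grid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.integrate import simpson
from scipy.sparse.linalg import spsolve

logger = logging.getLogger(__name__)

__all__ = [
    "SpatialGrid",
    "ModelParameters",
    "DosageConfig",
    "Gal3Config",
    "SteadyStateSolution",
    "ConvergenceError",
    "hill",
    "analytic_control_profile",
    "solve_steady_state",
    "solve_with_gal3",
    "lacz_readout",
    "mass_balance_residuals",
    "reference_parameters",
]


class ConvergenceError(RuntimeError):
    """Newton iteration failed to reach the residual tolerance.

    Attributes
    ----------
    residual : float
        Sup-norm of the nonlinear residual at the last iterate.
    """

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class SpatialGrid:
    """Uniform grid on [0, 1] (AP fraction, anterior pole at 0)."""

    x: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        object.__setattr__(self, "x", x)
        if x.ndim != 1 or x.size < 2:
            raise ValueError("grid must be a 1-D array with at least 2 nodes")
        if abs(x[0]) > 1e-12 or abs(x[-1] - 1.0) > 1e-12:
            raise ValueError("grid must span [0, 1]")
        dx = np.diff(x)
        if np.any(dx <= 0):
            raise ValueError("grid coordinates must be strictly increasing")
        if np.ptp(dx) > 1e-12:
            raise ValueError("grid spacing must be uniform within 1e-12")

    @classmethod
    def uniform(cls, n_nodes: int = 401) -> "SpatialGrid":
        if n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        return cls(np.linspace(0.0, 1.0, int(n_nodes)))

    @property
    def n_nodes(self) -> int:
        return self.x.size

    @property
    def h(self) -> float:
        return float(self.x[1] - self.x[0])


@dataclass(frozen=True)
class ModelParameters:
    """Nondimensional rates and length scales of the Gal4/Gal80 system.

    Parameters
    ----------
    lambda_g, lambda_r : float
        Diffusion length scales of free Gal4 and Gal80 (fraction of embryo
        length).
    chi : float
        Shuttling parameter >= 0, the enhancement of the complex's
        *transport range* over free Gal4's: the complex diffusion length is
        ``lambda_c = lambda_g * sqrt(rho_c * (1 + chi))`` so that its decay
        range ``lambda_c / sqrt(rho_c)`` equals ``lambda_g * sqrt(1 + chi)``.
        With ``chi = 0`` the complex disperses Gal4 exactly as far as free
        Gal4 would travel on its own — facilitated transport is disabled
        regardless of the complex's lifetime.
    mu, nu : float
        Forward binding rate and unbinding affinity of the reversible
        Gal4 + Gal80 <-> complex reaction.
    beta : float
        Stoichiometric scaling of the binding flux in the Gal80 equation.
    rho_c : float
        Complex degradation rate relative to Gal4's.
    K_r, n_r : float
        Half-max level and Hill coefficient of Gal4-driven Gal80 production.
    K_z, n_z : float
        Half-max level and Hill coefficient of the lacZ reporter readout.
    """

    lambda_g: float = 0.2
    lambda_r: float = 0.2
    chi: float = 0.0
    mu: float = 0.0
    nu: float = 0.0
    beta: float = 1.0
    rho_c: float = 1.0
    K_r: float = 1.0
    n_r: float = 2.0
    K_z: float = 1.0
    n_z: float = 2.0

    def __post_init__(self):
        for name in ("lambda_g", "lambda_r", "beta", "rho_c", "K_r", "n_r", "K_z", "n_z"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be a positive finite number, got {v}")
        for name in ("mu", "nu", "chi"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    @property
    def lambda_c(self) -> float:
        return self.lambda_g * math.sqrt(self.rho_c * (1.0 + self.chi))


@dataclass(frozen=True)
class DosageConfig:
    """Transgene-dosage amplitudes.

    ``q_g`` is the Gal4 flux at the anterior pole: 1 for four gal4 copies,
    ``q_2x`` for two (the two-copy flux need not be exactly half because the
    transgenes sit at different genomic loci).  ``q_r`` scales Gal80
    production: 0 (no gal80), 1 (one UAS-gal80 copy) or 2 (two copies).
    """

    q_g: float = 1.0
    q_r: float = 0.0
    q_2x: float = 0.35

    def __post_init__(self):
        if not np.isfinite(self.q_g) or self.q_g <= 0:
            raise ValueError("q_g must be positive")
        if not np.isfinite(self.q_r) or self.q_r < 0:
            raise ValueError("q_r must be >= 0")
        if not (0.35 - 1e-9 <= self.q_2x <= 0.65 + 1e-9):
            raise ValueError("q_2x must lie in [0.35, 0.65]")

    @classmethod
    def four_copy(cls, q_r: float = 0.0, q_2x: float = 0.35) -> "DosageConfig":
        return cls(q_g=1.0, q_r=q_r, q_2x=q_2x)

    @classmethod
    def two_copy(cls, q_r: float = 0.0, q_2x: float = 0.35) -> "DosageConfig":
        return cls(q_g=q_2x, q_r=q_r, q_2x=q_2x)


@dataclass(frozen=True)
class Gal3Config:
    """A stripe of Gal3 production that sequesters Gal80.

    Gal3 (``s``) is produced at rate ``q_3`` inside
    ``[domain_start, domain_end]``, diffuses with length scale ``lambda_s``,
    decays, and binds Gal80 at rate ``mu_3`` (reversibility ``nu_3``,
    irreversible by default).  The Gal3/Gal80 product is inert; it is
    reported for bookkeeping as its local steady-state level assuming unit
    turnover, ``c3 = mu_3*s*r / (1 + mu_3*nu_3)``.

    The default stripe is the posterior (gt23-like) domain, which sits well
    beyond the free-Gal4 range and therefore reports *delivered* Gal4 —
    released from incoming complex — rather than local relief of
    suppression; an eve-stripe-2-like domain (0.38-0.46 EL) is the other
    experimentally used choice.  ``mu_3`` is modest by default: Gal4
    competes effectively with Gal3 for Gal80.
    """

    domain_start: float = 0.55
    domain_end: float = 0.63
    q_3: float = 2.0
    lambda_s: float = 0.05
    mu_3: float = 5.0
    nu_3: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.domain_start < self.domain_end <= 1.0):
            raise ValueError("need 0 <= domain_start < domain_end <= 1")
        for name in ("q_3", "mu_3", "nu_3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.lambda_s <= 0:
            raise ValueError("lambda_s must be positive")


@dataclass
class SteadyStateSolution:
    """Converged steady-state fields on a spatial grid."""

    grid: SpatialGrid
    g: np.ndarray
    r: np.ndarray
    c: np.ndarray
    s: Optional[np.ndarray] = None
    c3: Optional[np.ndarray] = None
    max_residual: float = np.nan
    n_iterations: int = 0
    converged: bool = False


def hill(g, K: float, n: float):
    """Hill activation ``g**n / (K**n + g**n)``, in [0, 1].

    Accepts scalars or arrays; ``g`` must be finite and nonnegative.
    """
    if K <= 0 or n <= 0:
        raise ValueError("K and n must be positive")
    g = np.asarray(g, dtype=float)
    if np.any(~np.isfinite(g)) or np.any(g < 0):
        raise ValueError("g must be finite and nonnegative")
    # compute in a scale-free way to avoid overflow for large g/K
    with np.errstate(divide="ignore"):
        t = (g / K) ** n
    out = t / (1.0 + t)
    out = np.where(np.isinf(t), 1.0, out)
    if out.ndim == 0:
        return float(out)
    return out


def _hill_clipped(g, K, n):
    """Hill evaluated on max(g, 0): used inside Newton where trial iterates
    may transiently dip negative."""
    gpos = np.maximum(g, 0.0)
    t = (gpos / K) ** n
    out = t / (1.0 + t)
    return np.where(np.isinf(t), 1.0, out)


def _hill_deriv_clipped(g, K, n):
    gpos = np.maximum(g, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (gpos / K) ** n
        d = n * u / (gpos * (1.0 + u) ** 2)
    d = np.where(np.isfinite(d), d, 0.0)
    return d


def analytic_control_profile(lambda_g: float, q_g: float, grid: SpatialGrid) -> np.ndarray:
    """Closed-form free-Gal4 profile in the no-binding limit.

    With ``mu = 0`` or ``q_r = 0`` the Gal4 equation decouples and the exact
    solution is ``g(x) = q_g*cosh((1 - x)/lambda_g) / (lambda_g*sinh(1/lambda_g))``.
    Serves as the analytic oracle for the numerical solver and as its initial
    guess.
    """
    if lambda_g <= 0:
        raise ValueError("lambda_g must be positive")
    if q_g <= 0:
        raise ValueError("q_g must be positive")
    x = grid.x
    # cosh((1-x)/lam)/sinh(1/lam) computed stably for small lam
    lam = lambda_g
    num = np.exp(-x / lam) * (1.0 + np.exp(-2.0 * (1.0 - x) / lam))
    den = 1.0 - np.exp(-2.0 / lam)
    return q_g / lam * num / den


def _laplacian_residual(u: np.ndarray, lam2: float, h: float, flux0: float = 0.0) -> np.ndarray:
    """lam2 * u_xx with ghost-node Neumann closures; flux0 is the influx J in
    -lam2*u_x(0) = J."""
    out = np.empty_like(u)
    out[1:-1] = lam2 * (u[:-2] - 2.0 * u[1:-1] + u[2:]) / h**2
    out[0] = lam2 * (2.0 * u[1] - 2.0 * u[0]) / h**2 + 2.0 * flux0 / h
    out[-1] = lam2 * (2.0 * u[-2] - 2.0 * u[-1]) / h**2
    return out


def _diffusion_matrix(n: int, lam2: float, h: float) -> sparse.spmatrix:
    main = np.full(n, -2.0 * lam2 / h**2)
    off = np.full(n - 1, lam2 / h**2)
    upper = off.copy()
    lower = off.copy()
    upper[0] = 2.0 * lam2 / h**2   # ghost closure at x = 0
    lower[-1] = 2.0 * lam2 / h**2  # ghost closure at x = 1
    return sparse.diags([lower, main, upper], [-1, 0, 1], format="csr")


def _assemble(params: ModelParameters, dosage: DosageConfig,
              gal3: Optional[Gal3Config], x: np.ndarray):
    """Return (residual_fn, jacobian_fn, n_species) for the FD system."""
    n = x.size
    h = float(x[1] - x[0])
    p, d = params, dosage
    lam_g2 = p.lambda_g**2
    lam_r2 = p.lambda_r**2
    lam_c2 = p.lambda_c**2
    with_s = gal3 is not None
    if with_s:
        lam_s2 = gal3.lambda_s**2
        mu3_eff = gal3.mu_3 / (1.0 + gal3.mu_3 * gal3.nu_3)
        src3 = np.where((x >= gal3.domain_start) & (x <= gal3.domain_end), gal3.q_3, 0.0)
    nspec = 4 if with_s else 3

    D_g = _diffusion_matrix(n, lam_g2, h)
    D_r = _diffusion_matrix(n, lam_r2, h)
    D_c = _diffusion_matrix(n, lam_c2, h)
    if with_s:
        D_s = _diffusion_matrix(n, lam_s2, h)
    I = sparse.identity(n, format="csr")

    def split(u):
        return [u[i * n:(i + 1) * n] for i in range(nspec)]

    def residual(u):
        parts = split(u)
        g, r, c = parts[0], parts[1], parts[2]
        phi = p.mu * (g * r - p.nu * c)
        f_r = _hill_clipped(g, p.K_r, p.n_r)
        F_g = _laplacian_residual(g, lam_g2, h, flux0=d.q_g) - g - phi
        F_r = _laplacian_residual(r, lam_r2, h) - r - p.beta * phi + d.q_r * f_r
        F_c = _laplacian_residual(c, lam_c2, h) - p.rho_c * c + phi
        if with_s:
            s = parts[3]
            phi3 = mu3_eff * s * r
            F_r = F_r - phi3
            F_s = _laplacian_residual(s, lam_s2, h) - s - phi3 + src3
            return np.concatenate([F_g, F_r, F_c, F_s])
        return np.concatenate([F_g, F_r, F_c])

    def residual_floor(u):
        """Roundoff floor of the sup-norm residual: machine epsilon times the
        magnitude of the largest term entering any residual component."""
        parts = split(u)
        g, r, c = parts[0], parts[1], parts[2]
        gmax = float(np.max(np.abs(g)))
        rmax = float(np.max(np.abs(r)))
        cmax = float(np.max(np.abs(c)))
        lam2_max = max(lam_g2, lam_r2, lam_c2)
        umax = max(gmax, rmax, cmax)
        scale = lam2_max * umax / h**2 + 2.0 * d.q_g / h
        scale += p.mu * (gmax * rmax + p.nu * cmax) * max(1.0, p.beta)
        if with_s:
            smax = float(np.max(np.abs(parts[3])))
            scale += lam_s2 * smax / h**2 + mu3_eff * smax * rmax + gal3.q_3
        return 100.0 * np.finfo(float).eps * scale

    def jacobian(u):
        parts = split(u)
        g, r, c = parts[0], parts[1], parts[2]
        dphi_dg = p.mu * r
        dphi_dr = p.mu * g
        dphi_dc = -p.mu * p.nu
        dfr_dg = _hill_deriv_clipped(g, p.K_r, p.n_r)

        Dg = sparse.diags(dphi_dg)
        Dr = sparse.diags(dphi_dr)
        J_gg = D_g - I - Dg
        J_gr = -Dr
        J_gc = (p.mu * p.nu) * I
        J_rg = sparse.diags(-p.beta * dphi_dg + d.q_r * dfr_dg)
        J_rr = D_r - I - p.beta * Dr
        J_rc = (p.beta * p.mu * p.nu) * I
        J_cg = Dg
        J_cr = Dr
        J_cc = D_c - p.rho_c * I + dphi_dc * I
        if with_s:
            s = parts[3]
            Dphi3_dr = sparse.diags(mu3_eff * s)
            Dphi3_ds = sparse.diags(mu3_eff * r)
            J_rr = J_rr - Dphi3_dr
            J_rs = -Dphi3_ds
            J_sr = -Dphi3_dr
            J_ss = D_s - I - Dphi3_ds
            blocks = [
                [J_gg, J_gr, J_gc, None],
                [J_rg, J_rr, J_rc, J_rs],
                [J_cg, J_cr, J_cc, None],
                [None, J_sr, None, J_ss],
            ]
        else:
            blocks = [
                [J_gg, J_gr, J_gc],
                [J_rg, J_rr, J_rc],
                [J_cg, J_cr, J_cc],
            ]
        return sparse.bmat(blocks, format="csc")

    return residual, jacobian, residual_floor, nspec


def _newton(residual, jacobian, u0: np.ndarray, tol: float, max_iter: int,
            floor_fn=None):
    """Damped Newton with residual-norm backtracking.

    Trial iterates are clipped to nonnegative values only for evaluating the
    backtracking criterion; the accepted iterate itself is never clipped.
    The convergence tolerance is raised to the roundoff floor of the
    residual evaluation (``floor_fn``) when that exceeds ``tol`` — stiff
    binding rates make sup-norm residuals below machine noise unattainable.
    Returns (u, sup_residual, n_iter) or raises ConvergenceError.
    """
    u = u0.copy()
    F = residual(u)
    norm = np.linalg.norm(F, ord=np.inf)
    for it in range(1, max_iter + 1):
        tol_eff = tol if floor_fn is None else max(tol, floor_fn(u))
        if norm < tol_eff:
            return u, norm, it - 1
        J = jacobian(u)
        try:
            step = spsolve(J, -F)
        except RuntimeError as exc:  # singular factorization
            raise ConvergenceError(f"linear solve failed: {exc}", norm) from exc
        if not np.all(np.isfinite(step)):
            raise ConvergenceError("Newton step not finite", norm)
        alpha = 1.0
        accepted = False
        for _ in range(40):
            trial = u + alpha * step
            F_trial = residual(np.maximum(trial, 0.0))
            norm_trial = np.linalg.norm(F_trial, ord=np.inf)
            if np.isfinite(norm_trial) and norm_trial < norm * (1.0 - 1e-4 * alpha) + tol:
                u = trial
                F = residual(u)
                norm = np.linalg.norm(F, ord=np.inf)
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            if floor_fn is not None and norm < 10.0 * max(tol, floor_fn(u)):
                return u, norm, it  # stagnated at the roundoff floor
            raise ConvergenceError(
                f"line search stalled at iteration {it} (residual {norm:.3e})", norm)
    tol_eff = tol if floor_fn is None else max(tol, floor_fn(u))
    if norm < tol_eff:
        return u, norm, max_iter
    raise ConvergenceError(
        f"no convergence after {max_iter} iterations (residual {norm:.3e})", norm)


def _initial_guess(params, dosage, gal3, x, nspec):
    g0 = analytic_control_profile(params.lambda_g, dosage.q_g, SpatialGrid(x))
    zero = np.zeros_like(x)
    parts = [g0, zero, zero]
    if nspec == 4:
        parts.append(zero)
    return np.concatenate(parts)


def _solve_on_grid(params, dosage, gal3, x, tol, max_iter, u0=None):
    residual, jacobian, floor_fn, nspec = _assemble(params, dosage, gal3, x)
    if u0 is None:
        u0 = _initial_guess(params, dosage, gal3, x, nspec)
    try:
        return _newton(residual, jacobian, u0, tol, max_iter, floor_fn) + (nspec,)
    except ConvergenceError:
        pass
    # adaptive continuation in the binding rates: ramp mu (and mu_3) from the
    # weak-coupling limit, halving the ramp step whenever Newton stalls
    logger.info("direct Newton failed; entering mu-continuation")
    u = u0
    f_cur, f_step = 0.0, 1.0
    norm = np.inf
    nit_total = 0
    last_err: Optional[ConvergenceError] = None
    for _ in range(60):
        f_try = min(1.0, f_cur + f_step)
        p_f = replace(params, mu=params.mu * f_try)
        g3_f = gal3 if gal3 is None else replace(gal3, mu_3=gal3.mu_3 * f_try)
        residual_f, jacobian_f, floor_f, _ = _assemble(p_f, dosage, g3_f, x)
        try:
            u_new, norm, nit = _newton(residual_f, jacobian_f, u, tol, max_iter,
                                       floor_f)
        except ConvergenceError as exc:
            last_err = exc
            f_step *= 0.5
            if f_step < 1e-4:
                break
            continue
        u = u_new
        nit_total += nit
        f_cur = f_try
        if f_cur >= 1.0:
            return u, norm, nit_total, nspec
        f_step *= 2.0
    raise last_err if last_err is not None else ConvergenceError(
        "mu-continuation failed", float(norm))


def _solve(params: ModelParameters, dosage: DosageConfig,
           gal3: Optional[Gal3Config], grid: SpatialGrid,
           tol: float, max_iter: int, richardson: bool,
           initial: Optional[np.ndarray] = None) -> SteadyStateSolution:
    x = grid.x
    n = grid.n_nodes
    u0 = None
    if initial is not None:
        nspec_exp = 4 if gal3 is not None else 3
        initial = np.asarray(initial, dtype=float)
        if initial.size == nspec_exp * n and np.all(np.isfinite(initial)):
            u0 = initial
    u, norm, nit, nspec = _solve_on_grid(params, dosage, gal3, x, tol, max_iter,
                                         u0=u0)
    fields = [u[i * n:(i + 1) * n] for i in range(nspec)]
    if richardson:
        # repeat on the doubled grid (shared nodes at even indices) and
        # extrapolate the O(h^2) error away: fourth-order-accurate fields
        x2 = np.linspace(0.0, 1.0, 2 * n - 1)
        u0_fine = np.concatenate([np.interp(x2, x, f) for f in fields])
        u2, norm2, nit2, _ = _solve_on_grid(params, dosage, gal3, x2, tol, max_iter,
                                            u0=u0_fine)
        norm = max(norm, norm2)
        nit += nit2
        n2 = x2.size
        fields = [(4.0 * u2[i * n2:(i + 1) * n2][::2] - f) / 3.0
                  for i, f in enumerate(fields)]
    g, r, c = fields[0], fields[1], fields[2]
    sol = SteadyStateSolution(grid=grid, g=g, r=r, c=c,
                              max_residual=float(norm), n_iterations=nit,
                              converged=True)
    if nspec == 4:
        s = fields[3]
        mu3_eff = gal3.mu_3 / (1.0 + gal3.mu_3 * gal3.nu_3)
        sol.s = s
        sol.c3 = mu3_eff * s * r
    logger.info("steady state converged: %d Newton iterations, residual %.3e",
                nit, norm)
    return sol


def solve_steady_state(params: ModelParameters, dosage: DosageConfig,
                       grid: Optional[SpatialGrid] = None, *,
                       tol: float = 1e-10, max_iter: int = 200,
                       richardson: bool = True,
                       initial: Optional[np.ndarray] = None) -> SteadyStateSolution:
    """Solve the Gal4/Gal80 steady-state boundary-value problem.

    Parameters
    ----------
    params, dosage
        Model rate constants and transgene dosage amplitudes.
    grid
        Uniform spatial grid (default 401 nodes).
    tol
        Sup-norm residual tolerance of the damped Newton iteration.
    richardson
        Also solve on a doubled grid and Richardson-extrapolate (default);
        disable for speed inside optimization loops.
    initial
        Optional warm-start iterate: the concatenated (g, r, c) fields of a
        previous solution on the same grid.

    Raises
    ------
    ConvergenceError
        If Newton iteration (with a mu-continuation fallback) does not reach
        ``tol`` within ``max_iter`` iterations.
    """
    if grid is None:
        grid = SpatialGrid.uniform(401)
    return _solve(params, dosage, None, grid, tol, max_iter, richardson,
                  initial=initial)


def solve_with_gal3(params: ModelParameters, dosage: DosageConfig,
                    gal3: Gal3Config, grid: Optional[SpatialGrid] = None, *,
                    tol: float = 1e-10, max_iter: int = 200,
                    richardson: bool = True) -> SteadyStateSolution:
    """Solve the steady state with a Gal3 sequestration stripe added.

    With ``q_3 = 0`` this reproduces :func:`solve_steady_state` bitwise (the
    Gal3-free system is solved and zero Gal3 fields are attached).
    """
    if grid is None:
        grid = SpatialGrid.uniform(401)
    if gal3.q_3 == 0.0:
        sol = _solve(params, dosage, None, grid, tol, max_iter, richardson)
        sol.s = np.zeros(grid.n_nodes)
        sol.c3 = np.zeros(grid.n_nodes)
        return sol
    return _solve(params, dosage, gal3, grid, tol, max_iter, richardson)


def lacz_readout(solution: SteadyStateSolution, params: ModelParameters) -> np.ndarray:
    """Normalized lacZ reporter profile.

    The reporter responds to free Gal4 only (Gal80-bound Gal4 cannot
    activate UAS sites): a Hill function of ``g`` with half-max ``K_z`` and
    coefficient ``n_z``, rescaled so its maximum is 1.
    """
    if not solution.converged:
        raise ValueError("readout requires a converged solution")
    g = np.maximum(solution.g, 0.0)
    z = hill(g, params.K_z, params.n_z)
    zmax = z.max()
    if zmax <= 0.0:
        raise ValueError("profile undefined: free-Gal4 readout is zero everywhere")
    return z / zmax


def mass_balance_residuals(solution: SteadyStateSolution, params: ModelParameters,
                           dosage: DosageConfig,
                           gal3: Optional[Gal3Config] = None) -> tuple[float, float]:
    """Integral conservation diagnostics of a converged solution.

    Integrating the Gal4 and complex equations over [0, 1] with the no-flux
    boundaries gives the Gal4 balance ``int(g + rho_c*c) dx = q_g``;
    integrating the Gal80 equation gives
    ``q_r * int f_r(g) dx = int(r + beta*rho_c*c + phi3) dx`` where ``phi3``
    is the Gal3 sequestration flux (zero without Gal3).  Returns the absolute
    defects of the two balances (Simpson quadrature).
    """
    x = solution.grid.x
    g, r, c = solution.g, solution.r, solution.c
    res_g = abs(simpson(g + params.rho_c * c, x=x) - dosage.q_g)
    f_r = _hill_clipped(g, params.K_r, params.n_r)
    sink = r + params.beta * params.rho_c * c
    if gal3 is not None and solution.s is not None:
        mu3_eff = gal3.mu_3 / (1.0 + gal3.mu_3 * gal3.nu_3)
        sink = sink + mu3_eff * solution.s * r
    res_r = abs(dosage.q_r * simpson(f_r, x=x) - simpson(sink, x=x))
    return float(res_g), float(res_r)


def reference_parameters() -> ModelParameters:
    """Reference parameter set exhibiting both feedback regimes.

    Calibrated once so that, relative to the matching no-Gal80 controls, the
    reporter boundary shifts anterior by about 0.03 EL at moderate feedback
    (``q_r = 1``, ``q_g = 1``; attenuation) and posterior by about 0.056 EL
    at high Gal80:Gal4 ratio (``q_r = 2``, ``q_g = 0.35``; shuttling) —
    the magnitudes observed for the synthetic network in vivo.  At this set
    a Gal3 stripe (default :class:`Gal3Config`) produces a localized
    reporter increase in the shuttling scenario, while the same set with
    ``chi = 0`` responds only marginally.
    """
    return ModelParameters(
        lambda_g=0.255,
        lambda_r=0.108,
        chi=610.0,
        mu=1.0e4,
        nu=0.0566,
        beta=0.956,
        rho_c=0.00478,
        K_r=0.0196,
        n_r=1.61,
        K_z=36.4,
        n_z=1.174,
    )
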