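"""Modified Poisson-Boltzmann boundary-value solver for the grafted film.

Solves, on ``0 <= z <= total_height + pad * lambda_D``,

    eps_r eps0 d2psi/dz2 = -(rho_DNA(z) + rho_ion(psi)),

with a Dirichlet electrode potential at ``z = 0`` and a zero-field
(Neumann) condition at the truncated far boundary.  The mobile-ion charge
follows the Borukhov finite-ion-size form for a symmetric 1:1 salt,

    rho_ion = -2 e n_bulk sinh(u) / (1 - nu + nu cosh(u)),   u = e psi / kT,

which reduces to Gouy-Chapman (``-2 e n sinh u``) for point ions (nu = 0)
and saturates at the close-packing density for large ``|u|``.  Ions may be
excluded from the film entirely (the dense self-assembled monolayer picture);
in that regime the field inside the film is exactly piecewise linear by
Gauss's law.

Internally the equation is nondimensionalised with ``u = e psi / kT`` and
``x = z / lambda_D``:

    u'' = chi_out(x) sinh(u)/(1 - nu + nu cosh u) - rho_DNA(x)/(2 e n_bulk),

and solved by damped Newton iteration on the second-order finite-difference
residual with a tridiagonal Jacobian.  The initial guess is the linearised
Debye-Hueckel decay from the electrode; a short source-continuation ramp is
used as a fallback for stiff cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as _dfield

import numpy as np
from scipy.linalg import solve_banded

from .errors import ConvergenceError, DomainError, InvalidParameterError
from .layer_model import _E, _EPS0, _KB, _NM, ElectrolyteModel, LayerModel, fixed_charge_density

__all__ = [
    "SolverSettings",
    "PotentialProfile",
    "ion_charge_density",
    "solve_pbe",
    "electric_field_at",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SolverSettings:
    """Numerical controls for the finite-difference Newton solve.

    grid_spacing : nm between nodes (uniform).
    domain_pad : far boundary at total_height + domain_pad * lambda_D.
    residual_tol : max-norm tolerance on the dimensionless residual.
    max_iterations : Newton iteration cap.
    damping : initial Newton step fraction; line search halves from here.
    """

    grid_spacing: float = 0.005
    domain_pad: float = 10.0
    residual_tol: float = 1e-10
    max_iterations: int = 200
    damping: float = 1.0

    def __post_init__(self) -> None:
        if self.grid_spacing <= 0:
            raise InvalidParameterError("grid_spacing must be > 0")
        if self.domain_pad < 5:
            raise InvalidParameterError("domain_pad must be >= 5 Debye lengths")
        if self.residual_tol <= 0:
            raise InvalidParameterError("residual_tol must be > 0")
        if self.max_iterations < 1:
            raise InvalidParameterError("max_iterations must be >= 1")
        if not (0 < self.damping <= 1):
            raise InvalidParameterError("damping must be in (0, 1]")


@dataclass
class PotentialProfile:
    """Solved potential and field on a uniform grid.

    z_grid in nm from the electrode; psi in mV; psi_star = e psi / kT;
    field = -dpsi/dz in V/nm.
    """

    z_grid: np.ndarray
    psi: np.ndarray
    psi_star: np.ndarray
    field: np.ndarray
    converged: bool
    residual: float
    iterations: int = 0
    electrode_potential: float = 0.0  # mV, as applied
    meta: dict = _dfield(default_factory=dict)

    @property
    def z_max(self) -> float:
        return float(self.z_grid[-1])


def ion_charge_density(
    psi_star,
    electrolyte: ElectrolyteModel,
    inside_layer=False,
):
    """Mobile-ion charge density (C/m^3) at dimensionless potential psi_star.

    Symmetric Borukhov form; odd in psi_star; zero where ``inside_layer`` is
    true (ion exclusion from the film).  The denominator
    ``1 + nu (cosh u - 1)`` is >= 1 for nu in [0, 1], so the expression is
    well defined everywhere and saturates instead of diverging for large u.
    """
    u = np.asarray(psi_star, dtype=float)
    nu = electrolyte.steric_nu
    # cosh/sinh overflow past ~710; the ratio saturates, so clip the argument.
    uc = np.clip(u, -700.0, 700.0)
    denom = 1.0 + nu * (np.cosh(uc) - 1.0)
    # divide first: sinh/denom is bounded (by 1/nu for nu > 0)
    rho = -2.0 * _E * electrolyte.n_bulk * (np.sinh(uc) / denom)
    rho = np.where(np.asarray(inside_layer, dtype=bool), 0.0, rho)
    if np.isscalar(psi_star) and np.isscalar(inside_layer):
        return float(rho)
    return rho


def _dimensionless_source(
    layer: LayerModel, electrolyte: ElectrolyteModel, z_nm: np.ndarray
):
    """Fixed-charge source term q(z) = -rho_DNA / (2 e n_bulk) on the grid."""
    rho = fixed_charge_density(z_nm, layer, electrolyte)
    return -rho / (2.0 * _E * electrolyte.n_bulk)


def _newton_solve(
    u: np.ndarray,
    h: float,
    q: np.ndarray,
    ion_mask: np.ndarray,
    nu: float,
    u0: float,
    settings: SolverSettings,
    source_scale: float = 1.0,
):
    """Damped Newton on the FD residual; returns (u, residual, iters, ok)."""
    n = u.size

    def ion_term(uv):
        uc = np.clip(uv, -700.0, 700.0)
        denom = 1.0 + nu * (np.cosh(uc) - 1.0)
        return np.sinh(uc) / denom

    def ion_term_d(uv):
        uc = np.clip(uv, -700.0, 700.0)
        ch, sh = np.cosh(uc), np.sinh(uc)
        denom = 1.0 + nu * (ch - 1.0)
        return (ch * denom - sh * nu * sh) / denom**2

    # interior rows are scaled by h^2 (u_{i-1} - 2u_i + u_{i+1} - h^2 g_i)
    # so all residual entries live on the potential-update scale and the
    # max-norm tolerance is attainable down to machine precision.
    def residual(uv):
        g = ion_mask * ion_term(uv) + source_scale * q
        r = np.empty(n)
        r[0] = uv[0] - u0
        r[1:-1] = uv[2:] - 2.0 * uv[1:-1] + uv[:-2] - h**2 * g[1:-1]
        # reflected-ghost Neumann closure (second order, zero slope)
        r[-1] = 2.0 * (uv[-2] - uv[-1]) - h**2 * g[-1]
        return r

    r = residual(u)
    res = float(np.max(np.abs(r)))
    ab = np.zeros((3, n))
    for it in range(1, settings.max_iterations + 1):
        if res < settings.residual_tol:
            return u, res, it - 1, True
        dg = ion_mask * ion_term_d(u)
        # banded Jacobian: rows are (upper, diag, lower)
        ab[0, 1:] = 1.0
        ab[1, :] = -2.0 - h**2 * dg
        ab[2, :-1] = 1.0
        # Dirichlet row at 0
        ab[1, 0] = 1.0
        ab[0, 1] = 0.0
        # Neumann row at n-1: 2(u[n-2] - u[n-1]) - h^2 g
        ab[1, -1] = -2.0 - h**2 * dg[-1]
        ab[2, -2] = 2.0
        try:
            du = solve_banded((1, 1), ab, -r)
        except np.linalg.LinAlgError:  # pragma: no cover - defensive
            return u, res, it, False
        step = settings.damping
        for _ in range(40):
            u_try = u + step * du
            r_try = residual(u_try)
            res_try = float(np.max(np.abs(r_try)))
            if res_try < res:
                break
            step *= 0.5
        else:
            return u, res, it, False
        u, r, res = u_try, r_try, res_try
    return u, res, settings.max_iterations, res < settings.residual_tol


def solve_pbe(
    layer: LayerModel,
    electrolyte: ElectrolyteModel,
    electrode_potential: float,
    settings: SolverSettings | None = None,
    strict: bool = False,
) -> PotentialProfile:
    """Solve the modified PB problem for an applied electrode potential (mV).

    Returns a :class:`PotentialProfile` with the potential, its dimensionless
    form and the field ``E = -dpsi/dz`` (positive pointing from electrode
    into solution).  Non-convergence sets ``converged=False``; with
    ``strict=True`` it raises :class:`ConvergenceError` instead.
    """
    if settings is None:
        settings = SolverSettings()
    if abs(electrode_potential) > 1000:
        raise InvalidParameterError(
            f"|electrode_potential| must be <= 1000 mV, got {electrode_potential}"
        )
    lam = electrolyte.debye_length  # nm
    z_max = layer.total_height + settings.domain_pad * lam
    n = int(np.ceil(z_max / settings.grid_spacing)) + 1
    z = np.linspace(0.0, (n - 1) * settings.grid_spacing, n)
    h = settings.grid_spacing / lam  # dimensionless spacing

    u0 = (electrode_potential * 1e-3) / electrolyte.thermal_voltage
    q = _dimensionless_source(layer, electrolyte, z)
    inside = z < layer.total_height
    ion_mask = np.where(layer.exclude_ions & inside, 0.0, 1.0)
    nu = electrolyte.steric_nu

    u = u0 * np.exp(-z / lam)  # Debye-Hueckel initial guess
    u, res, iters, ok = _newton_solve(u, h, q, ion_mask, nu, u0, settings)
    if not ok:
        # continuation: ramp the fixed-charge source up in stages; the last
        # stage always runs at full strength so the returned profile solves
        # the intended problem (or is flagged unconverged).
        log.info("direct Newton stalled (residual %.3e); ramping source", res)
        u = u0 * np.exp(-z / lam)
        total_iters = 0
        for scale in (0.25, 0.5, 0.75, 1.0):
            u, res, it, ok = _newton_solve(
                u, h, q, ion_mask, nu, u0, settings, source_scale=scale
            )
            total_iters += it
        iters = total_iters

    # back to physical units
    kT_e = electrolyte.thermal_voltage  # V
    psi = u * kT_e * 1e3  # mV
    psi_v = u * kT_e  # V
    efield = np.empty_like(psi_v)
    efield[1:-1] = -(psi_v[2:] - psi_v[:-2]) / (2.0 * settings.grid_spacing)
    # second-order one-sided differences at the ends
    efield[0] = -(-3.0 * psi_v[0] + 4.0 * psi_v[1] - psi_v[2]) / (
        2.0 * settings.grid_spacing
    )
    efield[-1] = -(3.0 * psi_v[-1] - 4.0 * psi_v[-2] + psi_v[-3]) / (
        2.0 * settings.grid_spacing
    )

    profile = PotentialProfile(
        z_grid=z,
        psi=psi,
        psi_star=u,
        field=efield,
        converged=bool(ok),
        residual=float(res),
        iterations=int(iters),
        electrode_potential=float(electrode_potential),
        meta={
            "lambda_D_nm": lam,
            "nu": nu,
            "sigma_cm2": layer.grafting_density,
            "c_bulk_M": electrolyte.c_bulk,
            "temperature_K": electrolyte.temperature,
            "exclude_ions": layer.exclude_ions,
            "grid_spacing_nm": settings.grid_spacing,
        },
    )
    log.info(
        "PBE solve: psi0=%.1f mV sigma=%.2e cm^-2 -> %d iterations, residual %.2e",
        electrode_potential,
        layer.grafting_density,
        iters,
        res,
    )
    if strict and not ok:
        raise ConvergenceError(
            f"PBE solve did not converge: residual {res:.3e} after {iters} iterations"
        )
    return profile


def electric_field_at(profile: PotentialProfile, z: float) -> float:
    """Field E(z) in V/nm by linear interpolation on the solved grid."""
    z_arr = profile.z_grid
    if z < z_arr[0] or z > z_arr[-1]:
        raise DomainError(
            f"z = {z} nm outside the solved domain [0, {z_arr[-1]:.3f}] nm"
        )
    return float(np.interp(z, z_arr, profile.field))


def gauss_law_field_change(
    layer: LayerModel,
    electrolyte: ElectrolyteModel,
    z_low: float,
    z_high: float,
) -> float:
    """Analytic |Delta E| across an ion-free slab from Gauss's law, V/nm.

    The field change across a region containing only fixed charge equals the
    enclosed charge per area over eps_r eps0; used as an independent check on
    the numerical solution.
    """
    zg = np.linspace(z_low, z_high, 20001)
    rho = fixed_charge_density(zg, layer, electrolyte)
    enclosed = np.trapezoid(rho, zg * _NM)  # C/m^2
    return abs(enclosed / (electrolyte.epsilon_r * _EPS0)) * _NM


def gouy_chapman_potential(z_nm, psi0_mV: float, electrolyte: ElectrolyteModel):
    """Closed-form Gouy-Chapman psi(z) in mV for a bare 1:1 interface.

    Analytic oracle for the nu = 0, no-fixed-charge limit:
    u(x) = 4 artanh(tanh(u0/4) exp(-x)), x = z/lambda_D.
    """
    kT_e = electrolyte.thermal_voltage
    u0 = psi0_mV * 1e-3 / kT_e
    x = np.asarray(z_nm, dtype=float) / electrolyte.debye_length
    g = np.tanh(u0 / 4.0) * np.exp(-x)
    return 4.0 * np.arctanh(g) * kT_e * 1e3
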