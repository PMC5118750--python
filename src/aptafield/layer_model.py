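"""Physical model of an electrode-grafted DNA aptamer film in electrolyte.

The film is a thrombin-binding-aptamer (TBA) construct tethered to a gold
electrode: a charge-neutral thiol anchor, a single-stranded linker tail, and
the compact G-quadruplex aptamer head.  At brush-like grafting densities the
strands are treated as stretched rods, so the backbone phosphate charge
becomes a piecewise-constant volumetric density in the coordinate ``z``
normal to the electrode:

* ``[0, thiol_height)`` — neutral thiol sub-layer, zero charge;
* the linker band — ``N_linker`` bases smeared over ``linker_height``;
* the head band — ``N_head`` bases smeared over ``head_height``;
* beyond the film — zero fixed charge.

Counterion condensation (Manning) renormalises the bare backbone charge by
the charging fraction ``f = b / l_B`` where ``b`` is the axial spacing per
phosphate and ``l_B`` the Bjerrum length of the solvent; ``f`` is capped at 1
when ``b >= l_B`` (no condensation).

All lengths at the API surface are nanometres; charge densities are SI
(C/m^3).  Grafting density is quoted per cm^2, as is conventional for
surface-immobilised DNA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import constants as _const

from .errors import DomainError, InvalidParameterError

__all__ = [
    "ElectrolyteModel",
    "LayerModel",
    "bjerrum_length",
    "debye_length",
    "manning_fraction",
    "fixed_charge_density",
    "condensed_variant",
]

_E = _const.elementary_charge  # C
_KB = _const.Boltzmann  # J/K
_EPS0 = _const.epsilon_0  # F/m
_NA = _const.Avogadro
_NM = 1e-9


def bjerrum_length(epsilon_r: float, temperature: float) -> float:
    """Bjerrum length l_B = e^2 / (4 pi eps0 eps_r k_B T), in nm.

    The distance at which two unit charges in the solvent interact with
    energy k_B T.  For water (eps_r = 78.5) at 300 K this is ~0.71 nm.
    """
    if epsilon_r <= 0:
        raise InvalidParameterError(f"epsilon_r must be > 0, got {epsilon_r}")
    if temperature <= 0:
        raise InvalidParameterError(f"temperature must be > 0, got {temperature}")
    lb_m = _E**2 / (4 * math.pi * _EPS0 * epsilon_r * _KB * temperature)
    return lb_m / _NM


def manning_fraction(charge_spacing: float, bjerrum_len: float) -> float:
    """Manning charging fraction f = b / l_B, capped at 1.

    For a line charge with axial spacing ``b`` per unit charge below the
    Bjerrum length, counterions condense until the effective spacing equals
    l_B, leaving a fraction b/l_B of the bare charge.  For b >= l_B no
    condensation occurs and the strand keeps its full charge (f = 1).
    """
    if charge_spacing <= 0:
        raise InvalidParameterError(f"charge_spacing must be > 0, got {charge_spacing}")
    if bjerrum_len <= 0:
        raise InvalidParameterError(f"bjerrum_length must be > 0, got {bjerrum_len}")
    return min(charge_spacing / bjerrum_len, 1.0)


@dataclass(frozen=True)
class ElectrolyteModel:
    """Symmetric 1:1 electrolyte context.

    Parameters
    ----------
    c_bulk : float
        Bulk salt concentration in mol/L.
    temperature : float
        Absolute temperature in K.
    epsilon_r : float
        Relative permittivity of the solvent (78.5 for water near 300 K).
    ion_radius : float
        Effective (hydrated) ion radius in nm entering the Borukhov steric
        parameter ``nu = 2 n_bulk a^3``; 0 recovers point ions.
    """

    c_bulk: float = 0.1
    temperature: float = 300.0
    epsilon_r: float = 78.5
    ion_radius: float = 1.96

    def __post_init__(self) -> None:
        if self.c_bulk <= 0:
            raise InvalidParameterError(f"c_bulk must be > 0, got {self.c_bulk}")
        if self.temperature <= 0:
            raise InvalidParameterError(
                f"temperature must be > 0, got {self.temperature}"
            )
        if self.epsilon_r <= 0:
            raise InvalidParameterError(f"epsilon_r must be > 0, got {self.epsilon_r}")
        if self.ion_radius < 0:
            raise InvalidParameterError(
                f"ion_radius must be >= 0, got {self.ion_radius}"
            )

    @property
    def n_bulk(self) -> float:
        """Bulk number density of each ion species, per m^3."""
        return self.c_bulk * 1000.0 * _NA

    @property
    def bjerrum_length(self) -> float:
        """Bjerrum length in nm."""
        return bjerrum_length(self.epsilon_r, self.temperature)

    @property
    def debye_length(self) -> float:
        """Debye screening length lambda_D = (8 pi l_B n_bulk)^(-1/2), in nm."""
        lb_m = self.bjerrum_length * _NM
        lam_m = 1.0 / math.sqrt(8.0 * math.pi * lb_m * self.n_bulk)
        return lam_m / _NM

    @property
    def steric_nu(self) -> float:
        """Borukhov packing fraction nu = 2 n_bulk a^3 (dimensionless)."""
        return 2.0 * self.n_bulk * (self.ion_radius * _NM) ** 3

    @property
    def thermal_voltage(self) -> float:
        """k_B T / e in volts; the scale of the dimensionless potential."""
        return _KB * self.temperature / _E


def debye_length(electrolyte: ElectrolyteModel) -> float:
    """Debye length of the electrolyte in nm (see :class:`ElectrolyteModel`)."""
    return electrolyte.debye_length


@dataclass(frozen=True)
class LayerModel:
    """Geometry and charge content of the grafted film.

    Default geometry is the 50-base TBA construct: 1 nm neutral thiol,
    35-base linker stretched over 14 nm (0.4 nm per base) and the 15-base
    G-quadruplex head over its 1.6 nm axial length, 16.6 nm in total.
    """

    thiol_height: float = 1.0
    linker_bases: int = 35
    linker_height: float = 14.0
    head_bases: int = 15
    head_height: float = 1.6
    charge_spacing: float = 0.4
    grafting_density: float = 1e12  # strands per cm^2
    charging_fraction: float | None = None  # None -> computed from electrolyte
    exclude_ions: bool = True

    def __post_init__(self) -> None:
        for name in ("thiol_height", "linker_height", "head_height"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.total_height <= 0:
            raise InvalidParameterError("total layer height must be > 0")
        if self.linker_bases < 0 or self.head_bases < 0:
            raise InvalidParameterError("base counts must be >= 0")
        if self.linker_bases > 0 and self.linker_height <= 0:
            raise InvalidParameterError("charged linker band needs a positive height")
        if self.head_bases > 0 and self.head_height <= 0:
            raise InvalidParameterError("charged head band needs a positive height")
        if self.charge_spacing <= 0:
            raise InvalidParameterError("charge_spacing must be > 0")
        if self.grafting_density < 0:
            raise InvalidParameterError("grafting_density must be >= 0")
        if self.charging_fraction is not None and not (0 < self.charging_fraction <= 1):
            raise InvalidParameterError("charging_fraction must be in (0, 1]")

    @property
    def total_height(self) -> float:
        return self.thiol_height + self.linker_height + self.head_height

    @property
    def linker_top(self) -> float:
        return self.thiol_height + self.linker_height

    @property
    def sigma_m2(self) -> float:
        """Grafting density in strands per m^2."""
        return self.grafting_density * 1e4

    def fraction(self, electrolyte: ElectrolyteModel | None = None) -> float:
        """Charging fraction f: explicit override, else Manning b/l_B."""
        if self.charging_fraction is not None:
            return self.charging_fraction
        elec = electrolyte if electrolyte is not None else ElectrolyteModel()
        return manning_fraction(self.charge_spacing, elec.bjerrum_length)

    @classmethod
    def aptamer_only(cls, **kwargs) -> "LayerModel":
        """15-mer-head-only geometry: no linker band, total 2.6 nm."""
        kwargs.setdefault("linker_bases", 0)
        kwargs.setdefault("linker_height", 0.0)
        return cls(**kwargs)

    def band_charge_densities(
        self, electrolyte: ElectrolyteModel | None = None
    ) -> tuple[float, float]:
        """Volumetric fixed charge (C/m^3) of (linker band, head band)."""
        f = self.fraction(electrolyte)
        rho_linker = (
            -_E * f * self.linker_bases * self.sigma_m2 / (self.linker_height * _NM)
            if self.linker_bases > 0 and self.linker_height > 0
            else 0.0
        )
        rho_head = (
            -_E * f * self.head_bases * self.sigma_m2 / (self.head_height * _NM)
            if self.head_bases > 0 and self.head_height > 0
            else 0.0
        )
        return rho_linker, rho_head

    def total_surface_charge(self, electrolyte: ElectrolyteModel | None = None) -> float:
        """Integrated fixed charge per unit area (C/m^2); negative."""
        f = self.fraction(electrolyte)
        return -_E * f * (self.linker_bases + self.head_bases) * self.sigma_m2


def fixed_charge_density(
    z,
    layer: LayerModel,
    electrolyte: ElectrolyteModel | None = None,
):
    """Piecewise-constant backbone charge density rho_DNA(z) in C/m^3.

    Band edges are half-open ``[low, high)``: a coordinate exactly on an
    interior edge takes the density of the band that starts there, and the
    film top (z = total_height) is already outside.  Accepts scalars or
    arrays; ``z`` is in nm and must be >= 0.
    """
    z_arr = np.asarray(z, dtype=float)
    if np.any(z_arr < 0):
        raise DomainError("z must be >= 0 (electrode surface is z = 0)")
    rho_linker, rho_head = layer.band_charge_densities(electrolyte)
    rho = np.zeros_like(z_arr)
    rho = np.where(
        (z_arr >= layer.thiol_height) & (z_arr < layer.linker_top), rho_linker, rho
    )
    rho = np.where(
        (z_arr >= layer.linker_top) & (z_arr < layer.total_height), rho_head, rho
    )
    if np.isscalar(z) or z_arr.ndim == 0:
        return float(rho)
    return rho


def condensed_variant(layer: LayerModel, new_linker_height: float) -> LayerModel:
    """Compress the linker band to ``new_linker_height``, conserving charge.

    Models condensation/folding of the single-stranded tail onto itself: the
    same linker bases occupy a shorter band, so the band's volumetric charge
    density rises by the compression ratio while the head band (geometry
    unchanged) shifts down with the linker top.
    """
    if new_linker_height <= 0:
        raise InvalidParameterError(
            "new_linker_height must be > 0; build the head-only geometry via "
            "LayerModel.aptamer_only() instead"
        )
    if new_linker_height > layer.linker_height:
        raise InvalidParameterError(
            f"new_linker_height {new_linker_height} exceeds the original "
            f"{layer.linker_height}"
        )
    return replace(layer, linker_height=new_linker_height)
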