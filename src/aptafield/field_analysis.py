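"""Field diagnostics over the solved profiles: sweeps, changes, sign structure.

The quantities of interest for aptamer actuation are read off the solved
potential profile at named positions of the film: the top of the neutral
thiol band, the bottom of the aptamer head and the top of the layer.  A
positive field at the head repels the positively charged thrombin protein
(unbinding); a negative field attracts it.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import replace

import pandas as pd

from .errors import DomainError
from .layer_model import ElectrolyteModel, LayerModel, condensed_variant
from .pbe_solver import PotentialProfile, SolverSettings, electric_field_at, solve_pbe

__all__ = ["field_change", "sweep", "condensation_trend", "head_field_sign"]

#: tiny fields are classified as zero-sign to avoid labelling numerical noise
_SIGN_EPS = 1e-12


def field_change(profile: PotentialProfile, z_low: float, z_high: float) -> float:
    """|E(z_high) - E(z_low)| in V/nm."""
    if z_low >= z_high:
        raise DomainError(f"need z_low < z_high, got {z_low} >= {z_high}")
    return abs(electric_field_at(profile, z_high) - electric_field_at(profile, z_low))


def head_field_sign(e_min: float, e_max: float) -> str:
    """Classify a field region from its extreme values.

    'positive' / 'negative' when the whole range shares that sign, 'mixed'
    when the field changes sign within the region.  In sweeps the region is
    the charged film (thiol top to layer top): at high grafting density and
    strong positive bias the field switches sign inside the layer, while at
    low density it stays positive throughout for positive potentials.
    """
    if e_min > _SIGN_EPS and e_max > _SIGN_EPS:
        return "positive"
    if e_min < -_SIGN_EPS and e_max < -_SIGN_EPS:
        return "negative"
    return "mixed"


def _profile_row(
    layer: LayerModel,
    electrolyte: ElectrolyteModel,
    potential: float,
    settings: SolverSettings,
    strict: bool,
):
    profile = solve_pbe(layer, electrolyte, potential, settings, strict=strict)
    e_thiol = electric_field_at(profile, layer.thiol_height)
    e_head_bot = electric_field_at(profile, layer.linker_top)
    e_top = electric_field_at(profile, layer.total_height)
    in_film = (profile.z_grid >= layer.thiol_height) & (
        profile.z_grid <= layer.total_height
    )
    film_field = profile.field[in_film]
    return profile, {
        "grafting_density": layer.grafting_density,
        "electrode_potential": potential,
        "field_at_thiol_top": e_thiol,
        "field_at_head_bottom": e_head_bot,
        "field_at_layer_top": e_top,
        "field_change_full_layer": abs(e_top - e_thiol),
        "field_change_head": abs(e_top - e_head_bot),
        "head_field_sign": head_field_sign(
            float(film_field.min()), float(film_field.max())
        ),
        "converged": profile.converged,
    }


def sweep(
    layer: LayerModel,
    electrolyte: ElectrolyteModel,
    potentials: Sequence[float],
    densities: Sequence[float],
    settings: SolverSettings | None = None,
    strict: bool = False,
    return_profiles: bool = False,
):
    """Solve over the (grafting density, electrode potential) grid.

    Returns a DataFrame with one row per combination: the field (V/nm) at
    the thiol top, head bottom and layer top, the field changes across the
    full layer and the head band, and the sign classification of the head
    field.  Deterministic; row order follows the input lists.
    """
    if len(potentials) == 0 or len(densities) == 0:
        raise ValueError("potentials and densities must be non-empty")
    if settings is None:
        settings = SolverSettings()
    rows = []
    profiles = {}
    for density in densities:
        lay = replace(layer, grafting_density=density)
        for pot in potentials:
            profile, row = _profile_row(lay, electrolyte, pot, settings, strict)
            rows.append(row)
            if return_profiles:
                profiles[(density, pot)] = profile
    df = pd.DataFrame(rows)
    if return_profiles:
        return df, profiles
    return df


def condensation_trend(
    layer: LayerModel,
    electrolyte: ElectrolyteModel,
    potential: float,
    linker_heights: Sequence[float],
    settings: SolverSettings | None = None,
    strict: bool = False,
) -> pd.DataFrame:
    """Top-of-layer field as the linker tail condenses to shorter heights.

    Each entry compresses the same linker charge into a shorter band
    (charge-conserving) and re-solves; for positive electrode potentials the
    field at the (now lower) layer top becomes increasingly positive as the
    linker shortens.
    """
    if settings is None:
        settings = SolverSettings()
    rows = []
    for h in linker_heights:
        lay = layer if h == layer.linker_height else condensed_variant(layer, h)
        profile = solve_pbe(lay, electrolyte, potential, settings, strict=strict)
        rows.append(
            {
                "linker_height": h,
                "total_height": lay.total_height,
                "field_at_layer_top": electric_field_at(profile, lay.total_height),
            }
        )
    return pd.DataFrame(rows)
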