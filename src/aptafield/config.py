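"""Flat key/value run configuration with validation and overrides.

A config file is plain text, one ``key = value`` per line, '#' comments.
Unknown keys are rejected by name.  Defaults are the standard study
conditions: 0.1 M 1:1 salt at 300 K, water permittivity 78.5, and the
1 + 14 + 1.6 nm thiol/linker/head geometry with 0.4 nm charge spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigError
from .layer_model import ElectrolyteModel, InvalidParameterError, LayerModel
from .pbe_solver import SolverSettings

__all__ = ["RunConfig", "load_config", "DEFAULTS"]

SCHEMA_VERSION = "1"


def _to_bool(s: str) -> bool:
    v = str(s).strip().lower()
    if v in {"true", "1", "yes", "on"}:
        return True
    if v in {"false", "0", "no", "off"}:
        return False
    raise ValueError(f"not a boolean: {s!r}")


# key -> (coercion, default)
DEFAULTS: dict[str, tuple] = {
    "c_bulk_M": (float, 0.1),
    "temperature_K": (float, 300.0),
    "epsilon_r": (float, 78.5),
    "ion_radius_nm": (float, 1.96),
    "thiol_h_nm": (float, 1.0),
    "linker_bases": (int, 35),
    "linker_h_nm": (float, 14.0),
    "head_bases": (int, 15),
    "head_h_nm": (float, 1.6),
    "charge_spacing_nm": (float, 0.4),
    "grafting_density_cm2": (float, 1e12),
    "exclude_ions": (_to_bool, True),
    # solver
    "grid_spacing_nm": (float, 0.005),
    "domain_pad": (float, 10.0),
    "residual_tol": (float, 1e-10),
    "max_iterations": (int, 200),
    "damping": (float, 1.0),
    # WHAM / generator
    "n_bins": (int, 100),
    "wham_tolerance_kJ_mol": (float, 2.494e-8),
    "wham_max_iterations": (int, 100_000),
    "n_windows": (int, 42),
    "force_constant_kJ_mol_nm2": (float, 1000.0),
    "samples_per_window": (int, 5000),
}


@dataclass
class RunConfig:
    """Validated, merged parameter set with provenance."""

    values: dict
    provenance: dict = field(default_factory=dict)
    schema_version: str = SCHEMA_VERSION

    def __getitem__(self, key: str):
        return self.values[key]

    def electrolyte(self) -> ElectrolyteModel:
        v = self.values
        return ElectrolyteModel(
            c_bulk=v["c_bulk_M"], temperature=v["temperature_K"],
            epsilon_r=v["epsilon_r"], ion_radius=v["ion_radius_nm"],
        )

    def layer(self) -> LayerModel:
        v = self.values
        return LayerModel(
            thiol_height=v["thiol_h_nm"], linker_bases=v["linker_bases"],
            linker_height=v["linker_h_nm"], head_bases=v["head_bases"],
            head_height=v["head_h_nm"], charge_spacing=v["charge_spacing_nm"],
            grafting_density=v["grafting_density_cm2"],
            exclude_ions=v["exclude_ions"],
        )

    def solver_settings(self) -> SolverSettings:
        v = self.values
        return SolverSettings(
            grid_spacing=v["grid_spacing_nm"], domain_pad=v["domain_pad"],
            residual_tol=v["residual_tol"], max_iterations=v["max_iterations"],
            damping=v["damping"],
        )


def _parse_kv_lines(lines, source: str) -> dict:
    out = {}
    for ln, raw in enumerate(lines, 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{source}:{ln}: expected 'key = value', got {raw!r}")
        key, _, val = line.partition("=")
        out[key.strip()] = val.strip()
    return out


def load_config(
    path: str | Path | None = None,
    overrides: list[str] | dict | None = None,
) -> RunConfig:
    """Load defaults, then the file, then ``key=value`` overrides (which win).

    Raises :class:`ConfigError` naming the offending key for unknown keys,
    unparseable values or out-of-range parameters.
    """
    values = {k: d for k, (_, d) in DEFAULTS.items()}
    provenance: dict = {"file": str(path) if path else None, "overrides": {}}

    raw: dict[str, str] = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        raw.update(_parse_kv_lines(p.read_text().splitlines(), str(p)))
    if overrides:
        if isinstance(overrides, dict):
            items = {str(k): str(v) for k, v in overrides.items()}
        else:
            items = _parse_kv_lines(list(overrides), "<override>")
        raw.update(items)
        provenance["overrides"] = items

    for key, sval in raw.items():
        if key not in DEFAULTS:
            raise ConfigError(f"unknown configuration key: {key!r}")
        coerce, _ = DEFAULTS[key]
        try:
            values[key] = coerce(sval)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid value for {key!r}: {sval!r} ({exc})") from exc

    cfg = RunConfig(values=values, provenance=provenance)
    # construct the models once so range violations surface at load time
    try:
        cfg.electrolyte()
        cfg.layer()
        cfg.solver_settings()
    except InvalidParameterError as exc:
        raise ConfigError(f"out-of-range configuration value: {exc}") from exc
    return cfg
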