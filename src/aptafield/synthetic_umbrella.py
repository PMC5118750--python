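"""Synthetic umbrella-sampling data from a known analytic free-energy profile.

Stands in for biased molecular-dynamics trajectories: for a chosen "true"
PMF U(ξ) along the pulling coordinate, each window's samples are exact
i.i.d. draws from the biased Boltzmann density

    p_i(ξ) ∝ exp(−(U(ξ) + ½ k (ξ − ξ_i)²) / k_B T),

drawn by inverse-CDF lookup on a fine tabulation.  Because the samples are
exact and independent, estimator tests against the analytic U are sharp:
any discrepancy is attributable to the estimator (binning, WHAM iteration),
not to sampling dynamics.  What this deliberately does NOT emulate:
autocorrelation along a trajectory, equilibration transients, anharmonic
restraint artefacts or pulling hysteresis.  A Langevin-chain sampler is
provided for generating autocorrelated series where a correlated-input code
path (e.g. block bootstrap) needs exercising.

Defaults mirror a 42-window study with a 1000 kJ/mol/nm² restraint, windows
spaced uniformly over 1.2–4.0 nm of centre-of-mass separation, and a bound
well of ~20 k_BT rising to a flat unbound plateau — the shape and scale of
a protein unbinding from a surface-tethered aptamer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as _dfield
from pathlib import Path

import numpy as np

from .errors import GenerationError, InvalidParameterError
from .umbrella_wham import UmbrellaWindow, kBT

__all__ = ["TruePMF", "GeneratorConfig", "sample_window", "generate_windows",
           "generate_study", "langevin_window"]


@dataclass(frozen=True)
class TruePMF:
    """Analytic reference free-energy profile U(ξ) tabulated on a grid.

    ``values`` are kJ/mol on ``grid`` (nm); evaluation interpolates
    linearly.  Constructors: :meth:`harmonic`, :meth:`double_well`,
    :meth:`morse_like`, :meth:`tabulated`.
    """

    kind: str
    parameters: dict
    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if grid.size != values.size or grid.size < 2:
            raise InvalidParameterError("grid and values must match, length >= 2")
        if not np.all(np.isfinite(values)):
            raise InvalidParameterError("true PMF must be finite on its grid")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", values)

    def __call__(self, xi):
        return np.interp(np.asarray(xi, dtype=float), self.grid, self.values)

    def well_depth(self) -> float:
        """Plateau level minus global minimum, kJ/mol (the true binding ΔG)."""
        plateau = float(np.mean(self.values[-max(2, self.grid.size // 20):]))
        return plateau - float(np.min(self.values))

    def well_position(self) -> float:
        return float(self.grid[np.argmin(self.values)])

    # -- constructors ------------------------------------------------------

    @classmethod
    def harmonic(cls, kappa: float = 200.0, center: float = 0.0,
                 span: float = 1.5, n_grid: int = 10_001) -> "TruePMF":
        """U = ½ κ (ξ − c)², κ in kJ/mol/nm²."""
        grid = np.linspace(center - span, center + span, n_grid)
        return cls("harmonic", {"kappa": kappa, "center": center},
                   grid, 0.5 * kappa * (grid - center) ** 2)

    @classmethod
    def double_well(cls, depth_kBT: float = 20.0, depth2_kBT: float = 8.0,
                    pos1: float = 1.6, pos2: float = 2.4,
                    width1: float = 0.15, width2: float = 0.2,
                    temperature: float = 300.0,
                    grid_range: tuple[float, float] = (1.0, 4.2),
                    n_grid: int = 10_001) -> "TruePMF":
        """Primary bound well plus a shallower intermediate, flat plateau at 0.

        Depths are in k_BT at ``temperature``; the deeper well sits at
        ``pos1``.  Emulates a binding PMF with a metastable partially-bound
        state along the unbinding path.
        """
        kT = kBT(temperature)
        grid = np.linspace(*grid_range, n_grid)
        u = (-depth_kBT * kT * np.exp(-((grid - pos1) ** 2) / (2 * width1**2))
             - depth2_kBT * kT * np.exp(-((grid - pos2) ** 2) / (2 * width2**2)))
        return cls("double_well",
                   {"depth_kBT": depth_kBT, "depth2_kBT": depth2_kBT,
                    "pos1": pos1, "pos2": pos2, "temperature": temperature},
                   grid, u)

    @classmethod
    def morse_like(cls, depth_kBT: float = 20.0, position: float = 1.6,
                   steepness: float = 2.5, temperature: float = 300.0,
                   grid_range: tuple[float, float] = (1.0, 4.2),
                   n_grid: int = 10_001) -> "TruePMF":
        """Single Morse well of given depth (k_BT) rising to a flat plateau."""
        kT = kBT(temperature)
        grid = np.linspace(*grid_range, n_grid)
        x = np.clip(steepness * (grid - position), -60.0, 60.0)
        u = depth_kBT * kT * ((1.0 - np.exp(-x)) ** 2 - 1.0)
        return cls("morse_like",
                   {"depth_kBT": depth_kBT, "position": position,
                    "steepness": steepness, "temperature": temperature},
                   grid, u)

    @classmethod
    def tabulated(cls, grid, values) -> "TruePMF":
        return cls("tabulated", {}, np.asarray(grid), np.asarray(values))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study layout mirroring the umbrella-sampling protocol it emulates."""

    n_windows: int = 42
    window_range: tuple[float, float] = (1.2, 4.0)
    force_constant: float = 1000.0  # kJ/mol/nm^2
    samples_per_window: int = 5000
    temperature: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_windows < 1 or self.samples_per_window < 1:
            raise InvalidParameterError("window and sample counts must be >= 1")
        if self.force_constant < 0:
            raise InvalidParameterError("force_constant must be >= 0")
        if self.window_range[0] >= self.window_range[1] and self.n_windows > 1:
            raise InvalidParameterError("window_range must be increasing")

    @property
    def centers(self) -> np.ndarray:
        if self.n_windows == 1:
            return np.array([0.5 * sum(self.window_range)])
        return np.linspace(*self.window_range, self.n_windows)


def _biased_cdf(true_pmf: TruePMF, center: float, force_constant: float,
                temperature: float):
    """Grid, pdf and CDF of the biased density on the PMF's tabulation grid."""
    grid = true_pmf.grid
    kT = kBT(temperature)
    energy = true_pmf.values + 0.5 * force_constant * (grid - center) ** 2
    w = np.exp(-(energy - energy.min()) / kT)
    # trapezoid cumulative integral
    dz = np.diff(grid)
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * dz)])
    total = cum[-1]
    if not np.isfinite(total) or total <= 0:
        raise GenerationError(
            f"biased density has zero weight on the grid (window at {center} nm)"
        )
    cdf = cum / total
    # a bias pulling the density off the tabulated range piles probability
    # onto a grid edge; reject rather than return clipped samples
    span = grid[-1] - grid[0]
    lo_mass = float(np.interp(grid[0] + 0.01 * span, grid, cdf))
    hi_mass = 1.0 - float(np.interp(grid[-1] - 0.01 * span, grid, cdf))
    if max(lo_mass, hi_mass) > 0.5:
        raise GenerationError(
            f"window at {center} nm: bias concentrates the density at the "
            "edge of the tabulated grid"
        )
    return grid, w / total, cdf


def sample_window(
    true_pmf: TruePMF,
    center: float,
    force_constant: float,
    n: int,
    temperature: float = 300.0,
    seed: int | np.random.Generator = 0,
    label: str = "",
) -> UmbrellaWindow:
    """Draw n exact i.i.d. samples from the biased density of one window."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid, _, cdf = _biased_cdf(true_pmf, center, force_constant, temperature)
    u = rng.random(n)
    samples = np.interp(u, cdf, grid)
    return UmbrellaWindow(center=center, force_constant=force_constant,
                          samples=samples, label=label or f"w_{center:.3f}")


def langevin_window(
    true_pmf: TruePMF,
    center: float,
    force_constant: float,
    n: int,
    temperature: float = 300.0,
    seed: int | np.random.Generator = 0,
    step: float = 1e-3,
    friction_time: float = 1.0,
    label: str = "",
) -> UmbrellaWindow:
    """Overdamped-Langevin sampler producing autocorrelated window samples.

    Euler-Maruyama on the biased potential with unit mobility time scale;
    for exercising correlated-input code paths (block bootstrap), not for
    estimator accuracy tests.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kT = kBT(temperature)
    grid = true_pmf.grid
    dgrid = grid[1] - grid[0]
    grad = np.gradient(true_pmf.values, grid)
    diffusion = 1.0 / friction_time  # nm^2 per unit time, mobility D/kT
    dt = step
    noise_amp = np.sqrt(2.0 * diffusion * dt)
    xi = center
    out = np.empty(n)
    for i in range(n):
        force = np.interp(xi, grid, grad) + force_constant * (xi - center)
        xi = xi - (diffusion / kT) * force * dt + noise_amp * rng.standard_normal()
        xi = float(np.clip(xi, grid[0] + dgrid, grid[-1] - dgrid))
        out[i] = xi
    return UmbrellaWindow(center=center, force_constant=force_constant,
                          samples=out, label=label or f"lw_{center:.3f}")


def generate_windows(true_pmf: TruePMF, config: GeneratorConfig) -> list[UmbrellaWindow]:
    """In-memory study: one sampled window per configured centre.

    Per-window generators are spawned from the study seed, so the output is
    fully reproducible and windows are independent.
    """
    streams = np.random.SeedSequence(config.seed).spawn(config.n_windows)
    return [
        sample_window(
            true_pmf, float(c), config.force_constant,
            config.samples_per_window, config.temperature,
            np.random.default_rng(streams[i]), label=f"window_{i:02d}",
        )
        for i, c in enumerate(config.centers)
    ]


def generate_study(
    true_pmf: TruePMF,
    config: GeneratorConfig,
    out_dir: str | Path,
    time_step_ps: float = 1.0,
) -> dict:
    """Write a study to disk in the dialect the WHAM readers consume.

    Produces ``windows.tsv`` (label, center_nm, force_constant_kJ_mol_nm2,
    path) plus one two-column (time_ps, xi_nm) data file per window, and a
    JSON manifest describing the generation; returns the manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    windows = generate_windows(true_pmf, config)
    rows = ["label\tcenter_nm\tforce_constant_kJ_mol_nm2\tpath"]
    for i, w in enumerate(windows):
        fname = f"window_{i:02d}.dat"
        t = np.arange(w.samples.size) * time_step_ps
        header = (f"# synthetic umbrella window {i}: center={w.center:.6g} nm, "
                  f"k={w.force_constant:.6g} kJ/mol/nm^2\n"
                  "@ columns: time_ps coordinate_nm")
        np.savetxt(out_dir / fname, np.column_stack([t, w.samples]),
                   fmt="%.9g", header=header, comments="")
        rows.append(f"{w.label}\t{w.center:.9g}\t{w.force_constant:.9g}\t{fname}")
    (out_dir / "windows.tsv").write_text("\n".join(rows) + "\n")
    manifest = {
        "metadata_file": str(out_dir / "windows.tsv"),
        "n_windows": config.n_windows,
        "samples_per_window": config.samples_per_window,
        "force_constant_kJ_mol_nm2": config.force_constant,
        "temperature_K": config.temperature,
        "seed": config.seed,
        "true_pmf_kind": true_pmf.kind,
        "true_pmf_parameters": true_pmf.parameters,
        "true_well_depth_kJ_mol": true_pmf.well_depth(),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
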