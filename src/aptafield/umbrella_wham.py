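"""Umbrella-sampling free energies: WHAM, PMF, binding ΔG and bootstrap errors.

Umbrella sampling probes a reaction coordinate ξ (here the centre-of-mass
separation of a protein pulled off its surface-bound aptamer, reduced to a
1-D scalar) by running one biased simulation per *window*: window i adds a
harmonic restraint w_i(ξ) = ½ k_i (ξ − ξ_i)² and yields samples of the
biased density  p_i(ξ) ∝ exp(−(U(ξ) + w_i(ξ)) / k_B T).

The Weighted Histogram Analysis Method (WHAM) recombines the window
histograms into the unbiased probability P(ξ) by iterating the
self-consistent pair

    P_b  = Σ_i n_ib / Σ_j N_j exp((f_j − w_j(ξ_b)) / k_B T)
    f_i  = −k_B T ln Σ_b P_b exp(−w_i(ξ_b) / k_B T)

over histogram bins b, starting from f_i = 0 and anchoring f_1 = 0.  The
potential of mean force is PMF(ξ_b) = −k_B T ln P_b up to a constant; here
it is referenced to the mean over the unbound plateau so that the binding
free energy ΔG = PMF(plateau) − PMF(well minimum) is positive for a well.

Units: coordinates nm, force constants kJ/mol/nm², PMF kJ/mol, ΔG reported
in kcal/mol (1 kcal = 4.184 kJ).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as _dfield
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConvergenceError, EstimationError, InvalidParameterError

__all__ = [
    "UmbrellaWindow",
    "PMFProfile",
    "WHAMResult",
    "wham_solve",
    "delta_g_binding",
    "bootstrap_error",
    "read_windows",
    "boltzmann_inversion",
]

log = logging.getLogger(__name__)

KB_KJ = 0.008314462618  # kJ/mol/K
KJ_PER_KCAL = 4.184


def kBT(temperature: float) -> float:
    """Thermal energy in kJ/mol (2.494 kJ/mol at 300 K)."""
    return KB_KJ * temperature


@dataclass
class UmbrellaWindow:
    """One biased window: harmonic restraint centre, stiffness and samples."""

    center: float  # nm
    force_constant: float  # kJ/mol/nm^2
    samples: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.force_constant < 0:
            raise InvalidParameterError("force_constant must be >= 0")
        if self.samples is not None:
            self.samples = np.asarray(self.samples, dtype=float)
            if self.samples.size and not np.all(np.isfinite(self.samples)):
                raise InvalidParameterError(
                    f"window {self.label or self.center}: samples must be finite"
                )

    def bias(self, xi) -> np.ndarray:
        """Restraint energy w(ξ) = ½ k (ξ − ξ_c)² in kJ/mol."""
        xi = np.asarray(xi, dtype=float)
        return 0.5 * self.force_constant * (xi - self.center) ** 2


@dataclass
class PMFProfile:
    """Binned potential of mean force.

    ``pmf`` is in kJ/mol on ``bin_centers`` (nm); bins with zero occupancy
    are masked (NaN).  ``reference`` documents the zero point.
    """

    bin_centers: np.ndarray
    pmf: np.ndarray
    errors: np.ndarray | None = None
    reference: str = "minimum"
    n_bins: int = 0
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.pmf = np.asarray(self.pmf, dtype=float)
        if self.n_bins == 0:
            self.n_bins = self.bin_centers.size

    @property
    def occupied(self) -> np.ndarray:
        return np.isfinite(self.pmf)

    def in_kcal(self) -> np.ndarray:
        return self.pmf / KJ_PER_KCAL

    def in_kBT(self, temperature: float = 300.0) -> np.ndarray:
        return self.pmf / kBT(temperature)


@dataclass
class WHAMResult:
    pmf: PMFProfile
    window_free_energies: np.ndarray
    iterations: int
    converged: bool
    tolerance: float
    temperature: float = 300.0
    meta: dict = _dfield(default_factory=dict)


def _histograms(windows, n_bins, xi_range):
    edges = np.linspace(xi_range[0], xi_range[1], n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    total = np.zeros(n_bins)
    n_samples = np.zeros(len(windows))
    for i, w in enumerate(windows):
        if w.samples is None or w.samples.size == 0:
            continue
        counts, _ = np.histogram(w.samples, bins=edges)
        total += counts
        n_samples[i] = counts.sum()  # samples outside the range are dropped
    return centers, total, n_samples


def wham_solve(
    windows: list[UmbrellaWindow],
    n_bins: int = 100,
    xi_range: tuple[float, float] | None = None,
    temperature: float = 300.0,
    tolerance: float | None = None,
    max_iterations: int = 100_000,
    strict: bool = False,
) -> WHAMResult:
    """Self-consistent WHAM over the windows' histograms.

    Parameters
    ----------
    windows : biased windows with samples attached.
    n_bins : shared histogram bin count over ``xi_range``.
    xi_range : (lo, hi) in nm; defaults to the span of all samples.
    temperature : K.
    tolerance : convergence threshold on max |Δf_i| in kJ/mol; defaults to
        1e-8 k_B T.
    strict : raise :class:`ConvergenceError` instead of flagging.
    """
    windows = [w for w in windows if w.samples is not None and w.samples.size > 0]
    if not windows:
        raise EstimationError("no windows with samples")
    if n_bins < 2:
        raise InvalidParameterError("n_bins must be >= 2")
    kT = kBT(temperature)
    if tolerance is None:
        tolerance = 1e-8 * kT
    if xi_range is None:
        lo = min(float(np.min(w.samples)) for w in windows)
        hi = max(float(np.max(w.samples)) for w in windows)
        pad = 1e-9 * max(1.0, abs(hi))
        xi_range = (lo, hi + pad)

    centers, total_counts, n_samples = _histograms(windows, n_bins, xi_range)
    if total_counts.sum() == 0:
        raise EstimationError("all histogram bins are empty over the given range")

    beta = 1.0 / kT
    bias = np.stack([w.bias(centers) for w in windows])  # (S, B)
    log_a = -beta * bias
    active = n_samples > 0
    logn = np.where(active, np.log(np.maximum(n_samples, 1.0)), -np.inf)

    f = np.zeros(len(windows))  # kJ/mol
    occupied = total_counts > 0
    log_counts = np.where(occupied, np.log(np.maximum(total_counts, 1.0)), -np.inf)

    converged = False
    it = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        for it in range(1, max_iterations + 1):
            # log denominator per bin: logsumexp_j [ln N_j + beta f_j - beta w_jb]
            m = logn[:, None] + beta * f[:, None] + log_a
            mmax = np.max(m, axis=0)
            log_denom = mmax + np.log(np.sum(np.exp(m - mmax), axis=0))
            log_p = np.where(occupied, log_counts - log_denom, -np.inf)
            # f_i = -kT logsumexp_b [log P_b - beta w_ib]
            t = log_p[None, :] + log_a
            tmax = np.max(t, axis=1)
            f_new = -kT * (tmax + np.log(np.sum(np.exp(t - tmax[:, None]), axis=1)))
            f_new -= f_new[0]
            delta = float(np.max(np.abs(f_new - f)))
            f = f_new
            if delta < tolerance:
                converged = True
                break

    pmf_vals = np.where(occupied, -kT * log_p, np.nan)
    pmf_vals = pmf_vals - np.nanmin(pmf_vals)
    profile = PMFProfile(
        bin_centers=centers,
        pmf=pmf_vals,
        reference="global minimum",
        n_bins=n_bins,
        counts=total_counts,
    )
    log.info("WHAM: %d windows, %d bins, %d iterations, converged=%s",
             len(windows), n_bins, it, converged)
    if strict and not converged:
        raise ConvergenceError(
            f"WHAM did not converge within {max_iterations} iterations"
        )
    return WHAMResult(
        pmf=profile,
        window_free_energies=f,
        iterations=it,
        converged=converged,
        tolerance=tolerance,
        temperature=temperature,
        meta={"xi_range": xi_range, "n_samples": n_samples},
    )


def boltzmann_inversion(
    samples: np.ndarray,
    n_bins: int,
    xi_range: tuple[float, float],
    temperature: float = 300.0,
) -> PMFProfile:
    """Direct −k_B T ln(histogram) of unbiased samples (oracle for WHAM)."""
    edges = np.linspace(xi_range[0], xi_range[1], n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts, _ = np.histogram(np.asarray(samples, dtype=float), bins=edges)
    with np.errstate(divide="ignore"):
        pmf = np.where(counts > 0, -kBT(temperature) * np.log(counts), np.nan)
    pmf = pmf - np.nanmin(pmf)
    return PMFProfile(centers, pmf, reference="global minimum",
                      n_bins=n_bins, counts=counts.astype(float))


def _region_mask(pmf: PMFProfile, region: tuple[float, float]) -> np.ndarray:
    lo, hi = region
    return (pmf.bin_centers >= lo) & (pmf.bin_centers <= hi) & pmf.occupied


def delta_g_binding(
    pmf: PMFProfile,
    bound_region: tuple[float, float],
    unbound_region: tuple[float, float],
    units: str = "kcal/mol",
) -> float:
    """Binding free energy: plateau mean minus bound-well minimum.

    Positive for a binding well.  ``units`` is one of 'kcal/mol', 'kJ/mol'.
    """
    if bound_region[0] >= bound_region[1] or unbound_region[0] >= unbound_region[1]:
        raise InvalidParameterError("regions must be (lo, hi) with lo < hi")
    if max(bound_region[0], unbound_region[0]) < min(bound_region[1], unbound_region[1]):
        raise InvalidParameterError("bound and unbound regions must not overlap")
    m_bound = _region_mask(pmf, bound_region)
    m_unbound = _region_mask(pmf, unbound_region)
    if not m_bound.any():
        raise EstimationError("bound region has no occupied bins")
    if not m_unbound.any():
        raise EstimationError("unbound region has no occupied bins")
    dg_kj = float(np.mean(pmf.pmf[m_unbound]) - np.min(pmf.pmf[m_bound]))
    if units == "kJ/mol":
        return dg_kj
    if units == "kcal/mol":
        return dg_kj / KJ_PER_KCAL
    raise InvalidParameterError(f"unknown units {units!r}")


def bootstrap_error(
    windows: list[UmbrellaWindow],
    bound_region: tuple[float, float],
    unbound_region: tuple[float, float],
    n_bootstrap: int = 50,
    n_bins: int = 100,
    seed: int = 0,
    xi_range: tuple[float, float] | None = None,
    temperature: float = 300.0,
    tolerance: float | None = None,
    max_iterations: int = 100_000,
) -> tuple[float, np.ndarray]:
    """Bootstrap uncertainty of ΔG_binding and of the per-bin PMF.

    Resamples each window's observations with replacement, re-runs WHAM per
    replicate and returns (std of ΔG in kcal/mol, per-bin PMF std in kJ/mol).
    Deterministic for a fixed seed.  Replicates whose WHAM solve fails are
    dropped with a warning; more than 10% dropped is an error.
    """
    if n_bootstrap < 2:
        raise InvalidParameterError("n_bootstrap must be >= 2")
    live = [w for w in windows if w.samples is not None and w.samples.size > 0]
    if not live:
        raise EstimationError("no windows with samples")
    if xi_range is None:
        lo = min(float(np.min(w.samples)) for w in live)
        hi = max(float(np.max(w.samples)) for w in live)
        xi_range = (lo, hi + 1e-9 * max(1.0, abs(hi)))
    rng = np.random.default_rng(seed)
    dgs = []
    pmfs = []
    dropped = 0
    for _ in range(n_bootstrap):
        reps = []
        for w in live:
            idx = rng.integers(0, w.samples.size, size=w.samples.size)
            reps.append(
                UmbrellaWindow(w.center, w.force_constant, w.samples[idx], w.label)
            )
        try:
            res = wham_solve(
                reps, n_bins=n_bins, xi_range=xi_range, temperature=temperature,
                tolerance=tolerance, max_iterations=max_iterations,
            )
            dgs.append(
                delta_g_binding(res.pmf, bound_region, unbound_region, "kcal/mol")
            )
            # re-reference each replicate PMF to its unbound plateau so the
            # per-bin spread reflects shape, not the arbitrary constant
            m_u = _region_mask(res.pmf, unbound_region)
            pmfs.append(res.pmf.pmf - np.mean(res.pmf.pmf[m_u]))
        except (EstimationError, ConvergenceError) as exc:
            dropped += 1
            warnings.warn(f"bootstrap replicate dropped: {exc}", stacklevel=2)
    if dropped > 0.1 * n_bootstrap:
        raise EstimationError(
            f"{dropped}/{n_bootstrap} bootstrap replicates failed"
        )
    dg_std = float(np.std(dgs, ddof=1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        bin_std = np.nanstd(np.stack(pmfs), axis=0, ddof=1)
    return dg_std, bin_std


def read_windows(metadata_path: str | Path) -> list[UmbrellaWindow]:
    """Read a window-metadata table and its per-window data files.

    The metadata file is whitespace/comma-delimited with a header row:
    ``label  center_nm  force_constant_kJ_mol_nm2  path``.  Data files are
    two whitespace-separated columns (time, coordinate in nm); lines starting
    with '#' or '@' are ignored (pull-code output dialect).  Relative data
    paths resolve against the metadata file's directory.
    """
    metadata_path = Path(metadata_path)
    table = pd.read_csv(metadata_path, sep=None, engine="python", comment="#")
    required = {"label", "center_nm", "force_constant_kJ_mol_nm2", "path"}
    missing = required - set(table.columns)
    if missing:
        raise EstimationError(
            f"window metadata {metadata_path} lacks columns: {sorted(missing)}"
        )
    windows = []
    for row in table.itertuples(index=False):
        data_path = Path(row.path)
        if not data_path.is_absolute():
            data_path = metadata_path.parent / data_path
        raw = np.loadtxt(data_path, comments=("#", "@"))
        samples = np.atleast_2d(raw)[:, 1]
        windows.append(
            UmbrellaWindow(
                center=float(row.center_nm),
                force_constant=float(row.force_constant_kJ_mol_nm2),
                samples=samples,
                label=str(row.label),
            )
        )
    return windows
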