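"""CSV/JSON writers and readers.

All writers are atomic (write to a temporary file in the destination
directory, then rename), emit floats at 9 significant digits and are
byte-identical across runs for identical inputs.  Masked PMF bins carry an
explicit ``NA`` token.
"""

from __future__ import annotations

import json
import os
import tempfile
from contextlib import contextmanager
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AptafieldError
from .pbe_solver import PotentialProfile
from .umbrella_wham import PMFProfile

__all__ = [
    "write_profile_csv", "write_sweep_csv", "write_pmf_csv",
    "write_json_sidecar", "read_profile_csv", "read_pmf_csv",
]

_FMT = "%.9g"


@contextmanager
def _atomic_open(path: str | Path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            yield fh
        os.replace(tmp, path)
    except Exception as exc:
        try:
            os.unlink(tmp)
        except OSError:
            pass
        raise AptafieldError(f"failed writing {path}: {exc}") from exc


def _fmt(x: float) -> str:
    return "NA" if not np.isfinite(x) else _FMT % x


def write_profile_csv(profile: PotentialProfile, path: str | Path) -> None:
    """Write ``z_nm,psi_mV,E_V_per_nm`` rows for a solved profile."""
    with _atomic_open(path) as fh:
        fh.write("z_nm,psi_mV,E_V_per_nm\n")
        for z, psi, e in zip(profile.z_grid, profile.psi, profile.field):
            fh.write(f"{_fmt(z)},{_fmt(psi)},{_fmt(e)}\n")


def write_sweep_csv(sweep_df: pd.DataFrame, path: str | Path) -> None:
    """Write a sweep table; header-only file for an empty sweep."""
    columns = list(sweep_df.columns) if len(sweep_df.columns) else [
        "grafting_density", "electrode_potential", "field_at_thiol_top",
        "field_at_head_bottom", "field_at_layer_top",
        "field_change_full_layer", "field_change_head", "head_field_sign",
        "converged",
    ]
    with _atomic_open(path) as fh:
        fh.write(",".join(columns) + "\n")
        for row in sweep_df.itertuples(index=False):
            cells = [
                _fmt(v) if isinstance(v, (int, float, np.floating)) and not isinstance(v, bool)
                else str(v)
                for v in row
            ]
            fh.write(",".join(cells) + "\n")


def write_pmf_csv(pmf: PMFProfile, path: str | Path) -> None:
    """Write ``xi_nm,pmf_kJ_mol,err_kJ_mol``; masked bins as NA."""
    errs = pmf.errors if pmf.errors is not None else np.full(pmf.pmf.shape, np.nan)
    with _atomic_open(path) as fh:
        fh.write("xi_nm,pmf_kJ_mol,err_kJ_mol\n")
        for x, p, e in zip(pmf.bin_centers, pmf.pmf, errs):
            fh.write(f"{_fmt(x)},{_fmt(p)},{_fmt(e)}\n")


def write_json_sidecar(meta: dict, path: str | Path) -> None:
    """Deterministic (sorted-key) JSON metadata next to a CSV output."""
    with _atomic_open(path) as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_profile_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_pmf_csv(path: str | Path) -> PMFProfile:
    df = pd.read_csv(path, na_values=["NA"])
    errors = df["err_kJ_mol"].to_numpy()
    return PMFProfile(
        bin_centers=df["xi_nm"].to_numpy(),
        pmf=df["pmf_kJ_mol"].to_numpy(),
        errors=None if np.all(~np.isfinite(errors)) else errors,
    )
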