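"""Deterministic, byte-stable text output for spectra, modes and tables.

All delimited-text files carry '#' metadata headers recording the stack,
incidence condition and metal-interpolation scheme; floats are formatted to
3 decimals (matching the precision of the published tables) so identical
inputs always produce identical bytes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .resonances import ResonanceMode
from .tmm import FieldProfile, SpectralResult

__all__ = [
    "write_spectrum",
    "write_field_profile",
    "write_angular_map",
    "write_modes",
    "write_table",
]

_FMT = "%.3f"


def _header_lines(meta: dict) -> str:
    return "".join(f"# {k}: {meta[k]}\n" for k in sorted(meta))


def write_spectrum(result: SpectralResult, path, extra_meta=None) -> Path:
    """Columns wavelength_nm, R, T, A with a '#' metadata header."""
    meta = {
        "theta_deg": result.theta_deg,
        "polarization": result.polarization,
        "stack": result.stack_key,
        "interpolation": "pchip",
    }
    meta.update(extra_meta or {})
    df = pd.DataFrame({
        "wavelength_nm": result.wavelength_nm,
        "R": result.R, "T": result.T, "A": result.A,
    })
    return _write_csv(df, path, meta, float_format="%.9f")


def write_field_profile(profile: FieldProfile, path, extra_meta=None) -> Path:
    meta = {
        "wavelength_nm": profile.wavelength_nm,
        "theta_deg": profile.theta_deg,
        "polarization": profile.polarization,
    }
    meta.update(extra_meta or {})
    df = pd.DataFrame({
        "z_nm": profile.z_nm,
        "Re_E": profile.E.real,
        "Im_E": profile.E.imag,
        "abs2_E": profile.intensity,
        "n_real": profile.index.real,
        "n_imag": profile.index.imag,
    })
    return _write_csv(df, path, meta, float_format="%.6f")


def write_angular_map(lam_nm, theta_deg, Rmap, path, extra_meta=None) -> Path:
    """Long-format wavelength_nm, theta_deg, R."""
    lam = np.asarray(lam_nm)
    theta = np.asarray(theta_deg)
    tt, ll = np.meshgrid(theta, lam, indexing="ij")
    df = pd.DataFrame({
        "wavelength_nm": ll.ravel(),
        "theta_deg": tt.ravel(),
        "R": np.asarray(Rmap).ravel(),
    })
    return _write_csv(df, path, extra_meta or {}, float_format="%.6f")


def write_modes(modes: list[ResonanceMode], path, fmt: str = "json",
                extra_meta=None) -> Path:
    """Mode report (label, lambda0, FWHM, R0, Q, G, f_A, order) as JSON or CSV."""
    records = [m.as_dict() for m in modes]
    path = Path(path)
    if fmt == "json":
        payload = {"meta": dict(sorted((extra_meta or {}).items())),
                   "modes": records}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                                   default=float) + "\n")
        return path
    if fmt == "csv":
        df = pd.DataFrame(records) if records else pd.DataFrame(
            columns=["label", "lambda0_nm", "fwhm_nm", "r_min", "q",
                     "g_per_um", "f_analyte", "order", "flags"])
        return _write_csv(df, path, extra_meta or {}, float_format=_FMT)
    raise ValueError("fmt must be 'json' or 'csv'")


def write_table(df: pd.DataFrame, path, meta=None,
                float_format: str = _FMT) -> Path:
    """Generic deterministic table writer with '#' metadata header."""
    return _write_csv(df, path, meta or {}, float_format=float_format)


def _write_csv(df: pd.DataFrame, path, meta: dict, float_format: str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    body = df.to_csv(index=False, float_format=float_format,
                     lineterminator="\n")
    path.write_text(_header_lines(meta) + body)
    return path
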