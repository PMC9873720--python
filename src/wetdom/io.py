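"""Readers and writers for the pipeline's on-disk formats.

All formats are plain text:

* EEMs as wide CSV — first column the emission wavelengths (nm), header
  row the excitation wavelengths (nm), cells the intensities;
* absorbance as two-column CSV (nm, decadic absorbance) with the path
  length supplied separately (config or argument);
* incubation and site-flow tables as tidy CSV;
* scenario manifests and budget reports as JSON;
* run configuration as a flat key:value YAML mapping.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .spectra import EEM, AbsorbanceSpectrum

__all__ = [
    "write_eem_csv", "read_eem_csv",
    "write_absorbance_csv", "read_absorbance_csv",
    "write_indices_table",
    "write_manifest", "read_manifest",
    "load_config", "dump_config", "config_hash",
]


def write_eem_csv(eem: EEM, path) -> None:
    """Write an EEM as a wide matrix: rows emission, columns excitation."""
    df = pd.DataFrame(eem.intensity, index=eem.em, columns=eem.ex)
    df.index.name = "em_nm"
    df.to_csv(path)


def read_eem_csv(path, **flags) -> EEM:
    """Read a wide-matrix EEM CSV; correction flags may be set via kwargs."""
    df = pd.read_csv(path, index_col=0)
    em = df.index.to_numpy(dtype=float)
    ex = np.array([float(c) for c in df.columns])
    return EEM(ex=ex, em=em, intensity=df.to_numpy(dtype=float), **flags)


def write_absorbance_csv(spectrum: AbsorbanceSpectrum, path) -> None:
    pd.DataFrame({"wavelength_nm": spectrum.wavelength,
                  "absorbance": spectrum.absorbance}).to_csv(path, index=False)


def read_absorbance_csv(path, path_length: float = 0.01) -> AbsorbanceSpectrum:
    df = pd.read_csv(path)
    return AbsorbanceSpectrum(wavelength=df["wavelength_nm"].to_numpy(float),
                              absorbance=df["absorbance"].to_numpy(float),
                              path_length=path_length)


def write_indices_table(rows: list[dict], path) -> None:
    """One row per sample; peak dict flattened to peak_B ... peak_C columns."""
    flat = []
    for r in rows:
        r = dict(r)
        peaks = r.pop("peaks", {})
        for name, val in peaks.items():
            r[f"peak_{name}"] = val
        flat.append(r)
    pd.DataFrame(flat).to_csv(path, index=False)


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=_jsonable)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: Recognised configuration keys and their types (flat key:value document).
CONFIG_SCHEMA: dict[str, type] = {
    "seed": int,
    "outdir": str,
    # inputs
    "eem_dir": str, "absorbance_csv": str, "path_length_m": float,
    "incubation_csv": str, "flow_csv": str, "doc_mg_l": float,
    # corrections
    "raman_ex_nm": float, "raman_em_lo_nm": float, "raman_em_hi_nm": float,
    "fi_convention": str,
    "scatter_rayleigh1_nm": float, "scatter_rayleigh2_nm": float,
    "scatter_raman1_nm": float,
    # parafac
    "n_components": int, "n_starts": int, "max_iter": int, "tol": float,
    "split_half_threshold": float,
    # kinetics
    "incubation_days": float, "kinetics_method": str,
    # budget
    "phases": str, "volume_m3": float, "area_km2": float,
}


def load_config(path) -> dict:
    """Load and validate a flat key:value YAML config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a flat key: value mapping")
    cfg = {}
    for key, value in raw.items():
        if key not in CONFIG_SCHEMA:
            raise ValueError(f"unknown config key: {key!r}")
        typ = CONFIG_SCHEMA[key]
        try:
            cfg[key] = typ(value)
        except (TypeError, ValueError):
            raise ValueError(f"config key {key!r} expects {typ.__name__}, got {value!r}")
    return cfg


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, default_flow_style=False, sort_keys=True)


def config_hash(cfg: dict) -> str:
    """Stable short hash identifying a resolved configuration."""
    blob = json.dumps(cfg, sort_keys=True, default=_jsonable).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
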