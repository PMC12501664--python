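"""Plain-text I/O: waveform/spectrum exports, matrix CSVs with header
metadata, constraint/run configuration, and run manifests."""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .encoding import IntervalScheme, LinearEncodingModel
from .waveforms import EncodingSpectrum, HardwareConstraints, Waveform

TWO_PI = 2.0 * np.pi


class ConfigError(ValueError):
    pass


def write_waveform(w: Waveform, path) -> None:
    """Two-column tab-separated export: time (ms), effective gradient (mT/m)."""
    t = np.arange(w.n_samples) * w.dt
    data = np.column_stack([t * 1e3, w.samples * 1e3])
    header = (f"# family={w.family} params={json.dumps(w.params)}\n"
              f"# refocus_time_ms={w.refocus_time*1e3:.6g}\n"
              "# time_ms\tgradient_mT_m")
    with open(path, "w") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, data, fmt="%.9g", delimiter="\t")


def write_spectrum(s: EncodingSpectrum, path) -> None:
    """CSV export: frequency (Hz), encoding power |Q|^2."""
    with open(path, "w") as fh:
        fh.write(f"# label={s.label} b_s_mm2={s.bvalue_mm2:.6g}\n")
        fh.write("frequency_hz,power\n")
        np.savetxt(fh, np.column_stack([s.omega / TWO_PI, s.power]),
                   fmt="%.12g", delimiter=",")


def write_matrix(mat: np.ndarray, path, scheme: Optional[IntervalScheme] = None,
                 bvalue: Optional[float] = None, name: str = "matrix") -> None:
    """CSV with header comments recording interval edges (Hz) and b-value."""
    with open(path, "w") as fh:
        fh.write(f"# {name}\n")
        if scheme is not None:
            fh.write(f"# interval_edges_hz={list(np.round(scheme.edges_hz, 6))}\n")
        if bvalue is not None:
            fh.write(f"# b_s_mm2={bvalue:.6g}\n")
        np.savetxt(fh, np.atleast_2d(mat), fmt="%.17g", delimiter=",")


def read_matrix(path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", comments="#", ndmin=2)


def read_matrix_meta(path) -> dict:
    """Header metadata (interval edges, b-value) of an exported matrix."""
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, val = body.split("=", 1)
                try:
                    meta[key.strip()] = json.loads(val.strip())
                except json.JSONDecodeError:
                    meta[key.strip()] = val.strip()
    return meta


def read_table(path) -> pd.DataFrame:
    """Measurement table: one row per voxel, columns are per-measurement ADCs
    or grouped tensor elements."""
    return pd.read_csv(path, comment="#")


DEFAULT_CONFIG = {
    "constraints": {
        "gmax_mT_m": 200.0,
        "slew_mT_m_ms": 600.0,
        "b_s_mm2": 1000.0,
        "tdw_ms": 90.0,
        "dt_us": 10.0,
        "refocus_gap_ms": 6.0,
    },
    "scheme": {"interval_width_hz": 10.0, "f_max_hz": 50.0},
    "selection": {"m_select": 7, "m_max": 12, "df_hz": 0.1},
    "simulation": {
        "scenarios": ["scenario1", "scenario2", "scenario3", "scenario4"],
        "sigma_rel": 0.02,
        "reps": 3000,
        "n_dw": 16,
        "n_b0": 5,
        "seed": 0,
    },
}

_SCHEMA = {
    "constraints": dict,
    "scheme": dict,
    "selection": dict,
    "simulation": dict,
}


def load_config(path: Optional[str] = None) -> dict:
    """Load a YAML/JSON run configuration merged over protocol defaults.

    Unknown sections or keys raise :class:`ConfigError` with the offending
    location named.
    """
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is None:
        return cfg
    text = Path(path).read_text()
    user = yaml.safe_load(text) or {}
    if not isinstance(user, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    for section, val in user.items():
        if section not in _SCHEMA:
            raise ConfigError(f"{path}: unknown section {section!r}")
        if not isinstance(val, _SCHEMA[section]):
            raise ConfigError(f"{path}: section {section!r} must be a mapping")
        for key, v in val.items():
            if key not in cfg[section]:
                raise ConfigError(f"{path}: unknown key {section}.{key}")
            cfg[section][key] = v
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def scheme_from_config(cfg: dict) -> IntervalScheme:
    sc = cfg["scheme"]
    return IntervalScheme.uniform(float(sc["interval_width_hz"]),
                                  float(sc["f_max_hz"]))


def constraints_from_config(cfg: dict) -> HardwareConstraints:
    return HardwareConstraints.from_dict(cfg["constraints"])


def write_manifest(outdir: Path, cfg: dict, outputs: list[Path],
                   seed: Optional[int] = None) -> Path:
    """Machine-readable provenance record for a CLI run."""
    import tdspect
    manifest = {
        "config": cfg,
        "config_hash": config_hash(cfg),
        "seed": seed,
        "versions": {
            "tdspect": tdspect.__version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
        },
        "outputs": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()[:16]
            for p in outputs if p.exists()
        },
    }
    path = Path(outdir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def export_system(model: LinearEncodingModel, outdir: Path) -> list[Path]:
    """Write E, R, SRFs and the noise table for an encoding system."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    b = float(np.mean(model.bvalues))
    paths = []
    for name, mat in [("encoding_matrix", model.E),
                      ("reconstruction_matrix", model.R)]:
        p = outdir / f"{name}.csv"
        write_matrix(mat, p, scheme=model.scheme, bvalue=b, name=name)
        paths.append(p)
    srfs = model.srf()
    p = outdir / "srfs.csv"
    df = pd.DataFrame(srfs.values.T, columns=model.scheme.labels())
    df.insert(0, "frequency_hz", srfs.omega / TWO_PI)
    df.to_csv(p, index=False, float_format="%.12g")
    paths.append(p)
    p = outdir / "noise_table.csv"
    model.summary().to_csv(p, index=False, float_format="%.12g")
    paths.append(p)
    return paths
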