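"""File formats and run configuration.

Tabular outputs are CSV with units encoded in the column names plus a
``# units:`` comment line; position trajectories are standard XYZ frames
(element "C" for filament particles, "O" for beads); configs are YAML or
JSON, validated and re-written fully resolved next to the outputs so any
run is reproducible from its resolved config and seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import ForceStrainCurve, RawSamples

__all__ = [
    "load_config",
    "resolve_config",
    "write_config",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_xyz",
    "read_xyz",
    "write_raw_csv",
    "read_raw_csv",
    "write_curve_csv",
    "read_curve_csv",
    "ConfigError",
]


class ConfigError(ValueError):
    pass


_DEFAULTS = {
    "seed": 0,
    "output": ".",
    "log_level": "INFO",
    "model": {"kind": "1d", "B_pNum2": 4.0, "L_um": 4.1, "bead_radius_um": 0.5,
              "N": 48, "Ea_GPa": 0.9, "Ec_MPa": 4.0, "G_GPa": 4.0, "d_nm": 16.0},
    "protocol": {"dx_nm": 8.0, "coarse_dx_nm": 20.0, "max_strain": 0.2,
                 "extension_strain": 0.0, "backward": False, "tol_pN": 1e-3,
                 "to_kink": False},
    "observables": {"kink_drop_frac": 0.01, "flatness_min": 0.3,
                    "plateau_slope_frac": 0.1},
    "fitting": {"std_floor_pN": 0.02, "Ea_GPa": [0.1, 5.0], "Ec_MPa": [0.5, 100.0],
                "G_GPa": [0.1, 20.0], "B_pNum2": [0.5, 50.0]},
    "synthetic": {"step_nm": 5.0, "dwell_samples": 75, "sigma_pN": 0.1,
                  "n_cycles": 2, "ko_pN_nm": 0.05},
}


def load_config(path) -> dict:
    """Read a YAML or JSON config file (dialect chosen by content)."""
    text = Path(path).read_text()
    try:
        cfg = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} must be a mapping")
    return cfg


def resolve_config(cfg: dict) -> dict:
    """Merge user config over defaults and validate the schema."""
    out = {}
    for key, default in _DEFAULTS.items():
        if isinstance(default, dict):
            section = cfg.get(key, {})
            if not isinstance(section, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            unknown = set(section) - set(default)
            if unknown:
                raise ConfigError(f"unknown keys in section {key!r}: {sorted(unknown)}")
            out[key] = {**default, **section}
        else:
            out[key] = cfg.get(key, default)
    unknown = set(cfg) - set(_DEFAULTS)
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    kind = out["model"]["kind"]
    if kind not in ("1d", "3d"):
        raise ConfigError(f"model.kind must be '1d' or '3d', got {kind!r}")
    for name, sec, key in (("L_um", "model", "L_um"), ("dx_nm", "protocol", "dx_nm")):
        if not out[sec][key] > 0:
            raise ConfigError(f"{sec}.{key} must be positive")
    return out


def write_config(cfg: dict, path):
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


# ---------------------------------------------------------------------------
# trajectories

def write_trajectory_csv(traj, path):
    df = traj.to_dataframe()
    with open(path, "w") as fh:
        fh.write("# units: db nm, force pN (positive in compression), energies pN·nm, "
                 "max_transverse nm\n")
        df.to_csv(fh, index=False)


def read_trajectory_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_xyz(frames, path, n_beads: int = 2, comments=None):
    """Write position frames as concatenated XYZ blocks; the last
    ``n_beads`` particles are labeled "O" (beads), the rest "C"."""
    with open(path, "w") as fh:
        for k, pos in enumerate(frames):
            n = pos.shape[0]
            comment = comments[k] if comments is not None else f"frame {k}"
            fh.write(f"{n}\n{comment}\n")
            for i in range(n):
                el = "O" if i >= n - n_beads else "C"
                fh.write(f"{el} {pos[i,0]:.6f} {pos[i,1]:.6f} {pos[i,2]:.6f}\n")


def read_xyz(path):
    frames = []
    with open(path) as fh:
        while True:
            line = fh.readline()
            if not line:
                break
            n = int(line)
            fh.readline()
            pos = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                pos[i] = [float(x) for x in parts[1:4]]
            frames.append(pos)
    return frames


# ---------------------------------------------------------------------------
# raw samples and binned curves

def write_raw_csv(raw: RawSamples, path):
    with open(path, "w") as fh:
        fh.write(f"# ko_detection_pN_nm: {raw.ko_detection}\n")
        fh.write(f"# ko_manipulation_pN_nm: {raw.ko_manipulation}\n")
        fh.write(f"# meta: {json.dumps(raw.meta)}\n")
        raw.data.to_csv(fh, index=False)


def read_raw_csv(path) -> RawSamples:
    header = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition(":")
            header[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        data = pd.read_csv(fh)
    try:
        ko_d = float(header["ko_detection_pN_nm"])
        ko_m = float(header["ko_manipulation_pN_nm"])
    except KeyError as exc:
        raise ConfigError(f"raw CSV {path} missing trap stiffness header") from exc
    meta = json.loads(header.get("meta", "{}"))
    return RawSamples(data=data, ko_detection=ko_d, ko_manipulation=ko_m, meta=meta)


def write_curve_csv(curve: ForceStrainCurve, path):
    with open(path, "w") as fh:
        fh.write(f"# L_nm: {curve.L}\n")
        fh.write("# units: force pN (positive in compression)\n")
        curve.to_dataframe().to_csv(fh, index=False)


def read_curve_csv(path) -> ForceStrainCurve:
    L = None
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            if line[1:].strip().startswith("L_nm:"):
                L = float(line.split(":", 1)[1])
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    if L is None:
        raise ConfigError(f"curve CSV {path} missing '# L_nm:' header")
    return ForceStrainCurve(
        strain=df["strain"].to_numpy(),
        F_mean=df["F_mean_pN"].to_numpy(),
        F_std=df["F_std_pN"].to_numpy(),
        n=df["n"].to_numpy(),
        L=L,
        db=df["db_nm"].to_numpy() if "db_nm" in df else None,
    )
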