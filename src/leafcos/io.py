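"""CSV schema and flat-text configuration for reproducible runs.

One data point is one 150-second steady-state cuvette interval; datasets are
plain CSV with a fixed column set so that generated and measured data share
one schema.  Run configuration is a flat ``key = value`` text format (the
parameter space is shallow, and flat files diff cleanly in tests).
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

__all__ = [
    "OBSERVED_COLUMNS",
    "read_dataset",
    "write_dataset",
    "validate_dataset",
    "read_config",
    "write_config",
    "config_hash",
]

#: Column order of the observed-point schema.  Mole fractions: COS in
#: pmol mol-1 (dry basis), CO2 in umol mol-1 (dry basis), H2O in mmol mol-1.
OBSERVED_COLUMNS = [
    "point_id",
    "plant_id",
    "t_leaf_C",
    "p_air_Pa",
    "af_mol_s",
    "s_m2",
    "g_bw",
    "g_sw_meas",
    "cos_in_dry",
    "cos_out_dry",
    "co2_in_dry",
    "co2_out_dry",
    "h2o_in",
    "h2o_out",
    "sigma_cos",
    "sigma_co2",
    "sigma_h2o",
]

_ID_COLUMNS = {"point_id", "plant_id"}


def validate_dataset(df: pd.DataFrame) -> pd.DataFrame:
    """Check the observed-point schema; returns the frame with canonical
    column order."""
    missing = [c for c in OBSERVED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset is missing required columns: {missing}")
    out = df[OBSERVED_COLUMNS + [c for c in df.columns if c not in OBSERVED_COLUMNS]]
    numeric = [c for c in OBSERVED_COLUMNS if c not in _ID_COLUMNS]
    bad = [c for c in numeric if not pd.api.types.is_numeric_dtype(out[c])]
    if bad:
        raise ValueError(f"non-numeric values in columns: {bad}")
    if out[numeric].isna().any().any():
        na_cols = out[numeric].columns[out[numeric].isna().any()].tolist()
        raise ValueError(f"missing values in columns: {na_cols}")
    for c in ("sigma_cos", "sigma_co2", "sigma_h2o"):
        if (out[c] <= 0).any():
            raise ValueError(f"{c} must be strictly positive for every point")
    if out["point_id"].duplicated().any():
        raise ValueError("point_id values must be unique")
    return out


def read_dataset(path) -> pd.DataFrame:
    return validate_dataset(pd.read_csv(path))


def write_dataset(df: pd.DataFrame, path) -> None:
    """Write with 10 significant digits so read->write->read round-trips
    exactly at test tolerance."""
    validate_dataset(df).to_csv(path, index=False, float_format="%.10g")


def _coerce(raw: str):
    s = raw.strip()
    low = s.lower()
    if low in ("true", "false"):
        return low == "true"
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            pass
    return s


def read_config(path, allowed_keys=None) -> dict:
    """Parse a flat ``key = value`` config file.

    Blank lines and ``#`` comments are ignored.  When ``allowed_keys`` is
    given, any unknown key raises with its name (mistyped keys should fail
    loudly, not be silently dropped).
    """
    cfg = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if "=" not in stripped:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, raw = stripped.split("=", 1)
        key = key.strip()
        if allowed_keys is not None and key not in allowed_keys:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        cfg[key] = _coerce(raw)
    return cfg


def write_config(cfg: dict, path) -> None:
    lines = [f"{k} = {v}" for k, v in cfg.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def config_hash(cfg: dict) -> str:
    """Stable short hash of a resolved configuration, for run logs."""
    blob = "\n".join(f"{k}={cfg[k]}" for k in sorted(cfg))
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
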