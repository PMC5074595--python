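"""Configuration files, provenance headers, and tabular output.

Config files are flat YAML mappings, one key per model symbol:

    alpha, delta, rho_A, rho_B, K_A, K_B, K_M, f      (deterministic)
    omega, nu_A, nu_B                                  (stochastic)

plus optional experiment keys (seed, threshold, m_min, m_max, ...). Missing
model keys fall back to the bundled reference set; unknown keys produce a
warning but are carried through in ``extras``.

CSV outputs carry a provenance header ('# key: value' comment lines with
the config hash, seed and package version) and round-trip floats exactly
(repr precision).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import NoiseParams, ToggleParams

__all__ = [
    "RunConfig",
    "load_config",
    "dump_config",
    "reference_config_path",
    "write_table",
    "read_table",
    "TABLE_SCHEMAS",
]

_TOGGLE_KEYS = {
    "alpha": "alpha", "delta": "delta", "rho_A": "rho_a", "rho_B": "rho_b",
    "K_A": "k_a", "K_B": "k_b", "K_M": "k_m", "f": "f",
}
_NOISE_KEYS = {"omega": "omega", "nu_A": "nu_a", "nu_B": "nu_b"}
_EXPERIMENT_KEYS = {
    "seed", "threshold", "m", "m_min", "m_max", "n_m", "n_reps", "t_max",
    "dt", "rows", "cols", "mode",
}


@dataclass
class RunConfig:
    """Validated model + noise parameters plus experiment extras."""

    params: ToggleParams
    noise: NoiseParams
    extras: dict = field(default_factory=dict)

    def to_mapping(self) -> dict:
        out = {k: getattr(self.params, a) for k, a in _TOGGLE_KEYS.items()}
        out.update({k: getattr(self.noise, a) for k, a in _NOISE_KEYS.items()})
        out.update(self.extras)
        return out

    def hash(self) -> str:
        text = yaml.safe_dump(self.to_mapping(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Load and validate a flat key-value config file.

    Parameter-positivity and f > 1 are enforced before any run; violations
    raise ValueError naming the offending key.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    toggle_kw = {}
    noise_kw = {}
    extras = {}
    for key, value in raw.items():
        if key in _TOGGLE_KEYS:
            toggle_kw[_TOGGLE_KEYS[key]] = float(value)
        elif key in _NOISE_KEYS:
            noise_kw[_NOISE_KEYS[key]] = float(value)
        else:
            if key not in _EXPERIMENT_KEYS:
                warnings.warn(f"{path}: unknown config key {key!r}", stacklevel=2)
            extras[key] = value
    try:
        params = ToggleParams(**toggle_kw)
        noise = NoiseParams(**noise_kw)
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from err
    return RunConfig(params=params, noise=noise, extras=extras)


def dump_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_mapping(), fh, sort_keys=True)


def reference_config_path():
    """Path to the bundled reference parameter set (``figure2.cfg``)."""
    return resources.files("switchwave").joinpath("data/figure2.cfg")


#: Registered output-table column schemas.
TABLE_SCHEMAS = {
    "branches": ["M", "x_A", "x_B", "stability"],
    "pattern_time": ["M", "T"],
    "mfpt": ["M", "mean_T", "sem_T", "cv_T", "n_censored"],
    "map": ["index", "t", "x_A", "x_B"],
    "action_profile": ["M", "S_BA", "S_AB", "dS_BA_dM", "converged"],
    "trajectory": ["t", "x_A", "x_B"],
    "wave_summary": ["t", "m_50", "width", "flagged"],
}


def write_table(records, path, schema=None, meta=None) -> None:
    """Write a CSV with a provenance comment header and full float precision.

    ``records`` is a DataFrame or list of row tuples; ``schema`` either a
    registered schema name or an explicit column list. Rows keep their
    given (deterministic) order.
    """
    if schema is None:
        if not isinstance(records, pd.DataFrame):
            raise ValueError("schema required when records is not a DataFrame")
        columns = list(records.columns)
    else:
        columns = TABLE_SCHEMAS.get(schema, schema)
        if isinstance(columns, str):
            raise ValueError(f"unknown table schema {schema!r}")
    df = pd.DataFrame(records, columns=columns) if not isinstance(records, pd.DataFrame) \
        else records
    if list(df.columns) != list(columns):
        raise ValueError(f"records columns {list(df.columns)} do not match "
                         f"schema {list(columns)}")
    with open(path, "w") as fh:
        fh.write(f"# switchwave {__version__}\n")
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False, float_format=lambda v: repr(float(v)))


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")
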