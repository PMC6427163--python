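"""Configuration and standard-format I/O.

Daily series travel as CSV with columns ``date`` (ISO-8601), ``deaths``,
``pm25`` (ug/m3), ``swt`` (1-6) and ``dow`` (0-6); study configurations are
YAML validated against a fixed schema (unknown keys rejected, seeds
mandatory so that study runs are reproducible).  Every study run writes a
provenance block (config hash, seeds, package version) next to its outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic_data import MAX_LAG, CovariateSeries

SERIES_COLUMNS = ("date", "deaths", "pm25", "swt", "dow")


class FormatError(ValueError):
    """Malformed series file."""


class ConfigError(ValueError):
    """Invalid run configuration."""


def write_series(path, cov: CovariateSeries, deaths: np.ndarray) -> None:
    deaths = np.asarray(deaths, dtype=float)
    if len(deaths) != cov.n_days:
        raise FormatError("deaths and covariates must have equal length")
    df = pd.DataFrame(
        {
            "date": cov.dates.strftime("%Y-%m-%d"),
            "deaths": deaths,
            "pm25": cov.pm25,
            "swt": cov.swt,
            "dow": cov.dow,
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_series(path) -> tuple[CovariateSeries, np.ndarray]:
    """Load a daily series CSV (header-keyed; column order free).

    The file must cover at least ``MAX_LAG + 1`` consecutive days so the
    distributed-lag model has complete-lag rows to fit on.
    """
    df = pd.read_csv(path)
    missing = set(SERIES_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"missing columns: {sorted(missing)}")
    if len(df) < MAX_LAG + 1:
        raise FormatError(
            f"series must cover at least {MAX_LAG + 1} days, got {len(df)}"
        )
    dates = pd.to_datetime(df["date"])
    diffs = dates.diff().dropna()
    if not (diffs == pd.Timedelta(days=1)).all():
        raise FormatError("dates must be consecutive calendar days")
    cov = CovariateSeries(
        pm25=df["pm25"].to_numpy(float),
        swt=df["swt"].to_numpy(np.int64),
        dow=df["dow"].to_numpy(np.int64),
        start_date=dates.iloc[0].strftime("%Y-%m-%d"),
    )
    return cov, df["deaths"].to_numpy(float)


@dataclass(frozen=True)
class RunConfig:
    """Validated study-run configuration with defaults filled in."""

    study: int
    base_seed: int
    covariate_seed: int
    n_days: int = 1096
    replicates: int = 100
    engine: str = "freq"
    gammas: tuple[float, ...] = (0.5, 1.0)
    df_per_year: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 10.0, 16.0)
    prior_means: tuple[float, ...] = (0.001, 0.005, 0.010, 0.020)
    prior_var_factors: tuple[float, ...] = (0.5, 1.0)
    prior_variances: tuple[float, ...] | None = None
    true_beta1s: tuple[float, ...] = (0.001, 0.005, 0.010, 0.020)
    target_mean_deaths: float = 32.0
    burn_in: int = 1000
    iterations: int = 2000
    thinning: int = 1
    out_dir: str = "results"
    verbosity: str = "INFO"


_REQUIRED = ("study", "base_seed", "covariate_seed")
_SEQUENCE_FIELDS = {
    "gammas",
    "df_per_year",
    "prior_means",
    "prior_var_factors",
    "prior_variances",
    "true_beta1s",
}


def _validate(raw: dict) -> RunConfig:
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    missing = [k for k in _REQUIRED if k not in raw]
    if missing:
        raise ConfigError(f"missing required config keys: {missing}")
    clean = {}
    for key, value in raw.items():
        if key in _SEQUENCE_FIELDS and value is not None:
            if np.isscalar(value):
                value = (value,)
            value = tuple(float(v) for v in value)
        clean[key] = value
    cfg = RunConfig(**clean)
    if cfg.study not in (1, 2, 3):
        raise ConfigError(f"study must be 1, 2 or 3 (got {cfg.study})")
    if any(g < 0 for g in cfg.gammas):
        raise ConfigError("gammas: values must be nonnegative")
    if cfg.replicates < 1:
        raise ConfigError("replicates: must be >= 1")
    if cfg.engine not in ("freq", "bayes", "both"):
        raise ConfigError(f"engine must be freq, bayes or both (got {cfg.engine!r})")
    if cfg.n_days < MAX_LAG + 1:
        raise ConfigError(f"n_days: must be at least {MAX_LAG + 1}")
    if cfg.burn_in < 1 or cfg.iterations < 1 or cfg.thinning < 1:
        raise ConfigError("burn_in, iterations and thinning must be positive")
    return cfg


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    return _validate(raw)


def dump_config(cfg: RunConfig) -> dict:
    """Fully resolved config as a plain dict (the normalized form)."""
    out = dataclasses.asdict(cfg)
    for key in _SEQUENCE_FIELDS:
        if out[key] is not None:
            out[key] = list(out[key])
    return out


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(dump_config(cfg), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_provenance(out_dir, cfg: RunConfig) -> Path:
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    block = {
        "config": dump_config(cfg),
        "config_hash": config_hash(cfg),
        "seeds": {"base_seed": cfg.base_seed, "covariate_seed": cfg.covariate_seed},
        "version": __version__,
    }
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(block, indent=2))
    return path
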