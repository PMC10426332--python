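"""Tabular input/output, schema validation, and run configuration.

Input tables (comma-separated, ISO-8601 dates):

* ``temperatures.csv`` — city_id, date, tmean_c
* ``deaths.csv``       — city_id, date, age_group, deaths
* ``population.csv``   — city_id, year, age_group, population
* ``cities.csv``       — city_id, name, lat, lon

Output tables are written with 6 significant digits and a leading comment
line carrying the configuration hash, so any result file can be traced to
the exact run that produced it.
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

AGE_GROUPS = ("under75", "over75")

SCHEMAS = {
    "temperatures": ["city_id", "date", "tmean_c"],
    "deaths": ["city_id", "date", "age_group", "deaths"],
    "population": ["city_id", "year", "age_group", "population"],
    "cities": ["city_id", "name", "lat", "lon"],
}


@dataclass(frozen=True)
class RunConfig:
    """All knobs of a pipeline run; defaults match the stage modules."""

    input_dir: str = "."
    n_cities: int = 12
    fit_start: int = 1987
    fit_end: int = 2000
    horizon_end: int = 2100
    reference_decade: tuple[int, int] = (2011, 2020)
    mmt_window_percentiles: tuple[float, float] = (1.0, 99.0)
    extreme_percentiles: tuple[float, float] = (2.5, 97.5)
    adaptation_mode: str = "none"
    rho_override: float | None = None
    scenarios: tuple[str, ...] = (
        "all_factor", "fixed_climate", "fixed_demographics", "fixed_population")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("reference_decade", "mmt_window_percentiles",
                    "extreme_percentiles", "scenarios"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _check_columns(df: pd.DataFrame, table: str) -> None:
    expected = SCHEMAS[table]
    if list(df.columns) != expected:
        missing = [c for c in expected if c not in df.columns]
        extra = [c for c in df.columns if c not in expected]
        raise ValueError(
            f"{table}: header mismatch; expected columns {expected}, "
            f"missing {missing}, unexpected {extra}"
        )


def _parse_dates(values: pd.Series, table: str) -> pd.DatetimeIndex:
    try:
        return pd.DatetimeIndex(
            pd.to_datetime(values, format="%Y-%m-%d", exact=True))
    except (ValueError, TypeError) as err:
        raise ValueError(f"{table}: dates must be ISO-8601 (YYYY-MM-DD): {err}") from None


def _check_contiguous(df: pd.DataFrame, keys: list[str], table: str) -> None:
    for name, grp in df.groupby(keys):
        dates = pd.DatetimeIndex(grp["date"]).sort_values()
        full = pd.date_range(dates[0], dates[-1], freq="D")
        gaps = full.difference(dates)
        if len(gaps):
            shown = [d.date().isoformat() for d in gaps[:5]]
            raise ValueError(
                f"{table}: non-contiguous dates for {name}; "
                f"{len(gaps)} missing days, first: {shown}"
            )


def read_temperatures(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    _check_columns(df, "temperatures")
    df["date"] = _parse_dates(df["date"], "temperatures")
    if df.duplicated(["city_id", "date"]).any():
        dup = df[df.duplicated(["city_id", "date"])].iloc[0]
        raise ValueError(
            f"temperatures: duplicated (city,date) row: "
            f"({dup['city_id']}, {dup['date'].date()})"
        )
    if df["tmean_c"].isna().any():
        raise ValueError("temperatures: missing tmean_c values")
    _check_contiguous(df, ["city_id"], "temperatures")
    return df


def read_deaths(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    _check_columns(df, "deaths")
    df["date"] = _parse_dates(df["date"], "deaths")
    bad = ~df["age_group"].isin(AGE_GROUPS)
    if bad.any():
        raise ValueError(f"deaths: unknown age_group values: "
                         f"{sorted(df.loc[bad, 'age_group'].unique())}")
    if df.duplicated(["city_id", "date", "age_group"]).any():
        raise ValueError("deaths: duplicated (city,date,age_group) rows")
    counts = df["deaths"]
    if counts.isna().any() or (counts < 0).any() or (counts != counts.astype(int)).any():
        raise ValueError("deaths: counts must be nonnegative integers")
    _check_contiguous(df, ["city_id", "age_group"], "deaths")
    return df


def read_population(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    _check_columns(df, "population")
    bad = ~df["age_group"].isin(AGE_GROUPS)
    if bad.any():
        raise ValueError("population: unknown age_group values")
    if df.duplicated(["city_id", "year", "age_group"]).any():
        raise ValueError("population: duplicated (city,year,age_group) rows")
    if (df["population"] <= 0).any():
        raise ValueError("population: values must be positive")
    return df


def read_cities(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    _check_columns(df, "cities")
    if df["city_id"].duplicated().any():
        raise ValueError("cities: duplicated city_id")
    if df["lat"].isna().any():
        raise ValueError("cities: missing latitude")
    return df


READERS = {
    "temperatures": read_temperatures,
    "deaths": read_deaths,
    "population": read_population,
    "cities": read_cities,
}


def write_table(df: pd.DataFrame, path: str | Path, config_hash: str = "") -> None:
    """Write a result table: comment line with the config hash, then CSV with
    6-significant-digit floats and ISO dates."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        out.to_csv(fh, index=False, float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"required file {path} is missing; run '{produced_by}' first")
    return path


def write_manifest(outdir: Path, command: str, config: RunConfig) -> None:
    import statsmodels

    manifest = {
        "command": command,
        "config": dataclasses.asdict(config),
        "config_hash": config.hash(),
        "seed": config.seed,
        "versions": {
            "tempmort": "0.1.0",
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / f"manifest_{command}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
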