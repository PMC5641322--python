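"""Table readers/writers and run configuration.

All exchange formats are comma-separated UTF-8 text with a mandatory header
row and period decimal separator; the incubation design travels as a flat
YAML key-value file. Every writer embeds enough provenance (version, seed,
parameters) in the accompanying run log to re-run the result.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .core import IncubationDesign, IsotopologueSeries, Treatment

__all__ = [
    "read_series",
    "write_series",
    "read_design",
    "write_design",
    "read_marker_table",
    "read_peak_table",
    "write_table",
    "write_run_log",
    "ParseError",
]

_DESIGN_KEYS = {
    "water_volume_ml": float,
    "headspace_volume_ml": float,
    "temperature_c": float,
    "sampling_times_h": None,  # list of floats
    "replicates_per_time": int,
    "treatment": None,  # Treatment name
    "added_15n_ammonium": float,
    "added_15n_nitrite": float,
    "added_14n_nitrite": float,
    "background_ammonium": float,
    "background_nitrite": float,
}

_MARKER_COLUMNS = (
    "well",
    "marker",
    "molecule",
    "copies",
    "below_detection",
    "quantification_limit",
)

_PEAK_COLUMNS = ("well", "date", "area_ladderane3", "area_ladderane5", "area_C19_IS")


class ParseError(ValueError):
    """A table or configuration file failed validation, with location info."""


def _read_csv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty input file") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df


def read_series(
    path: str | Path, design: IncubationDesign | None = None
) -> IsotopologueSeries:
    """Read a bottle time-series table (time_h, replicate, excess29/30)."""
    df = _read_csv(path, IsotopologueSeries.REQUIRED_COLUMNS)
    for col in ("time_h", "excess29_nmol_per_L", "excess30_nmol_per_L"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header is line 1
            raise ParseError(
                f"{path}: non-numeric value in column '{col}' at line {row}"
            )
        df[col] = pd.to_numeric(df[col])
    try:
        return IsotopologueSeries(df, design=design)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_series(series: IsotopologueSeries, path: str | Path) -> None:
    series.data.to_csv(path, index=False, encoding="utf-8")


def read_design(path: str | Path) -> IncubationDesign:
    """Read an incubation design from a flat YAML key-value file."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raise ParseError(f"{path}: empty design file")
    if not isinstance(raw, Mapping):
        raise ParseError(f"{path}: design file must be a flat key-value mapping")
    unknown = set(raw) - set(_DESIGN_KEYS)
    if unknown:
        raise ParseError(f"{path}: unknown design keys {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        conv = _DESIGN_KEYS[key]
        if key == "treatment":
            try:
                kwargs[key] = Treatment[str(value).upper()]
            except KeyError as exc:
                raise ParseError(
                    f"{path}: unknown treatment '{value}' "
                    f"(expected one of {[t.name for t in Treatment]})"
                ) from exc
        elif key == "sampling_times_h":
            kwargs[key] = tuple(float(v) for v in value)
        else:
            kwargs[key] = conv(value)
    try:
        return IncubationDesign(**kwargs)
    except ValueError as exc:
        raise ParseError(f"{path}: invalid design: {exc}") from exc


def write_design(design: IncubationDesign, path: str | Path) -> None:
    data = {
        "water_volume_ml": design.water_volume_ml,
        "headspace_volume_ml": design.headspace_volume_ml,
        "temperature_c": design.temperature_c,
        "sampling_times_h": list(design.sampling_times_h),
        "replicates_per_time": design.replicates_per_time,
        "treatment": design.treatment.name,
        "added_15n_ammonium": design.added_15n_ammonium,
        "added_15n_nitrite": design.added_15n_nitrite,
        "added_14n_nitrite": design.added_14n_nitrite,
        "background_ammonium": design.background_ammonium,
        "background_nitrite": design.background_nitrite,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_marker_table(path: str | Path) -> pd.DataFrame:
    """Read a qPCR marker abundance table (copies per liter + flags)."""
    df = _read_csv(path, _MARKER_COLUMNS)
    df["copies"] = pd.to_numeric(df["copies"])
    if (df["copies"] < 0).any():
        raise ParseError(f"{path}: negative copy numbers")
    df["below_detection"] = df["below_detection"].astype(bool)
    return df


def read_peak_table(path: str | Path) -> pd.DataFrame:
    """Read a GC peak-area table for ladderane FAMEs + internal standard."""
    df = _read_csv(path, _PEAK_COLUMNS)
    for col in ("area_ladderane3", "area_ladderane5", "area_C19_IS"):
        df[col] = pd.to_numeric(df[col])
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8")


def write_run_log(
    path: str | Path,
    command: str,
    params: Mapping[str, Any],
    messages: list[str] | None = None,
) -> None:
    """Write a human-readable run log: version, parameters, warnings.

    The log captures everything needed to re-run the result: software
    version, command, every parameter including the seed, and any
    warnings raised (negative rates, below-detection exclusions).
    """
    lines = [
        f"n2pair version {__version__}",
        f"command: {command}",
        f"timestamp: {_dt.datetime.now().isoformat(timespec='seconds')}",
        "parameters:",
    ]
    for key, value in params.items():
        lines.append(f"  {key}: {value}")
    if messages:
        lines.append("messages:")
        lines.extend(f"  - {m}" for m in messages)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
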