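"""Reading long-form instrument CSVs and converting absorbance to concentration.

Temperature-controlled cuvette changers (e.g. a six-position changer on a
single-beam spectrophotometer) emit one row per reading: a sample label, a
timestamp, the cell temperature and the absorbance. This module parses that
long form, normalises units to seconds and kelvin, and applies the
Beer–Lambert law to turn absorbances into product and substrate
concentrations for each cuvette.

Conventions
-----------
* Time is converted to seconds (instrument software typically logs minutes).
* Temperatures below 150 are assumed to be Celsius and shifted by 273.15;
  no biochemical assay runs below 150 K, so the heuristic is safe and makes
  the conversion idempotent on already-kelvin data.
* The absorbance baseline of a cuvette defaults to its first reading, so the
  product concentration starts at zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParseError, ValidationError

logger = logging.getLogger(__name__)

#: Celsius/kelvin auto-detection threshold: values below this are Celsius.
CELSIUS_THRESHOLD = 150.0

ColumnKey = Union[str, int]


@dataclass(frozen=True)
class ColumnMap:
    """Maps the logical reading fields to CSV column names or 0-based positions."""

    sample: ColumnKey = "sample"
    time: ColumnKey = "time"
    temperature: ColumnKey = "temperature"
    absorbance: ColumnKey = "absorbance"


@dataclass(frozen=True)
class CsvFormat:
    """Dialect settings for an instrument CSV.

    ``time_unit`` is ``"min"`` (instrument default) or ``"s"``.
    ``temperature_unit`` is ``"auto"`` (< 150 treated as Celsius), ``"C"`` or ``"K"``.
    """

    columns: ColumnMap = field(default_factory=ColumnMap)
    delimiter: str = ","
    decimal: str = "."
    time_unit: str = "min"
    temperature_unit: str = "auto"

    def __post_init__(self) -> None:
        if self.time_unit not in ("min", "s"):
            raise ConfigurationError(f"time_unit must be 'min' or 's', got {self.time_unit!r}")
        if self.temperature_unit not in ("auto", "C", "K"):
            raise ConfigurationError(
                f"temperature_unit must be 'auto', 'C' or 'K', got {self.temperature_unit!r}"
            )


@dataclass(frozen=True)
class AssayDesign:
    """Assay-level metadata needed to turn absorbances into concentrations.

    Parameters
    ----------
    extinction_coefficient : molar extinction coefficient, M^-1 cm^-1.
    path_length : optical path length, cm.
    enzyme_concentration : total enzyme concentration E0, molar.
    s0 : initial substrate concentration per cuvette id, molar.
    baseline : optional per-cuvette absorbance baseline (AU); if missing for a
        cuvette, its first reading is used.
    ramp_rate : metadata only, K/min.
    temperature_range : metadata only, (K, K).
    """

    extinction_coefficient: float
    path_length: float
    enzyme_concentration: float
    s0: Mapping[str, float]
    baseline: Mapping[str, float] | None = None
    ramp_rate: float | None = None
    temperature_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.extinction_coefficient <= 0:
            raise ConfigurationError("extinction_coefficient must be positive")
        if self.path_length <= 0:
            raise ConfigurationError("path_length must be positive")
        if self.enzyme_concentration <= 0:
            raise ConfigurationError("enzyme_concentration (E0) must be positive")
        for cid, s0 in self.s0.items():
            if s0 <= 0:
                raise ConfigurationError(f"S0 for cuvette {cid!r} must be positive")


@dataclass
class CuvetteTrace:
    """Concentration-vs-time series for one cuvette.

    ``data`` has columns ``time_s``, ``temperature_K``, ``product_M``,
    ``substrate_M`` and ``out_of_range`` (True where the product
    concentration fell outside [0, S0] beyond tolerance; such points are
    flagged, never dropped).
    """

    cuvette_id: str
    s0: float
    data: pd.DataFrame

    def __len__(self) -> int:
        return len(self.data)


def _resolve_column(df: pd.DataFrame, key: ColumnKey, role: str) -> str:
    if isinstance(key, int):
        if key >= len(df.columns):
            raise ConfigurationError(
                f"column index {key} for {role!r} out of range (file has {len(df.columns)} columns)"
            )
        return df.columns[key]
    if key not in df.columns:
        raise ConfigurationError(
            f"missing column {key!r} for {role!r}; available: {list(df.columns)}"
        )
    return str(key)


def _coerce_numeric(df: pd.DataFrame, col: str, role: str) -> pd.Series:
    values = pd.to_numeric(df[col], errors="coerce")
    bad = values.isna() & df[col].notna() | df[col].isna()
    if bad.any():
        # +2: one for the header line, one for 0-based indexing
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ParseError(f"non-numeric {role} value {df[col].iloc[row - 2]!r} at row {row}")
    return values.astype(float)


def convert_units(time, temperature, fmt: CsvFormat):
    """Normalise raw time/temperature arrays to seconds and kelvin.

    Idempotent on already-normalised data when ``time_unit='s'`` and the
    temperatures are in kelvin (auto-detection leaves values >= 150 alone).
    """
    time = np.asarray(time, dtype=float)
    temperature = np.asarray(temperature, dtype=float)
    if fmt.time_unit == "min":
        time = time * 60.0
    if fmt.temperature_unit == "C":
        temperature = temperature + 273.15
    elif fmt.temperature_unit == "auto":
        temperature = np.where(temperature < CELSIUS_THRESHOLD, temperature + 273.15, temperature)
    return time, temperature


def parse_instrument_csv(
    path: str | Path, fmt: CsvFormat | None = None
) -> dict[str, pd.DataFrame]:
    """Parse a long-form instrument CSV into per-cuvette reading tables.

    Returns a dict mapping cuvette id to a DataFrame with columns
    ``time_s``, ``temperature_K``, ``absorbance``, sorted by time.

    Raises
    ------
    ConfigurationError
        if a mapped column is absent.
    ParseError
        if a cell in a numeric column is not a number (names the row).
    ValidationError
        if a cuvette has duplicate timestamps or non-positive temperatures.
    """
    fmt = fmt or CsvFormat()
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    try:
        raw = pd.read_csv(path, sep=fmt.delimiter, decimal=fmt.decimal, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"empty input file: {path}") from exc
    if raw.empty:
        raise ParseError(f"no data rows in {path}")

    sample_col = _resolve_column(raw, fmt.columns.sample, "sample")
    time_col = _resolve_column(raw, fmt.columns.time, "time")
    temp_col = _resolve_column(raw, fmt.columns.temperature, "temperature")
    abs_col = _resolve_column(raw, fmt.columns.absorbance, "absorbance")

    time = _coerce_numeric(raw, time_col, "time")
    temperature = _coerce_numeric(raw, temp_col, "temperature")
    absorbance = _coerce_numeric(raw, abs_col, "absorbance")
    time_s, temperature_K = convert_units(time.to_numpy(), temperature.to_numpy(), fmt)

    table = pd.DataFrame(
        {
            "cuvette_id": raw[sample_col].astype(str),
            "time_s": time_s,
            "temperature_K": temperature_K,
            "absorbance": absorbance.to_numpy(),
        }
    )
    if (table["temperature_K"] <= 0).any():
        raise ValidationError("non-physical temperature <= 0 K after unit conversion")

    groups: dict[str, pd.DataFrame] = {}
    for cid in table["cuvette_id"].unique():
        g = (
            table.loc[table["cuvette_id"] == cid, ["time_s", "temperature_K", "absorbance"]]
            .sort_values("time_s", kind="stable")
            .reset_index(drop=True)
        )
        if g["time_s"].duplicated().any():
            t_dup = float(g.loc[g["time_s"].duplicated(), "time_s"].iloc[0])
            raise ValidationError(f"duplicate reading time {t_dup} s for cuvette {cid!r}")
        if (g["time_s"] < 0).any():
            raise ValidationError(f"negative time for cuvette {cid!r}")
        groups[str(cid)] = g
    return groups


def to_concentrations(
    readings: pd.DataFrame,
    cuvette_id: str,
    design: AssayDesign,
    tolerance: float = 0.05,
) -> CuvetteTrace:
    """Convert one cuvette's absorbance readings to a concentration trace.

    Beer–Lambert: ``product = (A - baseline) / (epsilon * l)``;
    ``substrate = S0 - product``. Product concentrations outside
    ``[-tol*S0, (1+tol)*S0]`` are flagged ``out_of_range`` and retained
    (dropping is deferred to explicit temperature cut-offs downstream).
    """
    if cuvette_id not in design.s0:
        raise ValidationError(f"no initial substrate concentration (S0) for cuvette {cuvette_id!r}")
    s0 = float(design.s0[cuvette_id])
    baseline = None
    if design.baseline is not None:
        baseline = design.baseline.get(cuvette_id)
    if baseline is None:
        baseline = float(readings["absorbance"].iloc[0])

    net = readings["absorbance"].to_numpy() - baseline
    product = net / (design.extinction_coefficient * design.path_length)
    substrate = s0 - product
    out_of_range = (product < -tolerance * s0) | (product > (1.0 + tolerance) * s0)
    n_bad = int(out_of_range.sum())
    if n_bad:
        logger.warning(
            "cuvette %s: %d reading(s) imply product outside [0, S0] beyond %.0f%% tolerance; "
            "flagged and retained",
            cuvette_id,
            n_bad,
            100 * tolerance,
        )
    data = pd.DataFrame(
        {
            "time_s": readings["time_s"].to_numpy(),
            "temperature_K": readings["temperature_K"].to_numpy(),
            "product_M": product,
            "substrate_M": substrate,
            "out_of_range": out_of_range,
        }
    )
    return CuvetteTrace(cuvette_id=str(cuvette_id), s0=s0, data=data)


def traces_from_readings(
    groups: Mapping[str, pd.DataFrame], design: AssayDesign, tolerance: float = 0.05
) -> list[CuvetteTrace]:
    """Convert all parsed cuvette groups to concentration traces."""
    return [to_concentrations(g, cid, design, tolerance) for cid, g in groups.items()]


def trace_table(traces: list[CuvetteTrace]) -> pd.DataFrame:
    """Tidy long-form table of all traces (cuvette_id, time_s, temperature_K, product_M, substrate_M)."""
    frames = []
    for tr in traces:
        f = tr.data[["time_s", "temperature_K", "product_M", "substrate_M"]].copy()
        f.insert(0, "cuvette_id", tr.cuvette_id)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)
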