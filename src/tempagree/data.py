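"""Measurement tables and paired differences for device-comparison studies.

The data model is long format: one row per (participant, device, time point)
with a temperature in degrees Celsius. Missing readings are represented as
NaN temperatures, never as sentinel numbers. All between-device statistics
operate on *complete pairs*: (participant, time) cells where both devices
under comparison have a valid reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, IntegrityError, SchemaError

#: Devices of the default study design: a dual-sensor heat-flux forehead
#: monitor, an oral electronic thermometer and a non-contact infrared
#: forehead thermometer.
DEFAULT_DEVICES: tuple[str, ...] = ("heat_flux", "oral", "infrared")

#: Default column names of the long-format CSV schema.
DEFAULT_SCHEMA: dict[str, str] = {
    "participant_id": "participant_id",
    "device": "device",
    "time_min": "time_min",
    "temp_c": "temp_c",
}

_CANONICAL_COLUMNS = ["participant_id", "device", "time_min", "temp_c"]

#: Readings at or below this temperature (degC) are treated as device
#: artefacts rather than physiology and removed by the plausibility filter.
PLAUSIBILITY_THRESHOLD_C = 34.0


@dataclass
class LoadSummary:
    """Bookkeeping from a CSV load."""

    n_rows: int
    n_valid: int
    n_missing: int
    n_unparseable: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class MeasurementTable:
    """Long-format repeated temperature readings.

    Parameters
    ----------
    data : DataFrame
        Columns ``participant_id`` (str), ``device`` (str), ``time_min``
        (int, minutes since spinal anaesthesia), ``temp_c`` (float degC,
        NaN = missing reading).
    devices : tuple of str
        The declared device set; every ``device`` value must belong to it.
    provenance : str
        Free-text source label.
    """

    data: pd.DataFrame
    devices: tuple[str, ...] = DEFAULT_DEVICES
    provenance: str = ""
    load_summary: LoadSummary | None = None

    def __post_init__(self) -> None:
        df = self.data.reset_index(drop=True).copy()
        missing = [c for c in _CANONICAL_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        df = df[_CANONICAL_COLUMNS]
        df["participant_id"] = df["participant_id"].astype(str)
        df["device"] = df["device"].astype(str)
        df["time_min"] = df["time_min"].astype(int)
        df["temp_c"] = pd.to_numeric(df["temp_c"], errors="raise").astype(float)
        self.devices = tuple(self.devices)

        unknown = set(df["device"]) - set(self.devices)
        if unknown:
            raise SchemaError(
                f"device values {sorted(unknown)} not in declared set {self.devices}"
            )
        if (df["time_min"] < 0).any():
            raise IntegrityError("time_min must be non-negative")
        finite = np.isfinite(df["temp_c"].to_numpy())
        isnan = df["temp_c"].isna().to_numpy()
        if (~finite & ~isnan).any():
            raise IntegrityError("temp_c must be finite or missing (NaN)")

        dup = df.duplicated(subset=["participant_id", "device", "time_min"])
        if dup.any():
            key = df.loc[dup.idxmax(), ["participant_id", "device", "time_min"]]
            raise IntegrityError(
                "duplicate reading for (participant_id=%s, device=%s, time_min=%d)"
                % (key["participant_id"], key["device"], key["time_min"])
            )
        self.data = df

    # -- simple views ----------------------------------------------------
    @property
    def n_records(self) -> int:
        return len(self.data)

    @property
    def n_missing(self) -> int:
        return int(self.data["temp_c"].isna().sum())

    @property
    def participants(self) -> list[str]:
        return sorted(self.data["participant_id"].unique())

    @property
    def time_points(self) -> list[int]:
        return sorted(self.data["time_min"].unique())

    def copy(self) -> "MeasurementTable":
        return replace(self, data=self.data.copy())


@dataclass
class PairedDifferenceSet:
    """Complete paired readings for one ordered device pair.

    ``diff`` is always first-named device minus second-named device and
    ``pair_mean`` the arithmetic mean of the two readings. Swapping the
    device order negates every diff and leaves pair means unchanged.
    """

    device_a: str
    device_b: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        cols = ["participant_id", "time_min", "value_a", "value_b", "pair_mean", "diff"]
        self.data = self.data.reset_index(drop=True)[cols]

    @property
    def n_pairs(self) -> int:
        return len(self.data)

    @property
    def n_participants(self) -> int:
        return self.data["participant_id"].nunique()

    @property
    def diff(self) -> np.ndarray:
        return self.data["diff"].to_numpy()

    @property
    def pair_mean(self) -> np.ndarray:
        return self.data["pair_mean"].to_numpy()

    @property
    def label(self) -> str:
        return f"{self.device_a} vs {self.device_b}"

    def swapped(self) -> "PairedDifferenceSet":
        df = self.data.rename(columns={"value_a": "value_b", "value_b": "value_a"}).copy()
        df["diff"] = -df["diff"]
        return PairedDifferenceSet(self.device_b, self.device_a, df)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_measurements(
    path,
    schema: dict[str, str] | None = None,
    devices: tuple[str, ...] = DEFAULT_DEVICES,
    provenance: str | None = None,
) -> MeasurementTable:
    """Read a long-format CSV of temperature readings.

    ``schema`` maps canonical field names (participant_id, device, time_min,
    temp_c) to the column names used in the file. Unparseable temperature
    cells become missing readings and are counted in ``table.load_summary``.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        unknown = set(schema) - set(DEFAULT_SCHEMA)
        if unknown:
            raise SchemaError(f"unknown schema keys: {sorted(unknown)}")
        colmap.update(schema)

    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [v for v in colmap.values() if v not in raw.columns]
    if missing_cols:
        raise SchemaError(
            f"file {path!r} lacks required columns {missing_cols}; found {list(raw.columns)}"
        )
    df = pd.DataFrame(
        {canon: raw[col] for canon, col in colmap.items()}
    )
    raw_temp = df["temp_c"].str.strip()
    parsed = pd.to_numeric(raw_temp, errors="coerce")
    na_like = raw_temp.str.lower().isin({"", "na", "nan", "null", "none", "."})
    n_unparseable = int((parsed.isna() & ~na_like).sum())
    df["temp_c"] = parsed
    try:
        df["time_min"] = pd.to_numeric(df["time_min"], errors="raise").astype(int)
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"time column is not integer minutes: {exc}") from None

    table = MeasurementTable(
        data=df,
        devices=devices,
        provenance=provenance if provenance is not None else str(path),
    )
    table.load_summary = LoadSummary(
        n_rows=len(df),
        n_valid=len(df) - int(parsed.isna().sum()),
        n_missing=int(parsed.isna().sum()),
        n_unparseable=n_unparseable,
    )
    return table


def write_measurements(table: MeasurementTable, path, precision: int | None = None) -> None:
    """Write a table back to CSV (UTF-8, header row).

    With ``precision`` given, temperatures are written rounded to that many
    decimals; otherwise at full float repr so a round-trip is bit-exact.
    """
    df = table.data.copy()
    fmt = None if precision is None else f"%.{precision}f"
    df.to_csv(path, index=False, float_format=fmt)


# ---------------------------------------------------------------------------
# Filtering / restructuring
# ---------------------------------------------------------------------------

def apply_plausibility_filter(
    table: MeasurementTable, threshold: float = PLAUSIBILITY_THRESHOLD_C
) -> tuple[MeasurementTable, int]:
    """Remove clearly erroneous readings at or below ``threshold`` degC.

    The boundary is inclusive: a reading of exactly ``threshold`` is removed.
    Removed readings become missing; the original table is untouched.
    Idempotent: filtering twice removes nothing the second time.
    """
    if not np.isfinite(threshold):
        raise ConfigurationError("plausibility threshold must be finite")
    df = table.data.copy()
    bad = df["temp_c"].notna() & (df["temp_c"] <= threshold)
    df.loc[bad, "temp_c"] = np.nan
    out = MeasurementTable(df, devices=table.devices, provenance=table.provenance)
    return out, int(bad.sum())


def drop_time_point(table: MeasurementTable, time_min: int) -> MeasurementTable:
    """Return a table without any records at the given time point."""
    df = table.data[table.data["time_min"] != int(time_min)].copy()
    return MeasurementTable(df, devices=table.devices, provenance=table.provenance)


def pair_differences(
    table: MeasurementTable, device_a: str, device_b: str
) -> PairedDifferenceSet:
    """Build complete pairs for two devices.

    One row per (participant, time) where both devices have a non-missing
    reading; ``diff = value_a - value_b``.
    """
    if device_a == device_b:
        raise ConfigurationError("device_a and device_b must differ")
    for dev in (device_a, device_b):
        if dev not in table.devices:
            raise ConfigurationError(
                f"unknown device {dev!r}; declared devices: {table.devices}"
            )
    df = table.data.dropna(subset=["temp_c"])
    wide = df.pivot_table(
        index=["participant_id", "time_min"],
        columns="device",
        values="temp_c",
        aggfunc="first",
    )
    for dev in (device_a, device_b):
        if dev not in wide.columns:
            wide[dev] = np.nan
    both = wide[[device_a, device_b]].dropna()
    out = both.reset_index().rename(columns={device_a: "value_a", device_b: "value_b"})
    out["pair_mean"] = (out["value_a"] + out["value_b"]) / 2.0
    out["diff"] = out["value_a"] - out["value_b"]
    out = out.sort_values(["participant_id", "time_min"], kind="mergesort")
    return PairedDifferenceSet(device_a, device_b, out)
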