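"""Tidy CSV formats and pipeline configuration.

All tables are plain UTF-8 CSV with a mandatory header, "." decimal point
and no locale-dependent parsing. The central exchange format is the long
time-series table with columns ``time_h, channel, value, unit``; channel
names are ``co2_cum | co2_rate | biomass | ethanol | consumed_sugar |
temperature | aa:<name> | gas:<compound>``. Heterogeneous sampling grids
per channel are the reason for the long layout.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

TIMESERIES_COLUMNS = ("time_h", "channel", "value", "unit")
KNOWN_CHANNELS = (
    "co2_cum",
    "co2_rate",
    "biomass",
    "ethanol",
    "consumed_sugar",
    "temperature",
)


class FormatError(ValueError):
    """Malformed input table."""


@dataclass
class PipelineConfig:
    """Numeric knobs of the full pipeline; serialises losslessly to YAML."""

    sugar_per_co2: float = 180.0 / 88.0
    ethanol_per_co2: float = 92.0 / 88.0
    R: float = 8.314
    T_ref: float = 293.15
    aa0_threshold: float = 0.01
    span_grid: tuple[float, ...] = (0.1, 0.15, 0.2, 0.3, 0.4, 0.5, 0.7)
    max_phases: int = 4
    n_boot: int = 10_000
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self):
        for name in ("sugar_per_co2", "ethanol_per_co2", "R", "T_ref",
                     "aa0_threshold", "ci_level"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_phases < 1 or self.n_boot < 1:
            raise ValueError("max_phases and n_boot must be >= 1")
        self.span_grid = tuple(float(s) for s in self.span_grid)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["span_grid"] = list(d["span_grid"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def read_timeseries(path: str | Path) -> pd.DataFrame:
    """Read a tidy time-series CSV, validating columns and uniqueness."""
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = set(TIMESERIES_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    dup = frame.duplicated(subset=["time_h", "channel"])
    if dup.any():
        row = frame[dup].iloc[0]
        raise FormatError(
            f"{path}: duplicate (time_h, channel) pair at t={row['time_h']}, "
            f"channel={row['channel']!r}"
        )
    units = frame.groupby("channel")["unit"].nunique()
    bad = units[units > 1]
    if len(bad):
        raise FormatError(f"{path}: inconsistent units within channels {list(bad.index)}")
    return frame


def write_timeseries(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False, columns=list(TIMESERIES_COLUMNS))


def channel(frame: pd.DataFrame, name: str) -> pd.DataFrame:
    """Extract one channel as (time_h, value), sorted by time."""
    sub = frame[frame["channel"] == name]
    if sub.empty:
        raise KeyError(f"required channel {name!r} not found")
    return sub.sort_values("time_h")[["time_h", "value"]].reset_index(drop=True)


def gas_channels(frame: pd.DataFrame) -> pd.DataFrame:
    """All gas:<compound> channels as a long (compound, time_h, C_gas) table."""
    sub = frame[frame["channel"].str.startswith("gas:")].copy()
    sub["compound"] = sub["channel"].str.removeprefix("gas:")
    sub = sub.rename(columns={"value": "C_gas"})
    return sub[["compound", "time_h", "C_gas"]].reset_index(drop=True)


def aa_channels(frame: pd.DataFrame) -> pd.DataFrame:
    sub = frame[frame["channel"].str.startswith("aa:")].copy()
    sub["aa"] = sub["channel"].str.removeprefix("aa:")
    sub = sub.rename(columns={"value": "concentration"})
    return sub[["aa", "time_h", "concentration"]].reset_index(drop=True)


def read_partition_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = {"compound", "F1", "F2", "F3", "F4"} - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: partition table missing columns {sorted(missing)}")
    return frame
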