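"""Reading, validation, and writing of GPS fix tables.

Fix tables are delimited text with a header and at least animal id,
timestamp, and projected planar coordinates in meters.  Timestamps are
local standard time (no daylight-saving shifts).  On read, each animal's
record is placed on a nominal acquisition grid (default 240 min between
fixes); scheduled slots with no usable observation become invalid
placeholder fixes, so downstream code can account for fix success.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

DEFAULT_INTERVAL_MIN = 240.0
DEFAULT_TOLERANCE_MIN = 15.0

#: default source-column names; override via ``column_map``
DEFAULT_COLUMNS = {
    "animal_id": "animal_id",
    "timestamp": "timestamp",
    "x": "x",
    "y": "y",
    "valid": "valid",
}

_GEOGRAPHIC_NAMES = {
    "lon", "lng", "long", "longitude", "lat", "latitude",
}


@dataclass(frozen=True)
class Fix:
    """A single scheduled GPS acquisition.

    Invalid fixes (failed acquisitions or excluded off-grid observations)
    carry NaN coordinates.
    """

    animal_id: str
    seq: int
    timestamp: pd.Timestamp
    x: float
    y: float
    valid: bool

    def __post_init__(self) -> None:
        if self.valid and not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise DataError(
                f"valid fix {self.animal_id}#{self.seq} has non-finite coordinates"
            )


@dataclass
class Trajectory:
    """Ordered fixes for one animal on a nominal temporal grid.

    ``fixes`` is a DataFrame with columns seq, timestamp, x, y, valid,
    one row per scheduled slot, timestamps strictly increasing.
    """

    animal_id: str
    fixes: pd.DataFrame
    nominal_interval: float = DEFAULT_INTERVAL_MIN

    def __post_init__(self) -> None:
        ts = self.fixes["timestamp"]
        if not ts.is_monotonic_increasing or ts.duplicated().any():
            raise DataError(f"{self.animal_id}: timestamps not strictly increasing")
        bad = self.fixes["valid"] & ~(
            np.isfinite(self.fixes["x"]) & np.isfinite(self.fixes["y"])
        )
        if bad.any():
            raise DataError(f"{self.animal_id}: valid fixes with missing coordinates")

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def n_scheduled(self) -> int:
        return len(self.fixes)

    @property
    def n_valid(self) -> int:
        return int(self.fixes["valid"].sum())

    @property
    def fix_success_rate(self) -> float:
        """Valid fixes / scheduled slots in [0, 1]."""
        return self.n_valid / self.n_scheduled if self.n_scheduled else float("nan")

    def fix(self, seq: int) -> Fix:
        row = self.fixes.iloc[seq]
        return Fix(
            self.animal_id, int(row["seq"]), row["timestamp"],
            float(row["x"]), float(row["y"]), bool(row["valid"]),
        )

    def valid_mask(self) -> np.ndarray:
        return self.fixes["valid"].to_numpy(bool)

    def coords(self) -> np.ndarray:
        return self.fixes[["x", "y"]].to_numpy(float)

    def minutes(self) -> np.ndarray:
        """Elapsed minutes from the first scheduled slot."""
        ts = self.fixes["timestamp"]
        return ((ts - ts.iloc[0]).dt.total_seconds() / 60.0).to_numpy()


@dataclass(frozen=True)
class FieldVerification:
    """A field-verified site label linked to an animal and a fix reference."""

    animal_id: str
    ref: object  # int seq or pd.Timestamp
    observed_class: str  # "cache" | "non_feeding"

    def __post_init__(self) -> None:
        if self.observed_class not in ("cache", "non_feeding"):
            raise DataError(f"unknown verification class {self.observed_class!r}")


@dataclass
class ValidationReport:
    """Report-only summary of schedule conformance for one trajectory."""

    animal_id: str
    n_scheduled: int
    n_valid: int
    fix_success_rate: float
    gap_runs: list = field(default_factory=list)  # (start_seq, length)
    off_grid: list = field(default_factory=list)  # (seq, offset_minutes)

    @property
    def issues(self) -> list:
        out = [f"gap run at seq {s} length {n}" for s, n in self.gap_runs]
        out += [f"off-grid timestamp at seq {s} ({off:+.1f} min)" for s, off in self.off_grid]
        return out

    def to_dict(self) -> dict:
        return {
            "animal_id": self.animal_id,
            "n_scheduled": self.n_scheduled,
            "n_valid": self.n_valid,
            "fix_success_rate": self.fix_success_rate,
            "gap_runs": list(self.gap_runs),
            "off_grid": list(self.off_grid),
        }

    def to_text(self) -> str:
        lines = [
            f"animal: {self.animal_id}",
            f"scheduled slots: {self.n_scheduled}",
            f"valid fixes: {self.n_valid}",
            f"fix success rate: {self.fix_success_rate:.3f}",
        ]
        lines += self.issues or ["no issues"]
        return "\n".join(lines)


def _check_projected(df: pd.DataFrame, xcol: str, ycol: str) -> None:
    if xcol.strip().lower() in _GEOGRAPHIC_NAMES or ycol.strip().lower() in _GEOGRAPHIC_NAMES:
        raise ConfigurationError(
            f"columns {xcol!r}/{ycol!r} look like geographic coordinates; "
            "metrics require projected planar meters — project first or rename"
        )


def _grid_fill(
    animal_id: str,
    obs: pd.DataFrame,
    nominal_interval: float,
    tolerance: float,
) -> tuple[pd.DataFrame, list]:
    """Place observations on the nominal grid spanning first..last timestamp.

    An observation within ``tolerance`` minutes of a slot keeps its own
    timestamp; between tolerance and 2x tolerance it is snapped to the slot
    time; farther off it is excluded (the slot stays an invalid
    placeholder).  Returns (grid frame, off_grid list of (seq, offset)).
    """
    t0 = obs["timestamp"].iloc[0]
    t_end = obs["timestamp"].iloc[-1]
    step = pd.Timedelta(minutes=nominal_interval)
    n_slots = int(round((t_end - t0) / step)) + 1
    slots = t0 + step * np.arange(n_slots)

    out = pd.DataFrame(
        {
            "seq": np.arange(n_slots),
            "timestamp": slots,
            "x": np.nan,
            "y": np.nan,
            "valid": False,
        }
    )
    off_grid: list = []
    best_offset = np.full(n_slots, np.inf)
    for _, row in obs.iterrows():
        k = int(round((row["timestamp"] - t0) / step))
        k = min(max(k, 0), n_slots - 1)
        off = (row["timestamp"] - slots[k]).total_seconds() / 60.0
        if abs(off) > 2 * tolerance:
            off_grid.append((k, float(off)))
            continue
        if abs(off) >= best_offset[k]:
            raise DataError(
                f"{animal_id}: two observations map to scheduled slot {k}"
            )
        best_offset[k] = abs(off)
        out.loc[k, ["x", "y"]] = row["x"], row["y"]
        out.loc[k, "valid"] = bool(row.get("valid", True)) and math.isfinite(row["x"])
        # within tolerance: keep the observed timestamp; else snap to slot
        if abs(off) <= tolerance:
            out.loc[k, "timestamp"] = row["timestamp"]
    return out, off_grid


def read_fix_table(
    path,
    column_map: dict | None = None,
    delimiter: str = ",",
    timestamp_format: str | None = None,
    nominal_interval: float = DEFAULT_INTERVAL_MIN,
    tolerance: float = DEFAULT_TOLERANCE_MIN,
) -> list[Trajectory]:
    """Read a delimited fix table into one grid-filled Trajectory per animal.

    Parameters
    ----------
    path : file path
    column_map : mapping of logical names {animal_id, timestamp, x, y,
        [valid]} to source column names; defaults to the logical names.
    timestamp_format : strptime format; default ISO 8601 autodetection.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if column_map:
        colmap.update(column_map)
    raw = pd.read_csv(path, sep=delimiter)
    required = ["animal_id", "timestamp", "x", "y"]
    missing = [colmap[k] for k in required if colmap[k] not in raw.columns]
    if missing:
        raise ConfigurationError(f"missing mapped columns: {missing}")
    _check_projected(raw, colmap["x"], colmap["y"])

    df = pd.DataFrame(
        {
            "animal_id": raw[colmap["animal_id"]].astype(str),
            "timestamp": pd.to_datetime(
                raw[colmap["timestamp"]], format=timestamp_format
            ),
            "x": pd.to_numeric(raw[colmap["x"]], errors="coerce"),
            "y": pd.to_numeric(raw[colmap["y"]], errors="coerce"),
        }
    )
    if colmap["valid"] in raw.columns:
        df["valid"] = raw[colmap["valid"]].astype(bool)
    else:
        df["valid"] = np.isfinite(df["x"]) & np.isfinite(df["y"])
    df.loc[~df["valid"], ["x", "y"]] = np.nan

    if df.duplicated(subset=["animal_id", "timestamp"]).any():
        dup = df[df.duplicated(subset=["animal_id", "timestamp"], keep=False)]
        raise DataError(
            f"duplicate (animal, timestamp) rows: {dup['animal_id'].unique().tolist()}"
        )

    trajectories = []
    for animal_id, grp in df.groupby("animal_id", sort=True):
        grp = grp.sort_values("timestamp").reset_index(drop=True)
        # drop fully-invalid leading/trailing rows only if coordinates absent
        usable = grp[grp["valid"]]
        if usable.empty:
            raise DataError(f"{animal_id}: no valid fixes")
        grid, off_grid = _grid_fill(
            animal_id, grp[grp["valid"]], nominal_interval, tolerance
        )
        traj = Trajectory(str(animal_id), grid, nominal_interval)
        traj._off_grid = off_grid  # retained for validate_trajectory
        trajectories.append(traj)
    return trajectories


def write_fix_table(trajectories: list[Trajectory], path, delimiter: str = ",") -> None:
    """Write trajectories to delimited text round-trippable by read_fix_table."""
    frames = []
    for traj in trajectories:
        df = traj.fixes.copy()
        df.insert(0, "animal_id", traj.animal_id)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, sep=delimiter, index=False)


def validate_trajectory(
    traj: Trajectory, tolerance: float = DEFAULT_TOLERANCE_MIN
) -> ValidationReport:
    """Report gap runs, off-grid timestamps, and fix success; never mutates."""
    valid = traj.valid_mask()
    gap_runs = []
    i = 0
    n = len(valid)
    while i < n:
        if not valid[i]:
            j = i
            while j < n and not valid[j]:
                j += 1
            gap_runs.append((i, j - i))
            i = j
        else:
            i += 1

    t0 = traj.fixes["timestamp"].iloc[0]
    mins = traj.minutes()
    offsets = mins - np.round(mins / traj.nominal_interval) * traj.nominal_interval
    off_grid = [
        (int(s), float(off))
        for s, off in zip(traj.fixes["seq"], offsets)
        if abs(off) > tolerance
    ]
    off_grid += list(getattr(traj, "_off_grid", []))

    return ValidationReport(
        animal_id=traj.animal_id,
        n_scheduled=traj.n_scheduled,
        n_valid=traj.n_valid,
        fix_success_rate=traj.fix_success_rate,
        gap_runs=gap_runs,
        off_grid=off_grid,
    )


def read_verification_table(
    path,
    delimiter: str = ",",
    label_map: dict | None = None,
) -> list[FieldVerification]:
    """Read field-verification records (animal_id, seq or timestamp, class).

    ``label_map`` translates site labels (e.g. {"kill": "cache"}) before the
    two-category check.
    """
    raw = pd.read_csv(path, sep=delimiter)
    if raw.empty:
        return []
    if "animal_id" not in raw.columns or "observed_class" not in raw.columns:
        raise ConfigurationError("verification table needs animal_id and observed_class")
    if "seq" not in raw.columns and "timestamp" not in raw.columns:
        raise ConfigurationError("verification table needs a seq or timestamp column")

    records = []
    for _, row in raw.iterrows():
        label = str(row["observed_class"]).strip()
        if label_map and label in label_map:
            label = label_map[label]
        if label not in ("cache", "non_feeding"):
            raise DataError(f"unknown verification label {label!r}")
        if "seq" in raw.columns and not pd.isna(row["seq"]):
            ref: object = int(row["seq"])
        else:
            ref = pd.to_datetime(row["timestamp"])
        records.append(FieldVerification(str(row["animal_id"]), ref, label))
    return records
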