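"""Per-fix movement metrics and the composite movement index.

Four metrics are computed at each interior fix t0 from its valid temporal
neighbors t-1 and t+1:

* speed: mean of the two step displacements divided by their elapsed times
  (meters/minute);
* turning: absolute turn angle at t0 divided by 180 degrees;
* straightness: (d1 + d2) / chord — 1 for straight travel, large for
  out-and-back recursion;
* site fidelity: mean distance to valid fixes within a spatial radius
  (default 100 m) and temporal window (default +/- 8 weeks), weighted by
  the fraction of the maximum possible in-window fixes present; 0 when no
  neighbor qualifies.

Speed, straightness, and fidelity are rescaled per animal (speed and
fidelity by the observed maximum; straightness by its 90th percentile with
the top decile capped at 1).  The composite index is
(1 - speed_std) + turn_std + straightness_std + fidelity_std in [0, 4]:
low means fast straight travel through novel areas, high means slow
tortuous movement in a frequently revisited place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import DataError
from .telemetry import Trajectory

#: chord lengths below this (meters) make straightness unbounded; the record
#: gets a capped-high sentinel that standardizes to 1
CHORD_FLOOR_M = 1.0
CAPPED_HIGH = math.inf


@dataclass(frozen=True)
class StepGeometry:
    """Geometry of the two steps around an interior fix."""

    d1: float  # meters, t-1 -> t0
    d2: float  # meters, t0 -> t+1
    c: float   # meters, chord t-1 -> t+1
    dt1: float  # minutes
    dt2: float  # minutes
    turn_deg: float  # absolute turn at t0, [0, 180]

    def __post_init__(self) -> None:
        if self.dt1 <= 0 or self.dt2 <= 0:
            raise DataError("non-positive elapsed time in step geometry")
        if self.c > self.d1 + self.d2 + 1e-6:
            raise DataError("chord exceeds path length (triangle inequality)")


@dataclass
class MetricRecord:
    """Raw and standardized metrics for one fix."""

    seq: int
    speed: float = math.nan            # m/min
    ta_standard: float = math.nan      # [0, 1]
    straightness_raw: float = math.nan  # >= 1 or CAPPED_HIGH
    site_fidelity_raw: float = math.nan
    speed_std: float = math.nan
    straightness_std: float = math.nan
    fidelity_std: float = math.nan
    defined: bool = False


@dataclass
class MetricConfig:
    """Tunable parameters for metric computation."""

    fidelity_radius: float = 100.0          # meters
    fidelity_window_min: float = 8 * 7 * 24 * 60.0  # +/- 8 weeks, minutes
    max_possible_neighbors: int | None = None  # default 2*window/interval
    max_gap_factor: float = 2.0             # gaps > factor*interval undefine Eqs 1-3
    chord_floor: float = CHORD_FLOOR_M
    turn_by_animal_max: bool = False        # literal per-animal-max rescale of turning

    def resolved_max_neighbors(self, nominal_interval: float) -> int:
        if self.max_possible_neighbors is not None:
            return self.max_possible_neighbors
        return int(round(2 * self.fidelity_window_min / nominal_interval))


@dataclass
class ScalingConstants:
    """Per-animal rescaling constants for the composite index."""

    animal_id: str
    max_speed: float
    straightness_p90: float
    max_fidelity: float
    fidelity_radius: float = 100.0
    fidelity_window_min: float = 8 * 7 * 24 * 60.0
    max_possible_neighbors: int = 672

    def to_dict(self) -> dict:
        return asdict(self)


def _neighbor_indices(traj: Trajectory, seq: int, d1_ok: bool = True):
    """Indices of the nearest valid fixes before and after ``seq``."""
    valid = traj.valid_mask()
    prev_idx = next_idx = None
    for i in range(seq - 1, -1, -1):
        if valid[i]:
            prev_idx = i
            break
    for i in range(seq + 1, len(valid)):
        if valid[i]:
            next_idx = i
            break
    return prev_idx, next_idx


def step_geometry(
    traj: Trajectory, seq: int, config: MetricConfig | None = None
) -> StepGeometry | None:
    """Geometry at fix ``seq``, or None when the gap policy is violated.

    t-1 and t+1 are the nearest valid fixes before and after t0; if either
    is missing, or either elapsed gap exceeds ``max_gap_factor`` nominal
    intervals, the fix has no defined geometry.
    """
    config = config or MetricConfig()
    valid = traj.valid_mask()
    if seq < 0 or seq >= len(valid) or not valid[seq]:
        return None
    prev_idx, next_idx = _neighbor_indices(traj, seq)
    if prev_idx is None or next_idx is None:
        return None
    mins = traj.minutes()
    dt1 = mins[seq] - mins[prev_idx]
    dt2 = mins[next_idx] - mins[seq]
    max_gap = config.max_gap_factor * traj.nominal_interval
    if dt1 > max_gap + 1e-9 or dt2 > max_gap + 1e-9:
        return None
    xy = traj.coords()
    p_prev, p0, p_next = xy[prev_idx], xy[seq], xy[next_idx]
    d1 = float(np.hypot(*(p0 - p_prev)))
    d2 = float(np.hypot(*(p_next - p0)))
    c = float(np.hypot(*(p_next - p_prev)))
    turn = _turn_angle_deg(p_prev, p0, p_next)
    return StepGeometry(d1=d1, d2=d2, c=c, dt1=float(dt1), dt2=float(dt2), turn_deg=turn)


def _turn_angle_deg(p_prev, p0, p_next) -> float:
    """Absolute heading change at p0 in [0, 180]; 0 if either step is null."""
    v1 = p0 - p_prev
    v2 = p_next - p0
    if np.hypot(*v1) < 1e-12 or np.hypot(*v2) < 1e-12:
        return 0.0
    h1 = math.atan2(v1[1], v1[0])
    h2 = math.atan2(v2[1], v2[0])
    d = math.degrees(h2 - h1)
    d = (d + 180.0) % 360.0 - 180.0
    return abs(d)


def speed_at(geom: StepGeometry) -> float:
    """Mean of the two step speeds, meters/minute."""
    return (geom.d1 / geom.dt1 + geom.d2 / geom.dt2) / 2.0


def turn_standard(geom: StepGeometry) -> float:
    """Absolute turn angle scaled by 180 degrees, in [0, 1]."""
    return abs(geom.turn_deg) / 180.0


def straightness(geom: StepGeometry, chord_floor: float = CHORD_FLOOR_M) -> float:
    """(d1 + d2) / chord; capped-high sentinel when the chord ~ vanishes."""
    if geom.c < chord_floor:
        return CAPPED_HIGH
    return (geom.d1 + geom.d2) / geom.c


def site_fidelity(
    traj: Trajectory, seq: int, constants: ScalingConstants | MetricConfig | None = None
) -> float:
    """Spatiotemporal clustering value at one fix (brute-force path).

    Neighbors are valid fixes other than self within the spatial radius and
    the forward/backward temporal window.  With no neighbor the value is 0;
    otherwise it is the mean self-to-neighbor distance times the fraction of
    the maximum possible in-window fixes present.
    """
    radius, window, max_poss = _fidelity_params(traj, constants)
    valid = traj.valid_mask()
    if not valid[seq]:
        return math.nan
    xy = traj.coords()
    mins = traj.minutes()
    d = np.hypot(xy[:, 0] - xy[seq, 0], xy[:, 1] - xy[seq, 1])
    dt = np.abs(mins - mins[seq])
    mask = valid & (d <= radius) & (dt <= window)
    mask[seq] = False
    k = int(mask.sum())
    if k == 0:
        return 0.0
    return float(d[mask].mean() * (k / max_poss))


def _fidelity_params(traj: Trajectory, constants) -> tuple[float, float, int]:
    if isinstance(constants, ScalingConstants):
        return (
            constants.fidelity_radius,
            constants.fidelity_window_min,
            constants.max_possible_neighbors,
        )
    config = constants or MetricConfig()
    return (
        config.fidelity_radius,
        config.fidelity_window_min,
        config.resolved_max_neighbors(traj.nominal_interval),
    )


def _site_fidelity_all(traj: Trajectory, config: MetricConfig) -> np.ndarray:
    """Vectorized site fidelity for every fix via a KD-tree radius query."""
    radius = config.fidelity_radius
    window = config.fidelity_window_min
    max_poss = config.resolved_max_neighbors(traj.nominal_interval)
    valid = traj.valid_mask()
    xy = traj.coords()
    mins = traj.minutes()
    out = np.full(len(valid), np.nan)
    vidx = np.flatnonzero(valid)
    if len(vidx) == 0:
        return out
    tree = cKDTree(xy[vidx])
    neighbor_lists = tree.query_ball_tree(tree, r=radius)
    for a, neigh in enumerate(neighbor_lists):
        i = vidx[a]
        js = vidx[np.sort(np.array(neigh, dtype=int))]
        js = js[(js != i) & (np.abs(mins[js] - mins[i]) <= window)]
        if len(js) == 0:
            out[i] = 0.0
            continue
        dist = np.hypot(xy[js, 0] - xy[i, 0], xy[js, 1] - xy[i, 1])
        out[i] = dist.mean() * (len(js) / max_poss)
    return out


def compute_metrics(traj: Trajectory, config: MetricConfig | None = None) -> pd.DataFrame:
    """Raw metrics for every scheduled fix.

    Returns a DataFrame aligned to the trajectory grid with columns seq,
    timestamp, speed, turn_deg, ta_standard, straightness_raw,
    site_fidelity_raw, defined.  ``defined`` is True only where the full
    t-1/t0/t+1 geometry exists under the gap policy.
    """
    config = config or MetricConfig()
    n = len(traj)
    df = pd.DataFrame(
        {
            "seq": traj.fixes["seq"].to_numpy(),
            "timestamp": traj.fixes["timestamp"].to_numpy(),
            "speed": np.nan,
            "turn_deg": np.nan,
            "ta_standard": np.nan,
            "straightness_raw": np.nan,
            "site_fidelity_raw": _site_fidelity_all(traj, config),
            "defined": False,
        }
    )
    for i in range(n):
        geom = step_geometry(traj, i, config)
        if geom is None:
            continue
        df.loc[i, "speed"] = speed_at(geom)
        df.loc[i, "turn_deg"] = geom.turn_deg
        df.loc[i, "ta_standard"] = turn_standard(geom)
        df.loc[i, "straightness_raw"] = straightness(geom, config.chord_floor)
        df.loc[i, "defined"] = True
    df["defined"] &= np.isfinite(df["site_fidelity_raw"])
    return df


def _percentile_with_sentinels(values: np.ndarray, q: float) -> float:
    """Linear-interpolation percentile treating capped-high sentinels as +inf.

    Falls back to the largest finite value if interpolation lands in the
    sentinel tail (all-sentinel upper decile).
    """
    with np.errstate(invalid="ignore"):
        p = float(np.percentile(values, q))
    if math.isfinite(p):
        return p
    finite = values[np.isfinite(values)]
    if len(finite) == 0:
        raise DataError("no finite straightness values to scale by")
    return float(finite.max())


def compute_scaling(
    metrics: pd.DataFrame,
    animal_id: str = "",
    config: MetricConfig | None = None,
    nominal_interval: float = 240.0,
) -> ScalingConstants:
    """Per-animal rescaling constants from a metrics table."""
    config = config or MetricConfig()
    d = metrics[metrics["defined"]]
    if d.empty:
        raise DataError("no defined metric records to scale from")
    return ScalingConstants(
        animal_id=animal_id,
        max_speed=float(d["speed"].max()),
        straightness_p90=_percentile_with_sentinels(
            d["straightness_raw"].to_numpy(float), 90.0
        ),
        max_fidelity=float(d["site_fidelity_raw"].max()),
        fidelity_radius=config.fidelity_radius,
        fidelity_window_min=config.fidelity_window_min,
        max_possible_neighbors=config.resolved_max_neighbors(nominal_interval),
    )


def standardize(
    metrics: pd.DataFrame,
    constants: ScalingConstants,
    config: MetricConfig | None = None,
) -> pd.DataFrame:
    """Add standardized columns (all in [0, 1]) and the composite index.

    speed_std = speed / max observed speed; straightness_std =
    straightness / p90 capped at 1 (the top decile maps to 1);
    fidelity_std = fidelity / max observed fidelity (0 when the maximum is
    0).  Turning is already on [0, 1]; an optional literal mode further
    divides by the per-animal maximum.
    """
    config = config or MetricConfig()
    df = metrics.copy()
    max_speed = constants.max_speed if constants.max_speed > 0 else 1.0
    df["speed_std"] = np.clip(df["speed"] / max_speed, 0.0, 1.0)
    p90 = constants.straightness_p90 if constants.straightness_p90 > 0 else 1.0
    df["straightness_std"] = np.minimum(df["straightness_raw"] / p90, 1.0)
    if constants.max_fidelity > 0:
        df["fidelity_std"] = np.clip(
            df["site_fidelity_raw"] / constants.max_fidelity, 0.0, 1.0
        )
    else:
        df["fidelity_std"] = np.where(np.isfinite(df["site_fidelity_raw"]), 0.0, np.nan)
    df["ta_std"] = df["ta_standard"]
    if config.turn_by_animal_max:
        ta_max = df.loc[df["defined"], "ta_standard"].max()
        if ta_max > 0:
            df["ta_std"] = df["ta_standard"] / ta_max
    df["index"] = np.where(
        df["defined"],
        (1.0 - df["speed_std"]) + df["ta_std"] + df["straightness_std"] + df["fidelity_std"],
        np.nan,
    )
    return df


def movement_index(metrics: pd.DataFrame, constants: ScalingConstants) -> np.ndarray:
    """Composite index in [0, 4] for a metrics table (NaN where undefined)."""
    return standardize(metrics, constants)["index"].to_numpy(float)


def movement_index_record(rec: MetricRecord, constants: ScalingConstants) -> float:
    """Composite index for a single record; NaN when the record is undefined."""
    if not rec.defined:
        return math.nan
    speed_std = min(rec.speed / constants.max_speed, 1.0) if constants.max_speed > 0 else 0.0
    s_std = min(rec.straightness_raw / constants.straightness_p90, 1.0)
    f_std = (
        min(rec.site_fidelity_raw / constants.max_fidelity, 1.0)
        if constants.max_fidelity > 0
        else 0.0
    )
    return (1.0 - speed_std) + rec.ta_standard + s_std + f_std


def write_metrics_table(metrics: pd.DataFrame, path, delimiter: str = ",") -> None:
    metrics.to_csv(path, sep=delimiter, index=False)
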