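"""Multi-state caching-forager simulator with ground-truth states.

The generator is semi-Markov: each behavioral episode draws an explicit
dwell time (in fixes), because the phenomenon of interest is dwell-time
structure — long residence at cache/den sites punctuated by short rest
excursions, versus fast straight travel between hunting grounds.

Movement mechanics per state:

* directed: a persistent heading perturbed by small wrapped (von Mises)
  turns, long gamma-distributed steps;
* search: shorter steps with weakly concentrated (wide) turns;
* cache / den: positions jitter inside a disc around an anchor point; with
  a configured probability the animal leaves for a rest site 0.5-3 km away
  for one or two fixes and then returns to the anchor.

Fix failures are Bernoulli per scheduled slot.  All randomness flows from
one seeded generator; outputs are byte-identical per seed.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError
from .raster import CovariateRaster
from .stepselection import UseAvailPair
from .telemetry import Trajectory


@dataclass
class StateParams:
    mean_speed: float        # meters/minute
    speed_dispersion: float  # gamma shape; larger = less variable
    turn_kappa: float        # von Mises concentration; large = straight
    dwell_mean: float        # mean episode length, fixes


@dataclass
class SimConfig:
    seed: int = 0
    duration_days: float = 180.0
    nominal_interval: float = 240.0   # minutes
    fix_success: float = 0.90
    start_time: str = "2020-01-01 01:00:00"
    animal_id: str = "SIM01"
    states: dict = field(default_factory=lambda: {
        "directed": StateParams(mean_speed=14.0, speed_dispersion=16.0,
                                turn_kappa=60.0, dwell_mean=12.0),
        "search": StateParams(mean_speed=4.0, speed_dispersion=3.0,
                              turn_kappa=0.8, dwell_mean=8.0),
        "cache": StateParams(mean_speed=0.0, speed_dispersion=1.0,
                             turn_kappa=0.0, dwell_mean=20.0),
        "den": StateParams(mean_speed=0.0, speed_dispersion=1.0,
                           turn_kappa=0.0, dwell_mean=60.0),
    })
    # episode-to-episode transition weights (self-transitions excluded)
    transitions: dict = field(default_factory=lambda: {
        "directed": {"search": 0.8, "cache": 0.2, "den": 0.0},
        "search": {"directed": 0.25, "cache": 0.75, "den": 0.0},
        "cache": {"directed": 0.55, "search": 0.45, "den": 0.0},
        "den": {"search": 1.0, "directed": 0.0, "cache": 0.0},
    })
    initial_state: str = "directed"
    cache_radius: float = 50.0        # meters
    rest_prob: float = 0.25           # excursion start probability per cache fix
    rest_dist: tuple = (500.0, 3000.0)  # meters
    rest_fixes: tuple = (1, 2)

    def validate(self) -> None:
        if not (0.0 <= self.fix_success <= 1.0):
            raise ConfigurationError("fix_success must be in [0, 1]")
        if not (0.0 <= self.rest_prob <= 1.0):
            raise ConfigurationError("rest_prob must be in [0, 1]")
        if self.cache_radius <= 0:
            raise ConfigurationError("cache_radius must be positive")
        if self.nominal_interval <= 0 or self.duration_days <= 0:
            raise ConfigurationError("interval and duration must be positive")
        for name, sp in self.states.items():
            if sp.dwell_mean < 1:
                raise ConfigurationError(f"{name}: dwell mean must be >= 1 fix")
            if sp.mean_speed < 0 or sp.speed_dispersion <= 0:
                raise ConfigurationError(f"{name}: invalid speed parameters")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["states"] = {k: asdict(v) if isinstance(v, StateParams) else v
                       for k, v in self.states.items()}
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class SimOutput:
    trajectory: Trajectory
    truth: pd.DataFrame     # seq, timestamp, state, x, y (pre-failure)
    episodes: pd.DataFrame  # state, start_seq, end_seq, anchor_x, anchor_y
    config: SimConfig
    coupling_log: pd.DataFrame | None = None


def _draw_episodes(config: SimConfig, n_slots: int, rng) -> list[tuple[str, int]]:
    """Semi-Markov (state, dwell) sequence tiling n_slots."""
    out = []
    state = config.initial_state
    total = 0
    while total < n_slots:
        sp = config.states[state]
        dwell = 1 + rng.poisson(max(sp.dwell_mean - 1.0, 0.0))
        dwell = min(dwell, n_slots - total)
        out.append((state, int(dwell)))
        total += dwell
        weights = config.transitions[state]
        names = [k for k, w in weights.items() if w > 0]
        if not names:
            names, probs = [state], [1.0]
        else:
            probs = np.array([weights[k] for k in names], dtype=float)
            probs = probs / probs.sum()
        state = str(rng.choice(names, p=np.atleast_1d(probs)))
    return out


def _candidate_weights(endpoints, beta, raster, rng):
    """exp(beta * covariate) weights; NaN covariates get zero weight."""
    cov = np.array(
        [raster.value_at(x, y) if raster.contains(x, y) else math.nan
         for x, y in endpoints]
    )
    if not np.isfinite(cov).any():
        return np.full(len(endpoints), 1.0 / len(endpoints))
    w = np.where(np.isfinite(cov), np.exp(beta * (cov - np.nanmean(cov))), 0.0)
    if w.sum() <= 0:
        w = np.ones(len(endpoints))
    return w / w.sum()


def _select(endpoints: np.ndarray, rng, raster=None, beta: float = 0.0):
    if raster is None or beta == 0.0 or len(endpoints) == 1:
        return endpoints[rng.integers(len(endpoints))] if len(endpoints) > 1 else endpoints[0]
    p = _candidate_weights(endpoints, beta, raster, rng)
    return endpoints[rng.choice(len(endpoints), p=p)]


def _travel_endpoints(pos, heading, sp: StateParams, interval, rng, k: int):
    turns = rng.vonmises(0.0, max(sp.turn_kappa, 1e-9), size=k)
    shape = sp.speed_dispersion
    speeds = rng.gamma(shape, max(sp.mean_speed, 1e-9) / shape, size=k)
    steps = speeds * interval
    hs = heading + turns
    return np.column_stack([pos[0] + steps * np.cos(hs), pos[1] + steps * np.sin(hs)]), hs


def _disc_points(center, radius, rng, k: int):
    r = radius * np.sqrt(rng.random(k))
    th = rng.random(k) * 2 * np.pi
    return np.column_stack([center[0] + r * np.cos(th), center[1] + r * np.sin(th)])


def _generate_positions(
    config: SimConfig,
    episodes: list[tuple[str, int]],
    rng,
    raster: CovariateRaster | None = None,
    betas: dict | None = None,
    n_candidates: int = 20,
) -> tuple[np.ndarray, np.ndarray, list]:
    """Positions and per-slot states for an episode sequence.

    When ``raster``/``betas`` are given, each displacement is chosen among
    ``n_candidates`` draws with probability proportional to
    exp(beta_state * covariate) at the candidate endpoint.
    """
    n_slots = sum(d for _, d in episodes)
    xy = np.zeros((n_slots, 2))
    states = np.empty(n_slots, dtype=object)
    anchors = []
    pos = np.array([0.0, 0.0])
    heading = rng.random() * 2 * np.pi
    t = 0
    interval = config.nominal_interval
    for state, dwell in episodes:
        beta = (betas or {}).get(state, 0.0)
        k = n_candidates if (raster is not None and beta != 0.0) else 1
        sp = config.states[state]
        if state in ("directed", "search"):
            anchors.append((state, t, t + dwell - 1, math.nan, math.nan))
            for _ in range(dwell):
                cands, hs = _travel_endpoints(pos, heading, sp, interval, rng, k)
                if k == 1:
                    choice = 0
                else:
                    p = _candidate_weights(cands, beta, raster, rng)
                    choice = rng.choice(k, p=p)
                pos = cands[choice]
                heading = hs[choice]
                xy[t] = pos
                states[t] = state
                t += 1
        else:  # cache / den: anchored residency with rest excursions
            anchor = pos.copy()
            if k > 1:
                # coupled anchor choice among nearby candidate sites (within
                # roughly one searching step of the current position)
                reach = config.states["search"].mean_speed * interval
                cands = _disc_points(pos, max(reach, 500.0), rng, k)
                anchor = np.asarray(_select(cands, rng, raster, beta), dtype=float)
            anchors.append((state, t, t + dwell - 1, anchor[0], anchor[1]))
            i = 0
            while i < dwell:
                if rng.random() < config.rest_prob and dwell - i >= 2:
                    dist = rng.uniform(*config.rest_dist)
                    th = rng.random() * 2 * np.pi
                    if k > 1:
                        dists = rng.uniform(*config.rest_dist, size=k)
                        ths = rng.random(k) * 2 * np.pi
                        cands = np.column_stack(
                            [anchor[0] + dists * np.cos(ths), anchor[1] + dists * np.sin(ths)]
                        )
                        rest = _select(cands, rng, raster, beta)
                    else:
                        rest = anchor + dist * np.array([np.cos(th), np.sin(th)])
                    stay = int(rng.integers(config.rest_fixes[0], config.rest_fixes[1] + 1))
                    for _ in range(min(stay, dwell - i - 1)):
                        xy[t] = rest + rng.normal(0, 5.0, size=2)
                        states[t] = state
                        t += 1
                        i += 1
                # at (or back at) the anchor
                cands = _disc_points(anchor, config.cache_radius, rng, k)
                pos = _select(cands, rng, raster, beta) if k > 1 else cands[0]
                xy[t] = pos
                states[t] = state
                t += 1
                i += 1
            pos = anchor.copy()
            heading = rng.random() * 2 * np.pi
    return xy, states, anchors


def simulate(config: SimConfig | None = None,
             raster: CovariateRaster | None = None,
             betas: dict | None = None,
             n_candidates: int = 20) -> SimOutput:
    """Generate a trajectory, per-slot truth states, and an episode table."""
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_slots = int(round(config.duration_days * 24 * 60 / config.nominal_interval))
    episodes = _draw_episodes(config, n_slots, rng)
    xy, states, anchors = _generate_positions(
        config, episodes, rng, raster=raster, betas=betas, n_candidates=n_candidates
    )
    start = pd.Timestamp(config.start_time)
    timestamps = start + pd.to_timedelta(
        np.arange(n_slots) * config.nominal_interval, unit="m"
    )
    valid = rng.random(n_slots) < config.fix_success
    fixes = pd.DataFrame(
        {
            "seq": np.arange(n_slots),
            "timestamp": timestamps,
            "x": np.where(valid, xy[:, 0], np.nan),
            "y": np.where(valid, xy[:, 1], np.nan),
            "valid": valid,
        }
    )
    truth = pd.DataFrame(
        {
            "seq": np.arange(n_slots),
            "timestamp": timestamps,
            "state": states,
            "x": xy[:, 0],
            "y": xy[:, 1],
        }
    )
    episodes_df = pd.DataFrame(
        anchors, columns=["state", "start_seq", "end_seq", "anchor_x", "anchor_y"]
    )
    return SimOutput(
        trajectory=Trajectory(config.animal_id, fixes, config.nominal_interval),
        truth=truth,
        episodes=episodes_df,
        config=config,
    )


def couple_selection(
    sim: SimOutput,
    raster: CovariateRaster,
    betas: dict,
    seed: int | None = None,
    n_candidates: int = 20,
) -> SimOutput:
    """Re-draw the positions of a simulation with covariate-coupled steps.

    The episode/state sequence of ``sim`` is kept; every displacement
    endpoint is re-selected among candidates weighted by
    exp(beta_state * covariate).  Returns a new SimOutput.
    """
    config = sim.config
    rng_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(rng_seed)
    episodes = [
        (row["state"], int(row["end_seq"] - row["start_seq"] + 1))
        for _, row in sim.episodes.iterrows()
    ]
    xy, states, anchors = _generate_positions(
        config, episodes, rng, raster=raster, betas=betas, n_candidates=n_candidates
    )
    n_slots = len(states)
    timestamps = sim.truth["timestamp"]
    valid = sim.trajectory.fixes["valid"].to_numpy(bool)
    fixes = pd.DataFrame(
        {
            "seq": np.arange(n_slots),
            "timestamp": timestamps,
            "x": np.where(valid, xy[:, 0], np.nan),
            "y": np.where(valid, xy[:, 1], np.nan),
            "valid": valid,
        }
    )
    truth = pd.DataFrame(
        {"seq": np.arange(n_slots), "timestamp": timestamps, "state": states,
         "x": xy[:, 0], "y": xy[:, 1]}
    )
    cov = np.array(
        [raster.value_at(x, y) if raster.contains(x, y) else math.nan for x, y in xy]
    )
    log = pd.DataFrame({"seq": np.arange(n_slots), "state": states, "covariate": cov})
    return SimOutput(
        trajectory=Trajectory(config.animal_id, fixes, config.nominal_interval),
        truth=truth,
        episodes=pd.DataFrame(
            anchors, columns=["state", "start_seq", "end_seq", "anchor_x", "anchor_y"]
        ),
        config=config,
        coupling_log=log,
    )


def simulate_raster(
    seed: int = 0,
    extent: tuple = (-20000.0, -20000.0, 20000.0, 20000.0),
    cell_size: float = 30.0,
    roughness: float = 1.0,
    base: float = 83.0,
    amplitude: float = 6.0,
    correlation_cells: float = 8.0,
) -> CovariateRaster:
    """Smooth correlated exposure-like field; flats sit near ``base``.

    roughness 0 gives a constant raster at ``base``; positive roughness
    scales the spread, so ridges rise above the base value and valley
    bottoms drop below 80.
    """
    xmin, ymin, xmax, ymax = extent
    n_cols = int(math.ceil((xmax - xmin) / cell_size))
    n_rows = int(math.ceil((ymax - ymin) / cell_size))
    if roughness <= 0:
        values = np.full((n_rows, n_cols), base)
    else:
        rng = np.random.default_rng(seed)
        noise = rng.normal(size=(n_rows, n_cols))
        smooth = gaussian_filter(noise, sigma=correlation_cells, mode="wrap")
        smooth = (smooth - smooth.mean()) / smooth.std()
        values = base + amplitude * roughness * smooth
    return CovariateRaster(
        x_origin=xmin, y_origin=ymin + n_rows * cell_size,
        cell_size=cell_size, values=values,
    )


def simulate_selection_pairs(
    seed: int,
    n_pairs: int,
    beta: float,
    intercept: float = 0.0,
    cov_scale: float = 1.0,
    animal_id: str = "SIM01",
) -> list[UseAvailPair]:
    """Paired use/availability records with a known logistic selection slope.

    Covariate values are drawn i.i.d. and each is marked used with
    probability expit(intercept + beta * z); sampled cases (used) and
    controls (available) are paired.  Under case-control sampling the
    logistic slope on the stacked records is the generating ``beta`` (only
    the intercept shifts), so fitting recovers it.
    """
    rng = np.random.default_rng(seed)
    used_vals: list[float] = []
    avail_vals: list[float] = []
    while len(used_vals) < n_pairs or len(avail_vals) < n_pairs:
        z = rng.normal(0.0, cov_scale, size=4 * n_pairs)
        p = 1.0 / (1.0 + np.exp(-(intercept + beta * z)))
        y = rng.random(len(z)) < p
        used_vals.extend(z[y][: n_pairs - len(used_vals)])
        avail_vals.extend(z[~y][: n_pairs - len(avail_vals)])
    return [
        UseAvailPair(
            animal_id=animal_id,
            seq=i,
            used_value=float(used_vals[i]),
            avail_mean=float(avail_vals[i]),
            circadian="nocturnal",
            behavior="cache",
        )
        for i in range(n_pairs)
    ]
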