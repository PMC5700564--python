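"""Paired use-versus-availability step selection by behavior and time of day.

For each usable move, the covariate at the used location t0 is paired with
the mean covariate over a disc of radius d_max (the animal's maximum
single-interval step) centered at the previous fix t-1.  Pairs are
stratified into the 3 circadian x 3 behavior subsets and each subset gets
an ordinary binomial logistic fit on the stacked used(1)/availability(0)
records; relative shifts of the coefficient across subsets expose
nonstationary selection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .behavior import CACHE, CREPUSCULAR, DIRECTED, DIURNAL, NOCTURNAL, SEARCH
from .errors import DataError
from .raster import CovariateRaster
from .telemetry import Trajectory

CIRCADIAN_CLASSES = (NOCTURNAL, CREPUSCULAR, DIURNAL)
BEHAVIOR_CLASSES = (DIRECTED, SEARCH, CACHE)
DEFAULT_MIN_PAIRS = 20


@dataclass(frozen=True)
class UseAvailPair:
    """One paired observation: used covariate vs. availability-disc mean."""

    animal_id: str
    seq: int
    used_value: float
    avail_mean: float
    circadian: str
    behavior: str


@dataclass
class SelectionResult:
    """Logistic selection coefficient for one circadian x behavior subset."""

    subset_id: str
    n_pairs: int
    beta: float = math.nan
    se: float = math.nan
    converged: bool = False
    flag: str = ""  # "", "too_few_pairs", "separation", "no_convergence", "no_contrast"

    @property
    def ci95(self) -> tuple[float, float]:
        if not self.converged:
            return (math.nan, math.nan)
        return (self.beta - 1.96 * self.se, self.beta + 1.96 * self.se)


def max_step(traj: Trajectory, tolerance_min: float = 15.0) -> float:
    """Maximum Euclidean step over consecutive valid fixes one interval apart."""
    valid = traj.valid_mask()
    xy = traj.coords()
    mins = traj.minutes()
    best = -math.inf
    for i in range(len(valid) - 1):
        if not (valid[i] and valid[i + 1]):
            continue
        dt = mins[i + 1] - mins[i]
        if abs(dt - traj.nominal_interval) > tolerance_min:
            continue
        best = max(best, float(np.hypot(*(xy[i + 1] - xy[i]))))
    if not math.isfinite(best):
        raise DataError(f"{traj.animal_id}: no single-interval steps to measure")
    return best


def disc_mean(raster: CovariateRaster, cx: float, cy: float, radius: float) -> float:
    """Mean covariate over cells whose centers lie within radius of (cx, cy).

    No-data cells are excluded.  When the disc captures no cell center
    (radius smaller than a cell), the cell containing the center point is
    used (minimum-support rule).
    """
    cell = raster.cell_size
    xs, ys = raster.cell_centers()
    col_lo = max(int(np.floor((cx - radius - raster.x_origin) / cell)), 0)
    col_hi = min(int(np.ceil((cx + radius - raster.x_origin) / cell)), raster.n_cols)
    row_lo = max(int(np.floor((raster.y_origin - (cy + radius)) / cell)), 0)
    row_hi = min(int(np.ceil((raster.y_origin - (cy - radius)) / cell)), raster.n_rows)
    if col_lo >= col_hi or row_lo >= row_hi:
        return raster.value_at(cx, cy)
    sub = raster.values[row_lo:row_hi, col_lo:col_hi]
    dx = xs[col_lo:col_hi] - cx
    dy = ys[row_lo:row_hi] - cy
    inside = (dy[:, None] ** 2 + dx[None, :] ** 2) <= radius**2
    vals = sub[inside]
    vals = vals[vals != raster.nodata]
    if len(vals) == 0:
        return raster.value_at(cx, cy)
    return float(vals.mean())


def sample_pair(
    traj: Trajectory,
    seq: int,
    raster: CovariateRaster,
    d_max: float,
    circadian: str = "",
    behavior: str = "",
) -> UseAvailPair | None:
    """Build the paired sample at fix ``seq`` (the used location t0).

    Requires valid fixes at the slot before (t-1) and at ``seq``; returns
    None when either is missing or t0 falls outside the raster.
    """
    valid = traj.valid_mask()
    if seq < 1 or not (valid[seq] and valid[seq - 1]):
        return None
    xy = traj.coords()
    x0, y0 = xy[seq]
    xp, yp = xy[seq - 1]
    if not raster.contains(x0, y0):
        return None
    used = raster.value_at(x0, y0)
    avail = disc_mean(raster, xp, yp, d_max)
    if not (math.isfinite(used) and math.isfinite(avail)):
        return None
    return UseAvailPair(
        animal_id=traj.animal_id,
        seq=int(seq),
        used_value=used,
        avail_mean=avail,
        circadian=circadian,
        behavior=behavior,
    )


def sample_pairs(
    traj: Trajectory,
    raster: CovariateRaster,
    labels: pd.DataFrame,
    d_max: float | None = None,
) -> tuple[list[UseAvailPair], list[int]]:
    """All pairs for a labeled trajectory; returns (pairs, skipped seqs).

    ``labels`` must align to the grid with columns seq, behavior,
    circadian; fixes with undefined behavior are skipped.
    """
    if d_max is None:
        d_max = max_step(traj)
    beh = labels.set_index("seq")["behavior"]
    circ = labels.set_index("seq")["circadian"]
    pairs: list[UseAvailPair] = []
    skipped: list[int] = []
    for seq in range(1, len(traj)):
        b = beh.get(seq)
        if b is None or (isinstance(b, float) and np.isnan(b)):
            continue
        pair = sample_pair(traj, seq, raster, d_max, circadian=circ.get(seq, ""), behavior=b)
        if pair is None:
            skipped.append(seq)
        else:
            pairs.append(pair)
    return pairs, skipped


def partition_subsets(pairs: list[UseAvailPair]) -> dict:
    """Exhaustive, disjoint 3x3 partition keyed by (circadian, behavior)."""
    subsets = {(c, b): [] for c in CIRCADIAN_CLASSES for b in BEHAVIOR_CLASSES}
    for p in pairs:
        key = (p.circadian, p.behavior)
        if key not in subsets:
            raise DataError(f"pair with unknown stratum {key}")
        subsets[key].append(p)
    return subsets


def fit_selection(
    pairs: list[UseAvailPair],
    subset_id: str = "",
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> SelectionResult:
    """Binomial logistic fit on the stacked 0/1 records of a subset.

    Each pair contributes one used record (response 1, covariate
    used_value) and one availability record (response 0, avail_mean).
    Separation or non-convergence yields a flagged result with no
    coefficient.
    """
    n = len(pairs)
    result = SelectionResult(subset_id=subset_id, n_pairs=n)
    if n < min_pairs:
        result.flag = "too_few_pairs"
        return result
    used = np.array([p.used_value for p in pairs])
    avail = np.array([p.avail_mean for p in pairs])
    y = np.concatenate([np.ones(n), np.zeros(n)])
    x = np.concatenate([used, avail])
    if np.ptp(x) == 0:
        result.flag = "no_contrast"
        return result
    # complete separation: the two groups' covariate ranges do not overlap
    if used.min() > avail.max() or used.max() < avail.min():
        result.flag = "separation"
        return result
    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception:
        result.flag = "no_convergence"
        return result
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    if not (fit.mle_retvals.get("converged", False) and math.isfinite(beta) and math.isfinite(se)):
        result.flag = "no_convergence"
        return result
    if se > 1e3 * (1.0 + abs(beta)):
        result.flag = "separation"
        return result
    result.beta = beta
    result.se = se
    result.converged = True
    return result


def fit_all_subsets(
    subsets: dict, min_pairs: int = DEFAULT_MIN_PAIRS
) -> list[SelectionResult]:
    results = []
    for (circ, beh), pairs in subsets.items():
        results.append(fit_selection(pairs, subset_id=f"{circ}:{beh}", min_pairs=min_pairs))
    return results


def nonstationarity_report(results: list[SelectionResult]) -> pd.DataFrame:
    """Rank estimable subset coefficients with 95% intervals.

    Returns a DataFrame ordered by beta (descending) with a column noting
    whether each interval overlaps the next-ranked one; no hypothesis test
    beyond interval overlap is performed.  Raises when fewer than 2 subsets
    are estimable.
    """
    est = [r for r in results if r.converged]
    if len(est) < 2:
        raise DataError(
            f"nonstationarity report needs >= 2 estimable subsets, got {len(est)}"
        )
    est.sort(key=lambda r: r.beta, reverse=True)
    rows = []
    for rank, r in enumerate(est):
        lo, hi = r.ci95
        overlap = None
        if rank + 1 < len(est):
            lo2, hi2 = est[rank + 1].ci95
            overlap = bool(lo <= hi2 and lo2 <= hi)
        rows.append(
            {
                "rank": rank + 1,
                "subset": r.subset_id,
                "beta": r.beta,
                "se": r.se,
                "ci_low": lo,
                "ci_high": hi,
                "n_pairs": r.n_pairs,
                "overlaps_next": overlap,
            }
        )
    return pd.DataFrame(rows)
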