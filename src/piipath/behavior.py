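"""Behavior classification, circadian binning, segmentation, and evaluation.

PII thresholds carry the documented defaults: values strictly below 1.4 are
directed travel, values strictly above 1.8 are cache/denning behavior, and
the closed mid-band [1.4, 1.8] is searching (ties go to search).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .telemetry import FieldVerification, Trajectory

DIRECTED = "directed"
SEARCH = "search"
CACHE = "cache"

NOCTURNAL = "nocturnal"
CREPUSCULAR = "crepuscular"
DIURNAL = "diurnal"

DEFAULT_LOW = 1.4
DEFAULT_HIGH = 1.8

#: nominal collar hours mapped to circadian classes
DEFAULT_CIRCADIAN_HOURS = {
    21: NOCTURNAL,
    1: NOCTURNAL,
    5: CREPUSCULAR,
    17: CREPUSCULAR,
    9: DIURNAL,
    13: DIURNAL,
}


def round_half_up_percent(numerator: float, denominator: float) -> int:
    """Whole-percent rounding, half away from zero (75 from 116/155)."""
    if denominator == 0:
        raise DataError("cannot compute a percentage with zero total")
    pct = Decimal(numerator) / Decimal(denominator) * 100
    return int(pct.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def classify(pii, low: float = DEFAULT_LOW, high: float = DEFAULT_HIGH) -> np.ndarray:
    """Per-fix behavior labels from PII values (None where PII is undefined)."""
    if low >= high:
        raise ConfigurationError(f"low threshold {low} must be < high {high}")
    x = np.asarray(pii, dtype=float)
    out = np.full(len(x), None, dtype=object)
    defined = np.isfinite(x)
    out[defined & (x > high)] = CACHE
    out[defined & (x >= low) & (x <= high)] = SEARCH
    out[defined & (x < low)] = DIRECTED
    return out


def circadian(timestamp, scheme: dict | None = None) -> str:
    """Circadian class of a local time by nearest nominal collar hour.

    ``scheme`` maps nominal hours to class names; the default is the
    six-fix schedule {21, 1: nocturnal; 5, 17: crepuscular; 9, 13: diurnal}.
    Nearest is circular in hours; ties resolve to the earlier nominal hour.
    """
    scheme = scheme or DEFAULT_CIRCADIAN_HOURS
    ts = pd.Timestamp(timestamp)
    h = ts.hour + ts.minute / 60.0 + ts.second / 3600.0
    best = None
    best_dist = np.inf
    for hour in sorted(scheme):
        d = abs(h - hour)
        d = min(d, 24.0 - d)
        if d < best_dist - 1e-12:
            best_dist = d
            best = scheme[hour]
    return best


def circadian_series(timestamps, scheme: dict | None = None) -> np.ndarray:
    return np.array([circadian(t, scheme) for t in timestamps], dtype=object)


@dataclass(frozen=True)
class Segment:
    """A maximal run of identically-labeled consecutive fixes."""

    animal_id: str
    label: str
    start_seq: int
    end_seq: int
    duration_hours: float


def segment(
    labels,
    animal_id: str = "",
    interval_minutes: float = 240.0,
) -> list[Segment]:
    """Run-length encode per-fix labels; undefined fixes break runs."""
    labs = list(labels)
    segments: list[Segment] = []
    start = None
    current = None
    for i, lab in enumerate(labs + [None]):
        if lab is not None and not isinstance(lab, str):
            lab = None if (isinstance(lab, float) and np.isnan(lab)) else lab
        if lab == current and lab is not None:
            continue
        if current is not None:
            segments.append(
                Segment(
                    animal_id=animal_id,
                    label=current,
                    start_seq=start,
                    end_seq=i - 1,
                    duration_hours=(i - start) * interval_minutes / 60.0,
                )
            )
        current = lab
        start = i if lab is not None else None
    return segments


@dataclass
class ConfusionSummary:
    """Per-animal and pooled correct/incorrect counts by verified class.

    ``counts`` maps (animal_id, observed_class) -> [correct, incorrect].
    ``observed_class`` is "non_feeding" or "cache"; predicted directed and
    search labels collapse to non_feeding.
    """

    counts: dict = field(default_factory=dict)
    unresolved: list = field(default_factory=list)

    def add(self, animal_id: str, observed_class: str, correct: bool, n: int = 1) -> None:
        key = (animal_id, observed_class)
        cell = self.counts.setdefault(key, [0, 0])
        cell[0 if correct else 1] += n

    @classmethod
    def from_counts(cls, counts: dict) -> "ConfusionSummary":
        """Build from {(animal_id, observed_class): (correct, incorrect)}."""
        summary = cls()
        for (animal, klass), (ok, bad) in counts.items():
            summary.add(animal, klass, True, ok)
            summary.add(animal, klass, False, bad)
        return summary

    # -- totals ----------------------------------------------------------
    def animals(self) -> list:
        return sorted({a for a, _ in self.counts})

    def _sum(self, animal=None, observed_class=None) -> tuple[int, int]:
        ok = bad = 0
        for (a, k), (c, i) in self.counts.items():
            if animal is not None and a != animal:
                continue
            if observed_class is not None and k != observed_class:
                continue
            ok += c
            bad += i
        return ok, bad

    def n_total(self) -> int:
        ok, bad = self._sum()
        return ok + bad

    def percent_correct(self, animal=None) -> int:
        ok, bad = self._sum(animal=animal)
        return round_half_up_percent(ok, ok + bad)

    def class_percent_correct(self, observed_class: str, animal=None) -> int:
        ok, bad = self._sum(animal=animal, observed_class=observed_class)
        return round_half_up_percent(ok, ok + bad)

    # -- rendering -------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for animal in self.animals() + ["All"]:
            a = None if animal == "All" else animal
            for klass in ("non_feeding", "cache"):
                ok, bad = self._sum(animal=a, observed_class=klass)
                if ok + bad == 0:
                    continue
                rows.append(
                    {
                        "animal_id": animal,
                        "observed_class": klass,
                        "correct": ok,
                        "incorrect": bad,
                        "total": ok + bad,
                    }
                )
            ok, bad = self._sum(animal=a)
            if ok + bad:
                rows.append(
                    {
                        "animal_id": animal,
                        "observed_class": "total",
                        "correct": ok,
                        "incorrect": bad,
                        "total": ok + bad,
                        "percent_correct": self.percent_correct(animal=a),
                    }
                )
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        lines = []
        for animal in self.animals() + ["All"]:
            a = None if animal == "All" else animal
            ok, bad = self._sum(animal=a)
            if ok + bad == 0:
                continue
            lines.append(f"{animal}: {ok}/{ok + bad} correct ({self.percent_correct(animal=a)}%)")
        if self.unresolved:
            lines.append(f"unresolved verification records: {len(self.unresolved)}")
        return "\n".join(lines)


#: predicted-label collapse used for scoring against field verification
DEFAULT_TRUTH_MAPPING = {DIRECTED: "non_feeding", SEARCH: "non_feeding", CACHE: "cache"}


def evaluate(
    labels: pd.DataFrame,
    truth: list[FieldVerification],
    mapping: dict | None = None,
    nominal_interval: float = 240.0,
) -> ConfusionSummary:
    """Score per-fix behavior labels against field-verified site classes.

    ``labels`` needs columns animal_id, seq, timestamp, behavior.  Truth
    records are matched by seq or by nearest timestamp within one nominal
    interval; unresolvable records are listed and excluded.
    """
    if not truth:
        raise DataError("empty verification list")
    mapping = mapping or DEFAULT_TRUTH_MAPPING
    summary = ConfusionSummary()
    by_animal = {a: g for a, g in labels.groupby("animal_id")}
    for rec in truth:
        grp = by_animal.get(rec.animal_id)
        predicted = None
        if grp is not None:
            if isinstance(rec.ref, (int, np.integer)):
                hit = grp[grp["seq"] == int(rec.ref)]
                predicted = hit["behavior"].iloc[0] if len(hit) else None
            else:
                dt = (pd.to_datetime(grp["timestamp"]) - pd.Timestamp(rec.ref)).abs()
                i = dt.idxmin()
                if dt.loc[i] <= pd.Timedelta(minutes=nominal_interval):
                    predicted = grp.loc[i, "behavior"]
        if predicted is None or (isinstance(predicted, float) and np.isnan(predicted)):
            summary.unresolved.append(rec)
            continue
        summary.add(rec.animal_id, rec.observed_class, mapping[predicted] == rec.observed_class)
    if not summary.counts:
        raise DataError("no verification records could be matched to labeled fixes")
    return summary


def class_frequencies(
    labels: pd.DataFrame,
    window_days: float = 30.0,
    interval_minutes: float = 240.0,
) -> pd.DataFrame:
    """Rolling per-class proportions among defined fixes.

    Returns one row per fix with the fraction of each behavior class in the
    centered window; rows with no defined fix in the window are NaN.
    Proportions sum to 1 over the three classes.
    """
    if window_days < 1:
        raise ConfigurationError("window must be >= 1 day")
    w_fixes = max(int(round(window_days * 24 * 60 / interval_minutes)), 1)
    if w_fixes % 2 == 0:
        w_fixes += 1
    half = w_fixes // 2
    labs = labels["behavior"].to_numpy(object)
    n = len(labs)
    onehot = {
        k: np.concatenate([[0], np.cumsum((labs == k).astype(int))])
        for k in (DIRECTED, SEARCH, CACHE)
    }
    defined = np.concatenate([[0], np.cumsum(pd.notna(labs).astype(int))])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1) + 1
    total = (defined[hi] - defined[lo]).astype(float)
    out = pd.DataFrame({"seq": labels["seq"], "timestamp": labels["timestamp"]})
    with np.errstate(invalid="ignore", divide="ignore"):
        for k in (DIRECTED, SEARCH, CACHE):
            out[k] = np.where(total > 0, (onehot[k][hi] - onehot[k][lo]) / total, np.nan)
    return out
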