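"""Video-derived behaviour metrics: zones, locomotion, barcoding, feeding bouts.

Works on three inputs that mirror what a commercial tracker plus manual
scoring produce: a 2-D tracking trace (cm, fixed overhead camera), a zone
geometry (food zone around the receptacle, a 'food approach' annulus
extending a configurable margin — default 5 cm — outside it, and the
remaining floor), and a per-frame ethogram over a closed six-label
vocabulary.  Coordinates are cm with the origin at the arena's lower-left
corner; frame timestamps refer to frame start, so a session of n frames at
rate r lasts n/r seconds and per-zone durations partition it exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PhotocifError

#: closed behaviour vocabulary; order is the tie-break order for barcoding
BEHAVIOR_LABELS = ("eating", "sniffing_food", "walking", "stationary", "rearing", "grooming")
FOOD_RELATED = ("eating", "sniffing_food")
ZONE_NAMES = ("food", "approach", "floor")


@dataclass
class TrackingTrace:
    """Uniformly sampled 2-D position trace in arena coordinates (cm)."""

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.time.size == self.x.size == self.y.size):
            raise PhotocifError("tracking arrays must have equal length")
        if self.time.size == 0:
            raise PhotocifError("empty tracking trace")
        if not np.all(np.isfinite(self.x)) or not np.all(np.isfinite(self.y)):
            raise PhotocifError("non-finite coordinates in tracking trace")

    @property
    def n_frames(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        return self.n_frames / self.rate


@dataclass
class ZoneSet:
    """Arena rectangle plus food disc and approach annulus.

    The food zone is a disc around the receptacle; the approach zone extends
    ``approach_margin`` cm radially outside it; the floor is everything else
    inside the arena.  The three zones are disjoint and cover the arena.
    """

    arena_w: float = 40.0
    arena_h: float = 40.0
    food_center: tuple[float, float] = (10.0, 10.0)
    food_radius: float = 6.0
    approach_margin: float = 5.0

    def __post_init__(self) -> None:
        if self.approach_margin <= 0:
            raise PhotocifError("approach margin must be positive")
        cx, cy = self.food_center
        r = self.food_radius
        if r <= 0:
            raise PhotocifError("food radius must be positive")
        if not (r <= cx <= self.arena_w - r and r <= cy <= self.arena_h - r):
            raise PhotocifError("food zone not contained in arena")

    def classify(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Zone membership per frame: 'food', 'approach' or 'floor'."""
        d = np.hypot(np.asarray(x) - self.food_center[0], np.asarray(y) - self.food_center[1])
        out = np.full(d.shape, "floor", dtype=object)
        out[d <= self.food_radius + self.approach_margin] = "approach"
        out[d <= self.food_radius] = "food"
        return out


@dataclass
class Ethogram:
    """Per-frame behaviour labels over the closed vocabulary."""

    time: np.ndarray
    behavior: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.behavior = np.asarray(self.behavior, dtype=object)
        if self.time.size != self.behavior.size:
            raise PhotocifError("ethogram time and label lengths differ")
        bad = set(self.behavior) - set(BEHAVIOR_LABELS)
        if bad:
            raise PhotocifError(f"unknown behaviour labels {sorted(map(str, bad))}")

    @property
    def duration(self) -> float:
        return self.time.size / self.rate


@dataclass
class BoutList:
    """Non-overlapping, ordered (onset, offset) feeding bouts in seconds."""

    bouts: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["onset_s", "offset_s"])
    )

    def __post_init__(self) -> None:
        b = self.bouts
        if len(b):
            if not (b["offset_s"] > b["onset_s"]).all():
                raise PhotocifError("bout offsets must exceed onsets")
            if not (b["onset_s"].to_numpy()[1:] >= b["offset_s"].to_numpy()[:-1]).all():
                raise PhotocifError("bouts must be ordered and non-overlapping")

    @property
    def count(self) -> int:
        return len(self.bouts)

    @property
    def total_duration(self) -> float:
        if not len(self.bouts):
            return 0.0
        return float((self.bouts["offset_s"] - self.bouts["onset_s"]).sum())

    @property
    def onsets(self) -> np.ndarray:
        return self.bouts["onset_s"].to_numpy(dtype=float)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean array as half-open index pairs."""
    if mask.size == 0:
        return []
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = list(edges[mask[edges + 1]] + 1)
    stops = list(edges[~mask[edges + 1]] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def zone_metrics(
    track: TrackingTrace, zones: ZoneSet, hysteresis_s: float = 0.2
) -> pd.DataFrame:
    """Per-zone entry frequency, occupancy duration and first-entry latency.

    An entry is counted only once the animal has been continuously inside
    the zone for ``hysteresis_s`` seconds (suppresses boundary chatter);
    occupancy duration counts every in-zone frame regardless, so durations
    over the three zones partition the session exactly.  A zone that is
    never entered (no qualifying run) reports frequency 0, its raw duration,
    latency equal to the session length and ``not_reached=True``.
    """
    if track.n_frames == 0:
        raise PhotocifError("empty tracking trace")
    zone_of = zones.classify(track.x, track.y)
    period = 1.0 / track.rate
    min_frames = max(1, int(np.ceil(hysteresis_s * track.rate)))
    session_len = track.duration
    rows = []
    for name in ZONE_NAMES:
        inside = zone_of == name
        duration = float(inside.sum()) * period
        qual = [(i0, i1) for i0, i1 in _runs(inside) if i1 - i0 >= min_frames]
        freq = len(qual)
        if qual:
            latency = track.time[qual[0][0]] - track.time[0]
            not_reached = False
        else:
            latency = session_len
            not_reached = True
        rows.append((name, freq, duration, float(latency), not_reached))
    return pd.DataFrame(
        rows, columns=["zone", "frequency", "duration_s", "latency_s", "not_reached"]
    )


def locomotion_metrics(track: TrackingTrace) -> tuple[float, float]:
    """Total path length (cm) and mean velocity (cm/s) over the trace."""
    if track.n_frames < 2:
        raise PhotocifError("need at least 2 frames for locomotion metrics")
    steps = np.hypot(np.diff(track.x), np.diff(track.y))
    distance = float(steps.sum())
    elapsed = float(track.time[-1] - track.time[0])
    return distance, distance / elapsed


def barcode(
    eth: Ethogram,
    window: tuple[float, float] | None = None,
    bin_s: float = 10.0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Behavioural barcode: per-bin dominant label and % time per label.

    ``window`` defaults to the first 10 minutes (clipped to the session).
    Returns (bins, percent, aggregate): per-bin dominant labels for barcode
    strips, per-label percentage of window time, and the food-related
    (eating + sniffing_food) vs non-food split.  Dominant-label ties break
    toward the earlier label in the canonical vocabulary order.
    """
    if window is None:
        window = (eth.time[0], min(eth.time[0] + 600.0, eth.time[0] + eth.duration))
    w0, w1 = window
    if w1 <= w0:
        raise PhotocifError("empty barcode window")
    if w0 < eth.time[0] - 1e-9 or w1 > eth.time[0] + eth.duration + 1e-9:
        raise PhotocifError(f"window [{w0}, {w1}) outside session")
    if bin_s > (w1 - w0) + 1e-9:
        raise PhotocifError(f"bin {bin_s} s larger than window {w1 - w0} s")

    mask = (eth.time >= w0) & (eth.time < w1)
    labels = eth.behavior[mask]
    times = eth.time[mask]
    if labels.size == 0:
        raise PhotocifError("no frames in barcode window")

    counts = pd.Series(0, index=list(BEHAVIOR_LABELS), dtype=float)
    vc = pd.Series(labels).value_counts()
    counts[vc.index] = vc.to_numpy(dtype=float)
    percent = 100.0 * counts / counts.sum()

    agg = pd.Series(
        {
            "food_related": float(percent[list(FOOD_RELATED)].sum()),
            "non_food": float(percent[[l for l in BEHAVIOR_LABELS if l not in FOOD_RELATED]].sum()),
        }
    )

    edges = np.arange(w0, w1, bin_s)
    rows = []
    for b0 in edges:
        b1 = min(b0 + bin_s, w1)
        in_bin = (times >= b0) & (times < b1)
        if not in_bin.any():
            continue
        vcb = pd.Series(labels[in_bin]).value_counts()
        best = max(BEHAVIOR_LABELS, key=lambda lab: (vcb.get(lab, 0), -BEHAVIOR_LABELS.index(lab)))
        rows.append((b0, b1, best))
    bins = pd.DataFrame(rows, columns=["bin_start_s", "bin_end_s", "dominant"])
    return bins, percent, agg


def detect_bouts(
    eth: Ethogram, min_duration: float = 1.0, merge_gap: float = 2.0
) -> BoutList:
    """Segment 'eating' frames into feeding bouts.

    Maximal eating runs separated by gaps shorter than ``merge_gap`` seconds
    are merged, then merged runs shorter than ``min_duration`` seconds are
    discarded.  Bout offsets are frame-end times, so a bout spanning frames
    [i, j] lasts (j - i + 1) frame periods.
    """
    period = 1.0 / eth.rate
    eating = eth.behavior == "eating"
    runs = _runs(eating)
    if not runs:
        return BoutList()
    merged = [list(runs[0])]
    for i0, i1 in runs[1:]:
        if (i0 - merged[-1][1]) * period < merge_gap:
            merged[-1][1] = i1
        else:
            merged.append([i0, i1])
    keep = [
        (eth.time[i0], eth.time[0] + i1 * period)
        for i0, i1 in merged
        if (i1 - i0) * period >= min_duration
    ]
    return BoutList(pd.DataFrame(keep, columns=["onset_s", "offset_s"]))
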