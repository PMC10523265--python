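"""Fibre-photometry signal correction, normalisation and peri-event analysis.

The processing chain mirrors standard two-channel GCaMP photometry practice:
a calcium-dependent channel (465 nm excitation) and a calcium-independent
isosbestic channel (405 nm) are combined into a fractional fluorescence
change

    dff = (f465 - f405) / f405

which cancels additive artifacts shared by the two channels (motion, ambient
light) and, because photobleaching scales both channels together, cancels
the bleaching envelope in the numerator/denominator ratio.  Signals are then
expressed as baseline z-scores

    z = (x - mean(baseline)) / sd(baseline)

so that traces are comparable across animals, and aligned to repeated event
timestamps (context transfer, food presentation, feeding-bout onset) on a
common peri-event grid, each event re-normalised to its own pre-event
baseline.

Conventions
-----------
* Time is seconds everywhere in the library; minute-scale windows are
  converted at the interface.
* All analysis windows, including baseline windows, are half-open
  ``[start, end)`` on the sample grid, so adjacent windows never share a
  sample.
* z-scores use the sample (n-1) standard deviation.
* Events whose full peri-event window does not fit inside the recording are
  dropped and counted, never padded.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    DegenerateBaselineError,
    EmptyPeriEventError,
    PhotocifError,
)

log = logging.getLogger(__name__)

#: default peri-food windows, minutes relative to food presentation
FOOD_WINDOWS_MIN = (("baseline", -10.0, 0.0), ("0-10 min", 0.0, 10.0), ("10-20 min", 10.0, 20.0))
#: default peri-bout windows, seconds relative to bout onset
BOUT_WINDOWS_S = (("baseline", -10.0, 0.0), ("0-5 s", 0.0, 5.0), ("5-10 s", 5.0, 10.0))

_SD_TOL = 1e-12


@dataclass
class PhotometrySession:
    """Synchronised two-channel recording plus its event log for one session.

    Attributes
    ----------
    time : array of float
        Sample times in seconds, strictly increasing, uniformly spaced.
    f465, f405 : array of float
        Calcium-dependent and isosbestic fluorescence (arbitrary units).
    rate : float
        Sampling rate, Hz; must match the time spacing.
    events : list of (label, time_s)
        Labelled timestamps on the session clock.
    meta : dict
        Free-form provenance (mouse id, phase, context, ...).
    """

    time: np.ndarray
    f465: np.ndarray
    f405: np.ndarray
    rate: float
    events: list[tuple[str, float]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.f465 = np.asarray(self.f465, dtype=float)
        self.f405 = np.asarray(self.f405, dtype=float)
        n = self.time.size
        if not (self.f465.size == n and self.f405.size == n):
            raise PhotocifError(
                f"channel lengths differ: time={n}, f465={self.f465.size}, f405={self.f405.size}"
            )
        if n >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise PhotocifError("time must be strictly increasing")
            if not np.allclose(dt, 1.0 / self.rate, rtol=1e-6, atol=0):
                raise PhotocifError("sample spacing inconsistent with declared rate")
        bad = np.flatnonzero(self.f405 <= 0)
        if bad.size:
            raise PhotocifError(
                f"f405 must be positive everywhere; first offending index {bad[0]} "
                f"(value {self.f405[bad[0]]!r})"
            )

    @property
    def duration(self) -> float:
        return self.time.size / self.rate

    def event_times(self, label: str) -> np.ndarray:
        return np.array([t for lab, t in self.events if lab == label], dtype=float)


@dataclass
class PeriEventMatrix:
    """Events x samples grid of signal aligned to event timestamps."""

    values: np.ndarray              # (n_events, n_samples)
    rel_time: np.ndarray            # seconds relative to alignment, 0 = event
    baseline_window: tuple[float, float]
    event_labels: list[str]
    dropped_events: int = 0
    mode: str = "z"                 # normalisation applied per row

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=np.round(self.rel_time, 9))
        df.insert(0, "event", self.event_labels)
        return df


def compute_dff(f465: np.ndarray, f405: np.ndarray) -> np.ndarray:
    """Isosbestic-corrected fractional fluorescence, (f465 - f405) / f405.

    The equation is applied verbatim, element by element, with no fitting or
    smoothing; see :func:`fit_isosbestic_dff` for the regression-scaled
    variant (off by default throughout the pipeline).
    """
    f465 = np.asarray(f465, dtype=float)
    f405 = np.asarray(f405, dtype=float)
    if f465.shape != f405.shape:
        raise PhotocifError(f"length mismatch: f465 {f465.shape} vs f405 {f405.shape}")
    bad = np.flatnonzero(f405 <= 0)
    if bad.size:
        raise PhotocifError(f"f405 must be positive; first offending index {bad[0]}")
    return (f465 - f405) / f405


def fit_isosbestic_dff(f465: np.ndarray, f405: np.ndarray) -> np.ndarray:
    """Regression-scaled variant: dff = (f465 - fit) / fit with fit = a*f405 + b.

    Common elsewhere in the photometry literature; kept behind an explicit
    flag because the primary pipeline uses the unfitted subtraction.
    """
    f465 = np.asarray(f465, dtype=float)
    f405 = np.asarray(f405, dtype=float)
    if f465.shape != f405.shape:
        raise PhotocifError("length mismatch between channels")
    a, b = np.polyfit(f405, f465, 1)
    fit = a * f405 + b
    if np.any(fit <= 0):
        raise PhotocifError("fitted isosbestic crosses zero; cannot divide")
    return (f465 - fit) / fit


def _baseline_slice(time: np.ndarray, baseline: tuple[float, float]) -> np.ndarray:
    t0, t1 = baseline
    if t1 <= t0:
        raise PhotocifError(f"empty baseline interval ({t0}, {t1})")
    mask = (time >= t0) & (time < t1)
    if mask.sum() < 2:
        raise PhotocifError(
            f"baseline [{t0}, {t1}) holds {int(mask.sum())} samples; need at least 2"
        )
    return mask


def zscore_baseline(
    x: np.ndarray, time: np.ndarray, baseline: tuple[float, float]
) -> np.ndarray:
    """z-score a whole series against the mean/SD of its baseline window.

    z = (x - x0) / S with x0, S the mean and sample (n-1) SD of the samples
    falling in the half-open baseline interval.
    """
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    if x.size != time.size:
        raise PhotocifError("series and time lengths differ")
    if baseline[0] < time[0] - 0.5 / _rate_of(time) or baseline[1] > time[-1] + 1.5 / _rate_of(time):
        raise PhotocifError(
            f"baseline [{baseline[0]}, {baseline[1]}) outside recorded span "
            f"[{time[0]}, {time[-1]}]"
        )
    mask = _baseline_slice(time, baseline)
    mu = x[mask].mean()
    sd = x[mask].std(ddof=1)
    if not sd > _SD_TOL:
        raise DegenerateBaselineError(
            f"baseline SD {sd!r} below tolerance {_SD_TOL}; series constant on baseline?"
        )
    return (x - mu) / sd


def _rate_of(time: np.ndarray) -> float:
    if time.size < 2:
        return 1.0
    return 1.0 / (time[1] - time[0])


def build_perievent(
    signal: np.ndarray,
    time: np.ndarray,
    events: np.ndarray,
    pre: float,
    post: float,
    baseline: tuple[float, float] | None = None,
    mode: str = "z",
    event_labels: list[str] | None = None,
) -> PeriEventMatrix:
    """Align signal slices to event timestamps on a common relative-time grid.

    Each retained event contributes one row covering ``[-pre, +post]``
    (inclusive of 0), re-normalised to that row's own baseline window:
    ``mode='z'`` baseline z-score, ``mode='mean'`` baseline-mean
    subtraction (for signals whose baseline SD is not meaningful),
    ``mode='none'`` raw slice.  Events whose window leaves the recording are
    dropped and counted.
    """
    signal = np.asarray(signal, dtype=float)
    time = np.asarray(time, dtype=float)
    events = np.atleast_1d(np.asarray(events, dtype=float))
    if pre <= 0 or post <= 0:
        raise PhotocifError("pre and post must be positive")
    if baseline is None:
        baseline = (-pre, 0.0)
    if baseline[0] < -pre or baseline[1] > 0.0 + 1e-12:
        raise PhotocifError(f"baseline {baseline} must lie within [-pre, 0]")
    if mode not in ("z", "mean", "none"):
        raise PhotocifError(f"unknown normalisation mode {mode!r}")
    if events.size == 0:
        raise EmptyPeriEventError("no events supplied")

    rate = _rate_of(time)
    k_pre = int(round(pre * rate))
    k_post = int(round(post * rate))
    rel_time = np.arange(-k_pre, k_post + 1) / rate

    if event_labels is None:
        event_labels = [f"event_{i}" for i in range(events.size)]

    rows, kept_labels, dropped = [], [], 0
    for ev, lab in zip(events, event_labels):
        idx = int(round((ev - time[0]) * rate))
        i0, i1 = idx - k_pre, idx + k_post
        if i0 < 0 or i1 >= time.size:
            dropped += 1
            continue
        sl = signal[i0 : i1 + 1]
        if mode == "z":
            sl = zscore_baseline(sl, rel_time, baseline)
        elif mode == "mean":
            sl = sl - sl[_baseline_slice(rel_time, baseline)].mean()
        rows.append(sl)
        kept_labels.append(lab)
    if dropped:
        log.warning("dropped %d/%d events with windows outside the recording", dropped, events.size)
    if not rows:
        raise EmptyPeriEventError(
            f"all {events.size} events fell too close to the recording edges"
        )
    return PeriEventMatrix(
        values=np.vstack(rows),
        rel_time=rel_time,
        baseline_window=tuple(baseline),
        event_labels=kept_labels,
        dropped_events=dropped,
        mode=mode,
    )


def window_means(
    m: PeriEventMatrix, windows: list[tuple[str, float, float]]
) -> pd.DataFrame:
    """Per-event arithmetic means over half-open windows of the peri-event grid.

    Returns one row per event x window with columns
    ``event, window, start_s, end_s, mean``.
    """
    records = []
    for label, start, end in windows:
        if start < m.rel_time[0] - 1e-9 or end > m.rel_time[-1] + 1.0 / _rate_of(m.rel_time):
            raise PhotocifError(
                f"window {label!r} [{start}, {end}) outside peri-event span "
                f"[{m.rel_time[0]}, {m.rel_time[-1]}]"
            )
        mask = (m.rel_time >= start) & (m.rel_time < end)
        if not mask.any():
            raise PhotocifError(f"window {label!r} contains no samples after gridding")
        means = m.values[:, mask].mean(axis=1)
        for ev, val in zip(m.event_labels, means):
            records.append((ev, label, start, end, val))
    return pd.DataFrame(records, columns=["event", "window", "start_s", "end_s", "mean"])


def bout_triggered_average(
    session: PhotometrySession,
    bout_onsets: np.ndarray,
    mode: str = "z",
    pre: float = 10.0,
    post: float = 10.0,
    windows: tuple = BOUT_WINDOWS_S,
) -> tuple[PeriEventMatrix, pd.DataFrame]:
    """Feeding-bout-triggered average of the corrected signal.

    Convenience composition: dff -> peri-event alignment on bout onsets
    (default -10..+10 s, each bout re-baselined to its own -10..0 s window)
    -> per-bout window means over baseline / 0-5 s / 5-10 s.  Bouts, not
    animals, are the analysis unit.
    """
    bout_onsets = np.atleast_1d(np.asarray(bout_onsets, dtype=float))
    if bout_onsets.size == 0:
        raise EmptyPeriEventError("empty bout-onset list")
    dff = compute_dff(session.f465, session.f405)
    m = build_perievent(
        dff, session.time, bout_onsets, pre=pre, post=post, baseline=(-pre, 0.0), mode=mode
    )
    return m, window_means(m, list(windows))


def downsample(session: PhotometrySession, factor: int) -> PhotometrySession:
    """Block-mean decimation of both channels; trailing remainder truncated."""
    if int(factor) != factor or factor < 1:
        raise PhotocifError(f"factor must be a positive integer, got {factor!r}")
    factor = int(factor)
    if factor == 1:
        return replace(session)
    n = (session.time.size // factor) * factor

    def block(x: np.ndarray) -> np.ndarray:
        return x[:n].reshape(-1, factor).mean(axis=1)

    return PhotometrySession(
        time=block(session.time),
        f465=block(session.f465),
        f405=block(session.f405),
        rate=session.rate / factor,
        events=list(session.events),
        meta=dict(session.meta),
    )


def suppression_estimate(
    session: PhotometrySession,
    food_time: float,
    baseline_min: float = 10.0,
    window_min: tuple[float, float] = (0.0, 10.0),
    mode: str = "z",
) -> float:
    """Post-food suppression: baseline window mean minus post-food window mean.

    The dff trace is aligned to food presentation, normalised to the
    -baseline_min..0 window, and the suppression is reported as
    (baseline mean) - (mean over ``window_min`` minutes after food), so a
    positive value means activity fell after food.
    """
    dff = compute_dff(session.f465, session.f405)
    m = build_perievent(
        dff,
        session.time,
        np.array([food_time]),
        pre=baseline_min * 60.0,
        post=window_min[1] * 60.0,
        baseline=(-baseline_min * 60.0, 0.0),
        mode=mode,
    )
    wm = window_means(
        m,
        [
            ("baseline", -baseline_min * 60.0, 0.0),
            ("post", window_min[0] * 60.0, window_min[1] * 60.0),
        ],
    )
    base = wm.loc[wm["window"] == "baseline", "mean"].to_numpy()[0]
    post = wm.loc[wm["window"] == "post", "mean"].to_numpy()[0]
    return float(base - post)
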