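"""Synthetic AgRP photometry / behaviour / intake cohort generator.

Forward model used throughout the package as ground truth.  A latent AgRP
population-activity series is composed from interpretable pieces:

* a tonic level set by energy state (fasted high, fed low),
* a decaying novelty transient at context transfer (scaled down when the
  context is familiar),
* a food-evoked suppression after food presentation with a fast sensory
  drop (tau_fast) relaxing into a sustained post-ingestive plateau that
  decays slowly (tau_slow): kernel (1 - exp(-t/tau_fast)) * exp(-t/tau_slow),
* an additional transient dip per feeding bout (fast onset, exponential
  recovery after the bout ends),
* optogenetic drive modelled at the analysis rate by its envelope — a 20 Hz
  1 s ON / 3 s OFF train becomes a plateau scaled by its 0.25 duty cycle;
  constant inhibition clamps the drive toward a floor,
* Ornstein-Uhlenbeck noise (exact AR(1) discretisation, stationary start),
* a lower bound at zero.

The latent series is rendered into two photometry channels:

    f465 = (gain * activity + offset465) * bleach(t) + motion(t) + noise
    f405 =                     offset405 * bleach(t) + motion(t) + noise

with a double-exponential bleaching envelope and an additive motion-artifact
series that is numerically identical in both channels, so the subtractive
isosbestic correction removes it.  Tracking (biased random walk), per-frame
behaviour labels (dwell-time Markov chain, 'eating' forced during scheduled
bouts) and cohort-level intakes (per-mouse trait coupling training intake to
the programmed context-discrimination effect) complete the session bundle.

Every generator is a pure function of (parameters, protocol, seed); one
global seed expands into named per-stream sub-seeds (see `_rng.stream_rng`).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as _sig

from ._rng import stream_rng
from .behavior import BEHAVIOR_LABELS, Ethogram, TrackingTrace, ZoneSet
from .errors import PhotocifError
from .photometry import PhotometrySession

log = logging.getLogger(__name__)

LATENT_RATE_HZ = 20.0
TRACKING_RATE_HZ = 25.0
STIM_DUTY = {"excite_20Hz_1on3off": 0.25, "inhibit_constant": 1.0}


# ---------------------------------------------------------------------------
# parameters and protocols
# ---------------------------------------------------------------------------

@dataclass
class AgrpParams:
    """Ground-truth generator parameters (latent dynamics + render model).

    Amplitudes are in arbitrary latent-activity units, time constants in
    seconds.  Defaults are qualitative: they reproduce the phenomenology of
    fasting-elevated tonic activity, rapid food-evoked suppression with a
    sustained post-ingestive component, per-bout dips and novelty transients
    at context transfer, at magnitudes chosen to look like typical AgRP
    GCaMP recordings (z-scale drops of a few units), not fitted to any
    dataset.
    """

    # latent dynamics
    mu_fed: float = 1.0
    mu_fasted: float = 5.0
    a_drop: float = 3.0
    tau_fast: float = 10.0
    tau_slow: float = 1200.0
    a_bout: float = 1.0
    tau_bout_on: float = 0.5
    tau_bout: float = 10.0
    a_novel: float = 2.0
    tau_novel: float = 60.0
    a_stim: float = 4.0
    stim_floor: float = 0.2
    tau_stim: float = 1.0
    sigma_ou: float = 0.5
    tau_ou: float = 5.0
    # render model
    gain: float = 10.0
    offset465: float = 1500.0
    offset405: float = 1500.0
    noise_sd: float = 1.0
    bleach: tuple[float, float, float, float] = (0.005, 300.0, 0.01, 3000.0)
    motion_rate: float = 6.0          # artifact events per minute
    motion_amp: float = 25.0          # additive amplitude, channel units
    motion_dur_s: float = 1.5
    multiplicative_motion: bool = False

    def __post_init__(self) -> None:
        for name in ("tau_fast", "tau_slow", "tau_bout_on", "tau_bout", "tau_novel",
                     "tau_ou", "tau_stim"):
            if getattr(self, name) <= 0:
                raise PhotocifError(f"{name} must be positive")
        if self.sigma_ou < 0 or self.noise_sd < 0 or self.motion_rate < 0:
            raise PhotocifError("noise scales and rates must be non-negative")
        a1, t1, a2, t2 = self.bleach
        if not (0 <= a1 < 1 and 0 <= a2 < 1 and t1 > 0 and t2 > 0):
            raise PhotocifError("bleach amplitudes must be in [0,1) with positive taus")
        if self.offset405 <= 0:
            raise PhotocifError("offset405 must be positive (downstream division)")

    # -- model-implied ground truth used by parameter-recovery checks ------

    def dff_per_activity(self) -> float:
        """ΔF/F units per latent-activity unit, gain / offset405."""
        return self.gain / self.offset405

    def dff_noise_sd(self) -> float:
        """Stationary SD of a quiet-baseline ΔF/F trace (OU + white noise)."""
        return np.hypot(self.gain * self.sigma_ou, np.sqrt(2.0) * self.noise_sd) / self.offset405

    def programmed_z_suppression(
        self,
        protocol: "Protocol",
        baseline_s: float = 600.0,
        window_s: tuple[float, float] = (0.0, 600.0),
    ) -> float:
        """Model-implied z-scale post-food suppression for this protocol.

        Baseline-window mean minus post-food-window mean of the noise-free
        deterministic drive, divided by the model's stationary baseline SD
        (OU plus measurement noise expressed in the same latent units).
        """
        if protocol.food_time is None:
            return 0.0
        rate = LATENT_RATE_HZ
        t = np.arange(int(round(protocol.session_length * rate))) / rate
        drive = _deterministic_drive(self, protocol, t)
        rel = t - protocol.food_time
        base = drive[(rel >= -baseline_s) & (rel < 0)].mean()
        post = drive[(rel >= window_s[0]) & (rel < window_s[1])].mean()
        sd_latent = np.hypot(self.sigma_ou, np.sqrt(2.0) * self.noise_sd / self.gain)
        return float((base - post) / sd_latent)

    def programmed_dff_bout_dip(self) -> float:
        """Model-implied bout-dip amplitude on the ΔF/F scale."""
        return self.a_bout * self.dff_per_activity()


@dataclass
class Protocol:
    """Timeline of one recording session on a single clock (seconds).

    ``novelty_scale`` scales the context-transfer transient; familiar
    contexts (habituated mice, training days) use a reduced scale.
    """

    phase: str = "training"            # training | test | homecage
    state: str = "fasted"              # fed | fasted
    session_length: float = 2400.0
    context_entry_time: float | None = 600.0
    food_time: float | None = 1200.0
    bout_schedule: list[tuple[float, float]] = field(default_factory=list)
    stim_envelope: list[tuple[float, float, str]] = field(default_factory=list)
    context_id: str = "A"
    novelty_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.session_length <= 0:
            raise PhotocifError("session_length must be positive")
        if self.state not in ("fed", "fasted"):
            raise PhotocifError(f"unknown state {self.state!r}")
        for t in filter(None, (self.context_entry_time, self.food_time)):
            if not 0 <= t <= self.session_length:
                raise PhotocifError("event times must fall within the session")
        prev_end = None
        for onset, dur in self.bout_schedule:
            if dur <= 0:
                raise PhotocifError(f"bout at {onset} s has non-positive duration")
            if self.food_time is None or onset < self.food_time:
                raise PhotocifError("bouts must start after food presentation")
            if onset + dur > self.session_length:
                raise PhotocifError("bout extends past session end")
            if prev_end is not None and onset < prev_end:
                raise PhotocifError("bout schedule must be ordered and non-overlapping")
            prev_end = onset + dur
        prev_off = None
        for on, off, mode in self.stim_envelope:
            if off <= on or on < 0 or off > self.session_length:
                raise PhotocifError("stim envelope outside session or non-positive")
            if mode not in STIM_DUTY:
                raise PhotocifError(f"unknown stim mode {mode!r}")
            if prev_off is not None and on < prev_off:
                raise PhotocifError("overlapping stim envelopes")
            prev_off = off

    @property
    def bout_onsets(self) -> np.ndarray:
        return np.array([on for on, _ in self.bout_schedule], dtype=float)

    def events(self) -> list[tuple[str, float]]:
        ev: list[tuple[str, float]] = []
        if self.context_entry_time is not None:
            ev.append(("context_entry", self.context_entry_time))
        if self.food_time is not None:
            ev.append(("food", self.food_time))
        for on, dur in self.bout_schedule:
            ev.append(("bout", on))
        for on, off, mode in self.stim_envelope:
            ev.append((f"stim_on:{mode}", on))
            ev.append((f"stim_off:{mode}", off))
        return sorted(ev, key=lambda e: e[1])

    # -- factories mirroring the study timelines ---------------------------

    @classmethod
    def training(
        cls,
        state: str = "fasted",
        context_id: str = "A",
        homecage_s: float = 600.0,
        context_to_food_s: float = 600.0,
        post_food_s: float = 1200.0,
        n_bouts: int | None = None,
        rng: np.random.Generator | None = None,
        novelty_scale: float = 0.25,
    ) -> "Protocol":
        """Training session: home cage, transfer into context A, food 10 min later."""
        entry = homecage_s
        food = entry + context_to_food_s
        length = food + post_food_s
        if n_bouts is None:
            n_bouts = {"fasted": 10, "fed": 3}[state]
        bouts = make_bout_schedule(food, length, n_bouts, rng)
        return cls(
            phase="training", state=state, session_length=length,
            context_entry_time=entry, food_time=food, bout_schedule=bouts,
            context_id=context_id, novelty_scale=novelty_scale,
        )

    @classmethod
    def test(
        cls,
        context_id: str,
        familiar: bool,
        homecage_s: float = 600.0,
        context_to_food_s: float = 600.0,
        post_food_s: float = 1200.0,
        n_bouts: int = 6,
        rng: np.random.Generator | None = None,
    ) -> "Protocol":
        """Test session in context A or B, fed state, food added 10 min after transfer."""
        entry = homecage_s
        food = entry + context_to_food_s
        length = food + post_food_s
        bouts = make_bout_schedule(food, length, n_bouts, rng)
        return cls(
            phase="test", state="fed", session_length=length,
            context_entry_time=entry, food_time=food, bout_schedule=bouts,
            context_id=context_id, novelty_scale=0.4 if familiar else 1.0,
        )


def make_bout_schedule(
    food_time: float,
    session_end: float,
    n_bouts: int,
    rng: np.random.Generator | None = None,
    dur_range: tuple[float, float] = (5.0, 10.0),
    min_gap: float = 30.0,
    first_delay: float = 60.0,
) -> list[tuple[float, float]]:
    """Draw an ordered non-overlapping feeding-bout schedule after food.

    Bouts last 5-10 s, start at least ``first_delay`` s after food (off the
    steep part of the sensory drop) and are separated by at least
    ``min_gap`` s so recovery tails stay out of neighbouring baselines.
    Without an rng the schedule is evenly spaced (deterministic).
    """
    if n_bouts <= 0:
        return []
    t0 = food_time + first_delay
    span = session_end - 60.0 - t0
    max_bouts = int(span // (min_gap + dur_range[1])) + 1
    n_bouts = min(n_bouts, max_bouts)
    if n_bouts <= 0:
        return []
    slots = np.linspace(t0, t0 + span - dur_range[1], n_bouts)
    out = []
    prev_end = -np.inf
    for s in slots:
        if rng is not None:
            s = s + rng.uniform(0, min(10.0, max(span / max(n_bouts, 1) - min_gap, 0.0)))
            dur = rng.uniform(*dur_range)
        else:
            dur = float(np.mean(dur_range))
        s = max(s, prev_end + min_gap)
        if s + dur > session_end - 30.0:
            break
        out.append((float(s), float(dur)))
        prev_end = s + dur
    return out


# ---------------------------------------------------------------------------
# latent activity
# ---------------------------------------------------------------------------

@dataclass
class ActivityTrace:
    """Latent AgRP activity series with its generating protocol."""

    time: np.ndarray
    activity: np.ndarray
    rate: float
    protocol: Protocol


def _smooth_box(box: np.ndarray, tau: float, rate: float) -> np.ndarray:
    """First-order low-pass of a box envelope (exponential edges)."""
    alpha = np.exp(-1.0 / (tau * rate))
    return _sig.lfilter([1.0 - alpha], [1.0, -alpha], box)


def _deterministic_drive(params: AgrpParams, protocol: Protocol, t: np.ndarray) -> np.ndarray:
    """Noise-free latent drive; the 'programmed' part of the activity model."""
    p, pr = params, protocol
    a = np.full(t.shape, p.mu_fasted if pr.state == "fasted" else p.mu_fed)

    if pr.context_entry_time is not None:
        d = t - pr.context_entry_time
        m = d >= 0
        a[m] += pr.novelty_scale * p.a_novel * np.exp(-d[m] / p.tau_novel)

    if pr.food_time is not None:
        d = t - pr.food_time
        m = d >= 0
        a[m] -= p.a_drop * (1.0 - np.exp(-d[m] / p.tau_fast)) * np.exp(-d[m] / p.tau_slow)

    for onset, dur in pr.bout_schedule:
        d = t - onset
        during = (d >= 0) & (d < dur)
        a[during] -= p.a_bout * (1.0 - np.exp(-d[during] / p.tau_bout_on))
        depth_off = p.a_bout * (1.0 - np.exp(-dur / p.tau_bout_on))
        after = d >= dur
        a[after] -= depth_off * np.exp(-(d[after] - dur) / p.tau_bout)

    rate = 1.0 / (t[1] - t[0]) if t.size > 1 else LATENT_RATE_HZ
    for on, off, mode in pr.stim_envelope:
        box = ((t >= on) & (t < off)).astype(float)
        env = _smooth_box(box, p.tau_stim, rate)
        if mode.startswith("excite"):
            a = a + p.a_stim * STIM_DUTY[mode] * env
        else:
            a = p.stim_floor + (a - p.stim_floor) * (1.0 - env)
    return a


def _ou_noise(params: AgrpParams, n: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Exact AR(1) discretisation of an OU process, stationary start."""
    if params.sigma_ou == 0:
        return np.zeros(n)
    phi = np.exp(-1.0 / (params.tau_ou * rate))
    innov_sd = params.sigma_ou * np.sqrt(1.0 - phi**2)
    x0 = rng.standard_normal() * params.sigma_ou
    w = innov_sd * rng.standard_normal(n)
    x, _ = _sig.lfilter([1.0], [1.0, -phi], w, zi=np.array([phi * x0]))
    return x


def simulate_activity(
    params: AgrpParams, protocol: Protocol, seed: int, rate: float = LATENT_RATE_HZ
) -> ActivityTrace:
    """Latent AgRP activity: deterministic drive + OU noise, clipped at zero."""
    n = int(round(protocol.session_length * rate))
    t = np.arange(n) / rate
    drive = _deterministic_drive(params, protocol, t)
    ou = _ou_noise(params, n, rate, stream_rng(seed, "activity", protocol.phase, protocol.context_id))
    return ActivityTrace(time=t, activity=np.maximum(drive + ou, 0.0), rate=rate, protocol=protocol)


# ---------------------------------------------------------------------------
# photometry rendering
# ---------------------------------------------------------------------------

def _bleach_envelope(params: AgrpParams, t: np.ndarray) -> np.ndarray:
    a1, t1, a2, t2 = params.bleach
    return 1.0 - a1 * (1.0 - np.exp(-t / t1)) - a2 * (1.0 - np.exp(-t / t2))


def _motion_series(
    params: AgrpParams, t: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Sparse additive motion artifacts: half-sine pulses at Poisson times."""
    m = np.zeros(t.size)
    if params.motion_rate == 0 or params.motion_amp == 0:
        return m
    duration = t.size / rate
    n_ev = rng.poisson(params.motion_rate / 60.0 * duration)
    onsets = np.sort(rng.uniform(0, duration - params.motion_dur_s, size=n_ev))
    amps = params.motion_amp * rng.uniform(0.5, 1.5, size=n_ev)
    k = int(round(params.motion_dur_s * rate))
    pulse = np.sin(np.pi * np.arange(k) / k)
    for on, amp in zip(onsets, amps):
        i0 = int(round(on * rate))
        m[i0 : i0 + k] += amp * pulse[: t.size - i0]
    return m


def render_photometry(
    trace: ActivityTrace, params: AgrpParams, seed: int
) -> tuple[PhotometrySession, dict]:
    """Render latent activity into a two-channel session plus ground truth.

    The motion artifact series is numerically identical in both channels
    (additive mode, default); ``truth`` carries the artifact, bleach and
    latent series for correction tests.
    """
    a = np.asarray(trace.activity, dtype=float)
    if not np.all(np.isfinite(a)) or np.any(a < 0):
        raise PhotocifError("activity must be finite and non-negative")
    t = trace.time
    bleach = _bleach_envelope(params, t)
    motion = _motion_series(params, t, trace.rate, stream_rng(seed, "motion", trace.protocol.phase, trace.protocol.context_id))
    rng = stream_rng(seed, "shot", trace.protocol.phase, trace.protocol.context_id)
    s465 = (params.gain * a + params.offset465) * bleach
    s405 = params.offset405 * bleach
    if params.multiplicative_motion:
        f465 = s465 * (1.0 + motion / params.offset405) + params.noise_sd * rng.standard_normal(t.size)
        f405 = s405 * (1.0 + motion / params.offset405) + params.noise_sd * rng.standard_normal(t.size)
    else:
        f465 = s465 + motion + params.noise_sd * rng.standard_normal(t.size)
        f405 = s405 + motion + params.noise_sd * rng.standard_normal(t.size)
    session = PhotometrySession(
        time=t, f465=f465, f405=f405, rate=trace.rate,
        events=trace.protocol.events(),
        meta={"phase": trace.protocol.phase, "state": trace.protocol.state,
              "context": trace.protocol.context_id},
    )
    truth = {"motion": motion, "bleach": bleach, "activity": a}
    return session, truth


# ---------------------------------------------------------------------------
# tracking and ethogram
# ---------------------------------------------------------------------------

#: mean dwell time per behaviour state (s) for the label Markov chain
_DWELL_S = {"sniffing_food": 3.0, "walking": 4.0, "stationary": 6.0,
            "rearing": 2.0, "grooming": 5.0}


def simulate_tracking(
    protocol: Protocol,
    zones: ZoneSet,
    seed: int,
    rate: float = TRACKING_RATE_HZ,
    speed_cm_s: float = 6.0,
) -> tuple[TrackingTrace, Ethogram]:
    """Biased random walk plus a dwell-time Markov chain of behaviour labels.

    During scheduled feeding bouts the position is pinned inside the food
    zone and the frame label is 'eating'; the walk is confined to the arena
    by reflecting at the walls.  Arena coordinates are used for the whole
    session clock (the home-cage segment is not distinguished spatially).
    """
    n = int(round(protocol.session_length * rate))
    t = np.arange(n) / rate
    rng = stream_rng(seed, "tracking", protocol.phase, protocol.context_id)

    x = np.empty(n)
    y = np.empty(n)
    pos = np.array([zones.arena_w / 2.0, zones.arena_h / 2.0])
    heading = rng.uniform(0, 2 * np.pi)
    in_bout = np.zeros(n, dtype=bool)
    for onset, dur in protocol.bout_schedule:
        in_bout[(t >= onset) & (t < onset + dur)] = True

    step_len = speed_cm_s / rate
    fx, fy = zones.food_center
    for i in range(n):
        if in_bout[i]:
            jitter = rng.uniform(-1, 1, size=2) * (0.3 * zones.food_radius if speed_cm_s > 0 else 0.0)
            pos = np.array([fx, fy]) + jitter
        elif step_len > 0:
            heading += rng.normal(0, 0.6)
            step = step_len * abs(rng.normal(1.0, 0.3))
            pos = pos + step * np.array([np.cos(heading), np.sin(heading)])
            for k, hi in ((0, zones.arena_w), (1, zones.arena_h)):
                if pos[k] < 0:
                    pos[k] = -pos[k]
                    heading = np.pi - heading if k == 0 else -heading
                if pos[k] > hi:
                    pos[k] = 2 * hi - pos[k]
                    heading = np.pi - heading if k == 0 else -heading
            pos = np.clip(pos, 0, [zones.arena_w, zones.arena_h])
        x[i], y[i] = pos

    labels = np.empty(n, dtype=object)
    states = [lab for lab in BEHAVIOR_LABELS if lab != "eating"]
    state = states[rng.integers(len(states))]
    i = 0
    while i < n:
        p_leave = 1.0 / max(_DWELL_S[state] * rate, 1.0)
        dwell = int(rng.geometric(p_leave))
        labels[i : i + dwell] = state
        i += dwell
        k = int(rng.integers(len(states) - 1))
        if k >= states.index(state):
            k += 1
        state = states[k]
    labels[in_bout] = "eating"

    return (
        TrackingTrace(time=t, x=x, y=y, rate=rate),
        Ethogram(time=t, behavior=labels, rate=rate),
    )


# ---------------------------------------------------------------------------
# cohort-level simulation
# ---------------------------------------------------------------------------

@dataclass
class GroupSpec:
    """One experimental group of the cohort design."""

    label: str
    n: int
    state: str = "fasted"             # training energy state
    treatment: str = "saline"
    effect_g: float = 0.0             # programmed CIF discrimination (A - B), grams
    train_mean_g: float = 0.5         # mean intake per 30-min training session
    train_test_corr: float = 0.0      # programmed corr(training intake, A - B)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise PhotocifError(f"group {self.label!r} must have n >= 1")
        if not -1.0 <= self.train_test_corr <= 1.0:
            raise PhotocifError("train_test_corr must lie in [-1, 1]")


def default_groups() -> list[GroupSpec]:
    """Three-group design: fed, ghrelin-treated and fasted training."""
    return [
        GroupSpec("FED", 10, state="fed", treatment="saline",
                  effect_g=0.0, train_mean_g=0.15, train_test_corr=0.2),
        GroupSpec("GHRELIN", 10, state="fed", treatment="ghrelin",
                  effect_g=0.05, train_mean_g=0.35, train_test_corr=0.2),
        GroupSpec("FASTED", 9, state="fasted", treatment="saline",
                  effect_g=0.3, train_mean_g=0.8, train_test_corr=0.59),
    ]


@dataclass
class CohortDesign:
    """Cohort structure, programmed effects and noise levels."""

    groups: list[GroupSpec] = field(default_factory=default_groups)
    intake_noise_g: float = 0.15
    test_base_g: float = 0.3
    train_sd_g: float = 0.1           # per-mouse trait SD on training intake
    session_sd_g: float = 0.05        # per-session noise on training intake
    signals_per_group: int = 4        # mice per group with rendered signals
    seed: int = 0
    # session timeline knobs shared by all protocols
    homecage_s: float = 600.0
    context_to_food_s: float = 600.0
    post_food_s: float = 1200.0

    def __post_init__(self) -> None:
        if not self.groups:
            raise PhotocifError("cohort design needs at least one group")
        if self.intake_noise_g < 0:
            raise PhotocifError("intake noise SD must be non-negative")


@dataclass
class CohortResult:
    """Simulated cohort: intake records, ground truth, optional session bundles."""

    records: pd.DataFrame
    truth: dict
    sessions: dict | None = None      # (mouse, session_name) -> bundle dict


def _session_names(order_a_first: bool) -> list[tuple[str, int, str]]:
    tests = [("test", 1, "A"), ("test", 2, "B")] if order_a_first else [
        ("test", 1, "B"), ("test", 2, "A")]
    return [("training", d, "A") for d in (1, 2, 3)] + tests


def simulate_cohort(
    design: CohortDesign,
    params: AgrpParams | None = None,
    with_sessions: bool = True,
) -> CohortResult:
    """Simulate intake records (all mice) and session bundles (a subset).

    Per mouse: three training sessions in context A and two counterbalanced
    test sessions (A and B).  Test intake in A equals intake in B plus the
    group's programmed effect plus noise; a per-mouse trait couples training
    intake to the A-B difference at the group's programmed correlation.
    Negative intakes are truncated at 0 g and counted.
    """
    params = params or AgrpParams()
    rng = stream_rng(design.seed, "cohort")
    rows = []
    truncated = 0
    traits: dict[str, float] = {}
    sessions: dict | None = {} if with_sessions else None

    mouse_idx = 0
    for g in design.groups:
        for j in range(g.n):
            mouse = f"{g.label.lower()}_{j:02d}"
            u = rng.standard_normal()
            traits[mouse] = u
            order_a_first = j % 2 == 0

            train_intakes = []
            for day in (1, 2, 3):
                intake = (g.train_mean_g + design.train_sd_g * u
                          + design.session_sd_g * rng.standard_normal())
                if intake < 0:
                    truncated += 1
                    intake = 0.0
                train_intakes.append(intake)

            rho = g.train_test_corr
            diff = g.effect_g + design.intake_noise_g * (
                rho * u + np.sqrt(1.0 - rho**2) * rng.standard_normal())
            b = design.test_base_g + design.intake_noise_g * rng.standard_normal()
            if b < 0:
                truncated += 1
                b = 0.0
            a_int = b + diff
            if a_int < 0:
                truncated += 1
                a_int = 0.0

            for (phase, day, ctx) in _session_names(order_a_first):
                if phase == "training":
                    intake = train_intakes[day - 1]
                else:
                    intake = a_int if ctx == "A" else b
                rows.append((mouse, g.label, g.state, g.treatment, phase,
                             f"{phase}_d{day}" if phase == "training" else "test",
                             day, ctx, intake, order_a_first))

            if with_sessions and j < design.signals_per_group:
                srng = stream_rng(design.seed, "sessions", mouse)
                for (phase, day, ctx) in _session_names(order_a_first):
                    if phase == "training":
                        proto = Protocol.training(
                            state=g.state, context_id=ctx,
                            homecage_s=design.homecage_s,
                            context_to_food_s=design.context_to_food_s,
                            post_food_s=design.post_food_s, rng=srng,
                        )
                    else:
                        proto = Protocol.test(
                            context_id=ctx, familiar=(ctx == "A"),
                            homecage_s=design.homecage_s,
                            context_to_food_s=design.context_to_food_s,
                            post_food_s=design.post_food_s, rng=srng,
                            n_bouts=8 if ctx == "A" else 5,
                        )
                    sess_seed = int(stream_rng(design.seed, "seed", mouse, phase, day, ctx
                                               ).integers(2**31))
                    trace = simulate_activity(params, proto, sess_seed)
                    photo, truth_s = render_photometry(trace, params, sess_seed)
                    photo.meta.update({"mouse": mouse, "group": g.label, "day": day})
                    zones = ZoneSet()
                    track, eth = simulate_tracking(proto, zones, sess_seed)
                    key = (mouse, f"{phase}_d{day}_{ctx}" if phase == "training"
                           else f"test_{ctx}")
                    sessions[key] = {
                        "protocol": proto, "photometry": photo, "tracking": track,
                        "ethogram": eth, "zones": zones, "truth": truth_s,
                    }
            mouse_idx += 1

    if truncated:
        log.warning("truncated %d negative intake draws at 0 g", truncated)

    records = pd.DataFrame(
        rows,
        columns=["mouse", "group", "state", "treatment", "phase", "session",
                 "day", "context", "intake_g", "a_first"],
    )
    truth = {
        "effects": {g.label: g.effect_g for g in design.groups},
        "train_means": {g.label: g.train_mean_g for g in design.groups},
        "traits": traits,
        "truncated": truncated,
        "params": params,
        "design": design,
    }
    return CohortResult(records=records, truth=truth, sessions=sessions)
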