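"""Session-bundle I/O, run configuration and the end-to-end pipeline.

Interchange format is plain CSV (UTF-8, '.' decimal).  A session bundle is
one directory per mouse-session:

    photometry.csv   time_s, f465, f405
    events.csv       label, time_s
    tracking.csv     time_s, x_cm, y_cm
    labels.csv       time_s, behavior
    meta.yaml        rates, identifiers, protocol summary

plus a cohort-level ``intake.csv``.  Every CSV written by the pipeline
carries ``#``-prefixed header lines with the package version, the config
hash and the seed, so a run is traceable and two runs with identical config
and seed produce byte-identical outputs.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .behavior import (
    Ethogram,
    TrackingTrace,
    ZoneSet,
    barcode,
    detect_bouts,
    locomotion_metrics,
    zone_metrics,
)
from .errors import PhotocifError, SchemaError
from .photometry import (
    PhotometrySession,
    bout_triggered_average,
    build_perievent,
    compute_dff,
    suppression_estimate,
    window_means,
)
from .report import assemble_report, plot_report
from .synth import AgrpParams, CohortDesign, GroupSpec, simulate_cohort

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ZoneConfig(_Strict):
    arena_w: float = 40.0
    arena_h: float = 40.0
    food_x: float = 10.0
    food_y: float = 10.0
    food_radius: float = 6.0
    approach_margin: float = 5.0

    def to_zones(self) -> ZoneSet:
        return ZoneSet(self.arena_w, self.arena_h, (self.food_x, self.food_y),
                       self.food_radius, self.approach_margin)


class GroupConfig(_Strict):
    label: str
    n: int
    state: str = "fasted"
    treatment: str = "saline"
    effect_g: float = 0.0
    train_mean_g: float = 0.5
    train_test_corr: float = 0.0


class DesignConfig(_Strict):
    groups: list[GroupConfig] | None = None
    intake_noise_g: float = 0.15
    test_base_g: float = 0.3
    signals_per_group: int = 4
    homecage_s: float = 600.0
    context_to_food_s: float = 600.0
    post_food_s: float = 1200.0

    def to_design(self, seed: int) -> CohortDesign:
        kwargs = dict(
            intake_noise_g=self.intake_noise_g, test_base_g=self.test_base_g,
            signals_per_group=self.signals_per_group, seed=seed,
            homecage_s=self.homecage_s, context_to_food_s=self.context_to_food_s,
            post_food_s=self.post_food_s,
        )
        if self.groups is not None:
            kwargs["groups"] = [GroupSpec(**g.model_dump()) for g in self.groups]
        return CohortDesign(**kwargs)


class ParamsConfig(_Strict):
    """Overrides for the generator's ground-truth parameters."""
    model_config = ConfigDict(extra="forbid")
    overrides: dict[str, float | bool | list[float]] = Field(default_factory=dict)

    def to_params(self) -> AgrpParams:
        kw = dict(self.overrides)
        if "bleach" in kw:
            kw["bleach"] = tuple(kw["bleach"])
        return AgrpParams(**kw)


class AnalysisConfig(_Strict):
    """Peri-food analysis windows.

    When ``baseline_min`` / ``windows_min`` are left unset they follow the
    design's session timeline: baseline is the full context-to-food period
    and the post-food span splits into two equal windows (the study layout:
    -10..0, 0..10 and 10..20 min at the default timing).
    """

    align_label: str = "food"
    baseline_min: float | None = None
    windows_min: list[tuple[str, float, float]] | None = None
    mode: str = "z"
    fit_isosbestic: bool = False

    def resolve_windows_s(self, design: CohortDesign) -> tuple[float, list]:
        base_s = (self.baseline_min * 60.0 if self.baseline_min is not None
                  else design.context_to_food_s)
        if self.windows_min is not None:
            return base_s, [(lab, s * 60.0, e * 60.0) for lab, s, e in self.windows_min]
        half = design.post_food_s / 2.0
        windows = [
            (f"-{base_s / 60:g}-0 min", -base_s, 0.0),
            (f"0-{half / 60:g} min", 0.0, half),
            (f"{half / 60:g}-{2 * half / 60:g} min", half, 2 * half),
        ]
        return base_s, windows


class BehaviorConfig(_Strict):
    window_s: tuple[float, float] | None = None
    bin_s: float = 10.0
    min_bout_s: float = 1.0
    merge_gap_s: float = 2.0
    hysteresis_s: float = 0.2


class StatsConfig(_Strict):
    alpha: float = 0.05
    resamples: int = 10000


class RunConfig(_Strict):
    """Validated configuration for one end-to-end reproducible run."""

    seed: int = 0
    out: str = "photocif_out"
    design: DesignConfig = Field(default_factory=DesignConfig)
    params: ParamsConfig = Field(default_factory=ParamsConfig)
    zones: ZoneConfig = Field(default_factory=ZoneConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    behavior: BehaviorConfig = Field(default_factory=BehaviorConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)
    make_plots: bool = False

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output path excluded)."""
        payload = self.model_dump(mode="json")
        payload.pop("out", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return RunConfig(**raw)
    except Exception as exc:  # pydantic ValidationError
        raise SchemaError(f"{path}: invalid run config: {exc}") from exc


# ---------------------------------------------------------------------------
# CSV helpers
# ---------------------------------------------------------------------------

def _write_csv(path: Path, df: pd.DataFrame, header: dict | None = None) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        for key, val in (header or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False)


def _read_csv(path: Path, required: tuple[str, ...]) -> pd.DataFrame:
    if not Path(path).exists():
        raise SchemaError(f"{path}: file missing from session bundle")
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise SchemaError(f"{path}: unreadable CSV ({exc})") from exc
    missing = set(required) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    for i, col in enumerate(required):
        if df[col].isna().any():
            line = int(df[df[col].isna()].index[0]) + 2  # 1-based + header
            raise SchemaError(f"{path}: empty/invalid value in {col!r} near line {line}")
    return df


# ---------------------------------------------------------------------------
# session bundles
# ---------------------------------------------------------------------------

def write_session(
    path,
    photometry: PhotometrySession,
    tracking: TrackingTrace | None = None,
    ethogram: Ethogram | None = None,
    meta: dict | None = None,
    header: dict | None = None,
) -> Path:
    """Write one mouse-session bundle directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    _write_csv(path / "photometry.csv",
               pd.DataFrame({"time_s": photometry.time, "f465": photometry.f465,
                             "f405": photometry.f405}), header)
    _write_csv(path / "events.csv",
               pd.DataFrame(photometry.events, columns=["label", "time_s"]), header)
    if tracking is not None:
        _write_csv(path / "tracking.csv",
                   pd.DataFrame({"time_s": tracking.time, "x_cm": tracking.x,
                                 "y_cm": tracking.y}), header)
    if ethogram is not None:
        _write_csv(path / "labels.csv",
                   pd.DataFrame({"time_s": ethogram.time, "behavior": ethogram.behavior}),
                   header)
    full_meta = {"photometry_rate_hz": float(photometry.rate)}
    if tracking is not None:
        full_meta["tracking_rate_hz"] = float(tracking.rate)
    full_meta.update(photometry.meta)
    full_meta.update(meta or {})
    with open(path / "meta.yaml", "w") as fh:
        yaml.safe_dump(full_meta, fh, sort_keys=True)
    return path


def read_session(path) -> dict:
    """Read and validate one session bundle; all clocks reconciled.

    Returns a dict with keys ``photometry``, ``tracking``, ``ethogram``
    (the latter two None when absent) and ``meta``.  Photometry and
    tracking must start within one sample period of each other.
    """
    path = Path(path)
    meta_path = path / "meta.yaml"
    if not meta_path.exists():
        raise SchemaError(f"{meta_path}: file missing from session bundle")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh) or {}

    pdf = _read_csv(path / "photometry.csv", ("time_s", "f465", "f405"))
    t = pdf["time_s"].to_numpy(dtype=float)
    if t.size >= 2 and np.any(np.diff(t) <= 0):
        raise SchemaError(f"{path / 'photometry.csv'}: time_s not strictly increasing")
    rate = float(meta.get("photometry_rate_hz") or (1.0 / (t[1] - t[0])))
    events_df = _read_csv(path / "events.csv", ("label", "time_s")) if (
        path / "events.csv").exists() else pd.DataFrame(columns=["label", "time_s"])
    try:
        photometry = PhotometrySession(
            time=t, f465=pdf["f465"].to_numpy(dtype=float),
            f405=pdf["f405"].to_numpy(dtype=float), rate=rate,
            events=[(str(r.label), float(r.time_s)) for r in events_df.itertuples()],
            meta=dict(meta),
        )
    except PhotocifError as exc:
        raise SchemaError(f"{path / 'photometry.csv'}: {exc}") from exc

    tracking = ethogram = None
    if (path / "tracking.csv").exists():
        tdf = _read_csv(path / "tracking.csv", ("time_s", "x_cm", "y_cm"))
        trate = float(meta.get("tracking_rate_hz") or
                      (1.0 / (tdf["time_s"].iloc[1] - tdf["time_s"].iloc[0])))
        tracking = TrackingTrace(time=tdf["time_s"].to_numpy(dtype=float),
                                 x=tdf["x_cm"].to_numpy(dtype=float),
                                 y=tdf["y_cm"].to_numpy(dtype=float), rate=trate)
        if abs(tracking.time[0] - photometry.time[0]) > 1.0 / min(rate, trate):
            raise SchemaError(
                f"{path}: photometry and tracking clocks differ by more than one sample"
            )
    if (path / "labels.csv").exists():
        ldf = _read_csv(path / "labels.csv", ("time_s", "behavior"))
        lrate = float(meta.get("tracking_rate_hz") or
                      (1.0 / (ldf["time_s"].iloc[1] - ldf["time_s"].iloc[0])))
        ethogram = Ethogram(time=ldf["time_s"].to_numpy(dtype=float),
                            behavior=ldf["behavior"].to_numpy(dtype=object), rate=lrate)
    return {"photometry": photometry, "tracking": tracking,
            "ethogram": ethogram, "meta": meta}


def write_intake(path, records: pd.DataFrame, header: dict | None = None) -> None:
    cols = ["mouse", "group", "state", "treatment", "phase", "session",
            "day", "context", "intake_g", "a_first"]
    _write_csv(Path(path), records[cols], header)


def read_intake(path) -> pd.DataFrame:
    return _read_csv(Path(path), ("mouse", "group", "phase", "context", "intake_g"))


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """simulate -> photometry -> behaviour -> report, all under one seed.

    Writes session bundles, stage tables and the report to ``config.out``
    and returns a summary dict of output paths.  Re-running with an
    identical config reproduces byte-identical CSVs.
    """
    out = Path(config.out)
    header = {
        "photocif_version": __version__,
        "config_sha256": config.config_hash(),
        "seed": config.seed,
    }
    log.info("pipeline start: out=%s seed=%d config=%s", out, config.seed,
             config.config_hash())

    # --- stage 1: simulate -------------------------------------------------
    try:
        params = config.params.to_params()
        design = config.design.to_design(config.seed)
        cohort = simulate_cohort(design, params=params, with_sessions=True)
    except PhotocifError as exc:
        raise PhotocifError(f"[simulate] {exc}") from exc
    write_intake(out / "intake.csv", cohort.records, header)
    zones = config.zones.to_zones()
    session_dirs = {}
    for key, bundle in (cohort.sessions or {}).items():
        mouse, sess = key
        d = write_session(out / "sessions" / f"{mouse}__{sess}",
                          bundle["photometry"], bundle["tracking"],
                          bundle["ethogram"], header=header)
        session_dirs[key] = d
    log.info("[simulate] %d mice, %d session bundles",
             cohort.records["mouse"].nunique(), len(session_dirs))

    # --- stage 2: photometry ----------------------------------------------
    try:
        food_rows, bout_rows = [], []
        base_s, windows_s = config.analysis.resolve_windows_s(design)
        for (mouse, sess), bundle in (cohort.sessions or {}).items():
            photo: PhotometrySession = bundle["photometry"]
            food_times = photo.event_times(config.analysis.align_label)
            if food_times.size:
                dff = compute_dff(photo.f465, photo.f405)
                # stop one sample short so a window ending at session end fits
                m = build_perievent(
                    dff, photo.time, food_times,
                    pre=base_s,
                    post=max(e for _, _, e in windows_s) - 1.0 / photo.rate,
                    baseline=(-base_s, 0.0),
                    mode=config.analysis.mode,
                )
                wm = window_means(m, windows_s)
                wm.insert(0, "session", sess)
                wm.insert(0, "mouse", mouse)
                food_rows.append(wm)
            bouts = photo.event_times("bout")
            if bouts.size:
                _, bw = bout_triggered_average(photo, bouts, mode=config.analysis.mode)
                bw.insert(0, "session", sess)
                bw.insert(0, "mouse", mouse)
                bout_rows.append(bw)
        if food_rows:
            _write_csv(out / "photometry" / "window_means_food.csv",
                       pd.concat(food_rows, ignore_index=True), header)
        if bout_rows:
            _write_csv(out / "photometry" / "window_means_bouts.csv",
                       pd.concat(bout_rows, ignore_index=True), header)
    except PhotocifError as exc:
        raise PhotocifError(f"[photometry] {exc}") from exc

    # --- stage 3: behaviour ------------------------------------------------
    try:
        brows, crows = [], []
        for (mouse, sess), bundle in (cohort.sessions or {}).items():
            track: TrackingTrace = bundle["tracking"]
            eth: Ethogram = bundle["ethogram"]
            zm = zone_metrics(track, zones, hysteresis_s=config.behavior.hysteresis_s)
            dist, vel = locomotion_metrics(track)
            bouts = detect_bouts(eth, config.behavior.min_bout_s, config.behavior.merge_gap_s)
            entry = bundle["protocol"].context_entry_time or 0.0
            win = config.behavior.window_s or (entry, min(entry + 600.0, eth.duration))
            bins, percent, agg = barcode(eth, window=win, bin_s=config.behavior.bin_s)
            row = {"mouse": mouse, "session": sess, "distance_cm": dist,
                   "velocity_cm_s": vel, "n_bouts": bouts.count,
                   "eating_total_s": bouts.total_duration,
                   "pct_food_related": agg["food_related"]}
            for r in zm.itertuples():
                row[f"{r.zone}_frequency"] = r.frequency
                row[f"{r.zone}_duration_s"] = r.duration_s
                row[f"{r.zone}_latency_s"] = r.latency_s
                row[f"{r.zone}_not_reached"] = r.not_reached
            for lab, pct in percent.items():
                row[f"pct_{lab}"] = pct
            brows.append(row)
            bins.insert(0, "session", sess)
            bins.insert(0, "mouse", mouse)
            crows.append(bins)
        behavior_table = pd.DataFrame(brows)
        if len(behavior_table):
            _write_csv(out / "behavior" / "behavior_metrics.csv", behavior_table, header)
            _write_csv(out / "behavior" / "barcode.csv",
                       pd.concat(crows, ignore_index=True), header)
    except PhotocifError as exc:
        raise PhotocifError(f"[behavior] {exc}") from exc

    # --- stage 4: report ---------------------------------------------------
    try:
        tables = assemble_report(
            cohort.records,
            behavior_table=behavior_table if len(behavior_table) else None,
            alpha=config.stats.alpha, resamples=config.stats.resamples,
            seed=config.seed,
        )
        for name, tab in tables.items():
            _write_csv(out / "report" / f"{name}.csv", tab, header)
        if config.make_plots:
            plot_report(tables, out / "report" / "figures")
    except PhotocifError as exc:
        raise PhotocifError(f"[report] {exc}") from exc

    log.info("pipeline done: %d report tables", len(tables))
    return {"out": out, "tables": sorted(tables), "n_sessions": len(session_dirs),
            "config_hash": config.config_hash()}
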