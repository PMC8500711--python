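"""Session container types, plain-text I/O, and behavioral bookkeeping.

A recording day consists of three sessions (pre-threat, threat, post-threat)
on a linear nest-corridor apparatus: the nest interior is x < 0, the gateway
sits at x = 0, and the food pellet at x = 125 cm.  Each session bundles the
animal tracking (30 frames/s by default), a trial-indexed event log
(gate openings, pellet procurements, robot surges / stimulations), and the
simultaneously recorded BA and dHPC spike trains.

Times are seconds throughout; spike times are kept at 0.1 ms resolution.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EVENT_KINDS = ("gate_open", "pellet_procured", "robot_surge", "stim_on", "trial_end")
SURGE_KINDS = ("robot_surge", "stim_on")
EPOCH_LABELS = ("pre_surge", "post_surge", "pre_pellet", "post_pellet")
EPOCH_WIDTH = 2.5  # s, width of every analysis epoch
TIME_RESOLUTION = 1e-4  # 0.1 ms

PHASES = ("pre_threat", "threat", "post_threat")


class ValidationError(ValueError):
    """Raised when a session component violates a structural invariant."""


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times of one unit.

    Parameters
    ----------
    cell_id : str
        Unique unit label within the session.
    region : {"BA", "dHPC"}
        Recording site: basal amygdala or dorsal hippocampus.
    times : ndarray
        Spike times in seconds, strictly increasing at 0.1 ms resolution.
    spike_width : float, optional
        Average extracellular spike width in ms (used by the
        pyramidal/interneuron split).
    """

    cell_id: str
    region: str
    times: np.ndarray
    spike_width: float | None = None
    session_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def mean_rate(self, duration: float) -> float:
        return self.n_spikes / duration if duration > 0 else 0.0

    def min_isi(self) -> float:
        """Smallest inter-spike interval in seconds (inf for <2 spikes)."""
        if self.times.size < 2:
            return np.inf
        return float(np.min(np.diff(self.times)))

    def validate(self, duration: float | None = None) -> None:
        t = self.times
        if t.size and not np.all(np.isfinite(t)):
            raise ValidationError(f"cell {self.cell_id}: non-finite spike times")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValidationError(
                f"cell {self.cell_id}: spike times not strictly increasing"
            )
        if t.size and t[0] < 0:
            raise ValidationError(f"cell {self.cell_id}: negative spike time {t[0]}")
        if duration is not None and t.size and t[-1] > duration:
            raise ValidationError(
                f"cell {self.cell_id}: spike at {t[-1]:.4f}s exceeds session "
                f"duration {duration:.4f}s"
            )


@dataclass(frozen=True)
class Tracking:
    """Animal position samples on a uniform frame grid.

    ``x`` is the corridor axis in cm (nest interior negative, pellet at
    125 cm); ``y`` is the lateral offset in cm.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))

    @property
    def n_frames(self) -> int:
        return int(self.t.size)

    @property
    def frame_interval(self) -> float:
        if self.t.size < 2:
            raise ValidationError("tracking needs >=2 frames for a frame interval")
        return float(np.median(np.diff(self.t)))

    @property
    def frame_rate(self) -> float:
        return 1.0 / self.frame_interval

    def validate(self) -> None:
        if self.t.size != self.x.size or self.t.size != self.y.size:
            raise ValidationError("tracking arrays have mismatched lengths")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValidationError("tracking timestamps not increasing")
            med = np.median(dt)
            if np.any(np.abs(dt - med) > 0.01 * med + 1e-9):
                raise ValidationError("tracking frame interval varies by >1%")
        if not np.all(np.isfinite(self.x)):
            raise ValidationError("tracking x contains non-finite values")


@dataclass(frozen=True)
class EventLog:
    """Trial-indexed behavioral events as a tidy table.

    Columns: ``trial`` (int, >=1), ``kind`` (one of EVENT_KINDS),
    ``time_s`` (float).
    """

    df: pd.DataFrame

    @classmethod
    def from_records(cls, records: Iterable[tuple[int, str, float]]) -> "EventLog":
        df = pd.DataFrame(records, columns=["trial", "kind", "time_s"])
        return cls(df.astype({"trial": int, "kind": str, "time_s": float}))

    def times_of(self, kind: str | Sequence[str]) -> np.ndarray:
        kinds = (kind,) if isinstance(kind, str) else tuple(kind)
        sel = self.df[self.df["kind"].isin(kinds)]
        return sel["time_s"].to_numpy(dtype=float)

    def trials(self) -> np.ndarray:
        return np.unique(self.df["trial"].to_numpy())

    @property
    def n_events(self) -> int:
        return len(self.df)

    def validate(self) -> None:
        df = self.df
        bad = set(df["kind"]) - set(EVENT_KINDS)
        if bad:
            raise ValidationError(f"unknown event kinds: {sorted(bad)}")
        if (df["trial"] < 1).any():
            raise ValidationError("event trial indices must be >= 1")
        for trial, grp in df.groupby("trial"):
            if not grp["time_s"].is_monotonic_increasing:
                raise ValidationError(f"trial {trial}: event times not sorted")
            for kind in ("gate_open", "pellet_procured"):
                if (grp["kind"] == kind).sum() > 1:
                    raise ValidationError(f"trial {trial}: multiple {kind} events")


@dataclass(frozen=True)
class Session:
    """One behavioral session with tracking, events, and spike trains."""

    session_id: str
    phase: str
    tracking: Tracking
    events: EventLog
    trains: tuple[SpikeTrain, ...]
    duration: float

    def __post_init__(self):
        object.__setattr__(self, "trains", tuple(self.trains))

    def train(self, cell_id: str) -> SpikeTrain:
        for tr in self.trains:
            if tr.cell_id == cell_id:
                return tr
        raise KeyError(cell_id)

    def trains_in(self, region: str) -> list[SpikeTrain]:
        return [tr for tr in self.trains if tr.region == region]

    @property
    def cell_ids(self) -> list[str]:
        return [tr.cell_id for tr in self.trains]

    def validate(self) -> None:
        if self.phase not in PHASES:
            raise ValidationError(f"unknown phase {self.phase!r}")
        self.tracking.validate()
        self.events.validate()
        for tr in self.trains:
            tr.validate(self.duration)
        times = self.events.df["time_s"]
        if len(times) and (times.max() > self.duration or times.min() < 0):
            raise ValidationError("event times outside session duration")
        has_surge = bool(len(self.events.times_of(SURGE_KINDS)))
        if (self.phase == "threat") != has_surge:
            raise ValidationError(
                f"phase {self.phase!r} inconsistent with "
                f"{'presence' if has_surge else 'absence'} of surge/stim events"
            )


@dataclass(frozen=True)
class EpochSet:
    """Per-trial 2.5 s analysis windows around surge or pellet events.

    Windows are half-open ``[start, end)`` and carry the trial index of the
    triggering event so the shift predictor can shuffle trials.
    """

    label: str
    windows: np.ndarray  # (n, 2)
    trials: np.ndarray  # (n,)

    def __post_init__(self):
        object.__setattr__(
            self, "windows", np.asarray(self.windows, dtype=float).reshape(-1, 2)
        )
        object.__setattr__(self, "trials", np.asarray(self.trials, dtype=int))

    @property
    def n_windows(self) -> int:
        return int(self.windows.shape[0])

    @property
    def total_time(self) -> float:
        return float(np.sum(self.windows[:, 1] - self.windows[:, 0]))

    def validate(self) -> None:
        if self.label not in EPOCH_LABELS:
            raise ValidationError(f"unknown epoch label {self.label!r}")
        widths = self.windows[:, 1] - self.windows[:, 0]
        if self.n_windows and not np.allclose(widths, EPOCH_WIDTH, atol=1e-9):
            raise ValidationError("epoch windows must be exactly 2.5 s wide")
        if self.n_windows > 1:
            order = np.argsort(self.windows[:, 0])
            w = self.windows[order]
            if np.any(w[1:, 0] < w[:-1, 1] - 1e-12):
                raise ValidationError("epoch windows overlap")


@dataclass(frozen=True)
class BehaviorSummary:
    """Per-session behavioral metrics (success rate, outbound latency...)."""

    success_rate: float
    latencies: np.ndarray  # per analyzed trial, s
    mean_latency: float
    distance_traveled: float  # cm
    mean_speed: float  # cm/s
    n_trials: int


# ---------------------------------------------------------------------------
# Kinematics and behavioral metrics
# ---------------------------------------------------------------------------

def compute_speed(tracking: Tracking) -> np.ndarray:
    """Per-frame speed (cm/s) from central differences of (x, y).

    Endpoints use one-sided differences.  Raises for fewer than two frames.
    """
    if tracking.n_frames < 2:
        raise ValidationError("speed requires at least two tracking frames")
    vx = np.gradient(tracking.x, tracking.t)
    vy = np.gradient(tracking.y, tracking.t)
    return np.hypot(vx, vy)


def path_length(tracking: Tracking) -> float:
    """Total distance traveled (cm) along the sampled trajectory."""
    dx = np.diff(tracking.x)
    dy = np.diff(tracking.y)
    return float(np.sum(np.hypot(dx, dy)))


def behavior_metrics(session: Session) -> BehaviorSummary:
    """Success rate and outbound latencies for one session.

    The outbound latency runs from the gate opening to the pellet
    procurement, or — in threat sessions where the animal is repelled — to
    the first robot surge of the trial.  Trials without a gate opening are
    skipped with a logged warning; trials with neither procurement nor surge
    after the gate are skipped likewise.
    """
    ev = session.events.df
    latencies: list[float] = []
    n_attempted = 0
    n_success = 0
    for trial, grp in ev.groupby("trial"):
        gates = grp.loc[grp["kind"] == "gate_open", "time_s"]
        if gates.empty:
            logger.warning("trial %s has no gate_open; skipped", trial)
            continue
        n_attempted += 1
        gate_t = float(gates.iloc[0])
        pellets = grp.loc[grp["kind"] == "pellet_procured", "time_s"]
        surges = grp.loc[grp["kind"].isin(SURGE_KINDS), "time_s"]
        if not pellets.empty:
            n_success += 1
            latencies.append(float(pellets.iloc[0]) - gate_t)
        elif not surges.empty:
            latencies.append(float(surges.iloc[0]) - gate_t)
        else:
            logger.warning("trial %s has no outcome event; latency skipped", trial)
    lat = np.asarray(latencies, dtype=float)
    speeds = compute_speed(session.tracking)
    return BehaviorSummary(
        success_rate=n_success / n_attempted if n_attempted else 0.0,
        latencies=lat,
        mean_latency=float(np.mean(lat)) if lat.size else np.nan,
        distance_traveled=path_length(session.tracking),
        mean_speed=float(np.mean(speeds)),
        n_trials=n_attempted,
    )


def filter_surge_events(events: EventLog, refractory: float = 10.0) -> EventLog:
    """Drop surge/stim events closer than ``refractory`` s to the last kept one.

    Repeated pellet attempts within 10 s of the previous robot activation
    overlap the evoked-response window and are excluded.  The boundary is
    inclusive: a gap of exactly ``refractory`` seconds is kept.  Applied
    independently per surge-like kind; all other events pass through.
    """
    df = events.df
    keep = np.ones(len(df), dtype=bool)
    for kind in SURGE_KINDS:
        idx = df.index[df["kind"] == kind]
        if len(idx) == 0:
            continue
        times = df.loc[idx, "time_s"].to_numpy()
        order = np.argsort(times, kind="stable")
        last_kept = -np.inf
        for pos in order:
            if times[pos] - last_kept >= refractory - 1e-12:
                last_kept = times[pos]
            else:
                keep[df.index.get_loc(idx[pos])] = False
    return EventLog(df[keep].reset_index(drop=True))


def make_epochs(events: EventLog, label: str) -> EpochSet:
    """Build the 2.5 s pre/post windows around surge or pellet events.

    ``pre_*`` windows are ``[t - 2.5, t)`` and ``post_*`` are ``[t, t + 2.5)``.
    ``events`` should already have passed :func:`filter_surge_events`.
    """
    if label not in EPOCH_LABELS:
        raise ValidationError(f"unknown epoch label {label!r}")
    kind = SURGE_KINDS if "surge" in label else "pellet_procured"
    kinds = kind if isinstance(kind, tuple) else (kind,)
    sel = events.df[events.df["kind"].isin(kinds)]
    times = sel["time_s"].to_numpy(dtype=float)
    trials = sel["trial"].to_numpy(dtype=int)
    if label.startswith("pre"):
        windows = np.column_stack([times - EPOCH_WIDTH, times])
    else:
        windows = np.column_stack([times, times + EPOCH_WIDTH])
    return EpochSet(label=label, windows=windows, trials=trials)


def foraging_limit(threat_session: Session) -> float:
    """Maximum corridor position (cm) visited during the threat session.

    Place-field analyses of all three sessions are truncated at this limit,
    and cells whose pre-threat peak lies beyond it are dropped from the
    stability analysis (the animal never samples that territory under
    threat, so no comparison is possible).
    """
    return float(np.max(threat_session.tracking.x))


# ---------------------------------------------------------------------------
# Plain-text session I/O
# ---------------------------------------------------------------------------

_SPIKES = "spikes.csv"
_TRACKING = "tracking.csv"
_EVENTS = "events.csv"
_MANIFEST = "manifest.json"


def write_session(session: Session, dir_path: str | Path) -> None:
    """Write a session as three CSV tables plus a JSON manifest.

    Output is byte-stable for identical inputs: fixed column order, fixed
    float formatting (times at 0.1 ms resolution), sorted manifest keys.
    """
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for tr in session.trains:
        w = "" if tr.spike_width is None else f"{tr.spike_width:.4f}"
        for t in tr.times:
            rows.append((tr.cell_id, tr.region, f"{t:.4f}", w))
        if tr.times.size == 0:
            # keep an explicit empty marker so the cell round-trips
            pass
    spikes = pd.DataFrame(rows, columns=["cell_id", "region", "time_s", "spike_width_ms"])
    spikes.to_csv(d / _SPIKES, index=False)
    track = pd.DataFrame(
        {
            "t_s": [f"{v:.4f}" for v in session.tracking.t],
            "x_cm": [f"{v:.4f}" for v in session.tracking.x],
            "y_cm": [f"{v:.4f}" for v in session.tracking.y],
        }
    )
    track.to_csv(d / _TRACKING, index=False)
    ev = session.events.df.copy()
    ev["time_s"] = [f"{v:.4f}" for v in ev["time_s"]]
    ev.to_csv(d / _EVENTS, index=False)
    manifest = {
        "session_id": session.session_id,
        "phase": session.phase,
        "duration_s": round(session.duration, 4),
        "frame_rate_hz": round(session.tracking.frame_rate, 6),
        "cells": [
            {
                "cell_id": tr.cell_id,
                "region": tr.region,
                "spike_width_ms": tr.spike_width,
            }
            for tr in session.trains
        ],
    }
    (d / _MANIFEST).write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")


def read_session(dir_path: str | Path) -> Session:
    """Read and validate a session directory written by :func:`write_session`."""
    d = Path(dir_path)
    for name in (_SPIKES, _TRACKING, _EVENTS, _MANIFEST):
        if not (d / name).exists():
            raise FileNotFoundError(f"missing session file: {d / name}")
    manifest = json.loads((d / _MANIFEST).read_text())
    spikes = pd.read_csv(d / _SPIKES)
    track = pd.read_csv(d / _TRACKING)
    ev = pd.read_csv(d / _EVENTS)
    trains = []
    by_cell = dict(tuple(spikes.groupby("cell_id", sort=False))) if len(spikes) else {}
    for cell in manifest["cells"]:
        cid = cell["cell_id"]
        grp = by_cell.get(cid)
        times = (
            np.sort(grp["time_s"].to_numpy(dtype=float))
            if grp is not None
            else np.empty(0)
        )
        if grp is not None and np.any(np.diff(grp["time_s"].to_numpy(dtype=float)) <= 0):
            raise ValidationError(f"cell {cid}: spike times not sorted in file")
        trains.append(
            SpikeTrain(
                cell_id=cid,
                region=cell["region"],
                times=times,
                spike_width=cell.get("spike_width_ms"),
                session_id=manifest["session_id"],
            )
        )
    session = Session(
        session_id=manifest["session_id"],
        phase=manifest["phase"],
        tracking=Tracking(
            t=track["t_s"].to_numpy(dtype=float),
            x=track["x_cm"].to_numpy(dtype=float),
            y=track["y_cm"].to_numpy(dtype=float),
        ),
        events=EventLog(ev.astype({"trial": int, "kind": str, "time_s": float})),
        trains=tuple(trains),
        duration=float(manifest["duration_s"]),
    )
    session.validate()
    return session


def sessions_equal(a: Session, b: Session, tol: float = 5e-4) -> bool:
    """Structural equality of two sessions within the file time resolution."""
    if (a.session_id, a.phase) != (b.session_id, b.phase):
        return False
    if abs(a.duration - b.duration) > tol:
        return False
    for arr_a, arr_b in (
        (a.tracking.t, b.tracking.t),
        (a.tracking.x, b.tracking.x),
        (a.tracking.y, b.tracking.y),
    ):
        if arr_a.size != arr_b.size or not np.allclose(arr_a, arr_b, atol=tol):
            return False
    if a.cell_ids != b.cell_ids:
        return False
    for ta, tb in zip(a.trains, b.trains):
        if ta.region != tb.region or ta.times.size != tb.times.size:
            return False
        if ta.times.size and not np.allclose(ta.times, tb.times, atol=tol):
            return False
    ea, eb = a.events.df, b.events.df
    if len(ea) != len(eb):
        return False
    if not (ea["kind"].to_numpy() == eb["kind"].to_numpy()).all():
        return False
    if not np.allclose(ea["time_s"], eb["time_s"], atol=tol):
        return False
    return True
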