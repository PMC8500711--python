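"""Synthetic risky-foraging cohorts with known ground truth.

The simulator emulates the statistical structure of a nest-corridor foraging
experiment under predatory threat: a scripted trajectory (nest dwell, gate
opening, outbound run to a pellet at 125 cm, and — in the threat phase — a
robot surge triggered ~25 cm short of the pellet followed by a flight back
to the nest), dHPC units with Gaussian place fields that may be displaced
during the threat phase, BA units with baseline Poisson firing plus
event-locked excitation or inhibition, and optional pairwise BA→dHPC
co-firing injected only inside chosen 2.5 s epochs at a chosen lag.

All spike trains are inhomogeneous-Poisson realizations drawn by thinning.
The trajectory is piecewise-scripted rather than a behavioral model: the
analysis stages need realistic occupancy statistics, not realistic
decision-making.  Every operation is deterministic under a fixed seed, and
per-cell random streams are derived from the cell id so that adding a cell
never perturbs the spikes of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .session import (
    EventLog,
    EpochSet,
    Session,
    SpikeTrain,
    Tracking,
    TIME_RESOLUTION,
    filter_surge_events,
    make_epochs,
)

PHASE_ORDER = ("pre_threat", "threat", "post_threat")


@dataclass(frozen=True)
class PlaceCellSpec:
    """Ground-truth parameters of one simulated dHPC place cell.

    ``threat_shift`` displaces the field center (cm, signed along +x) during
    the threat phase only — the generative analogue of remapping.
    ``theta_depth`` adds sinusoidal rate modulation at ``theta_freq`` Hz
    during the threat phase (0 = none).
    """

    cell_id: str
    center_x: float
    width_sigma: float = 8.0
    peak_rate: float = 10.0
    baseline_rate: float = 1.0
    threat_shift: float = 0.0
    theta_depth: float = 0.0
    theta_freq: float = 8.0


@dataclass(frozen=True)
class BaCellSpec:
    """Ground-truth parameters of one simulated BA unit.

    ``event_kind`` selects which events modulate the cell (robot surges,
    pellet procurements, both, or none).  ``gain`` multiplies the baseline
    rate at the response peak: >1 excites, <1 inhibits.  The response starts
    ``latency`` s after the event and decays exponentially with time
    constant ``decay`` s.
    """

    cell_id: str
    baseline_rate: float = 3.0
    event_kind: str = "robot"  # robot | pellet | both | none
    gain: float = 5.0
    latency: float = 0.2
    decay: float = 1.5
    spike_width: float = 0.40  # ms; ~0.15 for a putative interneuron

    @property
    def sign(self) -> str:
        if self.event_kind == "none":
            return "none"
        return "excited" if self.gain >= 1.0 else "inhibited"


@dataclass(frozen=True)
class SynchronyInjection:
    """Epoch-restricted excess BA→dHPC co-firing to plant in a cohort."""

    ba_cell: str
    hpc_cell: str
    epoch_label: str = "pre_surge"
    lag_ms: float = 30.0
    excess: float = 0.3  # extra dHPC spikes per in-epoch BA spike


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of a synthetic cohort.

    Geometry and trial structure follow the emulated experiment: pellet at
    125 cm from the gateway, robot triggered when the animal is within 25 cm
    of the pellet (i.e. at x = 100 cm), 10 trials per phase, tracking at
    30 frames/s.
    """

    n_trials: int = 10
    pellet_x: float = 125.0
    trigger_offset: float = 25.0
    surge_travel: float = 23.0  # cosmetic: robot lunge extent, event timing only
    frame_rate: float = 30.0
    nest_depth: float = 45.0
    nest_dwell: float = 6.0  # s in the nest before each gate opening
    outbound_speed: float = 30.0  # cm/s
    return_speed: float = 30.0
    flight_speed: float = 60.0  # cm/s escape run after a surge
    pellet_dwell: float = 2.0  # s at the pellet before returning
    pause_prob: float = 0.0  # per-frame pause probability, threat outbound only
    threat_success_prob: float = 0.0
    y_noise: float = 5.0  # lateral wander bound, cm
    place_cells: tuple[PlaceCellSpec, ...] = ()
    ba_cells: tuple[BaCellSpec, ...] = ()
    injections: tuple[SynchronyInjection, ...] = ()
    rng_seed: int = 0

    def validate(self) -> None:
        if min(self.outbound_speed, self.return_speed, self.flight_speed) <= 0:
            raise ValueError("speeds must be positive")
        for pc in self.place_cells:
            if pc.width_sigma <= 0 or pc.peak_rate < 0 or pc.baseline_rate < 0:
                raise ValueError(f"bad place-cell params for {pc.cell_id}")
        for inj in self.injections:
            if abs(inj.lag_ms) > 100:
                raise ValueError("injection lag must lie within +/-100 ms")
            if inj.excess < 0:
                raise ValueError("injection excess must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """True labels attached to a simulated cohort."""

    place_class: dict  # cell_id -> nest | proximal | distal
    field_centers: dict  # cell_id -> {phase: center_x}
    ba_kind: dict  # cell_id -> robot | pellet | both | none
    injections: tuple[SynchronyInjection, ...]

    def to_frames(self) -> dict[str, pd.DataFrame]:
        place = pd.DataFrame(
            [
                {
                    "cell_id": cid,
                    "true_class": cls,
                    **{f"center_{ph}": self.field_centers[cid][ph] for ph in PHASE_ORDER},
                }
                for cid, cls in sorted(self.place_class.items())
            ]
        )
        ba = pd.DataFrame(
            [{"cell_id": cid, "event_kind": k} for cid, k in sorted(self.ba_kind.items())]
        )
        inj = pd.DataFrame([vars(i) for i in self.injections])
        return {"place": place, "ba": ba, "injections": inj}


@dataclass(frozen=True)
class Cohort:
    """Three phase-matched sessions plus their ground truth."""

    sessions: dict  # phase -> Session
    truth: GroundTruth
    config: SimConfig


def true_place_class(center_x: float) -> str:
    """Class implied by a field center: nest (<0), proximal [0,25], distal (>25)."""
    if center_x < 0:
        return "nest"
    if center_x <= 25:
        return "proximal"
    return "distal"


def _cell_rng(seed: int, cell_id: str, phase: str) -> np.random.Generator:
    """Independent, reproducible stream per (seed, cell, phase)."""
    h = zlib.crc32(f"{cell_id}|{phase}".encode())
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, h]))


REFRACTORY_S = 0.002  # absolute refractory dead time imposed on all trains


def _round_times(t: np.ndarray, refractory: float = REFRACTORY_S) -> np.ndarray:
    """Sort, snap to 0.1 ms, and enforce an absolute refractory period.

    Spikes closer than ``refractory`` to the previously kept spike are
    dropped (dead-time thinning), mirroring the refractory period real
    units exhibit and the 1 ms inclusion criterion downstream.
    """
    t = np.round(np.sort(t) / TIME_RESOLUTION) * TIME_RESOLUTION
    if t.size > 1:
        kept = [t[0]]
        for v in t[1:]:
            if v - kept[-1] >= refractory - TIME_RESOLUTION / 2:
                kept.append(v)
        t = np.asarray(kept)
    return t


# ---------------------------------------------------------------------------
# Trajectory
# ---------------------------------------------------------------------------

def simulate_trajectory(
    config: SimConfig, phase: str, rng: np.random.Generator
) -> tuple[Tracking, EventLog]:
    """Scripted foraging trajectory and event log for one phase.

    Each trial: a nest dwell (random walk inside the nest), a gate opening,
    a constant-speed outbound run, then either pellet procurement + return
    (pre/post phases, or a lucky threat trial) or a robot surge at
    x = pellet_x − trigger_offset followed by a fast flight to the nest.
    """
    config.validate()
    dt = 1.0 / config.frame_rate
    trigger_x = config.pellet_x - config.trigger_offset
    xs: list[float] = []
    events: list[tuple[int, str, float]] = []
    x = -config.nest_depth / 2

    def now() -> float:
        return len(xs) * dt

    for trial in range(1, config.n_trials + 1):
        # nest dwell: bounded random walk in the nest interior
        n_dwell = int(round(config.nest_dwell / dt))
        for _ in range(n_dwell):
            x = float(np.clip(x + rng.normal(0.0, 1.5), -config.nest_depth + 2, -2))
            xs.append(x)
        events.append((trial, "gate_open", now()))
        threat_trial = phase == "threat"
        succeed = (not threat_trial) or (rng.uniform() < config.threat_success_prob)
        # outbound run
        target = config.pellet_x
        while x < target:
            if threat_trial and config.pause_prob > 0 and rng.uniform() < config.pause_prob:
                xs.append(x)
            else:
                x = min(x + config.outbound_speed * dt, target)
                xs.append(x)
            if threat_trial and x >= trigger_x:
                # stamp the surge at the frame where the trigger was crossed
                events.append((trial, "robot_surge", (len(xs) - 1) * dt))
                if not succeed:
                    break
                threat_trial = False  # pushes past the robot to the pellet
        if x >= target:  # reached pellet
            events.append((trial, "pellet_procured", now()))
            for _ in range(int(round(config.pellet_dwell / dt))):
                xs.append(x)
            speed = config.return_speed
        else:
            speed = config.flight_speed
        while x > -10.0:  # return/flight into the nest
            x = max(x - speed * dt, -10.0)
            xs.append(x)
        events.append((trial, "trial_end", now()))
    for _ in range(int(round(2.0 / dt))):  # tail so post-event windows fit
        x = float(np.clip(x + rng.normal(0.0, 1.5), -config.nest_depth + 2, -2))
        xs.append(x)

    n = len(xs)
    t = np.arange(n) * dt
    # lateral wander: mean-reverting (OU) noise bounded at +/- y_noise
    innov = rng.normal(0.0, 0.65, n)
    y = np.empty(n)
    prev = 0.0
    for i in range(n):
        prev = 0.95 * prev + innov[i]
        y[i] = prev
    y = np.clip(y, -config.y_noise, config.y_noise)
    tracking = Tracking(t=t, x=np.asarray(xs), y=y)
    return tracking, EventLog.from_records(events)


# ---------------------------------------------------------------------------
# Spike trains
# ---------------------------------------------------------------------------

def _thin(
    rng: np.random.Generator,
    duration: float,
    lam_max: float,
    rate_fn,
) -> np.ndarray:
    """Inhomogeneous-Poisson times on [0, duration) by thinning."""
    if lam_max <= 0 or duration <= 0:
        return np.empty(0)
    n = rng.poisson(lam_max * duration)
    cand = np.sort(rng.uniform(0.0, duration, n))
    if cand.size == 0:
        return cand
    lam = np.asarray(rate_fn(cand), dtype=float)
    accept = rng.uniform(0.0, lam_max, cand.size) < lam
    t = _round_times(cand[accept])
    return t[t <= duration]  # rounding may overshoot the session end


def simulate_place_train(
    spec: PlaceCellSpec,
    tracking: Tracking,
    rng: np.random.Generator,
    phase: str = "pre_threat",
) -> SpikeTrain:
    """Place-modulated inhomogeneous-Poisson spike train.

    Intensity lambda(t) = baseline + (peak − baseline) ·
    exp(−(x(t) − center)² / 2σ²), with the field center displaced by
    ``threat_shift`` in the threat phase.  Optional theta-band sinusoidal
    modulation (depth ``theta_depth``) is applied in the threat phase only.
    """
    center = spec.center_x + (spec.threat_shift if phase == "threat" else 0.0)
    depth = spec.theta_depth if phase == "threat" else 0.0
    duration = float(tracking.t[-1]) if tracking.n_frames else 0.0
    amp = spec.peak_rate - spec.baseline_rate

    def rate_fn(t):
        x = np.interp(t, tracking.t, tracking.x)
        lam = spec.baseline_rate + amp * np.exp(-((x - center) ** 2) / (2 * spec.width_sigma**2))
        if depth > 0:
            lam = lam * (1.0 + depth * np.sin(2 * np.pi * spec.theta_freq * t))
        return np.clip(lam, 0.0, None)

    lam_max = max(spec.baseline_rate, spec.peak_rate) * (1.0 + max(depth, 0.0))
    times = _thin(rng, duration, lam_max, rate_fn)
    return SpikeTrain(cell_id=spec.cell_id, region="dHPC", times=times)


def simulate_ba_train(
    spec: BaCellSpec,
    events: EventLog,
    duration: float,
    rng: np.random.Generator,
) -> SpikeTrain:
    """Baseline-Poisson BA unit with event-locked multiplicative modulation.

    Rate(t) = baseline · (1 + (gain − 1) · Σ_e exp(−(t − t_e − latency)/decay))
    over events of the configured kind, with the kernel zero before
    t_e + latency.  Excited cells have gain > 1, inhibited gain < 1.
    """
    kinds = {"robot": ("robot_surge", "stim_on"), "pellet": ("pellet_procured",),
             "both": ("robot_surge", "stim_on", "pellet_procured"), "none": ()}[spec.event_kind]
    ev_times = events.times_of(kinds) if kinds else np.empty(0)

    def rate_fn(t):
        mod = np.zeros_like(t)
        for e in ev_times:
            dt_ = t - e - spec.latency
            mod += np.where(dt_ >= 0, np.exp(-np.clip(dt_, 0, None) / spec.decay), 0.0)
        lam = spec.baseline_rate * (1.0 + (spec.gain - 1.0) * mod)
        return np.clip(lam, 0.0, None)

    # events are >=10 s apart after filtering, so kernel overlap is negligible
    lam_max = spec.baseline_rate * max(1.0, 1.0 + (spec.gain - 1.0) * 1.05)
    times = _thin(rng, duration, lam_max, rate_fn)
    return SpikeTrain(
        cell_id=spec.cell_id, region="BA", times=times, spike_width=spec.spike_width
    )


def inject_synchrony(
    ba_train: SpikeTrain,
    hpc_train: SpikeTrain,
    epochs: EpochSet,
    lag_ms: float,
    excess: float,
    rng: np.random.Generator,
    t_max: float | None = None,
) -> SpikeTrain:
    """Insert excess dHPC spikes time-locked to in-epoch BA spikes.

    For every BA spike inside an epoch window, with probability ``excess`` a
    dHPC spike is added at lag ``lag_ms`` plus uniform ±5 ms jitter.  The
    returned train is re-sorted and deduplicated at 0.1 ms resolution.
    """
    if excess < 0:
        raise ValueError("excess must be >= 0")
    if epochs.n_windows == 0 or excess == 0:
        return hpc_train
    t = ba_train.times
    in_epoch = np.zeros(t.size, dtype=bool)
    for start, end in epochs.windows:
        in_epoch |= (t >= start) & (t < end)
    ref = t[in_epoch]
    take = rng.uniform(size=ref.size) < excess
    new = ref[take] + lag_ms / 1000.0 + rng.uniform(-0.005, 0.005, int(take.sum()))
    new = new[new >= 0]
    merged = _round_times(np.concatenate([hpc_train.times, new]))
    if t_max is not None:
        merged = merged[merged <= t_max]
    return replace(hpc_train, times=merged)


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def make_cohort(config: SimConfig) -> Cohort:
    """Simulate the three phase-matched sessions of one recording day.

    All cells are present in every phase; synchrony injections are applied
    after the base trains are drawn, in the session owning the requested
    epoch label (surge epochs → threat session, pellet epochs → pre-threat
    session, matching the emulated experimental design).
    """
    config.validate()
    sessions: dict[str, Session] = {}
    for phase in PHASE_ORDER:
        traj_rng = _cell_rng(config.rng_seed, "__trajectory__", phase)
        tracking, events = simulate_trajectory(config, phase, traj_rng)
        duration = float(tracking.t[-1])
        filtered = filter_surge_events(events)
        trains: list[SpikeTrain] = []
        for ba in config.ba_cells:
            rng = _cell_rng(config.rng_seed, ba.cell_id, phase)
            trains.append(simulate_ba_train(ba, filtered, duration, rng))
        for pc in config.place_cells:
            rng = _cell_rng(config.rng_seed, pc.cell_id, phase)
            trains.append(simulate_place_train(pc, tracking, rng, phase))
        sessions[phase] = Session(
            session_id=f"sim-{config.rng_seed}-{phase}",
            phase=phase,
            tracking=tracking,
            events=events,
            trains=tuple(trains),
            duration=duration,
        )

    for inj in config.injections:
        phase = "threat" if "surge" in inj.epoch_label else "pre_threat"
        sess = sessions[phase]
        epochs = make_epochs(filter_surge_events(sess.events), inj.epoch_label)
        rng = _cell_rng(config.rng_seed, f"inj|{inj.ba_cell}|{inj.hpc_cell}", phase)
        new_hpc = inject_synchrony(
            sess.train(inj.ba_cell), sess.train(inj.hpc_cell),
            epochs, inj.lag_ms, inj.excess, rng, t_max=sess.duration,
        )
        trains = tuple(new_hpc if tr.cell_id == inj.hpc_cell else tr for tr in sess.trains)
        sessions[phase] = replace(sess, trains=trains)

    for sess in sessions.values():
        sess.validate()

    truth = GroundTruth(
        place_class={pc.cell_id: true_place_class(pc.center_x) for pc in config.place_cells},
        field_centers={
            pc.cell_id: {
                ph: pc.center_x + (pc.threat_shift if ph == "threat" else 0.0)
                for ph in PHASE_ORDER
            }
            for pc in config.place_cells
        },
        ba_kind={ba.cell_id: ba.event_kind for ba in config.ba_cells},
        injections=config.injections,
    )
    return Cohort(sessions=sessions, truth=truth, config=config)


def default_cohort_config(seed: int = 0, **overrides) -> SimConfig:
    """The package's reference study-condition cohort.

    Emulates the headline structure of the emulated experiment: nest and
    proximal place cells are stable across phases; half of the distal cells
    remap under threat (field displaced 30 cm toward the nest) and co-fire
    with robot-responsive BA cells during the pre-surge epochs; the other
    distal cells stay stable and co-fire with non-robot BA cells.
    """
    rng = np.random.default_rng(seed)

    def width() -> float:
        return float(rng.normal(0.40, 0.03))

    ba_cells = tuple(
        [BaCellSpec(cell_id=f"ba_robot_{i}", event_kind="robot", baseline_rate=4.0,
                    gain=5.0, spike_width=width()) for i in range(3)]
        + [BaCellSpec(cell_id=f"ba_pellet_{i}", event_kind="pellet", baseline_rate=4.0,
                      gain=4.0, spike_width=width()) for i in range(2)]
        + [BaCellSpec(cell_id=f"ba_none_{i}", event_kind="none", baseline_rate=4.0,
                      spike_width=width()) for i in range(2)]
        # narrow-spike fast-firing putative interneurons (excluded downstream)
        + [BaCellSpec(cell_id=f"ba_int_{i}", event_kind="none", baseline_rate=16.0,
                      spike_width=float(rng.normal(0.15, 0.02))) for i in range(2)]
    )
    place: list[PlaceCellSpec] = []
    for i in range(8):
        place.append(PlaceCellSpec(f"hpc_nest_{i}", center_x=float(rng.uniform(-38, -6)),
                                   peak_rate=12.0, baseline_rate=1.0))
    for i in range(4):
        place.append(PlaceCellSpec(f"hpc_prox_{i}", center_x=float(rng.uniform(2, 23)),
                                   peak_rate=12.0, baseline_rate=1.0))
    for i in range(16):
        place.append(PlaceCellSpec(f"hpc_dist_r{i}", center_x=float(rng.uniform(45, 90)),
                                   peak_rate=12.0, baseline_rate=1.0, threat_shift=-30.0))
    for i in range(16):
        place.append(PlaceCellSpec(f"hpc_dist_n{i}", center_x=float(rng.uniform(45, 90)),
                                   peak_rate=12.0, baseline_rate=1.0, threat_shift=0.0))
    injections: list[SynchronyInjection] = []
    for i in range(16):
        injections.append(SynchronyInjection(
            ba_cell=f"ba_robot_{i % 3}", hpc_cell=f"hpc_dist_r{i}",
            epoch_label="pre_surge", lag_ms=30.0, excess=0.3))
        nr = f"ba_pellet_{i % 2}" if i % 2 == 0 else f"ba_none_{i % 2}"
        injections.append(SynchronyInjection(
            ba_cell=nr, hpc_cell=f"hpc_dist_n{i}",
            epoch_label="pre_surge", lag_ms=30.0, excess=0.3))
    # every nest/proximal cell is paired deliberately, half with each BA type,
    # so the nest_proximal contrast compares homogeneous stable groups
    for i in range(4):
        injections.append(SynchronyInjection(
            ba_cell=f"ba_robot_{i % 3}", hpc_cell=f"hpc_nest_{i}",
            epoch_label="pre_surge", lag_ms=30.0, excess=0.3))
        injections.append(SynchronyInjection(
            ba_cell=f"ba_pellet_{i % 2}", hpc_cell=f"hpc_nest_{4 + i}",
            epoch_label="pre_surge", lag_ms=30.0, excess=0.3))
    for i in range(4):
        partner = f"ba_robot_{i % 3}" if i < 2 else f"ba_none_{i % 2}"
        injections.append(SynchronyInjection(
            ba_cell=partner, hpc_cell=f"hpc_prox_{i}",
            epoch_label="pre_surge", lag_ms=30.0, excess=0.3))
    cfg = SimConfig(
        place_cells=tuple(place),
        ba_cells=ba_cells,
        injections=tuple(injections),
        rng_seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg
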