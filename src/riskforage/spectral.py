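"""Spike-train power spectra and theta-band (6–10 Hz) power fractions.

Spikes inside event-centered analysis windows are binned at 2 ms (Nyquist
250 Hz), each window is mean-subtracted, and a periodogram is averaged
across windows (Welch across windows, Hann taper by default).  Band power
is reported as a percentage of the total spectral power in [1, 50] Hz, with
the theta band fixed at [6, 10] Hz.  These are unit (point-process)
spectra, not LFP spectra.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import periodogram

from .session import Session, SpikeTrain, ValidationError, filter_surge_events, SURGE_KINDS

logger = logging.getLogger(__name__)

DEFAULT_BIN_S = 0.002
TOTAL_BAND = (1.0, 50.0)
BANDS = {
    "delta": (1.0, 4.0),
    "theta": (6.0, 10.0),
    "beta": (15.0, 30.0),
    "gamma": (30.0, 50.0),
}
MIN_TOTAL_S = 5.0


@dataclass(frozen=True)
class PsdResult:
    """Averaged periodogram of one unit plus canonical band fractions."""

    cell_id: str
    freqs: np.ndarray
    power: np.ndarray  # density, mean across windows
    band_fractions: dict  # band name -> % of total power in TOTAL_BAND
    n_windows: int
    total_power: float

    @property
    def theta_fraction(self) -> float:
        return self.band_fractions["theta"]


def spike_psd(
    train: SpikeTrain,
    windows: np.ndarray,
    bin_s: float = DEFAULT_BIN_S,
    taper: str = "hann",
    total_band: tuple[float, float] = TOTAL_BAND,
    bands: dict | None = None,
) -> PsdResult:
    """Window-averaged periodogram of a binned, demeaned spike train.

    ``windows`` is an (n, 2) array of (start, end) times; all windows must
    have equal duration and total at least 5 s.  Band fractions are band
    power / total power over ``total_band`` × 100.
    """
    windows = np.asarray(windows, dtype=float).reshape(-1, 2)
    if windows.size == 0:
        raise ValidationError("spike_psd requires at least one window")
    durations = windows[:, 1] - windows[:, 0]
    if not np.allclose(durations, durations[0], atol=1e-9):
        raise ValidationError("all PSD windows must have equal duration")
    if float(durations.sum()) < MIN_TOTAL_S:
        raise ValidationError(
            f"PSD needs >= {MIN_TOTAL_S} s of data, got {durations.sum():.2f} s"
        )
    n_samp = int(round(durations[0] / bin_s))
    fs = 1.0 / bin_s
    psds = []
    for start, end in windows:
        edges = start + bin_s * np.arange(n_samp + 1)
        counts, _ = np.histogram(train.times, bins=edges)
        x = counts.astype(float) - counts.mean()
        f, p = periodogram(x, fs=fs, window=taper, detrend=False)
        psds.append(p)
    power = np.mean(psds, axis=0)
    in_total = (f >= total_band[0]) & (f <= total_band[1])
    total = float(power[in_total].sum())
    fractions = {}
    for name, (lo, hi) in (bands or BANDS).items():
        # theta is closed [6, 10] per convention; other bands half-open so
        # adjacent bands never double-count a grid frequency
        sel = (f >= lo) & ((f <= hi) if name == "theta" else (f < hi))
        fractions[name] = 100.0 * float(power[sel].sum()) / total if total > 0 else np.nan
    return PsdResult(
        cell_id=train.cell_id,
        freqs=f,
        power=power,
        band_fractions=fractions,
        n_windows=int(windows.shape[0]),
        total_power=total,
    )


def _event_windows(session: Session, half_width: float = 2.5) -> np.ndarray:
    """±half_width windows around the session's aligning events.

    Threat sessions align on (refractory-filtered) robot surges or
    stimulations; pre/post sessions align on pellet procurements.
    """
    if session.phase == "threat":
        times = filter_surge_events(session.events).times_of(SURGE_KINDS)
    else:
        times = session.events.times_of("pellet_procured")
    times = times[(times - half_width) >= 0]
    times = times[(times + half_width) <= session.duration]
    return np.column_stack([times - half_width, times + half_width])


def theta_by_celltype(
    place_records: pd.DataFrame,
    sessions: dict[str, Session],
    half_width: float = 2.5,
    bin_s: float = DEFAULT_BIN_S,
) -> pd.DataFrame:
    """Per-cell theta fractions around events, grouped by class and session.

    Only included, classified place cells enter.  Classes with no cells in
    a session are omitted with a warning.  Returns one row per (cell,
    session) with the cell's class and theta percentage.
    """
    cells = place_records[place_records["included"] & place_records["class"].notna()]
    rows = []
    for phase, session in sessions.items():
        windows = _event_windows(session, half_width)
        if windows.shape[0] == 0:
            logger.warning("session %s: no aligning events for PSD", phase)
            continue
        for _, rec in cells.iterrows():
            train = session.train(rec["cell_id"])
            try:
                psd = spike_psd(train, windows, bin_s=bin_s)
            except ValidationError as e:
                logger.warning("cell %s %s: %s", rec["cell_id"], phase, e)
                continue
            rows.append(
                {
                    "cell_id": rec["cell_id"],
                    "class": rec["class"],
                    "phase": phase,
                    "theta_pct": psd.theta_fraction,
                    **{f"{b}_pct": v for b, v in psd.band_fractions.items() if b != "theta"},
                    "n_windows": psd.n_windows,
                }
            )
    df = pd.DataFrame(rows)
    for cls in ("nest", "proximal", "distal"):
        if len(df) and cls not in set(df["class"]):
            logger.warning("no %s cells present in theta summary", cls)
    return df


def theta_class_summary(theta_table: pd.DataFrame) -> pd.DataFrame:
    """Mean theta percentage per (class, session)."""
    return (
        theta_table.groupby(["class", "phase"], as_index=False)["theta_pct"]
        .agg(["mean", "sem", "count"])
        .reset_index()
    )
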