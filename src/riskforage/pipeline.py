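"""End-to-end cohort analysis: maps → PETH classes → synchrony → linkage.

One call takes the three phase-matched sessions of a recording day and
produces the standard result tables (place-cell records, BA classification,
pair screen, linkage, contrasts, regressions, theta summary) as plain
DataFrames, plus deterministic CSV export.  The analysis RNG (shift-
predictor shuffles) is the only stochastic element; with a fixed seed the
output tables are byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import ccg, linkage as linkage_mod, peth, place, spectral
from .session import Session, filter_surge_events, make_epochs
from .simulate import Cohort

logger = logging.getLogger(__name__)

DEFAULT_EPOCH_LABELS = ("pre_surge", "post_surge", "pre_pellet", "post_pellet")


def cohort_epoch_sets(
    sessions: dict[str, Session], labels=DEFAULT_EPOCH_LABELS
) -> dict[str, tuple]:
    """Epoch sets with their owning session (surge→threat, pellet→pre)."""
    out = {}
    for label in labels:
        phase = "threat" if "surge" in label else "pre_threat"
        sess = sessions[phase]
        epochs = make_epochs(filter_surge_events(sess.events), label)
        if epochs.n_windows >= 2:
            out[label] = (sess, epochs)
        else:
            logger.warning("epoch %s has <2 windows; skipped", label)
    return out


def analyze_cohort(
    sessions: dict[str, Session],
    seed: int = 0,
    epoch_labels: tuple[str, ...] = ("pre_surge", "post_surge"),
    n_shuffles: int = ccg.N_SHUFFLES,
    pixel_size: float = place.DEFAULT_PIXEL,
    smoothing_sigma: float = place.DEFAULT_SMOOTH_SIGMA,
    include_theta: bool = True,
) -> dict[str, pd.DataFrame]:
    """Run the full analysis pipeline on one cohort.

    Returns a dict of result tables: ``place_records``, ``ba_classes``,
    ``pairs``, ``pair_summary``, ``linkage``, ``stability_contrasts``,
    ``regressions``, ``rate_contrasts``, ``speed_control``, ``theta`` and
    ``behavior``.
    """
    from .session import behavior_metrics

    place_records, maps = place.build_place_records(
        sessions, pixel_size=pixel_size, smoothing_sigma=smoothing_sigma
    )
    ba_classes = peth.classify_ba_population(sessions["threat"], sessions["pre_threat"])

    rng = np.random.default_rng(seed)
    epoch_sets = cohort_epoch_sets(sessions, epoch_labels)
    pair_frames = []
    for label, (sess, epochs) in epoch_sets.items():
        pyramidal = set(
            ba_classes.loc[ba_classes["unit_type"] == "pyramidal", "cell_id"]
        )
        ba_trains = [tr for tr in sess.trains_in("BA") if tr.cell_id in pyramidal]
        hpc_trains = sess.trains_in("dHPC")
        pair_frames.append(
            ccg.pair_screen(ba_trains, hpc_trains, {label: epochs}, n_shuffles, rng)
        )
    pairs = (
        pd.concat(pair_frames, ignore_index=True)
        if pair_frames
        else pd.DataFrame(
            columns=["ba_cell", "hpc_cell", "epoch", "peak_z", "peak_lag_ms",
                     "significant", "direction", "ba_epoch_rate", "hpc_epoch_rate", "flags"]
        )
    )
    pair_summary = ccg.summarize_pairs(pairs) if len(pairs) else pd.DataFrame()

    link = linkage_mod.build_linkage(
        pairs, ba_classes, place_records,
        epochs=tuple(l for l in epoch_labels if l in set(pairs["epoch"])) or ("pre_surge",),
    )
    contrast_epoch = "pre_surge" if "pre_surge" in set(pairs["epoch"]) else (
        epoch_labels[0] if len(pairs) else "pre_surge"
    )
    if f"paired_{contrast_epoch}" in link.columns:
        contrasts = linkage_mod.contrasts_frame(
            linkage_mod.stability_by_pairing(link, epoch=contrast_epoch)
        )
        rate_contrasts = linkage_mod.rate_comparisons(
            link, pairs, ba_classes, epoch=contrast_epoch
        )
    else:
        contrasts = pd.DataFrame()
        rate_contrasts = pd.DataFrame()
    try:
        regressions = linkage_mod.regressions_frame(
            linkage_mod.stability_vs_position(link)
        )
    except Exception as e:  # too few cells for a regression
        logger.warning("position regression skipped: %s", e)
        regressions = pd.DataFrame()
    speed = linkage_mod.speed_control(link, sessions, maps)
    theta = (
        spectral.theta_by_celltype(place_records, sessions)
        if include_theta
        else pd.DataFrame()
    )
    behavior = pd.DataFrame(
        [
            {
                "phase": ph,
                "success_rate": bm.success_rate,
                "mean_latency_s": bm.mean_latency,
                "distance_cm": bm.distance_traveled,
                "mean_speed_cm_s": bm.mean_speed,
                "n_trials": bm.n_trials,
            }
            for ph, bm in ((p, behavior_metrics(s)) for p, s in sessions.items())
        ]
    )
    return {
        "place_records": place_records,
        "ba_classes": ba_classes,
        "pairs": pairs,
        "pair_summary": pair_summary,
        "linkage": link,
        "stability_contrasts": contrasts,
        "rate_contrasts": rate_contrasts,
        "regressions": regressions,
        "speed_control": speed,
        "theta": theta,
        "behavior": behavior,
    }


def write_tables(
    tables: dict[str, pd.DataFrame], out_dir: str | Path, seed: int | None = None
) -> None:
    """Write result tables as CSV with fixed formatting plus a run log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False, float_format="%.6g")
    digest = hashlib.sha256()
    for name in sorted(tables):
        digest.update((out / f"{name}.csv").read_bytes())
    log = {"tables": sorted(tables), "seed": seed, "sha256": digest.hexdigest()}
    (out / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True) + "\n")


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write a simulated cohort: one session directory per phase + truth."""
    from .session import write_session

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for phase, session in cohort.sessions.items():
        write_session(session, out / phase)
    for name, df in cohort.truth.to_frames().items():
        df.to_csv(out / f"ground_truth_{name}.csv", index=False, float_format="%.6g")


def read_cohort_sessions(dir_path: str | Path) -> dict[str, Session]:
    """Read the three session directories of a cohort written by write_cohort."""
    from .session import read_session

    d = Path(dir_path)
    sessions = {}
    for phase in ("pre_threat", "threat", "post_threat"):
        if (d / phase).exists():
            sessions[phase] = read_session(d / phase)
    if not sessions:
        raise FileNotFoundError(f"no session directories under {d}")
    return sessions
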