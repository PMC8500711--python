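"""Rate maps, place-cell inclusion and classification, and field stability.

The corridor is discretized into square pixels (4 cm default).  A rate map
is the Gaussian-smoothed ratio of spike counts to occupancy on visited
pixels; unvisited pixels are masked and never contribute to peaks,
information, or correlations.  Stability between two sessions is measured
two ways: the pixel-by-pixel Pearson correlation of the maps, converted to
a Fisher Z' (atanh) score for parametric comparison, and the absolute
distance between the x positions of the two map peaks.

Spatial information is the Skaggs rate formula
I = sum_i p_i * lambda_i * log2(lambda_i / lambda_bar)  [bits/s],
computed on unsmoothed rates, where p_i is the occupancy fraction of pixel
i and lambda_bar the occupancy-weighted mean rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .session import Session, SpikeTrain, Tracking, ValidationError, foraging_limit

logger = logging.getLogger(__name__)

DEFAULT_PIXEL = 4.0  # cm
DEFAULT_SMOOTH_SIGMA = 1.0  # pixels
R_CLIP = 1.0 - 1e-7  # correlation cap before atanh

PLACE_CLASSES = ("nest", "proximal", "distal")


@dataclass(frozen=True)
class RateMap:
    """Occupancy, spike counts, and smoothed firing rate on a pixel grid."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    occupancy: np.ndarray  # s, (nx, ny)
    spike_count: np.ndarray
    rate: np.ndarray  # Hz, smoothed, NaN on unvisited pixels
    rate_raw: np.ndarray  # Hz, unsmoothed, NaN on unvisited pixels
    visited: np.ndarray  # bool mask

    @property
    def pixel_size(self) -> float:
        return float(self.x_edges[1] - self.x_edges[0])

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def peak_rate(self) -> float:
        if not self.visited.any():
            return 0.0
        return float(np.nanmax(self.rate[self.visited]))

    @property
    def peak_index(self) -> tuple[int, int] | None:
        """Indices of the maximum-rate visited pixel; ties go to smaller x."""
        if not self.visited.any():
            return None
        r = np.where(self.visited, self.rate, -np.inf)
        # argmax scans x-major (rows are x bins), so ties already resolve
        # toward the smaller x index
        flat = int(np.argmax(r))
        return np.unravel_index(flat, r.shape)  # type: ignore[return-value]

    @property
    def peak_x(self) -> float | None:
        idx = self.peak_index
        if idx is None or self.peak_rate <= 0:
            return None
        return float(self.x_centers[idx[0]])

    @property
    def mean_rate(self) -> float:
        tot = float(self.occupancy.sum())
        return float(self.spike_count.sum()) / tot if tot > 0 else 0.0


def make_grid(
    x_min: float,
    x_max: float,
    pixel_size: float = DEFAULT_PIXEL,
    y_extent: tuple[float, float] = (-8.0, 8.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Shared pixel-grid edges covering [x_min, x_max] x y_extent."""
    nx = max(1, int(np.ceil((x_max - x_min) / pixel_size)))
    ny = max(1, int(np.ceil((y_extent[1] - y_extent[0]) / pixel_size)))
    return (
        x_min + pixel_size * np.arange(nx + 1),
        y_extent[0] + pixel_size * np.arange(ny + 1),
    )


def compute_occupancy(
    tracking: Tracking,
    pixel_size: float = DEFAULT_PIXEL,
    x_limit: float | None = None,
    x_min: float = -45.0,
    y_extent: tuple[float, float] = (-8.0, 8.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Frame-duration-weighted time per pixel for frames with x <= x_limit.

    Returns ``(occupancy, x_edges, y_edges)``.  Raises if no frame lies
    within the limit.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if x_limit is None:
        x_limit = float(np.max(tracking.x))
    x_edges, y_edges = make_grid(x_min, x_limit, pixel_size, y_extent)
    dt = tracking.frame_interval
    sel = tracking.x <= x_limit
    if not sel.any():
        raise ValidationError("no tracking frames within the foraging limit")
    occ, _, _ = np.histogram2d(
        tracking.x[sel],
        np.clip(tracking.y[sel], y_edges[0], y_edges[-1] - 1e-9),
        bins=(x_edges, y_edges),
        weights=np.full(int(sel.sum()), dt),
    )
    return occ, x_edges, y_edges


def compute_rate_map(
    train: SpikeTrain,
    tracking: Tracking,
    pixel_size: float = DEFAULT_PIXEL,
    smoothing_sigma: float = DEFAULT_SMOOTH_SIGMA,
    x_limit: float | None = None,
    x_min: float = -45.0,
    y_extent: tuple[float, float] = (-8.0, 8.0),
) -> RateMap:
    """Smoothed firing-rate map of one unit, truncated at the foraging limit.

    Spike positions are interpolated from the tracking.  The smoothed rate
    is Gaussian-filtered counts over Gaussian-filtered occupancy restricted
    to visited pixels, so masked pixels neither receive nor contribute
    weight.
    """
    occ, x_edges, y_edges = compute_occupancy(
        tracking, pixel_size, x_limit, x_min, y_extent
    )
    sx = np.interp(train.times, tracking.t, tracking.x)
    sy = np.interp(train.times, tracking.t, tracking.y)
    lim = x_edges[-1]
    keep = sx <= lim
    count, _, _ = np.histogram2d(
        sx[keep],
        np.clip(sy[keep], y_edges[0], y_edges[-1] - 1e-9),
        bins=(x_edges, y_edges),
    )
    visited = occ > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rate_raw = np.where(visited, count / np.where(visited, occ, 1.0), np.nan)
    if smoothing_sigma and smoothing_sigma > 0:
        w = visited.astype(float)
        sc = gaussian_filter(count * w, smoothing_sigma)
        so = gaussian_filter(occ * w, smoothing_sigma)
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(visited & (so > 0), sc / np.where(so > 0, so, 1.0), np.nan)
    else:
        rate = rate_raw.copy()
    return RateMap(
        x_edges=x_edges,
        y_edges=y_edges,
        occupancy=occ,
        spike_count=count,
        rate=rate,
        rate_raw=rate_raw,
        visited=visited,
    )


def spatial_information(rate_map: RateMap) -> float:
    """Skaggs spatial information in bits/s on unsmoothed rates.

    Pixels with zero rate contribute 0; returns 0 when the mean rate is 0.
    """
    occ = rate_map.occupancy[rate_map.visited]
    lam = rate_map.rate_raw[rate_map.visited]
    tot = occ.sum()
    if tot <= 0:
        raise ValidationError("spatial information needs positive occupancy")
    p = occ / tot
    lam_bar = float(np.sum(p * lam))
    if lam_bar <= 0:
        return 0.0
    pos = lam > 0
    return float(np.sum(p[pos] * lam[pos] * np.log2(lam[pos] / lam_bar)))


@dataclass(frozen=True)
class InclusionFlags:
    refractory_ok: bool
    peak_rate_ok: bool
    spatial_info_ok: bool

    @property
    def included(self) -> bool:
        return self.refractory_ok and self.peak_rate_ok and self.spatial_info_ok


def qualifies_as_place_cell(
    trains: dict[str, SpikeTrain],
    maps: dict[str, RateMap],
    min_isi_s: float = 1e-3,
    min_peak_hz: float = 2.0,
    min_info_bits: float = 1.0,
) -> InclusionFlags:
    """Place-cell inclusion: clean refractory period, peak >2 Hz and spatial
    information >1.0 bits/s in at least one session.

    The waveform-stability criterion of the emulated sorting pipeline is
    assumed satisfied (no raw waveforms here).
    """
    refractory_ok = all(tr.min_isi() >= min_isi_s for tr in trains.values())
    peak_ok = any(m.peak_rate > min_peak_hz for m in maps.values())
    info_ok = any(spatial_information(m) > min_info_bits for m in maps.values())
    return InclusionFlags(refractory_ok, peak_ok, info_ok)


def classify_place_cell(peak_x: float) -> str:
    """nest (x<0), proximal (0<=x<=25 cm), or distal (x>25 cm), from the
    pre-threat map peak."""
    if peak_x < 0:
        return "nest"
    if peak_x <= 25.0:
        return "proximal"
    return "distal"


def spatial_correlation(
    map_a: RateMap,
    map_b: RateMap,
    smoothed: bool = True,
    min_pixels: int = 10,
) -> tuple[float, float]:
    """Pixel-by-pixel Pearson r between two maps and its Fisher Z' score.

    Only pixels visited in both sessions enter the correlation (zero-filling
    unvisited pixels would inflate r).  r is clipped to ±(1 − 1e−7) before
    atanh.  Returns (nan, nan) with a logged warning when fewer than
    ``min_pixels`` pixels are common or either map is flat.
    """
    if map_a.rate.shape != map_b.rate.shape:
        raise ValidationError("rate maps are on different grids")
    common = map_a.visited & map_b.visited
    if common.sum() < min_pixels:
        logger.warning("only %d common visited pixels; correlation undefined", common.sum())
        return np.nan, np.nan
    a = (map_a.rate if smoothed else map_a.rate_raw)[common]
    b = (map_b.rate if smoothed else map_b.rate_raw)[common]
    if np.nanstd(a) == 0 or np.nanstd(b) == 0:
        logger.warning("flat rate map; correlation undefined")
        return np.nan, np.nan
    r = float(np.corrcoef(a, b)[0, 1])
    z = float(np.arctanh(np.clip(r, -R_CLIP, R_CLIP)))
    return r, z


def fisher_z(r: float) -> float:
    """Fisher Z' transform with clipping at ±(1 − 1e−7)."""
    return float(np.arctanh(np.clip(r, -R_CLIP, R_CLIP)))


def peak_distance(map_a: RateMap, map_b: RateMap) -> float:
    """Absolute x distance (cm) between the two map peaks (nan if undefined)."""
    pa, pb = map_a.peak_x, map_b.peak_x
    if pa is None or pb is None:
        logger.warning("peak undefined on an all-zero map; distance undefined")
        return np.nan
    return abs(pa - pb)


# ---------------------------------------------------------------------------
# Per-cohort place-cell table
# ---------------------------------------------------------------------------

SESSION_PAIRS = (("pre_threat", "threat"), ("threat", "post_threat"), ("pre_threat", "post_threat"))
_PAIR_TAG = {("pre_threat", "threat"): "pre_threat",
             ("threat", "post_threat"): "threat_post",
             ("pre_threat", "post_threat"): "pre_post"}


def build_place_records(
    sessions: dict[str, Session],
    pixel_size: float = DEFAULT_PIXEL,
    smoothing_sigma: float = DEFAULT_SMOOTH_SIGMA,
    nest_depth: float = 45.0,
    smoothed_correlation: bool = True,
) -> tuple[pd.DataFrame, dict[str, dict[str, RateMap]]]:
    """Maps, inclusion, classification, and stability for every dHPC unit.

    All maps share one grid truncated at the threat-session foraging limit;
    included cells whose pre-threat peak exceeds the limit are excluded from
    stability analysis (``beyond_limit`` flag).  Returns the per-cell table
    and the per-cell, per-phase rate maps.
    """
    limit = foraging_limit(sessions["threat"])
    phases = [p for p in ("pre_threat", "threat", "post_threat") if p in sessions]
    cell_ids = [tr.cell_id for tr in sessions[phases[0]].trains_in("dHPC")]
    maps: dict[str, dict[str, RateMap]] = {}
    rows = []
    for cid in cell_ids:
        trains = {ph: sessions[ph].train(cid) for ph in phases}
        cmaps = {
            ph: compute_rate_map(
                trains[ph], sessions[ph].tracking, pixel_size, smoothing_sigma,
                x_limit=limit, x_min=-nest_depth,
            )
            for ph in phases
        }
        maps[cid] = cmaps
        flags = qualifies_as_place_cell(trains, cmaps)
        row: dict = {
            "cell_id": cid,
            "included": flags.included,
            "refractory_ok": flags.refractory_ok,
            "peak_rate_ok": flags.peak_rate_ok,
            "spatial_info_ok": flags.spatial_info_ok,
        }
        for ph in phases:
            row[f"peak_rate_{ph}"] = cmaps[ph].peak_rate
            row[f"info_{ph}"] = spatial_information(cmaps[ph])
            row[f"peak_x_{ph}"] = cmaps[ph].peak_x
        pre_peak = cmaps["pre_threat"].peak_x
        row["beyond_limit"] = pre_peak is not None and pre_peak > limit
        row["class"] = (
            classify_place_cell(pre_peak)
            if flags.included and pre_peak is not None and not row["beyond_limit"]
            else None
        )
        for pair in SESSION_PAIRS:
            if pair[0] in cmaps and pair[1] in cmaps:
                tag = _PAIR_TAG[pair]
                r, z = spatial_correlation(
                    cmaps[pair[0]], cmaps[pair[1]], smoothed=smoothed_correlation
                )
                row[f"r_{tag}"] = r
                row[f"z_{tag}"] = z
                row[f"peak_dist_{tag}"] = peak_distance(cmaps[pair[0]], cmaps[pair[1]])
        rows.append(row)
    return pd.DataFrame(rows), maps
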