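"""Joining synchrony, BA class, and place-field stability.

The headline question: do dHPC place cells that synchronize with
threat-responsive (Robot) BA cells remap more under threat than cells
synchronizing with non-threat BA cells?  Each included place cell is
labeled per epoch as Robot-paired (≥1 significant pair with a Robot-class
BA cell; dominance rule when paired with both types), nonRobot-paired
(significant pairs only with Pellet or NonResponsive cells), or unpaired.
Robot+Pellet BA cells and putative interneurons are excluded from pairing.
Nest and proximal place cells are merged into one nest_proximal group.

Group contrasts use a Lilliefors (Kolmogorov–Smirnov) normality pre-test to
choose between Welch's t and the Mann–Whitney rank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .session import Session, Tracking, ValidationError, compute_speed

logger = logging.getLogger(__name__)

LINKAGE_CLASSES = ("nest_proximal", "distal")


def _merged_class(cls: str) -> str:
    return "nest_proximal" if cls in ("nest", "proximal") else "distal"


def build_linkage(
    pair_table: pd.DataFrame,
    ba_classes: pd.DataFrame,
    place_records: pd.DataFrame,
    epochs: tuple[str, ...] = ("pre_surge",),
    dominance: str = "robot",
) -> pd.DataFrame:
    """One row per included place cell with per-epoch pairing labels.

    ``dominance='robot'`` labels a cell paired with both Robot and nonRobot
    BA cells as Robot-paired; ``'exclusive'`` drops such cells from the
    contrast (label ``mixed``).
    """
    ba = ba_classes.set_index("cell_id")
    orphans = set(pair_table["ba_cell"]) - set(ba.index)
    if orphans:
        raise ValidationError(f"pair table references unknown BA cells: {sorted(orphans)}")
    place = place_records[place_records["included"] & place_records["class"].notna()]
    known_hpc = set(place["cell_id"])
    rows = []
    for _, rec in place.iterrows():
        cid = rec["cell_id"]
        row = {
            "cell_id": cid,
            "class": _merged_class(rec["class"]),
            "fine_class": rec["class"],
            "peak_x_pre": rec["peak_x_pre_threat"],
            "z_pre_threat": rec.get("z_pre_threat", np.nan),
            "z_pre_post": rec.get("z_pre_post", np.nan),
            "peak_dist_pre_threat": rec.get("peak_dist_pre_threat", np.nan),
            "peak_dist_pre_post": rec.get("peak_dist_pre_post", np.nan),
        }
        for epoch in epochs:
            sig = pair_table[
                (pair_table["hpc_cell"] == cid)
                & (pair_table["epoch"] == epoch)
                & pair_table["significant"]
            ]
            if len(sig):
                partner_cls = ba.loc[sig["ba_cell"], "ba_class"]
                unit_type = (
                    ba.loc[sig["ba_cell"], "unit_type"]
                    if "unit_type" in ba.columns
                    else pd.Series("pyramidal", index=sig["ba_cell"])
                )
                usable = (partner_cls != "RobotPellet") & (unit_type == "pyramidal")
                has_robot = bool((partner_cls[usable] == "Robot").any())
                has_nonrobot = bool(
                    partner_cls[usable].isin(["Pellet", "NonResponsive"]).any()
                )
            else:
                has_robot = has_nonrobot = False
            if has_robot and has_nonrobot and dominance == "exclusive":
                label = "mixed"
            elif has_robot:
                label = "Robot"
            elif has_nonrobot:
                label = "nonRobot"
            else:
                label = "unpaired"
            row[f"paired_{epoch}"] = label
            if len(sig):
                best = sig.loc[sig["peak_z"].idxmax()]
                row[f"direction_{epoch}"] = best["direction"]
                row[f"epoch_rate_{epoch}"] = best["hpc_epoch_rate"]
            else:
                row[f"direction_{epoch}"] = "none"
                rates = pair_table[
                    (pair_table["hpc_cell"] == cid) & (pair_table["epoch"] == epoch)
                ]["hpc_epoch_rate"]
                row[f"epoch_rate_{epoch}"] = float(rates.iloc[0]) if len(rates) else np.nan
        rows.append(row)
    missing = set(pair_table["hpc_cell"]) - set(place_records["cell_id"])
    if missing:
        raise ValidationError(f"pair table references unknown dHPC cells: {sorted(missing)}")
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroupContrast:
    """Two-sample comparison of one stability metric between pairing groups."""

    cell_class: str
    metric: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    estimate: float  # mean_a - mean_b
    test: str
    statistic: float
    p_value: float


def _normal_enough(x: np.ndarray, alpha: float = 0.05) -> bool:
    """Lilliefors KS normality pre-test (normal when p > alpha)."""
    if x.size < 4 or np.std(x) == 0:
        return False
    from statsmodels.stats.diagnostic import lilliefors

    _, p = lilliefors(x, dist="norm")
    return bool(p > alpha)


def _two_sample(a: np.ndarray, b: np.ndarray) -> tuple[str, float, float]:
    if _normal_enough(a) and _normal_enough(b):
        stat, p = stats.ttest_ind(a, b, equal_var=False)
        return "welch_t", float(stat), float(p)
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return "mannwhitney", float(stat), float(p)


def stability_by_pairing(
    linkage: pd.DataFrame,
    epoch: str = "pre_surge",
    metric: str = "z_pre_threat",
    min_group: int = 3,
) -> list[GroupContrast]:
    """Robot-paired vs nonRobot-paired stability contrast per cell class."""
    out = []
    col = f"paired_{epoch}"
    for cls in LINKAGE_CLASSES:
        sub = linkage[linkage["class"] == cls]
        a = sub.loc[sub[col] == "Robot", metric].dropna().to_numpy()
        b = sub.loc[sub[col] == "nonRobot", metric].dropna().to_numpy()
        if a.size < min_group or b.size < min_group:
            logger.warning("%s: group too small (Robot %d, nonRobot %d); skipped",
                           cls, a.size, b.size)
            out.append(GroupContrast(cls, metric, a.size, b.size,
                                     float(np.mean(a)) if a.size else np.nan,
                                     float(np.mean(b)) if b.size else np.nan,
                                     np.nan, "skipped", np.nan, np.nan))
            continue
        test, statv, p = _two_sample(a, b)
        out.append(
            GroupContrast(
                cell_class=cls, metric=metric, n_a=a.size, n_b=b.size,
                mean_a=float(np.mean(a)), mean_b=float(np.mean(b)),
                estimate=float(np.mean(a) - np.mean(b)),
                test=test, statistic=statv, p_value=p,
            )
        )
    return out


def contrasts_frame(contrasts: list[GroupContrast]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in contrasts])


@dataclass(frozen=True)
class RegressionResult:
    metric: str
    subgroup: str
    slope: float
    intercept: float
    r: float
    p_value: float
    n: int


def stability_vs_position(
    records: pd.DataFrame,
    metrics: tuple[str, ...] = ("z_pre_threat", "peak_dist_pre_threat"),
    x_col: str = "peak_x_pre",
    subgroup: str = "all",
) -> list[RegressionResult]:
    """OLS fit of each stability metric on the pre-threat field position."""
    x_all = records[x_col if x_col in records.columns else "peak_x_pre_threat"]
    out = []
    for metric in metrics:
        sub = records[[metric]].assign(x=x_all).dropna()
        if len(sub) < 10:
            raise ValidationError(f"regression needs >=10 cells, got {len(sub)}")
        if np.std(sub["x"]) == 0:
            raise ValidationError("degenerate x variance")
        res = stats.linregress(sub["x"], sub[metric])
        out.append(
            RegressionResult(
                metric=metric, subgroup=subgroup,
                slope=float(res.slope), intercept=float(res.intercept),
                r=float(res.rvalue), p_value=float(res.pvalue), n=len(sub),
            )
        )
    return out


def regressions_frame(results: list[RegressionResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def _field_sigma(rates: np.ndarray, xs: np.ndarray, peak_x: float) -> float:
    """Rate-weighted x dispersion around the peak — field extent estimate."""
    w = np.clip(rates, 0, None)
    if w.sum() <= 0:
        return np.nan
    mu = float(np.sum(w * xs) / w.sum())
    return float(np.sqrt(np.sum(w * (xs - mu) ** 2) / w.sum()))


def speed_change_table(
    linkage: pd.DataFrame,
    sessions: dict[str, Session],
    maps: dict[str, dict],
) -> pd.DataFrame:
    """Per-cell relative in-field speed change between pre-threat and threat.

    The field region is the x interval within one estimated field sigma
    (rate-weighted dispersion) of the pre-threat peak; the relative change
    is (mean in-field speed under threat − pre) / pre.  Cells with zero or
    undefined pre-threat in-field speed are dropped with a log message.
    """
    speeds = {ph: compute_speed(s.tracking) for ph, s in sessions.items()}
    rows = []
    for _, rec in linkage.iterrows():
        cid = rec["cell_id"]
        pre_map = maps[cid]["pre_threat"]
        peak_x = rec["peak_x_pre"]
        xc = pre_map.x_centers
        with np.errstate(invalid="ignore"):
            prof = np.nanmean(np.where(pre_map.visited, pre_map.rate, np.nan), axis=1)
        ok = np.isfinite(prof)
        sigma = _field_sigma(prof[ok], xc[ok], peak_x)
        if not np.isfinite(sigma) or sigma <= 0:
            logger.warning("cell %s: undefined field extent; dropped", cid)
            continue
        lo, hi = peak_x - sigma, peak_x + sigma
        means = {}
        for ph in ("pre_threat", "threat"):
            tr = sessions[ph].tracking
            sel = (tr.x >= lo) & (tr.x <= hi)
            means[ph] = float(np.mean(speeds[ph][sel])) if sel.any() else np.nan
        if not np.isfinite(means["pre_threat"]) or means["pre_threat"] == 0:
            logger.warning("cell %s: zero pre-threat field speed; dropped", cid)
            continue
        rows.append(
            {
                "cell_id": cid,
                "class": rec["class"],
                "rel_speed_change": (means["threat"] - means["pre_threat"])
                / means["pre_threat"],
            }
        )
    return pd.DataFrame(rows, columns=["cell_id", "class", "rel_speed_change"])


def speed_control(
    linkage: pd.DataFrame,
    sessions: dict[str, Session],
    maps: dict[str, dict],
    metric: str = "z_pre_threat",
) -> pd.DataFrame:
    """Correlate per-cell relative speed change with stability, per class."""
    per_cell = speed_change_table(linkage, sessions, maps)
    if len(per_cell) == 0:
        return pd.DataFrame(columns=["class", "r", "p_value", "n"])
    per_cell = per_cell.merge(linkage[["cell_id", metric]], on="cell_id")
    out = []
    for cls, grp in per_cell.groupby("class"):
        sub = grp.dropna(subset=["rel_speed_change", metric])
        if len(sub) < 3 or sub[metric].std() == 0 or sub["rel_speed_change"].std() == 0:
            continue
        r, p = stats.pearsonr(sub["rel_speed_change"], sub[metric])
        out.append({"class": cls, "r": float(r), "p_value": float(p), "n": len(sub)})
    return pd.DataFrame(out, columns=["class", "r", "p_value", "n"])


def rate_comparisons(
    linkage: pd.DataFrame,
    pair_table: pd.DataFrame,
    ba_classes: pd.DataFrame,
    epoch: str = "pre_surge",
    min_group: int = 3,
) -> pd.DataFrame:
    """Epoch firing-rate controls for the stability contrasts.

    Contrast 1: Robot-paired distal vs Robot-paired nest_proximal dHPC
    epoch rates.  Contrast 2: epoch rates of Robot BA cells significantly
    paired with each dHPC class.
    """
    rows = []
    col, rate_col = f"paired_{epoch}", f"epoch_rate_{epoch}"
    robot_paired = linkage[linkage[col] == "Robot"]
    a = robot_paired.loc[robot_paired["class"] == "distal", rate_col].dropna().to_numpy()
    b = robot_paired.loc[
        robot_paired["class"] == "nest_proximal", rate_col
    ].dropna().to_numpy()
    if a.size >= min_group and b.size >= min_group:
        test, statv, p = _two_sample(a, b)
        rows.append(
            {"contrast": "dhpc_rate_robot_paired_distal_vs_nest_proximal",
             "n_a": a.size, "n_b": b.size, "mean_a": float(a.mean()),
             "mean_b": float(b.mean()), "estimate": float(a.mean() - b.mean()),
             "test": test, "statistic": statv, "p_value": p}
        )
    else:
        logger.warning("rate contrast skipped: groups %d vs %d", a.size, b.size)
    ba = ba_classes.set_index("cell_id")
    cls_of = linkage.set_index("cell_id")["class"]
    sig = pair_table[
        (pair_table["epoch"] == epoch)
        & pair_table["significant"]
        & pair_table["hpc_cell"].isin(cls_of.index)
    ].copy()
    sig = sig[ba.loc[sig["ba_cell"], "ba_class"].to_numpy() == "Robot"]
    if len(sig):
        sig["hpc_class"] = cls_of.loc[sig["hpc_cell"]].to_numpy()
        a = sig.loc[sig["hpc_class"] == "distal", "ba_epoch_rate"].to_numpy()
        b = sig.loc[sig["hpc_class"] == "nest_proximal", "ba_epoch_rate"].to_numpy()
        if a.size >= min_group and b.size >= min_group:
            test, statv, p = _two_sample(a, b)
            rows.append(
                {"contrast": "ba_rate_robot_cells_by_partner_class",
                 "n_a": a.size, "n_b": b.size, "mean_a": float(a.mean()),
                 "mean_b": float(b.mean()), "estimate": float(a.mean() - b.mean()),
                 "test": test, "statistic": statv, "p_value": p}
            )
    return pd.DataFrame(rows)
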