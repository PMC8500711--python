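"""Pairing labels, group contrasts, regressions, and control analyses."""

import numpy as np
import pandas as pd
import pytest

from riskforage.linkage import (
    build_linkage,
    rate_comparisons,
    stability_by_pairing,
    stability_vs_position,
    speed_control,
)
from riskforage.session import ValidationError


def place_records(n_nest=4, n_dist=6, z_dist=0.3, z_nest=2.0):
    rows = []
    rng = np.random.default_rng(0)
    for i in range(n_nest):
        rows.append(dict(cell_id=f"n{i}", included=True, **{"class": "nest"},
                         peak_x_pre_threat=-20.0 + i,
                         z_pre_threat=z_nest + rng.normal(0, 0.05),
                         z_pre_post=2.0, peak_dist_pre_threat=4.0,
                         peak_dist_pre_post=2.0))
    for i in range(n_dist):
        rows.append(dict(cell_id=f"d{i}", included=True, **{"class": "distal"},
                         peak_x_pre_threat=60.0 + i,
                         z_pre_threat=z_dist + rng.normal(0, 0.05),
                         z_pre_post=1.0, peak_dist_pre_threat=30.0,
                         peak_dist_pre_post=5.0))
    return pd.DataFrame(rows)


PAIR_COLUMNS = ["ba_cell", "hpc_cell", "epoch", "peak_z", "peak_lag_ms",
                "significant", "direction", "ba_epoch_rate", "hpc_epoch_rate", "flags"]


def pair_rows(pairs, epoch="pre_surge"):
    rows = []
    for ba, hpc, sig in pairs:
        rows.append(dict(ba_cell=ba, hpc_cell=hpc, epoch=epoch, peak_z=4.0 if sig else 1.0,
                         peak_lag_ms=30.0, significant=sig, direction="BA->dHPC",
                         ba_epoch_rate=4.0, hpc_epoch_rate=3.0, flags=""))
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


BA_CLASSES = pd.DataFrame(
    {
        "cell_id": ["bR", "bP", "bN", "bRP", "bI"],
        "ba_class": ["Robot", "Pellet", "NonResponsive", "RobotPellet", "NonResponsive"],
        "unit_type": ["pyramidal"] * 4 + ["interneuron"],
    }
)


class TestBuildLinkage:
    def test_pairing_labels(self):
        records = place_records()
        pairs = pair_rows(
            [("bR", "d0", True), ("bP", "d1", True), ("bN", "n0", True), ("bR", "d2", False)]
        )
        link = build_linkage(pairs, BA_CLASSES, records)
        lab = link.set_index("cell_id")["paired_pre_surge"]
        assert lab["d0"] == "Robot"
        assert lab["d1"] == "nonRobot"
        assert lab["n0"] == "nonRobot"
        assert lab["d2"] == "unpaired"

    def test_dominance_rule(self):
        records = place_records()
        pairs = pair_rows([("bR", "d0", True), ("bP", "d0", True)])
        link = build_linkage(pairs, BA_CLASSES, records)
        assert link.set_index("cell_id").loc["d0", "paired_pre_surge"] == "Robot"
        link_ex = build_linkage(pairs, BA_CLASSES, records, dominance="exclusive")
        assert link_ex.set_index("cell_id").loc["d0", "paired_pre_surge"] == "mixed"

    def test_robotpellet_and_interneuron_partners_ignored(self):
        records = place_records()
        pairs = pair_rows([("bRP", "d0", True), ("bI", "d1", True)])
        link = build_linkage(pairs, BA_CLASSES, records)
        lab = link.set_index("cell_id")["paired_pre_surge"]
        assert lab["d0"] == "unpaired" and lab["d1"] == "unpaired"

    def test_nest_proximal_merged(self):
        link = build_linkage(pair_rows([]), BA_CLASSES, place_records())
        assert set(link["class"]) == {"nest_proximal", "distal"}

    def test_orphan_ba_cell_raises(self):
        pairs = pair_rows([("ghost", "d0", True)])
        with pytest.raises(ValidationError, match="ghost"):
            build_linkage(pairs, BA_CLASSES, place_records())


class TestStabilityByPairing:
    def _linkage(self, z_robot, z_nonrobot):
        rows = []
        for i, z in enumerate(z_robot):
            rows.append(dict(cell_id=f"r{i}", **{"class": "distal"},
                             paired_pre_surge="Robot", z_pre_threat=z,
                             epoch_rate_pre_surge=3.0, peak_x_pre=60.0))
        for i, z in enumerate(z_nonrobot):
            rows.append(dict(cell_id=f"n{i}", **{"class": "distal"},
                             paired_pre_surge="nonRobot", z_pre_threat=z,
                             epoch_rate_pre_surge=3.0, peak_x_pre=60.0))
        return pd.DataFrame(rows)

    def test_separated_groups_significant(self, rng):
        link = self._linkage(rng.normal(0.2, 0.2, 12), rng.normal(1.8, 0.2, 12))
        res = {c.cell_class: c for c in stability_by_pairing(link)}
        assert res["distal"].p_value < 0.01
        assert res["distal"].estimate < 0

    def test_label_swap_flips_sign(self, rng):
        a = rng.normal(0.2, 0.2, 10)
        b = rng.normal(1.5, 0.2, 10)
        c1 = {c.cell_class: c for c in stability_by_pairing(self._linkage(a, b))}
        c2 = {c.cell_class: c for c in stability_by_pairing(self._linkage(b, a))}
        assert c1["distal"].estimate == pytest.approx(-c2["distal"].estimate)

    def test_small_group_skipped(self, rng):
        link = self._linkage(rng.normal(0.2, 0.2, 2), rng.normal(1.5, 0.2, 10))
        res = {c.cell_class: c for c in stability_by_pairing(link)}
        assert res["distal"].test == "skipped"
        assert np.isnan(res["distal"].p_value)


class TestStabilityVsPosition:
    def test_shift_proportional_to_position(self, rng):
        x = rng.uniform(-40, 100, 60)
        z = 2.0 - 0.02 * x + rng.normal(0, 0.1, 60)
        d = 2.0 + 0.25 * x + rng.normal(0, 3.0, 60)
        df = pd.DataFrame({"peak_x_pre": x, "z_pre_threat": z, "peak_dist_pre_threat": d})
        res = {r.metric: r for r in stability_vs_position(df)}
        assert res["z_pre_threat"].slope < 0 and res["z_pre_threat"].p_value < 0.05
        assert res["peak_dist_pre_threat"].slope > 0

    def test_duplicating_rows_preserves_slope(self, rng):
        x = rng.uniform(0, 100, 20)
        df = pd.DataFrame({"peak_x_pre": x, "z_pre_threat": 1.5 - 0.01 * x,
                           "peak_dist_pre_threat": 5 + 0.1 * x})
        r1 = stability_vs_position(df)[0]
        r2 = stability_vs_position(pd.concat([df, df], ignore_index=True))[0]
        assert r1.slope == pytest.approx(r2.slope)

    def test_too_few_cells_errors(self):
        df = pd.DataFrame({"peak_x_pre": [1.0, 2.0], "z_pre_threat": [1.0, 2.0],
                           "peak_dist_pre_threat": [0.0, 1.0]})
        with pytest.raises(ValidationError):
            stability_vs_position(df)

    def test_degenerate_x_errors(self):
        df = pd.DataFrame({"peak_x_pre": np.full(12, 5.0),
                           "z_pre_threat": np.arange(12.0),
                           "peak_dist_pre_threat": np.arange(12.0)})
        with pytest.raises(ValidationError):
            stability_vs_position(df)


class TestRateComparisons:
    def test_matched_rates_nonsignificant_and_3x_detected(self, rng):
        def link(rate_distal):
            rows = []
            for i in range(10):
                rows.append(dict(cell_id=f"d{i}", **{"class": "distal"},
                                 paired_pre_surge="Robot",
                                 epoch_rate_pre_surge=float(rng.normal(rate_distal, 0.3))))
                rows.append(dict(cell_id=f"n{i}", **{"class": "nest_proximal"},
                                 paired_pre_surge="Robot",
                                 epoch_rate_pre_surge=float(rng.normal(3.0, 0.3))))
            return pd.DataFrame(rows)

        empty_pairs = pd.DataFrame(
            columns=["ba_cell", "hpc_cell", "epoch", "significant", "ba_epoch_rate"]
        )
        matched = rate_comparisons(link(3.0), empty_pairs, BA_CLASSES)
        assert matched.iloc[0]["p_value"] > 0.05
        different = rate_comparisons(link(9.0), empty_pairs, BA_CLASSES)
        assert different.iloc[0]["p_value"] < 0.01


@pytest.fixture(scope="module")
def cohort_link_maps():
    from riskforage import place as place_mod
    from riskforage.linkage import _merged_class
    from riskforage.simulate import default_cohort_config, make_cohort

    cohort = make_cohort(default_cohort_config(2))
    records, maps = place_mod.build_place_records(cohort.sessions)
    rows = records[records["included"] & records["class"].notna()]
    link = pd.DataFrame(
        {
            "cell_id": rows["cell_id"],
            "class": rows["class"].map(_merged_class),
            "peak_x_pre": rows["peak_x_pre_threat"],
            "z_pre_threat": rows["z_pre_threat"],
        }
    )
    return cohort, link, maps


class TestSpeedControl:
    def test_forced_dependence_detected(self, cohort_link_maps):
        """When stability is a deterministic function of the in-field speed
        change, the control correlation is (+/-)1."""
        from riskforage.linkage import speed_change_table

        cohort, link, maps = cohort_link_maps
        per_cell = speed_change_table(link, cohort.sessions, maps)
        forced = link.drop(columns="z_pre_threat").merge(
            per_cell[["cell_id", "rel_speed_change"]], on="cell_id"
        )
        forced["z_pre_threat"] = 0.5 - 2.0 * forced["rel_speed_change"]
        out = speed_control(forced[["cell_id", "class", "peak_x_pre", "z_pre_threat"]],
                            cohort.sessions, maps)
        assert (out["r"] < -0.999).all()

    def test_real_cohort_structure(self, cohort_link_maps):
        cohort, link, maps = cohort_link_maps
        out = speed_control(link, cohort.sessions, maps)
        assert set(out.columns) == {"class", "r", "p_value", "n"}
        assert out["n"].sum() > 0
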