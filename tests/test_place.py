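"""Rate maps, spatial information, inclusion, classification, stability."""

import numpy as np
import pytest

from riskforage.place import (
    RateMap,
    classify_place_cell,
    compute_occupancy,
    compute_rate_map,
    fisher_z,
    peak_distance,
    qualifies_as_place_cell,
    spatial_correlation,
    spatial_information,
)
from riskforage.session import SpikeTrain, Tracking, ValidationError

from conftest import linear_tracking


def make_map(occ, counts, rate=None):
    """Hand-built single-row RateMap (1-D corridor, one y bin)."""
    occ = np.asarray(occ, float).reshape(-1, 1)
    counts = np.asarray(counts, float).reshape(-1, 1)
    visited = occ > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(visited, counts / np.where(visited, occ, 1), np.nan)
    r = raw if rate is None else np.asarray(rate, float).reshape(-1, 1)
    n = occ.shape[0]
    return RateMap(
        x_edges=4.0 * np.arange(n + 1), y_edges=np.array([0.0, 4.0]),
        occupancy=occ, spike_count=counts, rate=r, rate_raw=raw, visited=visited,
    )


class TestOccupancy:
    def test_sitting_in_one_pixel(self):
        t = np.arange(10 * 30) / 30.0
        tr = Tracking(t=t, x=np.full(t.size, 10.0), y=np.zeros(t.size))
        occ, xe, ye = compute_occupancy(tr, pixel_size=4.0, x_limit=20.0, x_min=0.0)
        assert occ.sum() == pytest.approx(10.0, rel=1e-3)
        assert (occ > 0).sum() == 1

    def test_occupancy_conserves_time_below_limit(self):
        tr = linear_tracking(duration=5.0, speed=30.0)  # reaches 150 cm
        occ, _, _ = compute_occupancy(tr, x_limit=100.0, x_min=0.0)
        dt = tr.frame_interval
        expected = (tr.x <= 100.0).sum() * dt
        assert occ.sum() == pytest.approx(expected)

    def test_uniform_sweep_uniform_occupancy(self):
        tr = linear_tracking(duration=4.0, speed=25.0)
        occ, _, _ = compute_occupancy(tr, x_limit=100.0, x_min=0.0)
        prof = occ.sum(axis=1)
        inner = prof[1:-1]
        # occupancy is frame-quantized: per-pixel time can differ from the
        # ideal pixel/speed dwell by at most one frame interval
        assert np.all(np.abs(inner - inner.mean()) <= tr.frame_interval + 1e-9)

    def test_no_frames_in_limit_errors(self):
        tr = linear_tracking(duration=1.0, speed=30.0, x0=50.0)
        with pytest.raises(ValidationError):
            compute_occupancy(tr, x_limit=-10.0, x_min=-45.0)


class TestRateMap:
    def test_unsmoothed_ratio(self):
        t = np.arange(10 * 30) / 30.0
        tr = Tracking(t=t, x=np.full(t.size, 10.0), y=np.zeros(t.size))
        train = SpikeTrain("c", "dHPC", np.linspace(0.1, 9.5, 20))
        m = compute_rate_map(train, tr, smoothing_sigma=0.0, x_limit=20.0, x_min=0.0)
        assert m.peak_rate == pytest.approx(2.0, rel=1e-2)

    def test_conservation_identity(self):
        tr = linear_tracking(duration=5.0, speed=20.0)
        rng = np.random.default_rng(0)
        train = SpikeTrain("c", "dHPC", np.sort(rng.uniform(0, 5.0, 60)))
        m = compute_rate_map(train, tr, smoothing_sigma=0.0, x_limit=100.0, x_min=0.0)
        assert m.spike_count.sum() / m.occupancy.sum() == pytest.approx(
            m.mean_rate
        )

    def test_empty_train_zero_map(self):
        tr = linear_tracking(duration=5.0, speed=20.0)
        m = compute_rate_map(SpikeTrain("c", "dHPC", np.empty(0)), tr,
                             x_limit=100.0, x_min=0.0)
        assert m.peak_rate == 0.0
        assert m.peak_x is None

    def test_simulated_field_peak_recovery(self):
        from riskforage.simulate import PlaceCellSpec, SimConfig, simulate_place_train, simulate_trajectory

        cfg = SimConfig(n_trials=8, rng_seed=0)
        tracking, _ = simulate_trajectory(cfg, "pre_threat", np.random.default_rng(0))
        spec = PlaceCellSpec("c", center_x=80.0, width_sigma=10.0, peak_rate=15.0,
                             baseline_rate=0.5)
        train = simulate_place_train(spec, tracking, np.random.default_rng(1))
        m = compute_rate_map(train, tracking, x_limit=125.0)
        assert abs(m.peak_x - 80.0) <= 4.0  # within one pixel


class TestSpatialInformation:
    def test_uniform_rate_zero_bits(self):
        m = make_map([1, 1, 1, 1], [2, 2, 2, 2])
        assert spatial_information(m) == pytest.approx(0.0, abs=1e-12)

    def test_two_pixel_hand_value(self):
        # p = (1/2, 1/2), rates (0, 2) -> lambda_bar = 1, I = 1.0 bits/s
        m = make_map([5, 5], [0, 10])
        assert spatial_information(m) == pytest.approx(1.0)

    def test_four_pixel_hand_value(self):
        # p = 1/4 each, rates (0,0,0,4) -> I = 2.0 bits/s
        m = make_map([2, 2, 2, 2], [0, 0, 0, 8])
        assert spatial_information(m) == pytest.approx(2.0)

    def test_silent_map_zero(self):
        m = make_map([1, 1], [0, 0])
        assert spatial_information(m) == 0.0

    def test_nonnegative_random_maps(self, rng):
        for _ in range(20):
            occ = rng.uniform(0.1, 5, 12)
            counts = rng.poisson(3, 12)
            assert spatial_information(make_map(occ, counts)) >= 0


class TestInclusion:
    def test_low_peak_excluded(self):
        m = make_map([1] * 20, [1.5] * 20)
        flags = qualifies_as_place_cell(
            {"pre": SpikeTrain("c", "dHPC", np.arange(0, 10, 0.5))}, {"pre": m}
        )
        assert not flags.peak_rate_ok and not flags.included

    def test_short_isi_excluded(self):
        m = make_map([1] * 4, [0, 0, 0, 40])
        train = SpikeTrain("c", "dHPC", np.array([1.0, 1.0004, 2.0]))
        flags = qualifies_as_place_cell({"pre": train}, {"pre": m})
        assert not flags.refractory_ok

    def test_clean_cell_included(self):
        m = make_map([1] * 4, [0, 0, 0, 40])  # peak 40 Hz, info >> 1
        train = SpikeTrain("c", "dHPC", np.arange(0, 10, 0.5))
        flags = qualifies_as_place_cell({"pre": train}, {"pre": m})
        assert flags.included


class TestClassification:
    @pytest.mark.parametrize(
        "peak_x,expected",
        [(-10.0, "nest"), (-0.1, "nest"), (0.0, "proximal"), (12.0, "proximal"),
         (25.0, "proximal"), (25.1, "distal"), (80.0, "distal")],
    )
    def test_boundaries(self, peak_x, expected):
        assert classify_place_cell(peak_x) == expected


class TestStability:
    def test_self_correlation_capped(self):
        m = make_map([1] * 12, list(range(12)))
        r, z = spatial_correlation(m, m)
        assert r == pytest.approx(1.0)
        assert z == pytest.approx(np.arctanh(1 - 1e-7))

    def test_hand_pearson_anticorrelated(self):
        a = make_map([1, 1, 1], [1, 2, 3])
        b = make_map([1, 1, 1], [3, 2, 1])
        r, z = spatial_correlation(a, b, min_pixels=3)
        assert r == pytest.approx(-1.0)

    def test_fisher_z_closed_form(self):
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_z_monotone_in_r(self):
        rs = np.linspace(-0.99, 0.99, 21)
        zs = [fisher_z(r) for r in rs]
        assert np.all(np.diff(zs) > 0)

    def test_too_few_common_pixels_undefined(self):
        a = make_map([1, 1, 0, 0], [1, 2, 0, 0])
        b = make_map([0, 0, 1, 1], [0, 0, 2, 1])
        r, z = spatial_correlation(a, b)
        assert np.isnan(r) and np.isnan(z)

    def test_peak_distance_symmetric(self):
        a = make_map([1] * 10, [0, 0, 5, 0, 0, 0, 0, 0, 0, 0])
        b = make_map([1] * 10, [0, 0, 0, 0, 0, 0, 0, 5, 0, 0])
        assert peak_distance(a, b) == pytest.approx(20.0)
        assert peak_distance(b, a) == peak_distance(a, b)

    def test_identical_maps_zero_distance(self):
        a = make_map([1] * 10, [0, 1, 5, 1, 0, 0, 0, 0, 0, 0])
        assert peak_distance(a, a) == 0.0

    def test_undefined_peak_nan(self):
        a = make_map([1] * 10, [0] * 10)
        b = make_map([1] * 10, [0, 1, 5, 1, 0, 0, 0, 0, 0, 0])
        assert np.isnan(peak_distance(a, b))


def test_threat_shift_recovered_via_maps():
    """End-to-end: a simulated 30 cm displacement is read back from maps."""
    from riskforage import place
    from riskforage.evaluation import remapping_cohort_config
    from riskforage.simulate import make_cohort

    cohort = make_cohort(remapping_cohort_config(seed=11, n_per_class=6))
    records, _ = place.build_place_records(cohort.sessions)
    dist = records[records["class"] == "distal"]
    assert len(dist) >= 4
    assert dist["peak_dist_pre_threat"].median() == pytest.approx(30.0, abs=5.0)
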