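"""Cross-correlogram construction, shift predictor, and significance rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from riskforage import ccg
from riskforage.evaluation import brute_force_ccg, _random_epoch_spikes
from riskforage.session import EpochSet, EventLog, SpikeTrain, ValidationError, make_epochs


def spikes_by_trial(rel_lists, label="pre_surge"):
    return ccg.EpochSpikes(
        label=label,
        window_starts=20.0 * np.arange(len(rel_lists)),
        rel_times=tuple(np.asarray(r, float) for r in rel_lists),
    )


def bin_of(lag_s):
    return int(np.floor((lag_s + ccg.MAX_LAG_S) / ccg.BIN_S + 1e-9))


class TestEpochSpikes:
    def test_windowing_drops_outside(self):
        ev = EventLog.from_records([(1, "robot_surge", 100.0)])
        eps = make_epochs(ev, "pre_surge")  # [97.5, 100)
        train = SpikeTrain("c", "BA", np.array([97.6, 101.0]))
        out = ccg.epoch_spikes(train, eps)
        assert list(out.rel_times[0]) == pytest.approx([0.1])

    def test_boundaries_half_open(self):
        ev = EventLog.from_records([(1, "robot_surge", 100.0)])
        eps = make_epochs(ev, "post_surge")  # [100, 102.5)
        train = SpikeTrain("c", "BA", np.array([100.0, 102.5]))
        out = ccg.epoch_spikes(train, eps)
        assert list(out.rel_times[0]) == [0.0]

    def test_empty_train(self):
        ev = EventLog.from_records([(1, "robot_surge", 100.0)])
        out = ccg.epoch_spikes(
            SpikeTrain("c", "BA", np.empty(0)), make_epochs(ev, "pre_surge")
        )
        assert out.n_spikes == 0


class TestRawCcg:
    def test_single_pair_lag_bin(self):
        ref = spikes_by_trial([[1.00]])
        tgt = spikes_by_trial([[1.02]])
        counts = ccg.raw_ccg(ref, tgt)
        expected = np.zeros(ccg.N_BINS)
        expected[bin_of(0.02)] = 1
        assert np.array_equal(counts, expected)

    def test_out_of_range_lag_dropped(self):
        ref = spikes_by_trial([[1.0, 2.0]])
        tgt = spikes_by_trial([[0.95]])
        counts = ccg.raw_ccg(ref, tgt)
        assert counts.sum() == 1  # the -1.05 s lag falls outside +-500 ms
        assert counts[bin_of(-0.05)] == 1

    def test_cross_trial_pairs_not_counted(self):
        ref = spikes_by_trial([[1.0], []])
        tgt = spikes_by_trial([[], [1.0]])
        assert ccg.raw_ccg(ref, tgt).sum() == 0

    def test_antisymmetry(self, rng):
        ref = _random_epoch_spikes(rng, 5, 30)
        tgt = _random_epoch_spikes(rng, 5, 30)
        fwd = ccg.raw_ccg(ref, tgt)
        rev = ccg.raw_ccg(tgt, ref)
        # continuous lags never sit exactly on a bin edge, so reversing the
        # roles mirrors the histogram about lag zero exactly
        assert np.array_equal(fwd, rev[::-1])

    def test_mismatched_trials_error(self):
        with pytest.raises(ValidationError):
            ccg.raw_ccg(spikes_by_trial([[1.0]]), spikes_by_trial([[1.0], [2.0]]))

    @given(seed=st.integers(0, 10_000))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_trials = int(rng.integers(2, 8))
        ref = _random_epoch_spikes(rng, n_trials, 40)
        tgt = _random_epoch_spikes(rng, n_trials, 40)
        assert np.array_equal(ccg.raw_ccg(ref, tgt), brute_force_ccg(ref, tgt))


class TestShiftPredictor:
    def test_stimulus_locked_pattern_cancelled(self):
        """Identical per-trial spike patterns: predictor equals raw, the
        corrected CCG vanishes, and the pair is not significant."""
        pattern = [0.2, 0.9, 1.4, 2.1]
        ref = spikes_by_trial([pattern] * 8)
        tgt = spikes_by_trial([[p + 0.03 for p in pattern]] * 8)
        raw = ccg.raw_ccg(ref, tgt)
        pred = ccg.shift_predictor(ref, tgt, 50, np.random.default_rng(0))
        assert np.allclose(raw, pred)
        res = ccg.ccg_significance(raw, pred, ref.rate, tgt.rate)
        assert not res.significant and "degenerate" in res.flags

    def test_independent_trains_corrected_near_zero(self, rng):
        ref = spikes_by_trial([np.sort(rng.uniform(0, 2.5, 12)) for _ in range(10)])
        tgt = spikes_by_trial([np.sort(rng.uniform(0, 2.5, 12)) for _ in range(10)])
        raw = ccg.raw_ccg(ref, tgt)
        pred = ccg.shift_predictor(ref, tgt, 100, rng)
        corrected = raw - pred
        se = corrected.std() / np.sqrt(corrected.size)
        assert abs(corrected.mean()) < 3 * se + 0.05

    def test_fixed_seed_reproducible(self, rng):
        ref = _random_epoch_spikes(rng, 6, 20)
        tgt = _random_epoch_spikes(rng, 6, 20)
        p1 = ccg.shift_predictor(ref, tgt, 30, np.random.default_rng(5))
        p2 = ccg.shift_predictor(ref, tgt, 30, np.random.default_rng(5))
        assert np.array_equal(p1, p2)

    def test_single_trial_error(self):
        one = spikes_by_trial([[1.0]])
        with pytest.raises(ValidationError):
            ccg.shift_predictor(one, one, 10, np.random.default_rng(0))

    def test_derangement_has_no_fixed_points(self, rng):
        for n in (2, 3, 5, 9):
            perm = ccg._derangement(n, rng)
            assert not np.any(perm == np.arange(n))
            assert sorted(perm) == list(range(n))


class TestSignificance:
    def _flat(self, value=5.0):
        return np.full(ccg.N_BINS, value)

    def test_peak_outside_test_window_not_significant(self):
        raw = self._flat()
        raw[bin_of(0.150)] += 40  # strong peak at +150 ms only
        res = ccg.ccg_significance(raw, self._flat(), 5.0, 5.0)
        assert not res.significant

    def test_peak_inside_window_detected_with_direction(self):
        raw = self._flat()
        raw[bin_of(0.035)] += 40
        res = ccg.ccg_significance(raw, self._flat(), 5.0, 5.0)
        assert res.significant and res.direction == "BA->dHPC"
        assert res.peak_lag_ms == pytest.approx(30.0)
        raw2 = self._flat()
        raw2[bin_of(-0.035)] += 40
        res2 = ccg.ccg_significance(raw2, self._flat(), 5.0, 5.0)
        assert res2.significant and res2.direction == "dHPC->BA"

    def test_rate_floor_excludes(self):
        raw = self._flat()
        raw[bin_of(0.035)] += 40
        res = ccg.ccg_significance(raw, self._flat(), 5.0, 0.05)
        assert not res.significant and "rate_fail" in res.flags

    def test_injected_pair_recovered(self, rng):
        from riskforage.simulate import inject_synchrony

        ev = EventLog.from_records(
            [(i + 1, "robot_surge", 50.0 + 20.0 * i) for i in range(10)]
        )
        pre = make_epochs(ev, "pre_surge")
        dur = 260.0
        ba = SpikeTrain("ba", "BA", np.sort(rng.uniform(0, dur, int(5 * dur))))
        hpc = SpikeTrain("hpc", "dHPC", np.sort(rng.uniform(0, dur, int(5 * dur))))
        hpc = inject_synchrony(ba, hpc, pre, 30.0, 0.3, rng)
        res = ccg.analyze_pair(ba, hpc, pre, rng=rng)
        assert res.significant
        assert res.direction == "BA->dHPC"
        assert res.peak_lag_ms in (20.0, 30.0)  # +-5 ms jitter spans two bins


class TestPairScreen:
    def test_row_count_and_determinism(self, rng):
        ev = EventLog.from_records(
            [(i + 1, "robot_surge", 50.0 + 20.0 * i) for i in range(6)]
        )
        eps = {"pre_surge": make_epochs(ev, "pre_surge")}
        dur = 180.0
        bas = [SpikeTrain(f"b{i}", "BA", np.sort(rng.uniform(0, dur, 600))) for i in range(3)]
        hps = [SpikeTrain(f"h{i}", "dHPC", np.sort(rng.uniform(0, dur, 600))) for i in range(4)]
        t1 = ccg.pair_screen(bas, hps, eps, 50, np.random.default_rng(1))
        t2 = ccg.pair_screen(bas, hps, eps, 50, np.random.default_rng(1))
        assert len(t1) == 3 * 4
        assert t1.equals(t2)

    def test_summary_epoch_specificity(self):
        import pandas as pd

        table = pd.DataFrame(
            {
                "ba_cell": ["b"] * 2,
                "hpc_cell": ["h"] * 2,
                "epoch": ["pre_surge", "post_surge"],
                "significant": [True, False],
            }
        )
        summary = ccg.summarize_pairs(table)
        assert summary.loc[0, "surge_specificity"] == "pre_only"
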