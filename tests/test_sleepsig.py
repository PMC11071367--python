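"""Signal grid, band powers, staging, RBD detection, and sleep summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_grid
from phenomap.sleepsig import (
    BAND_NAMES,
    PolysomnogramRecord,
    build_signal_grid,
    detect_rbd_events,
    epoch_band_powers,
    rem_run_count,
    score_stages,
    summarize_sleep,
)

FS = 500.0


def sine(freq, amp, n, fs=FS):
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / fs)


class TestSignalGrid:
    def test_constant_emg_rms_is_exact(self):
        n = int(FS * 20)
        rec = PolysomnogramRecord(eeg=sine(3, 1, n), emg=np.full(n, 0.3), rate_hz=FS)
        assert build_signal_grid(rec).emg_rms[0] == pytest.approx(0.3, abs=0)

    def test_sine_emg_rms_matches_amplitude_over_sqrt2(self):
        n = int(FS * 20)
        rec = PolysomnogramRecord(eeg=sine(3, 1, n), emg=sine(10, 2.0, n), rate_hz=FS)
        assert build_signal_grid(rec).emg_rms[0] == pytest.approx(np.sqrt(2), rel=5e-3)

    def test_epoch_bookkeeping_one_hour(self, rng):
        n = int(FS * 3600)
        rec = PolysomnogramRecord(eeg=rng.standard_normal(n),
                                  emg=rng.standard_normal(n), rate_hz=FS)
        grid = build_signal_grid(rec)
        assert len(grid) == 180
        assert np.allclose(grid.frame["time_s"], 20.0 * np.arange(180))

    def test_trailing_partial_epoch_dropped(self, rng):
        n = int(FS * 50)  # 2.5 epochs
        rec = PolysomnogramRecord(eeg=rng.standard_normal(n),
                                  emg=rng.standard_normal(n), rate_hz=FS)
        assert len(build_signal_grid(rec)) == 2

    def test_nonfinite_samples_flag_artifact(self, rng):
        n = int(FS * 60)
        eeg = rng.standard_normal(n)
        eeg[int(FS * 25)] = np.nan  # second epoch
        rec = PolysomnogramRecord(eeg=eeg, emg=rng.standard_normal(n), rate_hz=FS)
        grid = build_signal_grid(rec)
        assert list(grid.frame["artifact"]) == [False, True, False]

    def test_rail_run_flags_artifact(self, rng):
        n = int(FS * 40)
        emg = rng.standard_normal(n)
        emg[100:400] = 5.0  # 300 pinned samples >> rate/10
        rec = PolysomnogramRecord(eeg=rng.standard_normal(n), emg=emg, rate_hz=FS)
        grid = build_signal_grid(rec, rail=5.0)
        assert bool(grid.frame["artifact"][0])
        assert not bool(grid.frame["artifact"][1])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            PolysomnogramRecord(eeg=np.zeros(10), emg=np.zeros(9), rate_hz=FS)

    def test_rms_scale_equivariance_preserves_rbd_flags(self, rng):
        n = int(FS * 20) * 30
        eeg = rng.standard_normal(n)
        emg = rng.standard_normal(n)
        g1 = build_signal_grid(PolysomnogramRecord(eeg=eeg, emg=emg, rate_hz=FS))
        g2 = build_signal_grid(PolysomnogramRecord(eeg=eeg, emg=3.0 * emg, rate_hz=FS))
        assert np.allclose(g2.emg_rms, 3.0 * g1.emg_rms)
        for g in (g1, g2):
            g.frame["stage"] = "REM"
        f1, _ = detect_rbd_events(g1)
        f2, _ = detect_rbd_events(g2)
        assert np.array_equal(f1.rbd, f2.rbd)


class TestBandPowers:
    def test_pure_theta_sine_dominates(self, rng):
        n = int(FS * 20)
        x = sine(6.0, 1.0, n) + 0.07 * rng.standard_normal(n)
        bp = epoch_band_powers(x, FS)
        assert max(bp, key=bp.get) == "theta"
        assert bp["theta"] >= 80.0

    def test_white_noise_delta_share_matches_flat_spectrum(self, rng):
        n = int(FS * 20)
        deltas = [epoch_band_powers(rng.standard_normal(n), FS)["delta"]
                  for _ in range(200)]
        assert np.mean(deltas) == pytest.approx(100.0 * 3.5 / 79.7, abs=1.0)

    def test_amplitude_scale_invariance(self, rng):
        x = rng.standard_normal(int(FS * 20))
        a = epoch_band_powers(x, FS)
        b = epoch_band_powers(7.3 * x, FS)
        for name in BAND_NAMES:
            assert a[name] == pytest.approx(b[name], rel=1e-9)

    def test_silent_epoch_rejected(self):
        with pytest.raises(ValueError, match="zero total power"):
            epoch_band_powers(np.zeros(int(FS * 20)), FS)

    def test_short_epoch_rejected(self):
        with pytest.raises(ValueError):
            epoch_band_powers(np.zeros(512), FS)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_bands_bounded_and_sum_below_100(self, seed):
        r = np.random.default_rng(seed)
        x = r.standard_normal(int(FS * 20)) * r.uniform(0.1, 10)
        x += sine(r.uniform(1, 60), r.uniform(0, 5), int(FS * 20))
        bp = epoch_band_powers(x, FS)
        assert all(0.0 <= v <= 100.0 for v in bp.values())
        assert sum(bp.values()) <= 100.0 + 1e-9


class TestScoring:
    def test_rule_application_on_crafted_features(self):
        # high-EMG epoch -> WAKE, high-delta/low-EMG -> NREM,
        # high-theta/delta & lowest EMG -> REM
        n = 30
        delta = np.r_[np.full(10, 30.0), np.full(10, 70.0), np.full(10, 10.0)]
        theta = np.r_[np.full(10, 20.0), np.full(10, 10.0), np.full(10, 50.0)]
        emg = np.r_[np.full(10, 1.0), np.full(10, 0.4), np.full(10, 0.1)]
        delta += np.linspace(0, 1e-3, n)  # avoid exactly zero variance
        theta += np.linspace(0, 1e-3, n)
        emg += np.linspace(0, 1e-4, n)
        grid = make_grid(["UNSCORED"] * n, emg_rms=emg, delta=delta, theta=theta)
        scored = score_stages(grid)
        assert list(scored.stage[:10]) == ["WAKE"] * 10
        assert list(scored.stage[10:20]) == ["NREM"] * 10
        assert list(scored.stage[20:]) == ["REM"] * 10

    def test_artifact_epochs_stay_unscored(self):
        n = 30
        art = np.zeros(n, bool)
        art[5] = True
        delta = 30 + np.arange(n, dtype=float)
        theta = 20 + np.arange(n, dtype=float) % 7
        emg = 0.1 + 0.01 * (np.arange(n) % 5)
        grid = make_grid(["UNSCORED"] * n, emg_rms=emg, delta=delta,
                         theta=theta, artifact=art)
        scored = score_stages(grid)
        assert scored.stage[5] == "UNSCORED"

    def test_more_than_1pct_artifacts_marks_excluded(self):
        n = 200
        art = np.zeros(n, bool)
        art[:4] = True  # 2%
        delta = 30 + np.arange(n, dtype=float) % 11
        theta = 20 + np.arange(n, dtype=float) % 7
        emg = 0.1 + 0.01 * (np.arange(n) % 5)
        grid = make_grid(["UNSCORED"] * n, emg_rms=emg, delta=delta,
                         theta=theta, artifact=art)
        scored = score_stages(grid)
        assert scored.excluded
        assert summarize_sleep(scored).excluded

    def test_degenerate_features_rejected(self):
        grid = make_grid(["UNSCORED"] * 20)  # constant features
        with pytest.raises(ValueError):
            score_stages(grid)


class TestRBDDetection:
    def test_zero_spread_baseline_flags_nothing(self):
        grid = make_grid(["REM"] * 10, emg_rms=np.full(10, 0.5))
        out, events = detect_rbd_events(grid)
        assert not out.rbd.any()
        assert events == []

    def test_threshold_and_merge_against_hand_case(self, rng):
        n = 105
        rms = rng.normal(1.0, 0.1, n)
        planted = [10, 20, 21, 40, 60]
        rms[planted] = 2.0
        assert rms.max(initial=0, where=~np.isin(np.arange(n), planted)) < 1.6
        grid = make_grid(["REM"] * n, emg_rms=rms)
        out, events = detect_rbd_events(grid)
        assert sorted(np.flatnonzero(out.rbd)) == planted
        assert len(events) == 4
        assert (events[1].start_epoch, events[1].end_epoch) == (20, 21)

    def test_no_rem_epochs_degenerate(self):
        grid = make_grid(["WAKE"] * 20)
        out, events = detect_rbd_events(grid)
        assert events == []
        assert summarize_sleep(out, events).rbd_per_rem_pct is None

    def test_adding_non_rem_epochs_leaves_flags_unchanged(self, rng):
        rms = rng.normal(1.0, 0.2, 50)
        g1 = make_grid(["REM"] * 50, emg_rms=rms)
        g2 = make_grid(["REM"] * 50 + ["WAKE"] * 30,
                       emg_rms=np.r_[rms, rng.normal(3.0, 0.2, 30)])
        f1, _ = detect_rbd_events(g1)
        f2, _ = detect_rbd_events(g2)
        assert np.array_equal(f1.rbd, f2.rbd[:50])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_matches_brute_force_oracle(self, seed):
        from phenomap.benchmarks import oracle_rbd

        r = np.random.default_rng(seed)
        n = int(r.integers(20, 120))
        stages = r.choice(["WAKE", "NREM", "REM"], size=n)
        rms = r.lognormal(-1, 0.7, n)
        grid = make_grid(stages, emg_rms=rms)
        out, events = detect_rbd_events(grid)
        oflags, oevents = oracle_rbd(stages, rms)
        assert np.array_equal(out.rbd, oflags)
        assert [(e.start_epoch, e.end_epoch) for e in events] == \
            [(e[0], e[-1]) for e in oevents]


class TestSummary:
    def test_hand_enumerated_sequence(self):
        grid = make_grid(list("WWNNRRW"))
        grid.frame["stage"] = ["WAKE", "WAKE", "NREM", "NREM", "REM", "REM", "WAKE"]
        s = summarize_sleep(grid)
        assert s.event_counts["REM"] == 1
        assert s.mean_event_duration_s["REM"] == 40.0
        assert s.longest_event_duration_s["NREM"] == 40.0
        assert s.pct_time["REM"] == pytest.approx(100.0 * 2 / 7)
        assert rem_run_count(grid) == 1

    def test_single_stage_grid(self):
        grid = make_grid(["WAKE"] * 5)
        s = summarize_sleep(grid)
        assert s.pct_time["WAKE"] == 100.0
        assert s.event_counts["REM"] == 0
        assert np.isnan(s.mean_event_duration_s["REM"])

    def test_percentages_sum_to_100(self, rng):
        stages = rng.choice(["WAKE", "NREM", "REM"], size=200)
        s = summarize_sleep(make_grid(stages))
        assert sum(s.pct_time.values()) == pytest.approx(100.0, abs=1e-9)

    def test_rbd_normalized_to_rem_runs(self):
        stages = ["REM"] * 3 + ["WAKE"] * 2 + ["REM"] * 3 + ["WAKE"] * 2
        rms = np.array([1, 1, 1, 5, 5, 1, 1, 3.0, 5, 5])
        grid = make_grid(stages, emg_rms=rms)
        out, events = detect_rbd_events(grid)
        s = summarize_sleep(out, events)
        # one flagged epoch (index 7) over two REM runs
        assert s.n_rbd_events == 1
        assert s.rbd_per_rem_pct == pytest.approx(50.0)
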