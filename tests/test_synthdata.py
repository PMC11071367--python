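"""Generators: determinism, label consistency, and construction guarantees."""

import numpy as np
import pytest

from phenomap.photometry import preprocess_trace
from phenomap.sleepsig import build_signal_grid, score_stages
from phenomap.synthdata import (
    DiskSpec,
    StageTruth,
    SynthGroupSeriesConfig,
    SynthImageConfig,
    SynthPhotometryConfig,
    SynthSleepConfig,
    generate_group_sections,
    generate_photometry,
    generate_polysomnogram,
    generate_section_image,
    generate_stage_sequence,
)

SHORT = dict(duration_s=1200.0)  # 60 epochs keeps unit tests quick


class TestPolysomnogram:
    def test_same_seed_bitwise_identical(self):
        a, _ = generate_polysomnogram(SynthSleepConfig(**SHORT, seed=7))
        b, _ = generate_polysomnogram(SynthSleepConfig(**SHORT, seed=7))
        assert np.array_equal(a.eeg, b.eeg)
        assert np.array_equal(a.emg, b.emg)

    def test_different_seed_differs(self):
        a, _ = generate_polysomnogram(SynthSleepConfig(**SHORT, seed=1))
        b, _ = generate_polysomnogram(SynthSleepConfig(**SHORT, seed=2))
        assert not np.array_equal(a.eeg, b.eeg)

    def test_rem_atonia_below_wake_tone_without_bursts(self):
        cfg = SynthSleepConfig(duration_s=7200.0, rbd_fraction=0.0, seed=3)
        rec, truth = generate_polysomnogram(cfg)
        assert not truth.rbd.any()
        grid = build_signal_grid(rec)
        rem = truth.stages == "REM"
        wake = truth.stages == "WAKE"
        assert rem.any() and wake.any()
        assert grid.emg_rms[rem].max() < grid.emg_rms[wake].min()

    def test_nrem_delta_exceeds_rem_delta_by_spectral_module(self):
        rec, truth = generate_polysomnogram(SynthSleepConfig(duration_s=7200.0, seed=1))
        grid = build_signal_grid(rec)
        delta = grid.frame["delta"].to_numpy()
        assert (np.median(delta[truth.stages == "NREM"])
                > np.median(delta[truth.stages == "REM"]))

    def test_explicit_runs_reproduced_exactly(self, rng):
        arch = [("WAKE", 5), ("NREM", 10), ("REM", 3), ("WAKE", 2)]
        stages = generate_stage_sequence(20, arch, rng)
        assert list(stages) == ["WAKE"] * 5 + ["NREM"] * 10 + ["REM"] * 3 + ["WAKE"] * 2

    def test_run_total_must_match_duration(self, rng):
        with pytest.raises(ValueError):
            generate_stage_sequence(10, [("WAKE", 5)], rng)

    def test_rbd_flags_only_on_rem(self):
        _, truth = generate_polysomnogram(
            SynthSleepConfig(duration_s=7200.0, rbd_fraction=0.5, seed=4))
        assert not (truth.rbd & (truth.stages != "REM")).any()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            generate_polysomnogram(SynthSleepConfig(duration_s=1010.0))  # not divisible
        with pytest.raises(ValueError):
            generate_polysomnogram(SynthSleepConfig(**SHORT, rbd_fraction=1.5))
        cfg = SynthSleepConfig(**SHORT)
        cfg.emg_tone["REM"] = -0.1
        with pytest.raises(ValueError):
            generate_polysomnogram(cfg)

    def test_staging_accuracy_degrades_with_band_contrast(self):
        """Shrinking the oscillator contrast towards flat monotonically hurts
        the scorer."""
        accs = []
        for shrink in (1.0, 0.35, 0.0):
            cfg = SynthSleepConfig(duration_s=7200.0, seed=11)
            for stage, amps in cfg.band_amplitudes.items():
                for comp in ("delta", "theta"):
                    amps[comp] = 1.0 + shrink * (amps[comp] - 1.0)
            rec, truth = generate_polysomnogram(cfg)
            grid = score_stages(build_signal_grid(rec))
            accs.append(float(np.mean(grid.stage == truth.stages)))
        assert accs[0] > 0.95
        assert accs[0] >= accs[1] >= accs[2]


class TestPhotometryGenerator:
    def test_same_seed_identical(self):
        truth = StageTruth(np.array(["WAKE"] * 4 + ["REM"] * 4),
                           np.zeros(8, bool))
        a = generate_photometry(SynthPhotometryConfig(seed=5), truth)
        b = generate_photometry(SynthPhotometryConfig(seed=5), truth)
        for ch in a.channels:
            assert np.array_equal(a.channels[ch], b.channels[ch])

    def test_rbd_offset_recovered_from_raw_means(self, rng):
        stages = np.array((["REM"] * 5 + ["NREM"] * 5) * 8)
        rbd = np.zeros(80, bool)
        rem_idx = np.flatnonzero(stages == "REM")
        rbd[rem_idx[::2]] = True  # 20 RBD + 20 clean REM epochs... >=30 total
        truth = StageTruth(stages, rbd)
        ses = generate_photometry(SynthPhotometryConfig(seed=6), truth)
        spe = int(20 * 500)
        per_epoch = ses.channels["da"].reshape(80, spe).mean(axis=1)
        diff = per_epoch[rbd].mean() - per_epoch[(stages == "REM") & ~rbd].mean()
        assert diff == pytest.approx(1.0, abs=0.2)

    def test_isosbestic_is_state_null(self):
        stages = np.array((["WAKE"] * 10 + ["NREM"] * 10 + ["REM"] * 10) * 4)
        truth = StageTruth(stages, np.zeros(120, bool))
        cfg = SynthPhotometryConfig(seed=7)
        ses = generate_photometry(cfg, truth)
        per_epoch = ses.channels["iso"].reshape(120, 10000).mean(axis=1)
        tol = 3.0 * cfg.noise_sd / np.sqrt(10000)
        means = [per_epoch[stages == s].mean() for s in ("WAKE", "NREM", "REM")]
        for a in means:
            for b in means:
                assert abs(a - b) < 3 * tol

    def test_unknown_stage_rejected(self):
        truth = StageTruth(np.array(["WAKE"] * 5), np.zeros(5, bool))
        cfg = SynthPhotometryConfig(offsets={"da": {"NREM": 0.0}})
        with pytest.raises(ValueError):
            generate_photometry(cfg, truth)


class TestSectionImageGenerator:
    def test_zero_clusters_blank_truth(self):
        img, truth = generate_section_image(SynthImageConfig(seed=1))
        assert truth == []
        assert img.data.max() < 200.0

    def test_requested_area_realized_within_2px(self):
        cfg = SynthImageConfig(clusters=[DiskSpec(100.0, (128.0, 128.0))], seed=2)
        _, truth = generate_section_image(cfg)
        assert abs(truth[0]["area_px"] - 100) <= 2

    def test_same_seed_identical_image(self):
        cfg = SynthImageConfig(clusters=[DiskSpec(50, (60, 60))], seed=9)
        a, _ = generate_section_image(cfg)
        b, _ = generate_section_image(cfg)
        assert np.array_equal(a.data, b.data)

    def test_out_of_bounds_cluster_rejected(self):
        cfg = SynthImageConfig(clusters=[DiskSpec(50, (300.0, 10.0))])
        with pytest.raises(ValueError):
            generate_section_image(cfg)

    def test_polygon_tissue_limits_background(self):
        poly = np.array([[20, 20], [20, 200], [200, 200], [200, 20]])
        cfg = SynthImageConfig(tissue_polygon=poly, seed=3)
        img, _ = generate_section_image(cfg)
        assert img.data[0, 0] == cfg.slide_intensity
        assert img.data[100, 100] > 20.0


class TestGroupSections:
    def test_null_effect_gives_empty_truth(self):
        cfg = SynthGroupSeriesConfig(effect_d=0.0, seed=1)
        _, effect, _ = generate_group_sections(cfg)
        assert not effect.any()

    def test_image_count_bookkeeping(self):
        cfg = SynthGroupSeriesConfig(
            group_sizes={"a": 8, "b": 8, "c": 8}, seed=2)
        images, _, manifest = generate_group_sections(cfg)
        assert sum(len(v) for v in images.values()) == 24
        assert len(manifest) == 24

    def test_effect_block_must_fit_grid(self):
        cfg = SynthGroupSeriesConfig(effect_blocks=[(0, 30, 0, 5)])
        with pytest.raises(ValueError):
            generate_group_sections(cfg)

    def test_effect_elevates_configured_rois_only(self):
        cfg = SynthGroupSeriesConfig(effect_d=3.0, within_sd=1.0, seed=3)
        images, effect, _ = generate_group_sections(cfg)
        control = np.mean([im.data for im in images["control"]], axis=0)
        treated = np.mean([im.data for im in images["early"]], axis=0)
        diff = (treated - control)
        roi_diff = diff.reshape(20, 5, 20, 5).mean(axis=(1, 3))
        assert roi_diff[effect].mean() > 2.0
        assert abs(roi_diff[~effect].mean()) < 0.5
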