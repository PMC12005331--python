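"""Generator-side tests: schedules, stimulus computations, EEG/gaze structure."""

import numpy as np
import pandas as pd
import pytest

from riftpipe.config import ConfigurationError, SimulationConfig
from riftpipe import rift, synthgen
from riftpipe.timing import timing_for


class TestTrialSchedule:
    def test_default_design_480_trials_15_blocks(self):
        cfg = SimulationConfig.for_experiment("pre-cue")
        meta = synthgen.build_trial_schedule(cfg, 0)
        assert len(meta) == 480
        assert meta["block"].nunique() == 15
        assert (meta.groupby("block").size() == 32).all()

    def test_counterbalancing_exact(self):
        cfg = SimulationConfig.for_experiment("pre-cue")
        meta = synthgen.build_trial_schedule(cfg, 0)
        assert meta["cue_side"].value_counts().to_dict() == {"left": 240, "right": 240}
        assert meta["freq_config"].value_counts().to_dict() == {"60L/64R": 240, "64L/60R": 240}

    def test_smallest_balanced_design(self):
        cfg = SimulationConfig.for_experiment("pre-cue", n_trials=4, block_size=4)
        meta = synthgen.build_trial_schedule(cfg, 0)
        cells = meta.groupby(["cue_side", "freq_config"]).size()
        assert len(cells) == 4 and (cells == 1).all()

    def test_cued_frequency_follows_assignment(self):
        cfg = SimulationConfig.for_experiment("pre-cue", n_trials=16, block_size=8)
        meta = synthgen.build_trial_schedule(cfg, 0)
        for row in meta.itertuples():
            expect = {
                ("left", "60L/64R"): 60.0, ("right", "60L/64R"): 64.0,
                ("left", "64L/60R"): 64.0, ("right", "64L/60R"): 60.0,
            }[(row.cue_side, row.freq_config)]
            assert row.cued_freq == expect
            assert row.cued_freq != row.uncued_freq

    def test_indivisible_trial_count_rejected(self):
        cfg = SimulationConfig.for_experiment("pre-cue", n_trials=30, block_size=30)
        with pytest.raises(ConfigurationError):
            synthgen.build_trial_schedule(cfg, 0)


class TestTransparencyMask:
    def test_center_is_half(self):
        assert synthgen.transparency_mask(0.0, 3.0) == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "x_frac,expected",
        [(1.0, 1.0 / (1.0 + np.exp(-6.0))), (0.5, 1.0 / (1.0 + np.exp(-3.0)))],
    )
    def test_interior_values(self, x_frac, expected):
        r = 3.0
        assert synthgen.transparency_mask(x_frac * r, r) == pytest.approx(expected, abs=1e-12)

    def test_monotone_and_bounded(self):
        x = np.linspace(0, 2.0, 64)
        t = synthgen.transparency_mask(x, 2.0)
        assert np.all(np.diff(t) > 0)
        assert t.min() >= 0.5 and t.max() <= 1.0

    def test_bad_radius_rejected(self):
        with pytest.raises(ValueError):
            synthgen.transparency_mask(0.5, -1.0)


class TestTaggingWaveform:
    def test_phase_zero_and_rising_at_origin(self):
        w = synthgen.tagging_waveform(60.0, 0.1, 2048.0)
        assert w[0] == pytest.approx(0.0)
        assert w[1] > 0

    def test_eight_samples_per_cycle_at_projector_rate(self):
        w = synthgen.tagging_waveform(60.0, 1.0, 480.0)
        assert w[::8] == pytest.approx(np.zeros(60), abs=1e-9)

    def test_cycle_count(self):
        w = synthgen.tagging_waveform(64.0, 1.0, 2048.0)
        upward = np.sum((w[:-1] <= 0) & (w[1:] > 0))
        assert upward == 64

    def test_nyquist_guard(self):
        with pytest.raises(ValueError):
            synthgen.tagging_waveform(300.0, 1.0, 480.0)


class TestFrameTiming:
    def test_nominal_grid_not_flagged(self):
        ft = [np.arange(100) / 480.0]
        assert synthgen.flag_offtime_trials(ft).tolist() == [False]

    @pytest.mark.parametrize("delay_ms,expected", [(5.0, True), (3.9, False)])
    def test_tolerance_boundary(self, delay_ms, expected):
        ft = np.arange(100) / 480.0
        ft[50] += delay_ms / 1000.0
        assert synthgen.flag_offtime_trials([ft])[0] == expected

    def test_empty_trial_flagged_invalid(self):
        assert synthgen.flag_offtime_trials([np.array([])])[0]


class TestEEGGenerator:
    def test_seed_determinism_bitwise(self, posterior_channels):
        cfg = SimulationConfig.for_experiment("pre-cue", n_trials=4, block_size=4, seed=42)
        a = synthgen.simulate_participant(cfg, 0, channels=posterior_channels)
        b = synthgen.simulate_participant(cfg, 0, channels=posterior_channels)
        assert np.array_equal(a.epochs.data, b.epochs.data)
        assert np.array_equal(a.gaze.x, b.gaze.x, equal_nan=True)
        assert a.meta.equals(b.meta)

    def test_null_generator_symmetric_tag_amplitudes(self, noiseless_config):
        """attention_gain=1 with symmetric amplitudes: cued and uncued envelopes equal."""
        part = synthgen.simulate_participant(noiseless_config, 0)
        es = part.epochs
        sl = es.time_slice(0.5, 1.5)
        mags = {}
        for f in noiseless_config.tag_freqs:
            an = rift.bandpass_hilbert(es, f)
            cued = (es.meta["cued_freq"] == f).to_numpy()
            mags[f] = (
                an.magnitude[cued][:, :, sl].mean(),
                an.magnitude[~cued][:, :, sl].mean(),
            )
        for f, (c, u) in mags.items():
            assert c == pytest.approx(u, rel=0.02)

    def test_attention_gain_scales_cued_magnitude(self, noiseless_config):
        import dataclasses

        gained = dataclasses.replace(noiseless_config, attention_gain=1.5)
        base = synthgen.simulate_participant(noiseless_config, 0)
        mod = synthgen.simulate_participant(gained, 0)
        sl = base.epochs.time_slice(0.5, 1.5)
        for f in noiseless_config.tag_freqs:
            cued = (base.meta["cued_freq"] == f).to_numpy()
            m0 = rift.bandpass_hilbert(base.epochs, f).magnitude[cued][:, :, sl]
            m1 = rift.bandpass_hilbert(mod.epochs, f).magnitude[cued][:, :, sl]
            # compare where the tag actually projects
            strong = m0.mean(axis=(0, 2)) > 0.2 * m0.mean(axis=(0, 2)).max()
            ratio = m1.mean(axis=(0, 2))[strong] / m0.mean(axis=(0, 2))[strong]
            assert ratio == pytest.approx(np.full(ratio.shape, 1.5), rel=0.02)

    def test_noiseless_spectrum_only_tag_and_alpha(self, noiseless_config):
        import dataclasses

        cfg = dataclasses.replace(noiseless_config, alpha_amplitude=4.0)
        part = synthgen.simulate_participant(cfg, 0)
        es = part.epochs
        sl = es.time_slice(0.3, 2.2)
        seg = es.data[0, :, sl.start : sl.stop].mean(axis=0)
        freqs = np.fft.rfftfreq(seg.size, 1.0 / es.fs)
        power = np.abs(np.fft.rfft(seg - seg.mean())) ** 2
        top = freqs[np.argsort(power)[-6:]]
        for f in top:
            # alpha leaks over neighbouring bins (finite window, per-trial
            # frequency jitter); tags are exact
            assert min(abs(f - 60.0), abs(f - 64.0), abs(f - cfg.alpha_freq)) < 2.0

    def test_negative_attention_gain_rejected(self, noiseless_config):
        import dataclasses

        bad = dataclasses.replace(noiseless_config, attention_gain=-0.5)
        meta = synthgen.build_trial_schedule(noiseless_config, 0)
        with pytest.raises(ConfigurationError):
            synthgen.simulate_eeg_trial(
                next(meta.itertuples(index=False)), bad, np.random.default_rng(0)
            )


class TestGazeGenerator:
    def test_flat_without_drift_or_noise(self, noiseless_config):
        part = synthgen.simulate_participant(noiseless_config, 0)
        # traces are constant per trial (baseline offset only)
        sd = np.nanstd(part.gaze.x, axis=2)
        assert np.all(sd < 1e-9)

    def test_drift_toward_cue(self):
        cfg = SimulationConfig.for_experiment(
            "pre-cue", n_trials=16, block_size=8, gaze_drift_dva=0.08,
            gaze_noise_dva=0.0, blink_rate=0.0, fixation_break_prob=0.0, seed=5,
        )
        part = synthgen.simulate_participant(cfg, 0)
        t = part.gaze.times
        pre = t < 0
        post = t > 0.5
        for i, row in enumerate(part.meta.itertuples()):
            mono = np.nanmean(part.gaze.x[i], axis=0)
            delta = mono[post].mean() - mono[pre].mean()
            assert (delta > 0.03) == (row.cue_side == "right")

    def test_blinks_marked_missing(self):
        cfg = SimulationConfig.for_experiment(
            "pre-cue", n_trials=8, block_size=8, blink_rate=2.0, seed=9
        )
        part = synthgen.simulate_participant(cfg, 0)
        assert np.isnan(part.gaze.x).any()

    def test_forced_fixation_breaks_are_flagged(self):
        from riftpipe import gaze as gaze_mod

        cfg = SimulationConfig.for_experiment(
            "pre-cue", n_trials=8, block_size=8, fixation_break_prob=1.0,
            blink_rate=0.0, seed=11,
        )
        part = synthgen.simulate_participant(cfg, 0)
        cleaned = gaze_mod.clean_gaze(part.gaze)
        flags = gaze_mod.exclude_gaze_trials(cleaned)
        assert flags["off_fixation"].all()
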