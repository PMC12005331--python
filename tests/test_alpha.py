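"""Alpha power: wavelet transform, dB baselining, lateralization contrasts."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from riftpipe import alpha as alpha_mod
from riftpipe import synthgen
from tests.conftest import make_epochs


class TestMorletTFR:
    fs = 512.0

    def test_ridge_at_stimulus_frequency(self):
        t = np.arange(int(4 * self.fs)) / self.fs
        sig = np.sin(2 * np.pi * 10.0 * t)
        es = make_epochs(sig[None, None, :], self.fs, ["POz"], t0=-2.0)
        tfr = alpha_mod.morlet_tfr(es, decim=8)
        ridge = tfr.power[0, 0, :, tfr.valid].mean(axis=0)
        # 3-cycle wavelets are spectrally broad and their L2 normalisation
        # tilts on-signal power slightly toward lower rows: allow a few bins
        assert tfr.freqs[int(np.argmax(ridge))] == pytest.approx(10.0, abs=0.8)

    def test_zero_signal_zero_power(self):
        es = make_epochs(np.zeros((2, 1, int(4 * self.fs))), self.fs, ["a"], t0=-2.0)
        tfr = alpha_mod.morlet_tfr(es, decim=8)
        assert np.all(tfr.power == 0.0)

    def test_default_grid_28_rows(self):
        assert len(alpha_mod.ALPHA_FREQS) == 28
        assert alpha_mod.ALPHA_FREQS[0] == 8.0 and alpha_mod.ALPHA_FREQS[-1] == 13.4

    def test_power_scales_with_amplitude_squared(self):
        t = np.arange(int(4 * self.fs)) / self.fs
        sig = np.sin(2 * np.pi * 10.0 * t)
        es = make_epochs(np.stack([sig, 3 * sig])[:, None, :], self.fs, ["a"], t0=-2.0)
        tfr = alpha_mod.morlet_tfr(es, decim=8)
        p = tfr.power[:, 0, :, tfr.valid].mean(axis=(0, 2))
        assert p[1] / p[0] == pytest.approx(9.0, rel=0.01)

    def test_short_epoch_rejected(self):
        es = make_epochs(np.zeros((1, 1, 64)), self.fs, ["a"])
        with pytest.raises(ValueError):
            alpha_mod.morlet_tfr(es)


class TestDbBaseline:
    def _tfr(self, power):
        n_tr, n_ch, n_f, n_t = power.shape
        return alpha_mod.TimeFrequencyPower(
            power=power,
            freqs=np.linspace(8, 13.4, n_f),
            times=np.linspace(-1.0, 1.0, n_t),
            fs=n_t / 2.0,
            channels=[f"c{i}" for i in range(n_ch)],
            meta=pd.DataFrame({"trial_id": np.arange(n_tr)}),
            valid=np.ones(n_t, dtype=bool),
        )

    def test_equal_power_is_zero_db(self):
        tfr = self._tfr(np.full((1, 1, 2, 10), 4.0))
        out = alpha_mod.db_baseline(tfr, (-1.0, 0.0))
        assert out.power == pytest.approx(np.zeros_like(out.power))

    @pytest.mark.parametrize("factor,expected", [(2.0, 10 * np.log10(2)), (0.1, -10.0)])
    def test_known_ratios(self, factor, expected):
        power = np.ones((1, 1, 1, 10))
        power[..., 5:] = factor
        tfr = self._tfr(power)
        out = alpha_mod.db_baseline(tfr, (-1.0, 0.0))
        assert out.power[0, 0, 0, -1] == pytest.approx(expected, abs=1e-9)

    def test_zero_baseline_rejected(self):
        tfr = self._tfr(np.zeros((1, 1, 1, 10)))
        with pytest.raises(ValueError):
            alpha_mod.db_baseline(tfr, (-1.0, 0.0))


@pytest.fixture(scope="module")
def lateralized_tfr():
    """dB TFR of a generator with strong contralateral alpha attenuation."""
    from riftpipe.config import SimulationConfig
    from riftpipe.timing import timing_for

    cfg = SimulationConfig.for_experiment(
        "pre-cue",
        n_trials=48,
        block_size=8,
        alpha_lateralization=0.4,
        alpha_amplitude=8.0,
        noise_scale=4.0,
        artifact_prob=0.0,
        seed=21,
    )
    chans = ["PO7", "PO3", "O1", "POz", "Oz", "PO8", "PO4", "O2"]
    part = synthgen.simulate_participant(cfg, 0, channels=chans)
    tfr = alpha_mod.morlet_tfr(part.epochs, decim=32)
    return alpha_mod.db_baseline(tfr, timing_for("pre-cue").alpha_baseline_window)


class TestLateralization:
    def test_sign_follows_generator_geometry(self, lateralized_tfr, layout):
        lat = alpha_mod.participant_lateralization(lateralized_tfr, interval=(0.4, 1.2))
        for ch, v in zip(lateralized_tfr.channels, lat):
            hemi = layout.hemisphere(ch)
            # right-cued minus left-cued: negative contralateral to the right
            # cue (left hemisphere), positive on the right hemisphere
            if hemi == "left":
                assert v < 0
            elif hemi == "right":
                assert v > 0

    def test_label_swap_flips_sign(self, lateralized_tfr):
        lat = alpha_mod.participant_lateralization(lateralized_tfr, interval=(0.4, 1.2))
        swapped = dataclasses.replace(lateralized_tfr, meta=lateralized_tfr.meta.copy())
        swapped.meta["cue_side"] = swapped.meta["cue_side"].map({"left": "right", "right": "left"})
        lat2 = alpha_mod.participant_lateralization(swapped, interval=(0.4, 1.2))
        assert lat2 == pytest.approx(-lat)

    def test_single_condition_rejected(self, lateralized_tfr):
        only_left = dataclasses.replace(lateralized_tfr, meta=lateralized_tfr.meta.copy())
        only_left.meta["cue_side"] = "left"
        with pytest.raises(ValueError):
            alpha_mod.participant_lateralization(only_left, interval=(0.4, 1.2))


class TestLateralizationMap:
    def test_null_values_rarely_flagged(self):
        rng = np.random.default_rng(0)
        values = rng.standard_normal((24, 30))
        lm = alpha_mod.lateralization_map(values, [f"c{i}" for i in range(30)], n_boot=2000, seed=1)
        assert lm.significant.mean() < 0.15  # ~5 % nominal false-flag rate

    def test_strong_effect_flagged_with_correct_sign(self):
        rng = np.random.default_rng(1)
        values = rng.standard_normal((20, 4)) * 0.1 - np.array([2.0, 2.0, -2.0, -2.0])
        lm = alpha_mod.lateralization_map(values, list("abcd"), n_boot=2000, seed=2)
        assert lm.significant.all()
        assert lm.mean[0] < 0 < lm.mean[2]


class TestTrialwise:
    def _db_tfr(self, values_by_channel, sides):
        """Constant dB power per channel; one row per trial."""
        channels = list(values_by_channel)
        n_tr = len(sides)
        power = np.zeros((n_tr, len(channels), 2, 8))
        for i, ch in enumerate(channels):
            power[:, i, :, :] = values_by_channel[ch]
        return alpha_mod.TimeFrequencyPower(
            power=power,
            freqs=np.array([10.0, 10.2]),
            times=np.linspace(0.0, 1.0, 8),
            fs=8.0,
            channels=channels,
            meta=pd.DataFrame(
                {"trial_id": np.arange(n_tr), "cue_side": sides, "experiment": "pre-cue"}
            ),
            valid=np.ones(8, dtype=bool),
            is_db=True,
        )

    def test_symmetric_power_gives_zero(self):
        tfr = self._db_tfr({"PO7": 1.5, "PO8": 1.5}, ["left", "right"])
        vals = alpha_mod.trialwise_lateralization(tfr, ["PO7", "PO8"], interval=(0.0, 1.0))
        assert vals == pytest.approx([0.0, 0.0])

    def test_contra_two_db_below_ipsi(self):
        # cue right: contra = left hemisphere (PO7); set it 2 dB below PO8
        tfr = self._db_tfr({"PO7": -1.0, "PO8": 1.0}, ["right"])
        vals = alpha_mod.trialwise_lateralization(tfr, ["PO7", "PO8"], interval=(0.0, 1.0))
        assert vals == pytest.approx([-2.0])

    def test_flipping_cue_side_flips_sign(self):
        tfr = self._db_tfr({"PO7": -1.0, "PO8": 1.0}, ["right", "left"])
        vals = alpha_mod.trialwise_lateralization(tfr, ["PO7", "PO8"], interval=(0.0, 1.0))
        assert vals[0] == pytest.approx(-vals[1])

    def test_midline_channels_ignored(self):
        tfr = self._db_tfr({"PO7": -1.0, "PO8": 1.0, "POz": 50.0}, ["right"])
        vals = alpha_mod.trialwise_lateralization(tfr, ["PO7", "PO8", "POz"], interval=(0.0, 1.0))
        assert vals == pytest.approx([-2.0])

    def test_single_hemisphere_set_rejected(self):
        tfr = self._db_tfr({"PO7": -1.0, "PO8": 1.0}, ["right"])
        with pytest.raises(ValueError, match="widen"):
            alpha_mod.trialwise_lateralization(tfr, ["PO7"], interval=(0.0, 1.0))
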