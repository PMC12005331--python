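"""Configuration dataclasses for the simulator and the preprocessing stage.

All tunable constants of the pipeline live here (or in
:mod:`riftpipe.timing` for the per-experiment event timelines) so that a run
is fully described by a YAML file plus one root seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import yaml

EXPERIMENTS = ("retro-cue", "pre-cue", "spatial-cue")


class ConfigurationError(ValueError):
    """Raised when a configuration violates a structural requirement."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic EEG / gaze / behaviour generator.

    Amplitudes are in microvolt, frequencies in Hz, gaze quantities in degrees
    of visual angle (dva).  ``attention_gain`` multiplies the amplitude of the
    tag at the cued location after the cue has been processed; 1.0 is the null
    (no attentional modulation).  ``alpha_lateralization`` multiplies alpha
    amplitude in the hemisphere contralateral to the cued side after the cue;
    1.0 is the null, values < 1 produce the classic contralateral
    desynchronization.
    """

    experiment: str = "pre-cue"
    n_participants: int = 24
    n_trials: int = 480
    n_practice: int = 10
    block_size: int = 32
    n_channels: int = 64
    fs_eeg: float = 2048.0
    fs_gaze: float = 500.0
    tag_freqs: tuple[float, float] = (60.0, 64.0)
    tag_amplitude: float = 0.8
    #: relative amplitude of the higher tag frequency (higher flicker rates
    #: evoke weaker steady-state responses)
    tag_high_rel_amplitude: float = 0.85
    attention_gain: float = 1.25
    #: half-range (ms) of the uniform trial-onset misalignment applied to the
    #: tag phase only, emulating display aliasing with a variable cue onset
    onset_jitter_ms: float = 0.0
    alpha_freq: float = 10.0
    alpha_amplitude: float = 6.0
    alpha_lateralization: float = 0.7
    noise_exponent: float = 1.0
    noise_scale: float = 10.0
    line_noise_amplitude: float = 1.0
    gaze_drift_dva: float = 0.06
    gaze_noise_dva: float = 0.12
    blink_rate: float = 0.08
    fixation_break_prob: float = 0.02
    offtime_prob: float = 0.002
    #: per-trial probability of a large (300 uV) transient on one channel,
    #: exercising the amplitude-based artifact rejection
    artifact_prob: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ConfigurationError(
                f"experiment must be one of {EXPERIMENTS}, got {self.experiment!r}"
            )
        lo, hi = self.tag_freqs
        if not lo < hi:
            raise ConfigurationError("tag_freqs must be (low, high) with low < high")
        if hi >= self.fs_eeg / 2:
            raise ConfigurationError("tag frequencies must be below fs_eeg / 2")
        if self.n_trials % 4 != 0:
            raise ConfigurationError(
                "n_trials must be divisible by 4 (2 cue sides x 2 frequency configurations)"
            )
        if self.attention_gain < 0:
            raise ConfigurationError("attention_gain must be >= 0")
        if self.n_trials % self.block_size != 0:
            raise ConfigurationError("n_trials must be divisible by block_size")

    @classmethod
    def for_experiment(cls, experiment: str, **overrides) -> "SimulationConfig":
        """Default parameter set for one of the three experiments.

        The retro-cue experiment uses no attentional tag modulation (the
        empirical finding for internal selection) and carries the +/-2 ms
        onset jitter caused by its variable stimulus-to-cue delay; the pre-cue
        and spatial-cue experiments carry an attentional gain > 1.
        """
        presets = {
            "retro-cue": dict(attention_gain=1.0, onset_jitter_ms=2.0),
            "pre-cue": dict(attention_gain=1.25, onset_jitter_ms=0.0),
            "spatial-cue": dict(attention_gain=1.25, onset_jitter_ms=0.0),
        }
        if experiment not in presets:
            raise ConfigurationError(
                f"experiment must be one of {EXPERIMENTS}, got {experiment!r}"
            )
        kwargs = dict(experiment=experiment)
        kwargs.update(presets[experiment])
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class PreprocessConfig:
    """Parameters of the deterministic EEG preprocessing stage."""

    bad_channels: tuple[str, ...] = ()
    highpass_hz: float = 0.01
    notch_hz: tuple[float, ...] = (50.0, 100.0, 150.0)
    #: peak-to-peak rejection threshold; deterministic stand-in for
    #: inspection-based artifact labelling
    artifact_amp_threshold_uv: float = 150.0
    #: participants with a flagged-trial fraction strictly above this are
    #: excluded from all further analysis
    participant_artifact_max: float = 0.5


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    return obj


def config_to_dict(cfg) -> dict:
    return _to_plain(cfg)


def _coerce(cls, data: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigurationError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        f = fields[name]
        if isinstance(value, list):
            value = tuple(value)
        kwargs[name] = value
    return cls(**kwargs)


def simulation_config_from_dict(data: dict) -> SimulationConfig:
    return _coerce(SimulationConfig, data)


def preprocess_config_from_dict(data: dict) -> PreprocessConfig:
    return _coerce(PreprocessConfig, data)


def load_yaml_config(path) -> dict:
    """Load a pipeline YAML config with ``simulation``/``preprocess`` sections.

    Returns a dict with dataclass instances under the section names; missing
    sections get defaults, unknown keys raise :class:`ConfigurationError`
    naming the key.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = {
        "simulation": simulation_config_from_dict(raw.get("simulation", {})),
        "preprocess": preprocess_config_from_dict(raw.get("preprocess", {})),
    }
    extra = set(raw) - {"simulation", "preprocess"}
    if extra:
        raise ConfigurationError(f"unknown config sections: {sorted(extra)}")
    return out


def save_yaml_config(path, simulation: SimulationConfig, preprocess: PreprocessConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"simulation": config_to_dict(simulation), "preprocess": config_to_dict(preprocess)},
            fh,
            sort_keys=True,
        )
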