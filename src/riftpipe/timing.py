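"""Per-experiment event timelines and analysis windows.

Epochs are aligned to the *alignment event* of each experiment: retro-cue
onset (retro-cue experiment), memory-stimuli onset (pre-cue experiment) or
spatial-cue onset (spatial-cue experiment); time 0 of every epoch is that
event.  All other windows below are expressed in seconds relative to it.

The original task has small uniform jitters in some delays; the simulator
fixes each delay at a single representative value so that every window is
identical across trials (the +/-2 ms retro-cue aliasing is modelled
separately, as a phase jitter of the tag).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ExperimentTiming:
    name: str
    #: EEG epoch window around the alignment event (s)
    epoch_window: tuple[float, float]
    #: EEG baseline-correction window (s)
    baseline_window: tuple[float, float]
    #: alpha-power dB baseline window (s)
    alpha_baseline_window: tuple[float, float]
    #: gaze epoch window (s)
    gaze_window: tuple[float, float]
    #: interval during which the tag flicker is on screen (s)
    tag_interval: tuple[float, float]
    #: onset of the attentional modulation ramp (cue processed), s
    attention_onset: float
    #: interval used to rank channels by tag coherence, clear of filter edges
    selection_interval: tuple[float, float]
    #: interval over which cued/uncued contrasts and trial-wise magnitudes
    #: are averaged by default
    analysis_interval: tuple[float, float]
    #: window used for band/time-averaged alpha lateralization maps
    alpha_interval: tuple[float, float]


#: Memory-stimuli onset in the retro-cue experiment: 1 s stimulus display
#: plus a 1.5 s maintenance delay before the cue.
_RETRO_STIM_ONSET = -2.5
#: Cue onset in the pre-cue experiment: 0.15 s cue plus 1 s delay before the
#: memory stimuli.
_PRE_CUE_ONSET = -1.15

TIMINGS: dict[str, ExperimentTiming] = {
    "retro-cue": ExperimentTiming(
        name="retro-cue",
        epoch_window=(-3.4, 2.0),
        baseline_window=(_RETRO_STIM_ONSET - 0.8, _RETRO_STIM_ONSET - 0.3),
        alpha_baseline_window=(_RETRO_STIM_ONSET - 0.6, _RETRO_STIM_ONSET - 0.3),
        gaze_window=(-1.5, 1.5),
        tag_interval=(_RETRO_STIM_ONSET, 2.0),
        attention_onset=0.2,
        selection_interval=(-1.8, 1.2),
        analysis_interval=(0.3, 1.4),
        alpha_interval=(0.4, 1.2),
    ),
    "pre-cue": ExperimentTiming(
        name="pre-cue",
        epoch_window=(-2.0, 2.5),
        baseline_window=(_PRE_CUE_ONSET - 0.8, _PRE_CUE_ONSET - 0.1),
        alpha_baseline_window=(_PRE_CUE_ONSET - 0.6, _PRE_CUE_ONSET - 0.3),
        gaze_window=(-1.5, 1.5),
        tag_interval=(0.0, 2.5),
        # the cue precedes the stimuli, so the attentional gain is in place
        # as soon as the flicker starts
        attention_onset=0.0,
        selection_interval=(0.3, 1.7),
        analysis_interval=(0.28, 1.14),
        alpha_interval=(0.4, 1.2),
    ),
    "spatial-cue": ExperimentTiming(
        name="spatial-cue",
        epoch_window=(-1.5, 2.05),
        baseline_window=(-1.0, -0.5),
        alpha_baseline_window=(-0.6, -0.3),
        gaze_window=(-1.5, 1.5),
        tag_interval=(-0.35, 2.05),
        attention_onset=0.2,
        selection_interval=(0.0, 1.6),
        analysis_interval=(0.47, 1.5),
        alpha_interval=(0.4, 0.7),
    ),
}


def timing_for(experiment: str) -> ExperimentTiming:
    try:
        return TIMINGS[experiment]
    except KeyError:
        raise KeyError(f"unknown experiment {experiment!r}; known: {sorted(TIMINGS)}")
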