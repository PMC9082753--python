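"""Trial timeline of the incomplete-asynchronous acquisition paradigm.

A single trial lasts 15 s.  Motor-imagery (MI) EEG is recorded alone during
the MI window (5.5-7.5 s); EEG and sEMG are recorded simultaneously only in
the short pre-movement window (7.5-8.5 s), which limits movement artifacts in
the EEG.  The movement itself is executed at 8-10 s and the remainder of the
trial is rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ParadigmError(ValueError):
    """Raised when a paradigm timeline is internally inconsistent."""


#: Default event schedule, in seconds from trial onset.
DEFAULT_CUE_TIMES = {
    "prompt_video": 0.0,    # first audio prompt + instruction video
    "fixation": 3.5,        # second prompt, "+" appears
    "mi_start": 5.5,        # subject begins motor imagery
    "prompt_move": 7.5,     # third prompt: prepare to move
    "move_start": 8.0,      # movement execution begins
    "move_end": 10.0,       # movement complete
    "rest": 10.0,           # rest marker until trial end
}


@dataclass(frozen=True)
class ParadigmSpec:
    """Event schedule and analysis windows for one trial.

    Parameters
    ----------
    cue_times : dict
        Named event times in seconds from trial onset.
    trial_length : float
        Total trial duration in seconds.
    mi_window : tuple of float
        ``(start, end)`` of the MI-only EEG analysis window.
    sync_window : tuple of float
        ``(start, end)`` of the simultaneous EEG+sEMG window; must start
        where the MI window ends.
    fs_eeg, fs_emg : float
        Sampling rates in Hz.
    """

    cue_times: dict = field(default_factory=lambda: dict(DEFAULT_CUE_TIMES))
    trial_length: float = 15.0
    mi_window: tuple = (5.5, 7.5)
    sync_window: tuple = (7.5, 8.5)
    fs_eeg: float = 1000.0
    fs_emg: float = 1500.0

    def __post_init__(self) -> None:
        if self.fs_eeg <= 0 or self.fs_emg <= 0:
            raise ParadigmError("sampling rates must be positive")
        for name, (a, b) in (("mi_window", self.mi_window),
                             ("sync_window", self.sync_window)):
            if not 0 <= a < b <= self.trial_length:
                raise ParadigmError(
                    f"{name} [{a}, {b}] must lie within [0, {self.trial_length}]"
                )
        if self.mi_window[1] != self.sync_window[0]:
            raise ParadigmError(
                "mi_window must abut sync_window: "
                f"mi ends at {self.mi_window[1]}, sync starts at {self.sync_window[0]}"
            )
        for name, t in self.cue_times.items():
            if not 0 <= t <= self.trial_length:
                raise ParadigmError(f"event {name!r} at {t}s outside trial")

    @property
    def n_eeg_samples(self) -> int:
        return int(round(self.trial_length * self.fs_eeg))

    @property
    def n_emg_samples(self) -> int:
        return int(round(self.trial_length * self.fs_emg))

    def events(self) -> list:
        """Events as a time-sorted ``[(time, name), ...]`` list."""
        return sorted((t, n) for n, t in self.cue_times.items())


def make_paradigm_timeline(
    trial_length: float = 15.0,
    mi_window: tuple = (5.5, 7.5),
    sync_window: tuple = (7.5, 8.5),
    fs_eeg: float = 1000.0,
    fs_emg: float = 1500.0,
    cue_times: dict | None = None,
) -> ParadigmSpec:
    """Build the default trial timeline.

    With default arguments this reproduces the standard schedule: audio
    prompts at 0, 3.5 and 7.5 s, MI at 5.5-8 s, movement at 8-10 s, rest to
    15 s; the MI analysis window is [5.5, 7.5] s and the synchronized
    window is [7.5, 8.5] s.

    Raises
    ------
    ParadigmError
        If windows are out of order or events fall outside the trial.
    """
    cues = dict(DEFAULT_CUE_TIMES) if cue_times is None else dict(cue_times)
    last_event = max(cues.values())
    if trial_length < last_event:
        raise ParadigmError(
            f"trial_length {trial_length}s precedes last event at {last_event}s"
        )
    return ParadigmSpec(
        cue_times=cues,
        trial_length=trial_length,
        mi_window=tuple(mi_window),
        sync_window=tuple(sync_window),
        fs_eeg=fs_eeg,
        fs_emg=fs_emg,
    )
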