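"""Synthetic multimodal (EEG + sEMG) recordings with recoverable class structure.

The generator emulates the statistical signatures a movement decoder exploits
rather than the biophysics of their generation:

* EEG: a 1/f ("pink") background per channel, low-passed near 45 Hz, plus
  narrowband mu (8-12 Hz) and beta (18-26 Hz) rhythms on sensorimotor
  electrodes.  Motor imagery is expressed as event-related desynchronization
  (ERD): during the MI and synchronized windows the rhythm amplitude on the
  class-designated channels drops so that band power scales by
  ``1 - erd_depth``.
* sEMG: a low-amplitude 20-450 Hz baseline per muscle, plus band-limited
  activation bursts on class-designated muscles.  Bursts begin ``onset_lead``
  seconds (0.5-1 s) before movement execution, the physiological
  electromechanical lead of muscle activation.

Class structure is configurable through a :class:`ClassCoding`.  The
``"distinct"`` coding gives each of the three movements (standing, sitting,
walking) its own ERD channel set and muscle set; the ``"partial"`` coding is a
designed ambiguity in which each modality alone can separate only two of the
three classes (EEG: standing vs. {sitting, walking}; sEMG: walking vs.
{standing, sitting}) so that only their fusion disambiguates all three.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .montage import (EEG_CHANNELS, EMG_CHANNELS, MUSCLES, SENSORIMOTOR)
from .paradigm import ParadigmSpec, make_paradigm_timeline

CLASSES = ("standing", "sitting", "walking")

MU_BAND = (8.0, 12.0)
BETA_BAND = (18.0, 26.0)
EMG_BAND = (20.0, 450.0)


@dataclass(frozen=True)
class ClassCoding:
    """Which EEG channels desynchronize and which muscles burst, per class.

    ``erd_scale`` and ``burst_scale`` multiply the subject-level base effect;
    a scale of 0 removes the effect for that class entirely.
    """

    erd_channels: dict
    erd_scale: dict
    burst_muscles: dict
    burst_scale: dict

    def __post_init__(self) -> None:
        for cls in CLASSES:
            for d in (self.erd_channels, self.erd_scale,
                      self.burst_muscles, self.burst_scale):
                if cls not in d:
                    raise ValueError(f"coding missing class {cls!r}")


def _sided(muscles):
    return [f"L_{m}" for m in muscles] + [f"R_{m}" for m in muscles]


#: Every class has its own ERD topography and muscle synergy.
DISTINCT_CODING = ClassCoding(
    erd_channels={
        "standing": ["FC1", "FC2", "Cz"],
        "sitting": ["C3", "C4", "CP1", "CP2"],
        "walking": ["C3", "Cz", "C4", "CP1", "CP2"],
    },
    erd_scale={"standing": 0.7, "sitting": 1.0, "walking": 1.0},
    burst_muscles={
        "standing": _sided(["RF", "VL"]),
        "sitting": _sided(["BF", "RF"]),
        "walking": _sided(["TA", "LG"]),
    },
    burst_scale={"standing": 1.0, "sitting": 1.0, "walking": 1.0},
)

#: Each modality alone separates only 2 of the 3 classes.
PARTIAL_CODING = ClassCoding(
    erd_channels={
        "standing": [],
        "sitting": ["C3", "Cz", "C4", "CP1", "CP2"],
        "walking": ["C3", "Cz", "C4", "CP1", "CP2"],
    },
    erd_scale={"standing": 0.0, "sitting": 1.0, "walking": 1.0},
    burst_muscles={
        "standing": _sided(["RF", "VL"]),
        "sitting": _sided(["RF", "VL"]),
        "walking": _sided(["TA", "LG"]),
    },
    burst_scale={"standing": 1.0, "sitting": 1.0, "walking": 1.0},
)

CODINGS = {"distinct": DISTINCT_CODING, "partial": PARTIAL_CODING}


@dataclass
class SubjectProfile:
    """Subject-level generative parameters.

    ``erd_depth`` maps class -> fractional mu/beta band-power decrease in
    [0, 1); ``burst_gain`` maps class -> per-muscle burst amplitude (in units
    of the sEMG baseline standard deviation).
    """

    subject_id: int
    channel_gains: dict          # {"eeg": (32,), "emg": (10,)}
    erd_depth: dict              # class -> float in [0, 1)
    burst_gain: dict             # class -> (10,) array, >= 0
    onset_lead: float            # seconds, sEMG activation before movement
    noise_level: float
    seed: int

    def __post_init__(self) -> None:
        for cls, d in self.erd_depth.items():
            if not 0.0 <= d < 1.0:
                raise ValueError(f"erd_depth[{cls}]={d} outside [0, 1)")
        for cls, g in self.burst_gain.items():
            if np.any(np.asarray(g) < 0):
                raise ValueError(f"burst_gain[{cls}] must be >= 0")


def simulate_subject_profile(
    subject_id: int,
    seed: int,
    coding: ClassCoding | str = "distinct",
    noise_level: float = 1.0,
    erd_depth_base: float | None = None,
    burst_gain_base: float | None = None,
) -> SubjectProfile:
    """Draw a subject's generative parameters, deterministically in
    ``(subject_id, seed)``.

    Base effect sizes default to subject-specific draws: ERD depth in
    [0.45, 0.65] and burst gain in [3, 5] baseline standard deviations,
    then modulated per class by the coding's scale factors.
    """
    if isinstance(coding, str):
        coding = CODINGS[coding]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(subject_id)]))
    gains = {
        "eeg": np.exp(rng.normal(0.0, 0.1, size=len(EEG_CHANNELS))),
        "emg": np.exp(rng.normal(0.0, 0.1, size=len(EMG_CHANNELS))),
    }
    depth_base = rng.uniform(0.45, 0.65) if erd_depth_base is None else erd_depth_base
    gain_base = rng.uniform(3.0, 5.0) if burst_gain_base is None else burst_gain_base
    muscle_jitter = np.exp(rng.normal(0.0, 0.05, size=len(EMG_CHANNELS)))

    erd_depth, burst_gain = {}, {}
    for cls in CLASSES:
        erd_depth[cls] = float(np.clip(depth_base * coding.erd_scale[cls], 0.0, 0.95))
        g = np.zeros(len(EMG_CHANNELS))
        idx = [EMG_CHANNELS.index(m) for m in coding.burst_muscles[cls]]
        g[idx] = gain_base * coding.burst_scale[cls] * muscle_jitter[idx]
        burst_gain[cls] = g
    return SubjectProfile(
        subject_id=int(subject_id),
        channel_gains=gains,
        erd_depth=erd_depth,
        burst_gain=burst_gain,
        onset_lead=float(rng.uniform(0.5, 1.0)),
        noise_level=float(noise_level),
        seed=int(seed),
    )


@dataclass
class ContinuousTrialRecording:
    """One full 15 s trial: continuous EEG + sEMG plus event markers."""

    eeg: np.ndarray              # (n_eeg_channels, trial_length * fs_eeg)
    emg: np.ndarray              # (n_emg_channels, trial_length * fs_emg)
    events: list                 # [(time_s, marker_name)] sorted by time
    label: str
    subject_id: int
    fs_eeg: float
    fs_emg: float
    eeg_channels: list = field(default_factory=lambda: list(EEG_CHANNELS))
    emg_channels: list = field(default_factory=lambda: list(EMG_CHANNELS))

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValueError(f"unknown class {self.label!r}; expected one of {CLASSES}")
        if self.eeg.shape[0] != len(self.eeg_channels):
            raise ValueError("eeg row count != number of EEG channel names")
        if self.emg.shape[0] != len(self.emg_channels):
            raise ValueError("emg row count != number of sEMG channel names")
        times = [t for t, _ in self.events]
        if times != sorted(times):
            raise ValueError("events must be monotone in time")


def _pink_background(rng, n, fs, f_cut=45.0, rolloff=3.0):
    """Unit-variance 1/f noise, steeply attenuated above ``f_cut``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.empty_like(f)
    f_floor = max(f[1], 0.3)
    amp[:] = 1.0 / np.sqrt(np.maximum(f, f_floor))
    fc = min(f_cut, 0.9 * fs / 2.0)
    hi = f > fc
    amp[hi] *= (fc / f[hi]) ** rolloff
    amp[0] = 0.0
    x = np.fft.irfft(spec * amp, n)
    return x / x.std()


def _narrowband(rng, n, fs, lo, hi, order=4):
    """Unit-variance band-limited Gaussian noise; band clipped to Nyquist."""
    nyq = fs / 2.0
    hi = min(hi, 0.95 * nyq)
    if hi <= lo:
        return np.zeros(n)
    sos = sps.butter(order, [lo / nyq, hi / nyq], btype="band", output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    s = x.std()
    return x / s if s > 0 else x


# Rhythm amplitude relative to the background standard deviation.  Chosen so
# the mu band is rhythm-dominated (band SNR ~ 15-20): the measured MI/baseline
# band-power ratio then tracks 1 - erd_depth closely.
_MU_AMP = 1.0
_BETA_AMP = 0.7
#: sEMG baseline standard deviation in profile noise units.
_EMG_BASELINE = 0.1


def simulate_trial(
    profile: SubjectProfile,
    spec: ParadigmSpec,
    class_label: str,
    seed: int,
    coding: ClassCoding | str = "distinct",
) -> ContinuousTrialRecording:
    """Generate one continuous trial for ``class_label``.

    EEG channels in the coding's ERD set for this class have their mu/beta
    rhythm amplitude scaled by ``sqrt(1 - erd_depth)`` from MI onset to the
    end of the synchronized window.  Muscles in the coding's burst set
    activate from ``onset_lead`` seconds before the movement marker to the
    movement end.
    """
    if class_label not in CLASSES:
        raise ValueError(f"unknown class {class_label!r}; expected one of {CLASSES}")
    if isinstance(coding, str):
        coding = CODINGS[coding]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    noise = profile.noise_level

    # ---- EEG -------------------------------------------------------------
    n_eeg = spec.n_eeg_samples
    t_eeg = np.arange(n_eeg) / spec.fs_eeg
    eeg = np.empty((len(EEG_CHANNELS), n_eeg))

    erd_gate = np.ones(n_eeg)
    in_erd = (t_eeg >= spec.mi_window[0]) & (t_eeg < spec.sync_window[1])
    depth = profile.erd_depth[class_label]
    erd_channels = set(coding.erd_channels[class_label])

    for ci, ch in enumerate(EEG_CHANNELS):
        g = profile.channel_gains["eeg"][ci] * noise
        x = _pink_background(rng, n_eeg, spec.fs_eeg) * g
        if ch in SENSORIMOTOR:
            mu = _narrowband(rng, n_eeg, spec.fs_eeg, *MU_BAND) * (_MU_AMP * g)
            beta = _narrowband(rng, n_eeg, spec.fs_eeg, *BETA_BAND) * (_BETA_AMP * g)
            if ch in erd_channels and depth > 0:
                gate = erd_gate.copy()
                gate[in_erd] = np.sqrt(1.0 - depth)
                mu = mu * gate
                beta = beta * gate
            x = x + mu + beta
        eeg[ci] = x

    # ---- sEMG ------------------------------------------------------------
    n_emg = spec.n_emg_samples
    t_emg = np.arange(n_emg) / spec.fs_emg
    emg = np.empty((len(EMG_CHANNELS), n_emg))

    move_start = spec.cue_times.get("move_start", spec.sync_window[1])
    move_end = spec.cue_times.get("move_end", move_start + 2.0)
    burst_on = move_start - profile.onset_lead
    env = np.zeros(n_emg)
    active = (t_emg >= burst_on) & (t_emg < move_end)
    env[active] = 1.0
    ramp = max(1, int(round(0.1 * spec.fs_emg)))
    kernel = np.hanning(2 * ramp + 1)
    env = np.convolve(env, kernel / kernel.sum(), mode="same")

    gains = profile.burst_gain[class_label]
    for mi, _ in enumerate(EMG_CHANNELS):
        g = profile.channel_gains["emg"][mi] * noise
        base = _narrowband(rng, n_emg, spec.fs_emg, *EMG_BAND) * (_EMG_BASELINE * g)
        x = base
        if gains[mi] > 0:
            carrier = _narrowband(rng, n_emg, spec.fs_emg, *EMG_BAND)
            x = x + carrier * env * (gains[mi] * _EMG_BASELINE * g)
        emg[mi] = x

    return ContinuousTrialRecording(
        eeg=eeg,
        emg=emg,
        events=spec.events(),
        label=class_label,
        subject_id=profile.subject_id,
        fs_eeg=spec.fs_eeg,
        fs_emg=spec.fs_emg,
    )


def _group_order(rng, trials_per_class: int):
    """Class order in one acquisition group: walking/sitting shuffled in the
    first two thirds, standing last (subjects must start a movement from the
    complementary posture)."""
    first = ["walking"] * trials_per_class + ["sitting"] * trials_per_class
    rng.shuffle(first)
    return first + ["standing"] * trials_per_class


def make_dataset(
    n_subjects: int = 10,
    groups: int = 3,
    trials_per_class_per_group: int = 10,
    seed: int = 0,
    coding: ClassCoding | str = "distinct",
    spec: ParadigmSpec | None = None,
    noise_level: float = 1.0,
) -> list:
    """Generate a full multi-subject dataset of continuous trials.

    Defaults mirror the acquisition protocol: 10 subjects x 3 groups x
    (10 standing + 10 sitting + 10 walking) = 900 trials, 90 per subject.
    Deterministic in ``seed``.
    """
    if min(n_subjects, groups, trials_per_class_per_group) < 1:
        raise ValueError("all counts must be >= 1")
    if spec is None:
        spec = make_paradigm_timeline()
    if isinstance(coding, str):
        coding = CODINGS[coding]
    root = np.random.SeedSequence([int(seed), 0x5EED])
    trial_seeds = root.generate_state(n_subjects * groups * 3 * trials_per_class_per_group)
    order_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x0D0E]))

    recordings = []
    k = 0
    for sid in range(1, n_subjects + 1):
        profile = simulate_subject_profile(sid, seed, coding=coding,
                                           noise_level=noise_level)
        for _ in range(groups):
            for cls in _group_order(order_rng, trials_per_class_per_group):
                rec = simulate_trial(profile, spec, cls,
                                     seed=int(trial_seeds[k] & 0x7FFFFFFF),
                                     coding=coding)
                recordings.append(rec)
                k += 1
    return recordings
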