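"""Channel layouts for the simulated recordings.

32 EEG electrodes on a 10-20-style montage and 10 lower-limb sEMG electrodes
(5 muscles per leg).  "Unilateral" selection keeps one body side: lower-limb
movement decoding in hemiplegia uses the affected side only, i.e. 16 EEG
channels and the 5 muscles of one leg.
"""

from __future__ import annotations

EEG_CHANNELS = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "PO7", "PO3", "PO4", "PO8",
    "O1", "O2", "Oz",
]

# Odd-numbered electrodes sit over the left hemisphere; two midline channels
# are assigned to each side so both unilateral sets have 16 channels.
EEG_LEFT = [
    "Fp1", "F7", "F3", "Fz", "FC5", "FC1", "T7", "C3", "Cz",
    "CP5", "CP1", "P7", "P3", "PO7", "PO3", "O1",
]
EEG_RIGHT = [
    "Fp2", "F8", "F4", "Pz", "FC6", "FC2", "T8", "C4", "Oz",
    "CP6", "CP2", "P8", "P4", "PO8", "PO4", "O2",
]

#: Central/sensorimotor electrodes carrying mu and beta rhythms.
SENSORIMOTOR = ["FC1", "FC2", "C3", "Cz", "C4", "CP1", "CP2"]

#: Muscles per leg: rectus femoris, vastus lateralis, tibialis anterior,
#: biceps femoris, lateral gastrocnemius.
MUSCLES = ["RF", "VL", "TA", "BF", "LG"]
EMG_CHANNELS = [f"L_{m}" for m in MUSCLES] + [f"R_{m}" for m in MUSCLES]
EMG_LEFT = [f"L_{m}" for m in MUSCLES]
EMG_RIGHT = [f"R_{m}" for m in MUSCLES]

SIDE_MAPS = {
    "left": {"eeg": EEG_LEFT, "emg": EMG_LEFT},
    "right": {"eeg": EEG_RIGHT, "emg": EMG_RIGHT},
}
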