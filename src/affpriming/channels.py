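"""Standard 32-channel montage used by the recording setup and simulator.

Channel order follows the actiCHamp 32-electrode layout of the extended
10-20 system. Analysis code never assumes this order; it always looks
channels up by name.
"""

from __future__ import annotations

import numpy as np

CHANNELS_32 = [
    "Fp1", "Fz", "F3", "F7", "FT9", "FC5", "FC1", "C3",
    "T7", "TP9", "CP5", "CP1", "Pz", "P3", "P7", "O1",
    "Oz", "O2", "P4", "P8", "TP10", "CP6", "CP2", "Cz",
    "C4", "T8", "FT10", "FC6", "FC2", "F4", "F8", "Fp2",
]

# Relative projection strength of an eye blink onto each electrode group,
# decaying from the front of the head to the back. Maximal at Fp1 by
# construction (blink detection correlates ICA components with Fp1).
_BLINK_WEIGHT_BY_PREFIX = {
    "Fp1": 1.00, "Fp2": 0.95,
    "F7": 0.50, "F3": 0.55, "Fz": 0.55, "F4": 0.55, "F8": 0.50,
    "FT9": 0.30, "FC5": 0.32, "FC1": 0.35, "FC2": 0.35, "FC6": 0.32, "FT10": 0.30,
    "T7": 0.15, "C3": 0.15, "Cz": 0.16, "C4": 0.15, "T8": 0.15,
    "TP9": 0.08, "CP5": 0.08, "CP1": 0.09, "CP2": 0.09, "CP6": 0.08, "TP10": 0.08,
    "P7": 0.04, "P3": 0.04, "Pz": 0.05, "P4": 0.04, "P8": 0.04,
    "O1": 0.02, "Oz": 0.02, "O2": 0.02,
}


def blink_topography(ch_names: list[str]) -> np.ndarray:
    """Per-channel blink projection weights, peaking at Fp1."""
    return np.array([_BLINK_WEIGHT_BY_PREFIX.get(name, 0.05) for name in ch_names])


def channel_index(ch_names: list[str], name: str) -> int:
    try:
        return ch_names.index(name)
    except ValueError:
        raise KeyError(f"channel {name!r} not in montage: {ch_names}") from None
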