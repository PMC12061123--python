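"""In-memory containers shared by the simulation and analysis stages.

Units are µV and seconds at every interface; sample indices are an
internal detail. All containers carry a ``history`` list recording the
processing chain applied so far, for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CONGRUENT = "congruent"
INCONGRUENT = "incongruent"


@dataclass
class RawRecording:
    """Continuous multi-channel EEG with event markers.

    data : (n_channels, n_samples) array, µV
    events : list of (sample_index, trial_index, condition) with
        condition in {"congruent", "incongruent"}
    """

    data: np.ndarray
    sfreq: float
    ch_names: list
    events: list = field(default_factory=list)
    history: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_channels, n_samples)")
        if self.data.shape[0] != len(self.ch_names):
            raise ValueError(
                f"channel count mismatch: {self.data.shape[0]} rows vs {len(self.ch_names)} names"
            )
        samples = [e[0] for e in self.events]
        if samples != sorted(samples):
            raise ValueError("events must be sorted by sample index")
        if samples and (samples[0] < 0 or samples[-1] >= self.data.shape[1]):
            raise ValueError("event sample index outside the recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq

    def copy_with(self, data=None, events=None, step=None) -> "RawRecording":
        out = RawRecording(
            data=self.data.copy() if data is None else data,
            sfreq=self.sfreq,
            ch_names=list(self.ch_names),
            events=list(self.events) if events is None else events,
            history=list(self.history),
        )
        if step:
            out.history.append(step)
        return out


@dataclass
class EpochSet:
    """Target-locked epochs: (n_trials, n_channels, n_times), µV.

    ``times`` is the common epoch time axis in seconds relative to target
    onset. ``labels`` holds "congruent"/"incongruent" per retained trial.
    ``rejected`` logs dropped trials as dicts with at least
    {"trial", "reason"}.
    """

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    ch_names: list
    labels: np.ndarray
    baseline: tuple = None
    rejected: list = field(default_factory=list)
    history: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_times)")
        if self.data.shape[0] != len(self.labels):
            raise ValueError("one label per trial required")
        if self.data.shape[1] != len(self.ch_names):
            raise ValueError("channel count mismatch")
        if self.data.shape[2] != len(self.times):
            raise ValueError("time axis mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def condition_data(self, condition: str) -> np.ndarray:
        return self.data[self.labels == condition]

    def copy_with(self, data=None, labels=None, rejected=None, step=None) -> "EpochSet":
        out = EpochSet(
            data=self.data.copy() if data is None else data,
            times=self.times,
            sfreq=self.sfreq,
            ch_names=list(self.ch_names),
            labels=self.labels.copy() if labels is None else labels,
            baseline=self.baseline,
            rejected=list(self.rejected) if rejected is None else rejected,
            history=list(self.history),
        )
        if step:
            out.history.append(step)
        return out


@dataclass
class ICADecomposition:
    """Linear ICA decomposition of a continuous recording.

    sources : (n_components, n_samples) component time courses
    mixing : (n_channels, n_components); unmixing : (n_components, n_channels)
    mean : (n_channels,) channel means removed before unmixing
    fp1_r : per-component Pearson r with the Fp1 trace (filled by
        blink detection); flagged : indices with |r| above threshold
    """

    sources: np.ndarray
    mixing: np.ndarray
    unmixing: np.ndarray
    mean: np.ndarray
    seed: int
    fp1_r: np.ndarray = None
    flagged: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.sources.shape[0]


def sample_window(times: np.ndarray, sfreq: float, start: float, end: float) -> np.ndarray:
    """Boolean mask selecting the half-open window [start, end) seconds.

    Selection is done on integer sample indices (round(t*sfreq)) so that
    the simulator's effect injection and the analysis windows pick
    exactly the same samples regardless of float rounding of the time
    axis.
    """
    idx = np.round(np.asarray(times) * sfreq).astype(int)
    s, e = int(round(start * sfreq)), int(round(end * sfreq))
    return (idx >= s) & (idx < e)
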