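"""Readers and writers for the pipeline's on-disk formats.

Continuous recordings are written as BrainVision triplets
(.vhdr/.vmrk/.eeg, IEEE float32 multiplexed, µV) — the dialect of the
amplifier the recording setup uses — and read back through MNE, which
also provides EDF reading. Behavioural logs and questionnaire tables
are plain CSV; epoch sets are saved as an .npz array plus a JSON
sidecar carrying labels, window, rejection log and history.

Stimulus markers encode the condition: ``S  1`` = congruent,
``S  2`` = incongruent; trial order gives the trial index.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CONGRUENT, INCONGRUENT, EpochSet, RawRecording

_COND_TO_CODE = {CONGRUENT: 1, INCONGRUENT: 2}
_CODE_TO_COND = {v: k for k, v in _COND_TO_CODE.items()}


def write_brainvision(raw: RawRecording, basename) -> Path:
    """Write ``<basename>.vhdr/.vmrk/.eeg``; returns the header path."""
    base = Path(basename)
    vhdr, vmrk, eeg = base.with_suffix(".vhdr"), base.with_suffix(".vmrk"), base.with_suffix(".eeg")

    sampling_interval_us = 1e6 / raw.sfreq
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={raw.n_channels}",
        f"SamplingInterval={sampling_interval_us:.6f}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, name in enumerate(raw.ch_names, start=1):
        lines.append(f"Ch{i}={name},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    for k, (sample, _trial, condition) in enumerate(raw.events, start=2):
        code = _COND_TO_CODE[condition]
        # marker positions are 1-based in BrainVision
        mlines.append(f"Mk{k}=Stimulus,S{code:>3},{sample + 1},1,0")
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")

    raw.data.T.astype("<f4").tofile(eeg)
    return vhdr


def read_raw(path, format: str = "brainvision") -> RawRecording:
    """Read a continuous recording (``brainvision`` or ``edf``) into a
    RawRecording, data in µV, stimulus markers decoded to conditions."""
    import mne

    path = Path(path)
    if format == "brainvision":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    elif format == "edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unknown format {format!r}")

    data_uv = raw.get_data() * 1e6          # MNE holds volts
    events = []
    trial = 0
    for ann in raw.annotations:
        desc = ann["description"]
        if "Stimulus" not in desc:
            continue
        code = int(desc.split("S")[-1].strip())
        sample = int(round(ann["onset"] * raw.info["sfreq"]))
        events.append((sample, trial, _CODE_TO_COND.get(code, str(code))))
        trial += 1
    return RawRecording(data=data_uv, sfreq=float(raw.info["sfreq"]),
                        ch_names=list(raw.ch_names), events=events,
                        history=[{"step": "read_raw", "path": str(path), "format": format}])


def write_epochs(epochs: EpochSet, basename) -> Path:
    """Save epochs as ``<basename>.npz`` with a ``<basename>.json`` sidecar."""
    base = Path(basename)
    npz = base.with_suffix(".npz")
    np.savez_compressed(npz, data=epochs.data, times=epochs.times)
    sidecar = {
        "sfreq": epochs.sfreq,
        "ch_names": list(epochs.ch_names),
        "labels": [str(l) for l in epochs.labels],
        "baseline": list(epochs.baseline) if epochs.baseline else None,
        "rejected": epochs.rejected,
        "history": epochs.history,
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1), encoding="utf-8")
    return npz


def read_epochs(basename) -> EpochSet:
    base = Path(basename)
    arrays = np.load(base.with_suffix(".npz"))
    meta = json.loads(base.with_suffix(".json").read_text(encoding="utf-8"))
    return EpochSet(
        data=arrays["data"], times=arrays["times"], sfreq=meta["sfreq"],
        ch_names=meta["ch_names"], labels=np.array(meta["labels"], dtype=object),
        baseline=tuple(meta["baseline"]) if meta["baseline"] else None,
        rejected=meta["rejected"], history=meta["history"],
    )


def write_behaviour_csv(log: pd.DataFrame, path) -> Path:
    path = Path(path)
    log.to_csv(path, index=False)
    return path


def read_behaviour_csv(path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
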