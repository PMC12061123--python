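"""Continuous-to-epoch preprocessing chain.

The canonical order is: band-pass filter (0.1–30 Hz, zero-phase FIR) →
common-average re-reference → ICA blink removal (components whose |r|
with the Fp1 trace exceeds 0.5) → target-locked epoching → baseline
correction over −60..+40 ms → peak-to-peak artifact rejection. Each step
appends to the container's ``history`` so outputs record the chain
actually applied.

The peak-to-peak budget is exposed as a single number: a trial is
rejected when any channel's max−min within the epoch exceeds it. The
default budget of 200 µV corresponds to reading "±100 µV" as the signal
leaving a ±100 µV band; pass 100 to treat the figure as the range
itself.
"""

from __future__ import annotations

import numpy as np
from mne.filter import filter_data
from scipy.stats import pearsonr
from sklearn.decomposition import FastICA

from .channels import channel_index
from .containers import EpochSet, ICADecomposition, RawRecording

BLINK_R_THRESHOLD = 0.5
PTP_BUDGET_UV = 200.0


def bandpass_filter(raw: RawRecording, low: float = 0.1, high: float = 30.0) -> RawRecording:
    """Zero-phase FIR band-pass; length preserved, no latency shift."""
    nyq = raw.sfreq / 2.0
    if not (0 < low < high):
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    if high >= nyq:
        raise ValueError(f"high edge {high} Hz at or above Nyquist {nyq} Hz")
    filtered = filter_data(raw.data, raw.sfreq, low, high, verbose="error")
    return raw.copy_with(data=filtered, step={"step": "bandpass", "low": low, "high": high})


def rereference_average(raw: RawRecording) -> RawRecording:
    """Common-average reference: per-sample mean across channels becomes 0."""
    if raw.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    data = raw.data - raw.data.mean(axis=0, keepdims=True)
    return raw.copy_with(data=data, step={"step": "rereference_average"})


def _effective_rank(data: np.ndarray) -> int:
    cov = np.cov(data)
    eig = np.linalg.eigvalsh(cov)
    return int(np.sum(eig > eig.max() * 1e-10))


def fit_ica(raw: RawRecording, n_components: int = None, seed: int = 0) -> ICADecomposition:
    """FastICA decomposition; component count defaults to the channel rank
    (one less than the channel count after average referencing)."""
    if n_components is None:
        n_components = min(raw.n_channels, _effective_rank(raw.data))
    ica = FastICA(n_components=n_components, random_state=seed,
                  whiten="unit-variance", max_iter=1000, tol=1e-4)
    sources = ica.fit_transform(raw.data.T).T
    return ICADecomposition(
        sources=sources,
        mixing=ica.mixing_,
        unmixing=ica.components_,
        mean=ica.mean_,
        seed=seed,
    )


def detect_blink_components(ica: ICADecomposition, raw: RawRecording,
                            threshold: float = BLINK_R_THRESHOLD) -> list:
    """Flag components whose |Pearson r| with the Fp1 trace exceeds
    ``threshold``. The r values are stored on the decomposition."""
    if "Fp1" not in raw.ch_names:
        raise ValueError(
            "blink detection requires an Fp1 channel (used in place of a "
            f"vEOG); channels present: {raw.ch_names}"
        )
    if ica.sources.shape[1] != raw.n_samples:
        raise ValueError("ICA was not fitted on this recording (length mismatch)")
    fp1 = raw.data[channel_index(raw.ch_names, "Fp1")]
    rs = np.array([pearsonr(src, fp1)[0] if np.std(src) > 0 else 0.0
                   for src in ica.sources])
    ica.fp1_r = rs
    ica.flagged = [int(i) for i in np.flatnonzero(np.abs(rs) > threshold)]
    return list(ica.flagged)


def remove_components(raw: RawRecording, ica: ICADecomposition, indices) -> RawRecording:
    """Reconstruct the recording without the given components."""
    indices = list(indices)
    for i in indices:
        if not 0 <= i < ica.n_components:
            raise IndexError(f"component index {i} out of range [0, {ica.n_components})")
    keep = [i for i in range(ica.n_components) if i not in set(indices)]
    recon = ica.mixing[:, keep] @ ica.sources[keep] + ica.mean[:, None]
    # components span only the retained subspace; add back the residual
    # the decomposition never captured so that removing nothing is identity
    full = ica.mixing @ ica.sources + ica.mean[:, None]
    data = raw.data - full + recon
    return raw.copy_with(data=data, step={"step": "remove_components", "indices": indices})


def epoch_and_baseline(raw: RawRecording, tmin: float = -0.1, tmax: float = 1.0,
                       baseline: tuple = (-0.060, 0.040)) -> EpochSet:
    """Cut target-locked epochs and subtract the per-trial/channel mean
    over the baseline window. Events too close to the recording edge are
    dropped and logged, never silently truncated."""
    sfreq = raw.sfreq
    i0, i1 = int(round(tmin * sfreq)), int(round(tmax * sfreq))
    times = np.arange(i0, i1 + 1) / sfreq

    kept, labels, rejected = [], [], []
    for sample, trial, condition in raw.events:
        lo, hi = sample + i0, sample + i1 + 1
        if lo < 0 or hi > raw.n_samples:
            rejected.append({"trial": trial, "reason": "epoch outside recording"})
            continue
        kept.append(raw.data[:, lo:hi])
        labels.append(condition)
    data = np.array(kept) if kept else np.empty((0, raw.n_channels, len(times)))

    if baseline is not None and len(kept):
        mask = (np.round(times * sfreq).astype(int) >= int(round(baseline[0] * sfreq))) & \
               (np.round(times * sfreq).astype(int) <= int(round(baseline[1] * sfreq)))
        data = data - data[:, :, mask].mean(axis=2, keepdims=True)

    return EpochSet(
        data=data, times=times, sfreq=sfreq, ch_names=list(raw.ch_names),
        labels=np.array(labels, dtype=object), baseline=baseline, rejected=rejected,
        history=list(raw.history) + [{"step": "epoch_and_baseline",
                                      "tmin": tmin, "tmax": tmax, "baseline": baseline}],
    )


def reject_peak_to_peak(epochs: EpochSet, budget_uv: float = PTP_BUDGET_UV) -> EpochSet:
    """Drop trials whose within-epoch max−min exceeds ``budget_uv`` on any
    channel; the log records the worst channel and its range."""
    if budget_uv <= 0:
        raise ValueError("budget must be positive")
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)   # trials × channels
    worst = ptp.argmax(axis=1)
    worst_val = ptp.max(axis=1) if len(ptp) else np.array([])
    bad = worst_val > budget_uv
    log = list(epochs.rejected)
    for t in np.flatnonzero(bad):
        log.append({"trial": int(t), "reason": "peak_to_peak",
                    "channel": epochs.ch_names[worst[t]],
                    "value_uv": float(worst_val[t])})
    return epochs.copy_with(
        data=epochs.data[~bad], labels=epochs.labels[~bad], rejected=log,
        step={"step": "reject_peak_to_peak", "budget_uv": budget_uv,
              "n_rejected": int(bad.sum())},
    )


def preprocess_recording(raw: RawRecording, low: float = 0.1, high: float = 30.0,
                         ica_seed: int = 0, blink_threshold: float = BLINK_R_THRESHOLD,
                         budget_uv: float = PTP_BUDGET_UV, run_ica: bool = True,
                         tmin: float = -0.1, tmax: float = 1.0,
                         baseline: tuple = (-0.060, 0.040)) -> EpochSet:
    """The full chain in canonical order; ``run_ica=False`` skips blink
    removal (useful when the simulation contains no blinks)."""
    raw = bandpass_filter(raw, low, high)
    raw = rereference_average(raw)
    if run_ica:
        ica = fit_ica(raw, seed=ica_seed)
        flagged = detect_blink_components(ica, raw, blink_threshold)
        if flagged:
            raw = remove_components(raw, ica, flagged)
    epochs = epoch_and_baseline(raw, tmin=tmin, tmax=tmax, baseline=baseline)
    return reject_peak_to_peak(epochs, budget_uv)
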