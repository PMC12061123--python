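"""Synthetic cohorts for the affective-priming experiments.

The generator emulates the statistical structure the analysis stages
assume, so every stage can be verified end to end without access to the
original recordings:

* trial schedules with balanced target valences and coin-flip primes
  (:mod:`affpriming.schedule`),
* per-trial reaction times with a congruency shift and multiplicative
  lognormal noise, plus response errors and timeouts,
* continuous 32-channel EEG as the sum of a stereotyped evoked template
  at each target onset, a condition difference injected symmetrically
  (± half the amplitude) over configurable electrode/time windows,
  1/f-shaped background noise, and frontally-projected eye blinks at
  Poisson times,
* questionnaire scores (FMI mindfulness, BIS-11 impulsivity, PExE
  exceptional experiences) with an optional latent coupling between
  mindfulness and each virtual participant's reaction-time effect.

Because only the congruent-minus-incongruent *contrast* is constrained
by published numbers, the effect is split ±half between conditions,
leaving the grand-average waveform untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .channels import CHANNELS_32, blink_topography, channel_index
from .containers import CONGRUENT, INCONGRUENT, EpochSet, RawRecording, sample_window
from .schedule import FIXATION_MS, ISI_MS, PRIME_MS, TrialSchedule, make_schedule

EPOCH_TMIN = -0.1
EPOCH_TMAX = 1.0
BASELINE = (-0.060, 0.040)
TRIAL_LEN_S = 5.0  # fixation + prime + ISI + full target slot + blank

#: default congruency contrasts (electrode, window start s, end s, amplitude µV),
#: matching the published condition differences: forward P8 0.18−1.32 = −1.14 µV
#: over 586–889 ms; backward CP5 0.91−0.59 = +0.32 µV over 207–290 ms.
DEFAULT_EFFECTS = {
    "forward": [("P8", 0.586, 0.889, -1.14)],
    "backward": [("CP5", 0.207, 0.290, +0.32)],
}


@dataclass(frozen=True)
class SimParams:
    """Knobs of the synthetic experiment.

    Amplitudes in µV, times in seconds, rates in events/s. ``rt_*`` are
    in ms. ``rt_delta`` is the congruent-minus-incongruent median shift
    (negative = congruent faster); ``rt_delta_sd``/``rt_base_sd`` are
    between-participant standard deviations.
    """

    n_channels: int = 32
    sfreq: float = 250.0
    ch_names: tuple = tuple(CHANNELS_32)
    effect_spec: tuple = ()            # (electrode, start_s, end_s, amplitude_µV)
    noise_sd: float = 8.0
    noise_exponent: float = 1.0
    blink_rate: float = 0.1
    blink_amplitude: float = 150.0
    rt_base: float = 735.5
    rt_delta: float = -31.0
    rt_sigma: float = 0.25
    rt_base_sd: float = 80.0
    rt_delta_sd: float = 45.0
    error_rate: float = 0.05

    def __post_init__(self):
        if self.rt_base <= 0:
            raise ValueError("rt_base must be positive")
        if self.rt_sigma < 0:
            raise ValueError("rt_sigma must be non-negative")
        if self.noise_sd < 0 or self.blink_rate < 0:
            raise ValueError("noise_sd and blink_rate must be non-negative")
        if not 0 <= self.error_rate <= 1:
            raise ValueError("error_rate must be a probability")
        for el, start, end, amp in self.effect_spec:
            channel_index(list(self.ch_names), el)
            if not np.isfinite(amp):
                raise ValueError(f"effect amplitude for {el} not finite")
            if not (EPOCH_TMIN <= start < end <= EPOCH_TMAX):
                raise ValueError(
                    f"effect window ({start}, {end}) s outside epoch span "
                    f"({EPOCH_TMIN}, {EPOCH_TMAX}) s"
                )

    def with_effects(self, experiment: str) -> "SimParams":
        """Return a copy carrying the default contrast for ``experiment``."""
        return replace(self, effect_spec=tuple(DEFAULT_EFFECTS[experiment]))


def epoch_times(sfreq: float, tmin: float = EPOCH_TMIN, tmax: float = EPOCH_TMAX) -> np.ndarray:
    i0, i1 = int(round(tmin * sfreq)), int(round(tmax * sfreq))
    return np.arange(i0, i1 + 1) / sfreq


def erp_template(times: np.ndarray, ch_names) -> np.ndarray:
    """Stereotyped evoked waveform per channel (identical across conditions).

    A sum of Gaussian components with realistic latencies: an early
    occipital positivity (~100 ms), a posterior negativity (~170 ms) and
    a broad centro-parietal late positivity (~450 ms). Zero before
    stimulus onset. Only the injected *difference* is calibrated to
    published values; the absolute shape is a plausible stand-in.
    """
    times = np.asarray(times)

    def weight(name, groups):
        for prefix, w in groups:
            if name.startswith(prefix):
                return w
        return 0.2

    posterior = [("O", 1.0), ("P", 0.9), ("TP", 0.5), ("CP", 0.5), ("C", 0.3), ("F", 0.1)]
    centropar = [("CP", 1.0), ("Pz", 1.0), ("P", 0.8), ("C", 0.8), ("F", 0.3), ("O", 0.4)]

    def bump(mu, sigma, amp):
        return amp * np.exp(-0.5 * ((times - mu) / sigma) ** 2)

    p1 = bump(0.100, 0.020, 3.0)
    n1 = bump(0.170, 0.025, -4.0)
    lpp = bump(0.450, 0.120, 5.0)

    out = np.zeros((len(ch_names), len(times)))
    for i, name in enumerate(ch_names):
        out[i] = weight(name, posterior) * (p1 + n1) + weight(name, centropar) * lpp
    out[:, times < 0] = 0.0
    return out


def one_over_f_noise(rng: np.random.Generator, shape, sfreq: float,
                     sd: float, exponent: float = 1.0) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum along the last axis.

    Spectrally shaped white noise, rescaled so each series has standard
    deviation ``sd``. The DC bin is zeroed.
    """
    n = shape[-1]
    white = rng.standard_normal(shape)
    if sd == 0 or n < 2:
        return np.zeros(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n=n, axis=-1)
    std = x.std(axis=-1, keepdims=True)
    std[std == 0] = 1.0
    return x / std * sd


# ---------------------------------------------------------------------------
# behaviour


def simulate_rt(schedule: TrialSchedule, params: SimParams, seed: int,
                base_shift: float = 0.0, delta_shift: float = 0.0,
                participant: int = 0) -> pd.DataFrame:
    """Per-trial behavioural log for one participant.

    RT = (base ± delta/2) · exp(σZ): the per-condition *median* is then
    exactly base ± delta/2 (the median of the lognormal factor is 1),
    which is the quantity the analysis works with. ``base_shift`` and
    ``delta_shift`` move this participant away from the cohort defaults.
    Responses are wrong with probability ``error_rate``; RTs above the
    2000 ms response deadline are flagged as timeouts.
    """
    rng = np.random.default_rng(seed)
    base = params.rt_base + base_shift
    delta = params.rt_delta + delta_shift
    rows = []
    for t in schedule.trials:
        shift = delta / 2.0 if t.congruent else -delta / 2.0
        rt = (base + shift) * np.exp(params.rt_sigma * rng.standard_normal())
        correct = rng.random() >= params.error_rate
        if t.target_valence == "pos":
            response = "pos" if correct else "neg"
        else:
            response = "neg" if correct else "pos"
        rows.append({
            "participant": participant,
            "trial": t.index,
            "block": t.block,
            "experiment": schedule.experiment,
            "congruent": t.congruent,
            "prime_valence": t.prime_valence,
            "target_valence": t.target_valence,
            "rt_ms": float(rt),
            "response": response,
            "correct": bool(correct),
            "timeout": bool(rt > 2000.0),
        })
    return pd.DataFrame(rows)


def simulate_cohort_rt(n_participants: int, experiment: str, params: SimParams,
                       seed: int, n_trials: int = 400):
    """Behavioural logs for a cohort; returns (log, realized per-participant deltas).

    Each virtual participant gets their own baseline speed and
    congruency effect, drawn around the cohort defaults; the realized
    effects are returned so questionnaire scores can be coupled to them.
    """
    rng = np.random.default_rng(seed)
    logs, deltas = [], []
    for p in range(n_participants):
        base_shift = rng.normal(0.0, params.rt_base_sd)
        delta_shift = rng.normal(0.0, params.rt_delta_sd)
        sched = make_schedule(experiment, n_trials, seed=int(rng.integers(2**31)))
        log = simulate_rt(sched, params, seed=int(rng.integers(2**31)),
                          base_shift=base_shift, delta_shift=delta_shift, participant=p)
        logs.append(log)
        deltas.append(params.rt_delta + delta_shift)
    return pd.concat(logs, ignore_index=True), np.array(deltas)


# ---------------------------------------------------------------------------
# EEG


def _effect_offsets(params: SimParams, sfreq: float):
    """Resolve effect_spec into (channel index, positive-lag sample mask, amp)."""
    # offsets 0 .. 1.0 s relative to target onset, matching the epoch grid
    offs = np.arange(0, int(round(EPOCH_TMAX * sfreq)) + 1)
    times = offs / sfreq
    resolved = []
    for el, start, end, amp in params.effect_spec:
        ci = channel_index(list(params.ch_names), el)
        mask = sample_window(times, sfreq, start, end)
        resolved.append((ci, offs[mask], amp))
    return resolved


def simulate_eeg(schedule: TrialSchedule, params: SimParams, seed: int) -> RawRecording:
    """Continuous event-marked recording for one participant.

    Every trial occupies a fixed 5 s slot (fixation + prime + ISI + full
    2 s target window + blank); the evoked template plus the
    condition-split effect are inserted at each target onset, on top of
    1/f background noise and Poisson-timed blinks projected through a
    frontal topography peaking at Fp1.
    """
    rng = np.random.default_rng(seed)
    sfreq = params.sfreq
    ch_names = list(params.ch_names)
    n_ch = len(ch_names)
    slot = int(round(TRIAL_LEN_S * sfreq))
    n_samples = slot * schedule.n_trials + int(round(2.0 * sfreq))

    if params.noise_sd > 0:
        data = one_over_f_noise(rng, (n_ch, n_samples), sfreq,
                                params.noise_sd, params.noise_exponent)
    else:
        data = np.zeros((n_ch, n_samples))

    # target onset within its slot: after fixation(+prime+ISI) for forward,
    # right after fixation for backward
    if schedule.experiment == "forward":
        target_off_ms = FIXATION_MS + PRIME_MS + ISI_MS
    else:
        target_off_ms = FIXATION_MS
    target_offset = int(round(target_off_ms / 1000.0 * sfreq))

    tmpl_offs = np.arange(0, int(round(EPOCH_TMAX * sfreq)) + 1)
    template = erp_template(tmpl_offs / sfreq, ch_names)
    effects = _effect_offsets(params, sfreq)

    events = []
    for t in schedule.trials:
        onset = t.index * slot + target_offset
        data[:, onset:onset + len(tmpl_offs)] += template
        sign = 0.5 if t.congruent else -0.5
        for ci, offs, amp in effects:
            data[ci, onset + offs] += sign * amp
        events.append((onset, t.index, CONGRUENT if t.congruent else INCONGRUENT))

    n_blinks = 0
    if params.blink_rate > 0 and params.blink_amplitude != 0:
        n_blinks = int(rng.poisson(params.blink_rate * n_samples / sfreq))
        blink_samples = np.sort(rng.integers(0, n_samples, size=n_blinks))
        topo = blink_topography(ch_names) * params.blink_amplitude
        half = int(round(0.2 * sfreq))
        tt = np.arange(-half, half + 1) / sfreq
        wave = np.exp(-0.5 * (tt / 0.05) ** 2)
        for s in blink_samples:
            lo, hi = max(0, s - half), min(n_samples, s + half + 1)
            data[:, lo:hi] += topo[:, None] * wave[lo - (s - half): hi - (s - half)]

    return RawRecording(data=data, sfreq=sfreq, ch_names=ch_names, events=events,
                        history=[{"step": "simulate_eeg", "seed": seed,
                                  "experiment": schedule.experiment,
                                  "n_blinks": n_blinks}])


def simulate_epochs(schedule: TrialSchedule, params: SimParams, seed: int) -> EpochSet:
    """Epoch-level shortcut: target-locked epochs without the continuous
    round trip (no blinks, no filtering) — template + split effect + 1/f
    noise drawn directly per trial. Used for replicate-heavy studies
    where the continuous path would dominate runtime.
    """
    rng = np.random.default_rng(seed)
    sfreq = params.sfreq
    ch_names = list(params.ch_names)
    times = epoch_times(sfreq)
    n_t = len(times)
    n_trials = schedule.n_trials

    template = erp_template(times, ch_names)
    data = np.broadcast_to(template, (n_trials, len(ch_names), n_t)).copy()

    labels = np.where(schedule.labels(), CONGRUENT, INCONGRUENT)
    signs = np.where(schedule.labels(), 0.5, -0.5)
    for el, start, end, amp in params.effect_spec:
        ci = channel_index(ch_names, el)
        mask = sample_window(times, sfreq, start, end)
        data[:, ci, mask] += signs[:, None] * amp

    if params.noise_sd > 0:
        data += one_over_f_noise(rng, (n_trials, len(ch_names), n_t), sfreq,
                                 params.noise_sd, params.noise_exponent)

    return EpochSet(data=data, times=times, sfreq=sfreq, ch_names=ch_names,
                    labels=labels, baseline=None,
                    history=[{"step": "simulate_epochs", "seed": seed}])


# ---------------------------------------------------------------------------
# questionnaires

_FMI_ITEMS = 14          # 4-point items; presence 6 + acceptance 8
_FMI_PRESENCE = 6
_BIS_ITEMS = 30          # 4-point items, sum in [30, 120]
_PEXE_FACTORS = 4        # 5 five-level items each
_ITEM_LOADING = 0.75


def _discretize(x: np.ndarray, n_levels: int) -> np.ndarray:
    """Map standard-normal values to 1..n_levels via equal-probability cuts."""
    from scipy.stats import norm
    cuts = norm.ppf(np.arange(1, n_levels) / n_levels)
    return 1 + np.searchsorted(cuts, x, side="right")


def simulate_questionnaires(n: int, latent_coupling: float = 0.0, seed: int = 0,
                            rt_deltas: np.ndarray = None) -> pd.DataFrame:
    """Questionnaire score table for ``n`` virtual participants.

    ``latent_coupling`` is the target correlation between the FMI
    (mindfulness) latent trait and the participants' realized RT
    congruency effects ``rt_deltas``; items load 0.75 on their latent and
    are discretized onto the questionnaire's Likert scale, so the
    observed sum-score correlation is mildly attenuated relative to the
    latent one.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if abs(latent_coupling) > 1:
        raise ValueError("|latent_coupling| must be <= 1")
    rng = np.random.default_rng(seed)

    if latent_coupling != 0.0:
        if rt_deltas is None:
            rt_deltas = rng.standard_normal(n)
        z_rt = (rt_deltas - np.mean(rt_deltas)) / (np.std(rt_deltas) or 1.0)
        fmi_latent = latent_coupling * z_rt + \
            np.sqrt(1 - latent_coupling**2) * rng.standard_normal(n)
    else:
        fmi_latent = rng.standard_normal(n)

    def items(latent, n_items, n_levels):
        e = rng.standard_normal((n, n_items))
        cont = _ITEM_LOADING * latent[:, None] + np.sqrt(1 - _ITEM_LOADING**2) * e
        return _discretize(cont, n_levels)

    fmi = items(fmi_latent, _FMI_ITEMS, 4)
    bis = items(rng.standard_normal(n), _BIS_ITEMS, 4)
    out = {
        "participant": np.arange(n),
        "fmi_presence": fmi[:, :_FMI_PRESENCE].sum(axis=1),
        "fmi_accept": fmi[:, _FMI_PRESENCE:].sum(axis=1),
        "fmi_sum": fmi.sum(axis=1),
        "bis_sum": bis.sum(axis=1),
    }
    for f in range(_PEXE_FACTORS):
        pexe = items(rng.standard_normal(n), 5, 5)
        out[f"pexe_f{f + 1}"] = pexe.sum(axis=1)
    return pd.DataFrame(out)
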