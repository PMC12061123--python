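"""ERPs, difference traces, running paired t-tests and exploratory
window selection.

The exploratory procedure: a paired t-test is run at every electrode ×
timepoint across participants (uncorrected by design — it generates
hypotheses, it does not test them); the electrode carrying the longest
contiguous run of p < α is selected together with that run's bounds;
the minimum p inside the run defines a reference time t*, and each
electrode is summarized by the median p over t* ± 10 ms, capped at 0.05
(the values behind a statistical topographic map).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channels import channel_index
from .containers import CONGRUENT, INCONGRUENT, EpochSet, sample_window
from scipy import stats


@dataclass
class ERPSet:
    """Per-participant condition means and their cohort summaries.

    cong/incong : (n_participants, n_channels, n_times) µV
    diff = cong − incong per participant; grand_* are means across
    participants, sem_* = sd/√n.
    """
    cong: np.ndarray
    incong: np.ndarray
    times: np.ndarray
    sfreq: float
    ch_names: list
    excluded: list = field(default_factory=list)

    @property
    def n_participants(self) -> int:
        return self.cong.shape[0]

    @property
    def diff(self) -> np.ndarray:
        return self.cong - self.incong

    def grand(self, condition: str) -> np.ndarray:
        return {CONGRUENT: self.cong, INCONGRUENT: self.incong}[condition].mean(axis=0)

    def grand_diff(self) -> np.ndarray:
        return self.diff.mean(axis=0)

    def sem_diff(self) -> np.ndarray:
        return self.diff.std(axis=0, ddof=1) / np.sqrt(self.n_participants)


@dataclass
class WindowSelection:
    electrode: str = None            # None → empty selection
    window_ms: tuple = None          # (start, end) ms, end inclusive sample
    length_ms: float = 0.0
    min_p: float = None
    min_p_time_ms: float = None
    tie_break: str = None

    @property
    def empty(self) -> bool:
        return self.electrode is None


@dataclass
class RunningTestResult:
    t_trace: np.ndarray              # channels × times
    p_trace: np.ndarray              # NaN where undefined (zero variance)
    d_trace: np.ndarray
    times: np.ndarray
    sfreq: float
    ch_names: list
    alpha: float = 0.05
    n: int = 0
    corrected: bool = False          # deliberately uncorrected


def participant_erps(epoch_sets: list, time_window: tuple = (0.0, 1.0)) -> ERPSet:
    """Average trials per condition per participant over the analysis
    window (target onset to +1000 ms by default). Participants missing a
    condition are excluded and listed in ``excluded``."""
    cong, incong, excluded = [], [], []
    ref = None
    for pid, ep in enumerate(epoch_sets):
        c = ep.condition_data(CONGRUENT)
        i = ep.condition_data(INCONGRUENT)
        if len(c) == 0 or len(i) == 0:
            excluded.append({"participant": pid,
                             "reason": "missing condition",
                             "n_congruent": len(c), "n_incongruent": len(i)})
            continue
        mask = sample_window(ep.times, ep.sfreq, time_window[0], time_window[1])
        # include the end point of the analysis window
        mask |= np.round(ep.times * ep.sfreq).astype(int) == int(round(time_window[1] * ep.sfreq))
        cong.append(c.mean(axis=0)[:, mask])
        incong.append(i.mean(axis=0)[:, mask])
        ref = ep
    if not cong:
        raise ValueError("no participant has trials in both conditions")
    times = ref.times[sample_window(ref.times, ref.sfreq, time_window[0], time_window[1]) |
                      (np.round(ref.times * ref.sfreq).astype(int)
                       == int(round(time_window[1] * ref.sfreq)))]
    return ERPSet(cong=np.array(cong), incong=np.array(incong), times=times,
                  sfreq=ref.sfreq, ch_names=list(ref.ch_names), excluded=excluded)


def running_ttest(erps: ERPSet, alpha: float = 0.05) -> RunningTestResult:
    """Paired t-test (two-sided) at every electrode × timepoint.

    Points where the across-participant differences have zero variance
    but a nonzero mean get p = NaN (undefined), never p = 0; such points
    break contiguous runs during window selection. No multiplicity
    correction is applied; the result records that fact.
    """
    n = erps.n_participants
    if n < 3:
        raise ValueError(f"running t-test needs >= 3 participants, got {n}")
    d = erps.diff                      # participants × channels × times
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        cohens_d = mean / sd
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    # all-zero differences are a genuine null: t = 0, p = 1; a nonzero
    # mean with zero variance is undefined, marked NaN (never p = 0)
    exact_null = (sd == 0) & (mean == 0)
    undefined = (sd == 0) & (mean != 0)
    t[exact_null], p[exact_null], cohens_d[exact_null] = 0.0, 1.0, 0.0
    t[undefined] = np.nan
    p[undefined] = np.nan
    cohens_d[undefined] = np.nan
    return RunningTestResult(t_trace=t, p_trace=p, d_trace=cohens_d,
                             times=erps.times, sfreq=erps.sfreq,
                             ch_names=list(erps.ch_names), alpha=alpha, n=n)


def _runs(mask: np.ndarray):
    """Yield (start, stop_exclusive) index pairs of True runs."""
    padded = np.concatenate([[False], mask, [False]])
    change = np.flatnonzero(padded[1:] != padded[:-1])
    return list(zip(change[::2], change[1::2]))


def select_longest_window(result: RunningTestResult) -> WindowSelection:
    """Across all electrodes, the longest contiguous run of p < α.

    Run length is measured in milliseconds so the outcome does not
    depend on the sampling rate. Ties go to the earlier-onset run, then
    to montage order; the applied tie-break is recorded. With no
    sub-alpha point anywhere the selection is empty (no exception).
    """
    best = WindowSelection()
    best_key = None
    for ci, ch in enumerate(result.ch_names):
        sub = result.p_trace[ci] < result.alpha      # NaN compares False
        for start, stop in _runs(sub):
            length_ms = (stop - start) * 1000.0 / result.sfreq
            onset_ms = result.times[start] * 1000.0
            key = (-length_ms, onset_ms, ci)
            if best_key is None or key < best_key:
                seg_p = result.p_trace[ci, start:stop]
                imin = int(np.nanargmin(seg_p))
                best = WindowSelection(
                    electrode=ch,
                    window_ms=(result.times[start] * 1000.0,
                               result.times[stop - 1] * 1000.0),
                    length_ms=length_ms,
                    min_p=float(seg_p[imin]),
                    min_p_time_ms=float(result.times[start + imin] * 1000.0),
                    tie_break="longest, then earlier onset, then montage order",
                )
                best_key = key
    return best


def summarize_window(result: RunningTestResult, selection: WindowSelection,
                     stat: str = "median", cap: float = 0.05) -> dict:
    """Per-electrode p summary in the ±10 ms neighbourhood of the
    selected minimum-p time, capped at ``cap``.

    The neighbourhood is centred on the *selected electrode's* t* for
    every electrode (one common time window). ``stat`` may be "median"
    (default) or "mean". NaN p-values count as above the cap.
    """
    if selection.empty:
        raise ValueError("cannot summarize an empty selection")
    if stat not in ("median", "mean"):
        raise ValueError("stat must be 'median' or 'mean'")
    t_star = selection.min_p_time_ms / 1000.0
    # all samples within ±10 ms of t*, inclusive at both ends
    mask = np.abs(result.times - t_star) <= 0.010 + 1e-9
    fn = np.nanmedian if stat == "median" else np.nanmean
    out = {}
    for ci, ch in enumerate(result.ch_names):
        seg = result.p_trace[ci, mask]
        val = cap if np.all(np.isnan(seg)) else float(fn(seg))
        out[ch] = float(min(val, cap))
    return out


def windowed_amplitude(erps: ERPSet, electrode: str, window: tuple) -> dict:
    """Mean of each participant's difference trace at ``electrode`` over
    ``window`` (seconds, half-open). Returns per-participant values plus
    the cohort mean ± sd."""
    ci = channel_index(erps.ch_names, electrode)
    start, end = window
    if start < erps.times[0] or end > erps.times[-1] + 1.0 / erps.sfreq:
        raise ValueError(f"window {window} outside epoch span "
                         f"({erps.times[0]}, {erps.times[-1]}) s")
    mask = sample_window(erps.times, erps.sfreq, start, end)
    if not mask.any():
        raise ValueError(f"window {window} contains no samples at sfreq {erps.sfreq}")
    per_participant = erps.diff[:, ci, mask].mean(axis=1)
    return {
        "electrode": electrode,
        "window_s": (float(start), float(end)),
        "per_participant": per_participant,
        "mean": float(per_participant.mean()),
        "sd": float(per_participant.std(ddof=1)) if len(per_participant) > 1 else 0.0,
    }
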