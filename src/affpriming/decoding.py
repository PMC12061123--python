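"""Per-participant single-trial decoding of congruent vs incongruent
epochs.

Protocol: trials are restricted to the 400–700 ms post-target window,
classes are balanced by seeded subsampling of the majority class, and a
4-fold cross-validation is run under 3 random seeds (per seed: fresh
shuffling, fold assignment and weight initialization), giving 12
held-out accuracies per participant. The reported summary is the mean
of the 12 (the per-seed fold means and the median are also kept).
Hyperparameters come from a 10-draw uniform random search over the
activation × filters × optimizer × learning-rate × loss space, scored
by the same CV protocol; note the search scores on the same folds it
selects on — a nested variant is available via ``nested=True``.

Per-channel standardization uses training-fold statistics only, so no
test-fold information leaks into training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import CONGRUENT, EpochSet, sample_window
from .nn import (ACTIVATIONS, LEARNING_RATES, LOSSES, N_FILTERS_CHOICES,
                 OPTIMIZERS, ConvNet, NetSpec)

DECODING_WINDOW = (0.400, 0.700)
N_FOLDS = 4
N_SEEDS = 3
DEFAULT_SEEDS = (11, 22, 33)         # arbitrary; config-exposed
N_SEARCH_DRAWS = 10


@dataclass
class AccuracyReport:
    participant: int
    experiment: str
    accuracies: np.ndarray           # 12 values: folds × seeds, fold-major per seed
    seeds: tuple
    spec: NetSpec
    n_trials_used: int

    @property
    def per_seed_means(self) -> np.ndarray:
        return self.accuracies.reshape(len(self.seeds), N_FOLDS).mean(axis=1)

    @property
    def summary(self) -> float:
        """Mean of the 12 fold × seed accuracies."""
        return float(np.mean(self.accuracies))

    @property
    def summary_median(self) -> float:
        return float(np.median(self.accuracies))

    def to_dict(self) -> dict:
        return {
            "participant": self.participant,
            "experiment": self.experiment,
            "accuracies": [float(a) for a in self.accuracies],
            "per_seed_means": [float(a) for a in self.per_seed_means],
            "summary": self.summary,
            "summary_median": self.summary_median,
            "seeds": list(self.seeds),
            "spec": vars(self.spec) | {},
            "n_trials_used": self.n_trials_used,
        }


def extract_decoding_tensor(epochs: EpochSet, window: tuple = DECODING_WINDOW):
    """Slice epochs to the half-open decoding window; labels are 1 for
    congruent, 0 for incongruent."""
    mask = sample_window(epochs.times, epochs.sfreq, window[0], window[1])
    if not mask.any():
        raise ValueError(f"window {window} is empty at sfreq {epochs.sfreq}")
    x = epochs.data[:, :, mask]
    y = (epochs.labels == CONGRUENT).astype(int)
    return x, y


def balance_classes(labels: np.ndarray, seed: int = 0) -> np.ndarray:
    """Indices of a class-balanced subset: the majority class is randomly
    subsampled (seeded) to the minority count. Order is preserved."""
    labels = np.asarray(labels)
    ones = np.flatnonzero(labels == 1)
    zeros = np.flatnonzero(labels == 0)
    if len(ones) == 0 or len(zeros) == 0:
        raise ValueError("both classes must be present to balance")
    rng = np.random.default_rng(seed)
    k = min(len(ones), len(zeros))
    keep_ones = ones if len(ones) == k else np.sort(rng.choice(ones, k, replace=False))
    keep_zeros = zeros if len(zeros) == k else np.sort(rng.choice(zeros, k, replace=False))
    return np.sort(np.concatenate([keep_ones, keep_zeros]))


def stratified_folds(labels: np.ndarray, n_folds: int, seed: int):
    """Fold assignment with exactly 50/50 classes in every train and test
    split. Per class, trial counts are truncated (seeded) to a multiple
    of ``n_folds``; the dropped remainder is returned for the log."""
    rng = np.random.default_rng(seed)
    folds = [[] for _ in range(n_folds)]
    dropped = []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        perm = rng.permutation(idx)
        per_fold = len(idx) // n_folds
        for f in range(n_folds):
            folds[f].extend(perm[f * per_fold:(f + 1) * per_fold])
        dropped.extend(perm[n_folds * per_fold:])
    return [np.sort(np.array(f, dtype=int)) for f in folds], np.array(dropped, dtype=int)


def _standardize(train: np.ndarray, test: np.ndarray):
    """Per-channel z-scoring with training-fold statistics only."""
    mean = train.mean(axis=(0, 2), keepdims=True)
    sd = train.std(axis=(0, 2), keepdims=True)
    sd[sd == 0] = 1.0
    return (train - mean) / sd, (test - mean) / sd


def train_eval_cv(x: np.ndarray, y: np.ndarray, spec: NetSpec,
                  seeds: tuple = DEFAULT_SEEDS, n_folds: int = N_FOLDS,
                  participant: int = 0, experiment: str = "forward") -> AccuracyReport:
    """The 4-fold × 3-seed protocol on balanced data.

    For each seed, trials are re-assigned to folds and the network is
    re-initialized; each fold is the held-out test set exactly once.
    """
    y = np.asarray(y)
    if min((y == 0).sum(), (y == 1).sum()) < n_folds:
        raise ValueError(f"need at least {n_folds} trials per class")
    accuracies = []
    for seed in seeds:
        folds, _ = stratified_folds(y, n_folds, seed)
        for f, test_idx in enumerate(folds):
            train_idx = np.concatenate([folds[g] for g in range(n_folds) if g != f])
            xtr, xte = _standardize(x[train_idx], x[test_idx])
            net = ConvNet(spec, x.shape[1], x.shape[2], seed=seed + 1000 * f)
            net.fit(xtr, y[train_idx], seed=seed + 1000 * f)
            accuracies.append(net.accuracy(xte, y[test_idx]))
    return AccuracyReport(participant=participant, experiment=experiment,
                          accuracies=np.array(accuracies), seeds=tuple(seeds),
                          spec=spec, n_trials_used=len(y))


def sample_specs(n_draws: int, seed: int, epochs: int = 80, batch_size: int = 32) -> list:
    """Uniform seeded draws from the search space."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(n_draws):
        specs.append(NetSpec(
            activation=str(rng.choice(ACTIVATIONS)),
            n_filters=int(rng.choice(N_FILTERS_CHOICES)),
            optimizer=str(rng.choice(OPTIMIZERS)),
            learning_rate=float(rng.choice(LEARNING_RATES)),
            loss=str(rng.choice(LOSSES)),
            epochs=epochs, batch_size=batch_size,
        ))
    return specs


def random_search(x: np.ndarray, y: np.ndarray, n_draws: int = N_SEARCH_DRAWS,
                  seed: int = 0, seeds: tuple = DEFAULT_SEEDS, epochs: int = 80,
                  batch_size: int = 32, participant: int = 0,
                  experiment: str = "forward"):
    """Evaluate ``n_draws`` sampled specs with the CV protocol; return
    (best report, leaderboard sorted best-first)."""
    specs = sample_specs(n_draws, seed, epochs=epochs, batch_size=batch_size)
    leaderboard = []
    for spec in specs:
        report = train_eval_cv(x, y, spec, seeds=seeds,
                               participant=participant, experiment=experiment)
        leaderboard.append(report)
    leaderboard.sort(key=lambda r: r.summary, reverse=True)
    return leaderboard[0], leaderboard


def decode_participant(epochs: EpochSet, window: tuple = DECODING_WINDOW,
                       spec: NetSpec = None, balance_seed: int = 0,
                       seeds: tuple = DEFAULT_SEEDS, participant: int = 0,
                       experiment: str = "forward", search_draws: int = 0,
                       search_seed: int = 0) -> AccuracyReport:
    """End-to-end per-participant decoding: window extraction, class
    balancing, then either a fixed ``spec`` or a random search."""
    x, y = extract_decoding_tensor(epochs, window)
    keep = balance_classes(y, seed=balance_seed)
    x, y = x[keep], y[keep]
    if search_draws:
        best, _ = random_search(x, y, n_draws=search_draws, seed=search_seed,
                                seeds=seeds, epochs=(spec or NetSpec()).epochs,
                                batch_size=(spec or NetSpec()).batch_size,
                                participant=participant, experiment=experiment)
        return best
    spec = spec or NetSpec()
    return train_eval_cv(x, y, spec, seeds=seeds, participant=participant,
                         experiment=experiment)
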