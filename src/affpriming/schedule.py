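"""Trial schedules for the forward and backward affective-priming tasks.

Each experiment runs ``n_trials`` priming trials split into blocks of 36
(plus one remainder block). The target image's valence is exactly
balanced across the experiment (half positive, half negative, order
permuted), while the prime word's valence is an independent fair coin per
trial — so the congruent/incongruent split is random around 50%, not
forced. A trial is *congruent* when prime and target share valence.

Forward trials run fixation (1200 ms) → prime (500 ms) → ISI (300 ms) →
target (up to 2000 ms) → blank (1000 ms); backward trials present the
target first and the prime after the response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FIXATION_MS = 1200.0
PRIME_MS = 500.0
ISI_MS = 300.0
TARGET_MAX_MS = 2000.0
BLANK_MS = 1000.0
BLOCK_SIZE = 36


@dataclass(frozen=True)
class TrialRecord:
    index: int
    block: int
    prime_valence: str        # "pos" | "neg"
    target_valence: str       # "pos" | "neg"
    congruent: bool
    # onset of each event in ms from trial start; target duration is the
    # response time, so only onsets up to the target are fixed a priori
    onset_times: dict = field(default_factory=dict)


@dataclass(frozen=True)
class TrialSchedule:
    trials: tuple
    experiment: str           # "forward" | "backward"
    seed: int

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def block_sizes(self) -> list[int]:
        sizes: dict[int, int] = {}
        for t in self.trials:
            sizes[t.block] = sizes.get(t.block, 0) + 1
        return [sizes[b] for b in sorted(sizes)]

    def congruent_fraction(self) -> float:
        return float(np.mean([t.congruent for t in self.trials]))

    def labels(self) -> np.ndarray:
        """Boolean congruency labels in trial order."""
        return np.array([t.congruent for t in self.trials], dtype=bool)


def _event_onsets(experiment: str) -> dict:
    """Fixed within-trial event onsets (ms); target end depends on the RT."""
    if experiment == "forward":
        prime_on = FIXATION_MS
        target_on = prime_on + PRIME_MS + ISI_MS
        return {
            "fixation": 0.0,
            "prime": prime_on,
            "isi": prime_on + PRIME_MS,
            "target": target_on,
        }
    # backward: target directly after fixation; ISI and prime follow the
    # response, so their onsets are relative to target offset (filled in
    # by the simulator once the RT is known)
    return {"fixation": 0.0, "target": FIXATION_MS}


def make_schedule(experiment: str, n_trials: int = 400, seed: int = 0) -> TrialSchedule:
    """Generate a reproducible trial schedule.

    Parameters
    ----------
    experiment : {"forward", "backward"}
    n_trials : even trial count (default 400 → blocks of 11×36 + 1×4).
    seed : RNG seed; the same seed yields bit-identical schedules, and
        forward/backward schedules with the same seed share identical
        prime/target valence sequences.
    """
    if experiment not in ("forward", "backward"):
        raise ValueError(f"experiment must be 'forward' or 'backward', got {experiment!r}")
    if n_trials <= 0 or n_trials % 2 != 0:
        raise ValueError(f"n_trials must be even and positive to balance target valences, got {n_trials}")

    rng = np.random.default_rng(seed)
    targets = np.array(["pos"] * (n_trials // 2) + ["neg"] * (n_trials // 2))
    rng.shuffle(targets)
    primes = np.where(rng.random(n_trials) < 0.5, "pos", "neg")

    onsets = _event_onsets(experiment)
    trials = tuple(
        TrialRecord(
            index=i,
            block=i // BLOCK_SIZE,
            prime_valence=str(primes[i]),
            target_valence=str(targets[i]),
            congruent=bool(primes[i] == targets[i]),
            onset_times=dict(onsets),
        )
        for i in range(n_trials)
    )
    return TrialSchedule(trials=trials, experiment=experiment, seed=seed)
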