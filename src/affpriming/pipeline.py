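"""End-to-end pipeline tying the stages together for a synthetic cohort.

``run_pipeline`` executes, per experiment: behavioural simulation →
validity filtering → median contrasts → paired tests; epoch-level EEG
simulation per participant → per-participant ERPs → running t-tests →
longest-window selection → topographic p summary → windowed amplitudes;
optional per-participant decoding; questionnaire simulation →
correlations. All randomness flows from ``config.seed``; identical
configs yield identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import behaviour, decoding, erp
from .config import RunConfig
from .simulate import (SimParams, make_schedule, simulate_cohort_rt,
                       simulate_epochs, simulate_questionnaires)


class StageError(RuntimeError):
    def __init__(self, stage, experiment, participant=None, cause=None):
        msg = f"stage {stage!r} failed for experiment {experiment!r}"
        if participant is not None:
            msg += f", participant {participant}"
        super().__init__(f"{msg}: {cause}")
        self.stage, self.experiment, self.participant = stage, experiment, participant


def _sim_params(config: RunConfig, experiment: str) -> SimParams:
    params = SimParams(**config.sim)
    if config.inject_default_effects and not params.effect_spec:
        params = params.with_effects(experiment)
    return params


def run_experiment(config: RunConfig, experiment: str) -> dict:
    rng = np.random.default_rng([config.seed, {"forward": 1, "backward": 2}[experiment]])
    params = _sim_params(config, experiment)
    bundle = {"experiment": experiment, "provenance": config.provenance()}

    # behaviour ------------------------------------------------------------
    try:
        log, deltas = simulate_cohort_rt(config.n_participants, experiment, params,
                                         seed=int(rng.integers(2**31)),
                                         n_trials=config.n_trials)
        valid, exclusions = behaviour.filter_valid(log)
        contrasts = behaviour.rt_contrast(valid)
        ok = contrasts[~contrasts["excluded"]]
        tests = behaviour.paired_tests(ok["difference"].to_numpy(), sided=config.sided)
        bundle["behaviour"] = {
            "exclusions": exclusions,
            "contrasts": contrasts.to_dict(orient="records"),
            "tests": dataclasses.asdict(tests),
        }
    except Exception as e:                                    # noqa: BLE001
        raise StageError("behaviour", experiment, cause=e) from e

    # erp ------------------------------------------------------------------
    try:
        epoch_sets = []
        for p in range(config.n_participants):
            sched = make_schedule(experiment, config.n_trials,
                                  seed=int(rng.integers(2**31)))
            epoch_sets.append(simulate_epochs(sched, params,
                                              seed=int(rng.integers(2**31))))
        erps = erp.participant_erps(epoch_sets)
        running = erp.running_ttest(erps, alpha=config.alpha)
        selection = erp.select_longest_window(running)
        bundle["erp"] = {
            "selection": dataclasses.asdict(selection),
            "n_participants": erps.n_participants,
        }
        if not selection.empty:
            bundle["erp"]["topographic_p"] = erp.summarize_window(
                running, selection, stat=config.erp_summary)
            amp = erp.windowed_amplitude(
                erps, selection.electrode,
                (selection.window_ms[0] / 1000.0, selection.window_ms[1] / 1000.0))
            bundle["erp"]["windowed_amplitude"] = {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in amp.items()}
    except Exception as e:                                    # noqa: BLE001
        raise StageError("erp", experiment, cause=e) from e

    # classifier -----------------------------------------------------------
    if config.run_classifier:
        reports = []
        for p, ep in enumerate(epoch_sets):
            try:
                spec = decoding.NetSpec(epochs=config.net_epochs,
                                        batch_size=config.net_batch_size)
                report = decoding.decode_participant(
                    ep, spec=spec, balance_seed=int(rng.integers(2**31)),
                    seeds=config.cv_seeds, participant=p, experiment=experiment,
                    search_draws=config.search_draws,
                    search_seed=int(rng.integers(2**31)))
                reports.append(report.to_dict())
            except Exception as e:                            # noqa: BLE001
                raise StageError("classifier", experiment, participant=p, cause=e) from e
        bundle["classifier"] = {
            "reports": reports,
            "mean_summary": float(np.mean([r["summary"] for r in reports])),
        }

    # questionnaires + correlations ---------------------------------------
    try:
        scores = simulate_questionnaires(config.n_participants,
                                         latent_coupling=config.latent_coupling,
                                         seed=int(rng.integers(2**31)),
                                         rt_deltas=deltas)
        merged = scores.merge(ok[["participant", "difference"]], on="participant")
        correlations = {}
        for col in ("fmi_presence", "fmi_accept", "fmi_sum", "bis_sum"):
            r = behaviour.correlate(merged[col], merged["difference"],
                                    x_label=col, y_label="rt_difference")
            correlations[col] = dataclasses.asdict(r)
        bundle["questionnaires"] = {
            "scores": scores.to_dict(orient="records"),
            "correlations_with_rt_difference": correlations,
        }
    except Exception as e:                                    # noqa: BLE001
        raise StageError("correlate", experiment, cause=e) from e

    return bundle


def run_pipeline(config: RunConfig) -> dict:
    bundle = {"provenance": config.provenance(),
              "experiments": {exp: run_experiment(config, exp)
                              for exp in config.experiments}}
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "results.json").write_text(
            json.dumps(bundle, indent=1, default=float), encoding="utf-8")
    return bundle
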