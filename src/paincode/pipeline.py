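"""End-to-end driver: simulate (or load) data, run every analysis stage,
write tables and a machine-readable summary.

The pipeline mirrors the study design: mixed two-intensity recording
sessions analysed per regime (naive ``pre_cfa`` vs chronic-pain ``post_cfa``),
responsive-unit classification, peak-response tuning fits with a slope
comparison, population decoding with permutation chance levels, and the
behavioral assays (place-aversion cohorts and up-down thresholds).  Every
randomized stage receives its own child seed spawned from the root seed, so
reruns with the same configuration are reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import (cpa_score_for_stimulus, filter_cpa_baseline,
                       summarize_cpa, updown_50pct_threshold, withdrawal_summary)
from .config import PipelineConfig, spawn_seeds
from .decoding import (aggregate_sessions, build_cumulative_features,
                       evaluate_decoder, permutation_chance)
from .io import write_behavior_table, write_sessions
from .psth import filter_low_rate_units, session_psth
from .responsive import classify_responsive, identify_intensity_coding
from .synth import (GeneratorConfig, generate_cpa_cohort, generate_mixed_session,
                    simulate_updown_sequence)
from .tuning import compare_slopes, extract_peak_pairs, fit_tuning_from_pairs

# mean seconds of avoidance conditioned into the synthetic place-aversion
# cohorts: chronic pain amplifies the response to the low stimulus and
# erases the extra aversion of the high stimulus
DEFAULT_CPA_EFFECTS = {
    "LS": {"saline": 80.0, "cfa": 170.0},     # LS conditioned against NS
    "HS": {"saline": 120.0, "cfa": 30.0},     # HS conditioned against LS
}
VONFREY_TRUE_THRESHOLDS_G = {"saline": 8.0, "cfa": 1.5}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:         # noqa: BLE001 - rewrap with stage name
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


@_stage("simulate")
def _simulate(config: PipelineConfig, gen: GeneratorConfig, n_sessions: int,
              seed: int) -> dict:
    sessions = {}
    seeds = spawn_seeds(seed, 2 * n_sessions)
    for r, regime in enumerate(("pre_cfa", "post_cfa")):
        cfg = dataclasses.replace(gen, tuning_regime=regime)
        sessions[regime] = [
            generate_mixed_session(cfg, ("LS", "HS"), seed=seeds[r * n_sessions + i],
                                  session_id=f"{regime}_s{i}")
            for i in range(n_sessions)
        ]
    return sessions


@_stage("responsive")
def _responsive(config: PipelineConfig, sessions: dict) -> tuple[pd.DataFrame, dict]:
    rows, responsive_by_regime = [], {}
    for regime, sess_list in sessions.items():
        responsive_units: list[str] = []
        for sess in sess_list:
            psth_hs = session_psth(sess, "HS", config.psth_bin_size_s,
                                   config.baseline_sd_mode)
            for res in classify_responsive(
                    psth_hs, thresholds=(config.z_threshold_abs,
                                         config.z_threshold_lower)):
                rows.append({"regime": regime, "session_id": sess.session_id,
                             "unit_id": res.unit_id,
                             "is_responsive": res.is_responsive,
                             "indeterminate": res.indeterminate,
                             "n_bins_c1": len(res.bins_criterion_1),
                             "n_bins_c2": len(res.bins_criterion_2)})
                if res.is_responsive:
                    responsive_units.append(res.unit_id)
        responsive_by_regime[regime] = responsive_units
    return pd.DataFrame(rows), responsive_by_regime


@_stage("intensity_coding")
def _intensity(config: PipelineConfig, sessions: dict,
               responsive_by_regime: dict) -> pd.DataFrame:
    rows = []
    for regime, sess_list in sessions.items():
        for sess in sess_list:
            res = identify_intensity_coding(
                responsive_by_regime[regime], sess, sess, alpha=config.alpha,
                pairing=config.pairing, bin_size_s=config.psth_bin_size_s)
            for r in res:
                rows.append({"regime": regime, "session_id": sess.session_id,
                             "unit_id": r.unit_id, "hs_gt_ls": r.hs_gt_ls,
                             "t_statistic": r.t_statistic, "p_value": r.p_value,
                             "ls_mean_peak": r.ls_mean_peak,
                             "hs_mean_peak": r.hs_mean_peak})
    return pd.DataFrame(rows)


@_stage("tuning")
def _tuning(config: PipelineConfig, sessions: dict) -> tuple[pd.DataFrame, dict]:
    pairs_frames, fits = [], {}
    for regime, sess_list in sessions.items():
        frames = []
        for sess in sess_list:
            psth_ls = session_psth(sess, "LS", config.psth_bin_size_s,
                                   config.baseline_sd_mode)
            psth_hs = session_psth(sess, "HS", config.psth_bin_size_s,
                                   config.baseline_sd_mode)
            frames.append(extract_peak_pairs(psth_ls, psth_hs))
        pairs = pd.concat(frames, ignore_index=True)
        pairs.insert(0, "regime", regime)
        pairs_frames.append(pairs)
        if len(pairs) >= 3:
            fits[regime] = fit_tuning_from_pairs(pairs)
    out = {"fits": {k: dataclasses.asdict(v) for k, v in fits.items()}}
    if set(fits) == {"pre_cfa", "post_cfa"}:
        cmp = compare_slopes(fits["pre_cfa"], fits["post_cfa"])
        out["slope_comparison"] = dataclasses.asdict(cmp)
    return pd.concat(pairs_frames, ignore_index=True), out


@_stage("decoding")
def _decoding(config: PipelineConfig, sessions: dict, seed: int) -> tuple[pd.DataFrame, dict]:
    rows, summary = [], {}
    seeds = spawn_seeds(seed, 2 * sum(len(v) for v in sessions.values()))
    k = 0
    for regime, sess_list in sessions.items():
        results = []
        for sess in sess_list:
            feats = build_cumulative_features(sess, config.decode_bin_size_s,
                                              config.window_s)
            res = evaluate_decoder(feats, folds=config.cv_folds,
                                   mc_repeats=config.mc_repeats, seed=seeds[k],
                                   kernel=config.svm_kernel, degree=config.svm_degree,
                                   coef0=config.svm_coef0, c=config.svm_c)
            res.chance_mean = permutation_chance(
                feats, n_permutations=config.n_permutations, folds=config.cv_folds,
                seed=seeds[k + 1], kernel=config.svm_kernel,
                degree=config.svm_degree, coef0=config.svm_coef0, c=config.svm_c)
            k += 2
            results.append(res)
            for b in range(len(res.accuracy_mean)):
                rows.append({"regime": regime, "session_id": sess.session_id,
                             "bin_start_s": b * config.decode_bin_size_s,
                             "accuracy_mean": res.accuracy_mean[b],
                             "accuracy_sem": res.accuracy_sem[b],
                             "chance_mean": res.chance_mean[b]})
        summary[regime] = aggregate_sessions(results, config.min_units_per_session)
        chance = np.mean([r.chance_mean for r in results], axis=0)
        summary[regime]["chance_mean_overall"] = float(np.mean(chance))
    return pd.DataFrame(rows), summary


@_stage("behavior")
def _behavior(gen: GeneratorConfig, seed: int, n_animals: int) -> tuple[pd.DataFrame, dict]:
    seeds = spawn_seeds(seed, 8)
    summary: dict = {"cpa": {}, "vonfrey": {}}
    score_rows = []
    si = 0
    for stim, paired_vs in (("LS", "NS"), ("HS", "LS")):
        for group in ("saline", "cfa"):
            effect = DEFAULT_CPA_EFFECTS[stim][group]
            cohort = generate_cpa_cohort(gen, n_animals, effect, seed=seeds[si],
                                         group=f"{group}_{stim}",
                                         paired=(stim, paired_vs))
            si += 1
            kept, excluded = filter_cpa_baseline(cohort)
            for rec in kept:
                score_rows.append({"group": rec.group, "animal_id": rec.animal_id,
                                   "stimulus": stim,
                                   "cpa_score_s": cpa_score_for_stimulus(rec, stim)})
            entry = summarize_cpa(kept, stim) if kept else {"n": 0}
            entry["n_excluded_baseline"] = len(excluded)
            summary["cpa"][f"{group}_{stim}"] = entry
    rng_seeds = spawn_seeds(seeds[si], 2 * n_animals)
    for g, group in enumerate(("saline", "cfa")):
        thr = [updown_50pct_threshold(simulate_updown_sequence(
                   VONFREY_TRUE_THRESHOLDS_G[group], seed=rng_seeds[g * n_animals + i],
                   response_sd_log=0.05))
               for i in range(n_animals)]
        thr = np.asarray(thr)
        summary["vonfrey"][group] = {
            "threshold_mean_g": float(thr.mean()),
            "threshold_sem_g": float(thr.std(ddof=1) / np.sqrt(len(thr))),
            "n": int(len(thr)),
        }
    return pd.DataFrame(score_rows), summary


def run_pipeline(config: PipelineConfig, gen: GeneratorConfig | None = None,
                 out_dir: str | Path = "results/pipeline", n_sessions: int = 3,
                 n_animals: int = 12) -> dict:
    """Run every stage on synthetic data and write the report bundle.

    Writes ``spikes.csv``/``trials.csv``, per-stage tables and
    ``summary.json`` under ``out_dir`` and returns the summary dict.
    """
    gen = gen or GeneratorConfig(rng_seed=config.rng_seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_seeds = spawn_seeds(config.rng_seed, 4)

    sessions = _simulate(config, gen, n_sessions, stage_seeds[0])
    flat = [s for lst in sessions.values() for s in lst]
    write_sessions(flat, out / "spikes.csv", out / "trials.csv")

    sessions = {regime: [filter_low_rate_units(s, config.min_peak_rate_hz,
                                               config.psth_bin_size_s)
                         for s in lst]
                for regime, lst in sessions.items()}

    resp_table, responsive_by_regime = _responsive(config, sessions)
    resp_table.to_csv(out / "responsiveness.csv", index=False)
    intensity_table = _intensity(config, sessions, responsive_by_regime)
    intensity_table.to_csv(out / "intensity_coding.csv", index=False)
    pairs_table, tuning_summary = _tuning(config, sessions)
    pairs_table.to_csv(out / "tuning_pairs.csv", index=False)
    decode_table, decode_summary = _decoding(config, sessions, stage_seeds[1])
    decode_table.to_csv(out / "decoding_curve.csv", index=False)
    cpa_table, behavior_summary = _behavior(gen, stage_seeds[2], n_animals)
    cpa_table.to_csv(out / "cpa_scores.csv", index=False)
    withdrawal = withdrawal_summary(
        pd.concat([s.trials for s in sessions["pre_cfa"]], ignore_index=True))
    withdrawal.to_csv(out / "withdrawal_summary.csv", index=False)

    summary = {
        "versions": {"paincode": __version__, "python": platform.python_version()},
        "config": config.to_dict(),
        "generator": {k: v for k, v in dataclasses.asdict(gen).items()},
        "stage_seeds": stage_seeds,
        "n_units_analysed": {r: int(sum(s.n_units for s in lst))
                             for r, lst in sessions.items()},
        "n_responsive": {r: len(set(u)) for r, u in responsive_by_regime.items()},
        "n_intensity_coding": {
            r: int(intensity_table.query("regime == @r")["hs_gt_ls"].sum())
            if len(intensity_table) else 0
            for r in sessions},
        "tuning": tuning_summary,
        "decoding": decode_summary,
        "behavior": behavior_summary,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
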