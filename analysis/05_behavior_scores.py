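#!/usr/bin/env python
"""Behavioral readouts: place-aversion scores, withdrawal, and thresholds.

Filters the simulated place-aversion cohorts by baseline side bias, scores
chamber avoidance per group, compares chronic-pain vs control groups, and
estimates up-down 50% withdrawal thresholds for simulated animals.  Writes
results/behavior_summary.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from paincode import (compare_groups, cpa_score_for_stimulus,
                      filter_cpa_baseline, read_behavior_table, read_sessions,
                      simulate_updown_sequence, updown_50pct_threshold,
                      withdrawal_summary)
from paincode.config import spawn_seeds
from paincode.pipeline import VONFREY_TRUE_THRESHOLDS_G

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 515


def main() -> None:
    records = read_behavior_table(ROOT / "data" / "behavior.csv")
    kept, excluded = filter_cpa_baseline(records)
    print(f"baseline filter: kept {len(kept)}/{len(records)} animals "
          f"({len(excluded)} with side bias outside 100-500 s)")

    summary = {"n_excluded_baseline": len(excluded), "cpa": {}}
    scores = {}
    for rec in kept:
        stim = rec.group.split("_")[1]
        scores.setdefault(rec.group, []).append(cpa_score_for_stimulus(rec, stim))
    for group, vals in sorted(scores.items()):
        summary["cpa"][group] = {
            "mean_s": float(np.mean(vals)),
            "sem_s": float(np.std(vals, ddof=1) / np.sqrt(len(vals))),
            "n": len(vals)}
    for stim, direction in (("LS", "higher"), ("HS", "lower")):
        cmp = compare_groups(scores[f"cfa_{stim}"], scores[f"saline_{stim}"])
        summary["cpa"][f"cfa_vs_saline_{stim}"] = cmp
        print(f"{stim} aversion, chronic pain vs control: "
              f"{cmp['mean_a']:.0f} vs {cmp['mean_b']:.0f} s "
              f"(expected {direction} with chronic pain; p={cmp['p_value']:.4f})")

    trials = pd.read_csv(ROOT / "data" / "trials.csv")
    wd = withdrawal_summary(trials)
    wd.to_csv(ROOT / "withdrawal_summary.csv", index=False)
    wd = wd.set_index("stimulus")
    print(f"withdrawal latency: HS {wd.loc['HS', 'latency_mean_s']:.2f} s < "
          f"LS {wd.loc['LS', 'latency_mean_s']:.2f} s")

    seeds = spawn_seeds(SEED, 24)
    summary["vonfrey"] = {}
    for g, group in enumerate(("saline", "cfa")):
        thr = [updown_50pct_threshold(simulate_updown_sequence(
                   VONFREY_TRUE_THRESHOLDS_G[group], seed=seeds[g * 12 + i],
                   response_sd_log=0.05)) for i in range(12)]
        summary["vonfrey"][group] = {"mean_g": float(np.mean(thr)),
                                     "sem_g": float(np.std(thr, ddof=1)
                                                    / np.sqrt(len(thr))),
                                     "n": len(thr)}
        print(f"50% withdrawal threshold ({group}): "
              f"{np.mean(thr):.2f} +/- {np.std(thr, ddof=1)/np.sqrt(len(thr)):.2f} g")

    with open(ROOT / "behavior_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)


if __name__ == "__main__":
    main()
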