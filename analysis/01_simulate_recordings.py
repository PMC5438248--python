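#!/usr/bin/env python
"""Simulate the study's recording and behavior datasets.

Generates mixed low/high-intensity (LS/HS) spike sessions for the naive
(pre_cfa) and chronic-pain (post_cfa) regimes, plus place-aversion cohorts,
and writes them as CSV under results/data/ for the downstream scripts.
"""

from pathlib import Path

from paincode import (GeneratorConfig, generate_cpa_cohort,
                      generate_mixed_session, write_behavior_table,
                      write_sessions)
from paincode.config import spawn_seeds
from paincode.pipeline import DEFAULT_CPA_EFFECTS

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 2026
N_SESSIONS = 6


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    seeds = spawn_seeds(SEED, 2 * N_SESSIONS + 4)
    sessions = []
    for r, regime in enumerate(("pre_cfa", "post_cfa")):
        for i in range(N_SESSIONS):
            cfg = GeneratorConfig(tuning_regime=regime, rng_seed=SEED)
            sessions.append(generate_mixed_session(
                cfg, ("LS", "HS"), seed=seeds[r * N_SESSIONS + i],
                session_id=f"{regime}_s{i}"))
    write_sessions(sessions, OUT / "spikes.csv", OUT / "trials.csv")
    n_spikes = sum(len(s.spikes) for s in sessions)
    print(f"wrote {len(sessions)} sessions ({n_spikes} spikes) to {OUT}")

    cohorts = []
    k = 2 * N_SESSIONS
    for stim, vs in (("LS", "NS"), ("HS", "LS")):
        for group in ("saline", "cfa"):
            cohorts += generate_cpa_cohort(
                GeneratorConfig(rng_seed=SEED), 14,
                DEFAULT_CPA_EFFECTS[stim][group], seed=seeds[k],
                group=f"{group}_{stim}", paired=(stim, vs))
            k += 1
    write_behavior_table(cohorts, OUT / "behavior.csv")
    print(f"wrote {len(cohorts)} place-aversion records to {OUT / 'behavior.csv'}")


if __name__ == "__main__":
    main()
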