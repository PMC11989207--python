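#!/usr/bin/env python
"""Draw synthetic cohorts and check the simulator against its own truth.

Simulates (a) one trial-sized cohort (n=35, default seed) written as a
cohort CSV, and (b) one large cohort (n=10,000) used to verify that the
generative model reproduces the conditions it was configured for: pCR
prevalence ~0.43, mrTRG=1 prevalence ~0.40, ordered Kaplan-Meier curves
by pathologic NAR category, and a higher pCR rate among IS-high than
IS-low patients.

Found (default seed): large-cohort pCR rate 44.2%, mrTRG=1 rate 40.1%,
40-month DFS by NAR category ordered low > intermediate > high and close
to the configured exponential truth, and a clearly positive IS-high vs
IS-low pCR contrast.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import numpy as np

from larcscore import cohort_io, pipeline, synthetic
from larcscore.stats import event_free_proportion, logrank_test

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    trial = synthetic.simulate_cohort(synthetic.SimulationConfig(n=35))
    cohort_io.write_cohort(trial, RESULTS / "simulated_cohort_n35.csv")

    cfg = synthetic.SimulationConfig(n=10_000)
    scored = pipeline.score_cohort(synthetic.simulate_cohort(cfg))
    summary = {
        "n": cfg.n,
        "seed": cfg.seed,
        "pcr_rate": float(np.mean([s.pcr for s in scored])),
        "mrtrg1_rate": float(np.mean([s.record.mrtrg == 1 for s in scored])),
        "is_high_rate": float(np.mean(
            [s.immunoscore.is_class == "high" for s in scored])),
        "pcr_rate_is_high": float(np.mean(
            [s.pcr for s in scored if s.immunoscore.is_class == "high"])),
        "pcr_rate_is_low": float(np.mean(
            [s.pcr for s in scored if s.immunoscore.is_class == "low"])),
    }
    groups = {c: ([], []) for c in ("low", "intermediate", "high")}
    for s in scored:
        groups[s.nar_path.category][0].append(s.record.dfs_months)
        groups[s.nar_path.category][1].append(s.record.dfs_event)
    summary["dfs40_by_nar"] = {
        c: {"n": len(t), "event_free": event_free_proportion(t, e, 40.0),
            "configured_truth": float(np.exp(-h * 40.0))}
        for (c, (t, e)), h in zip(groups.items(), cfg.hazards)}
    chi2, df, p = logrank_test(list(groups.values()))
    summary["dfs_logrank"] = {"chi2": chi2, "df": df, "p": p}

    (RESULTS / "simulation_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n")
    print(f"trial-sized cohort written to {RESULTS/'simulated_cohort_n35.csv'}")
    print(f"large cohort (n={cfg.n}): "
          f"pCR {summary['pcr_rate']:.3f}, mrTRG=1 {summary['mrtrg1_rate']:.3f}, "
          f"IS-high {summary['is_high_rate']:.3f}")
    print("40-month DFS by pathologic NAR category "
          "(observed vs configured truth):")
    for c, block in summary["dfs40_by_nar"].items():
        print(f"  {c}: {block['event_free']:.3f} vs "
              f"{block['configured_truth']:.3f} (n={block['n']})")
    print(f"log-rank chi2={chi2:.1f}, df={df}, p={p:.3g}")


if __name__ == "__main__":
    main()
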