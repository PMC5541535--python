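#!/usr/bin/env python
"""Recovery study: how well does the pipeline re-identify planted structure?

Runs the full inference chain on replicate simulations of the four named
influence scenarios and scores each replicate against ground truth:
sign recall of planted edges, false-edge rate among planted-zero dyads,
Jaccard overlap of the detected and planted core, the per-animal WAIC
pattern, and whether the core/periphery permutation test fires.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
import troopmove as tm

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 20260925

SCENARIOS = [("chain", 6), ("leader", 6), ("diffuse", 6), ("core_periphery", 12)]
rows = []
for scen, n in SCENARIOS:
    reports = tm.experiment_recovery(
        scen, n, hours=100.0, replicates=5, seed=SEED, n_perm=1000,
        fit_reduced=(scen == "chain"),
    )
    summary = tm.summarize_reports(reports)
    summary["scenario"] = scen
    rows.append(summary)
    print(f"{scen:15s} recall={summary['edge_sign_recall']:.2f} "
          f"false={summary['false_edge_rate']:.2f} "
          f"core_jaccard={summary['core_jaccard']:.2f} "
          f"exceeds_null={summary['exceeds_null_frac']:.2f}")

df = pd.DataFrame(rows).set_index("scenario")
df.to_csv(OUT / "recovery_summary.csv")
print(f"\nwrote {OUT / 'recovery_summary.csv'}")
print("note: the high false-edge rate in chain/leader scenarios is the "
      "correlated-position (downstream) artefact, not estimator noise; "
      "see docs/methods.md")
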