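#!/usr/bin/env python
"""Diagnostic evaluation of the simulated cohort.

Reads results/cohort.csv (written by 01_simulate_cohort.py; regenerated here
if absent), cross-tabulates every classifier against pneumothorax, computes
sensitivity/specificity/AUC/phi/Fisher p, runs the ROC threshold analysis on
the continuous densities, and fits the two logistic risk models. Writes
results/diagnostics.json plus a classifier table CSV.
"""

import json
from pathlib import Path

from bromolb import CohortSimParams, RunConfig, run_study

OUT = Path(__file__).resolve().parents[1] / "results"


def main(n_cases: int = 720, seed: int = 1) -> None:
    OUT.mkdir(exist_ok=True)
    cfg = RunConfig(cohort=CohortSimParams(n_cases=n_cases), seed=seed,
                    out_dir=str(OUT / "study"))
    _, results = run_study(cfg)
    (OUT / "diagnostics.json").write_text(json.dumps(results, indent=2,
                                                     sort_keys=True) + "\n")
    import pandas as pd
    pd.DataFrame(results["classifier_tables"]).T.to_csv(OUT / "classifier_tables.csv")

    print("classifier performance vs pneumothorax:")
    for name, row in results["classifier_tables"].items():
        print(f"  {name:16s} Se {row['sensitivity']:.3f}  Sp {row['specificity']:.3f} "
              f" AUC {row['auc']:.3f}  phi {row['phi']:.3f}  p {row['fisher_p']:.2e}")
    for key in ("roc_minip", "roc_lw"):
        r = results[key]
        print(f"{key}: AUC {r['auc']:.3f}, Youden threshold "
              f"{r['youden_threshold_hu']:.0f} HU, top-left "
              f"{r['top_left_threshold_hu']:.0f} HU")
    fit = results["logit_pneumothorax"]
    print(f"pneumothorax model OR[brom_olb_minip] = {fit['OR'][1]:.2f} "
          f"(95% CI {fit['ci_low'][1]:.2f}-{fit['ci_high'][1]:.2f}), "
          f"R2 {fit['nagelkerke_r2']:.2f}, f2 {fit['cohens_f2']:.2f}")
    hem = results["logit_hemorrhage"]
    print(f"hemorrhage model OR[lw_value] = {hem['OR'][1]:.4f} per HU "
          f"(95% CI {hem['ci_low'][1]:.4f}-{hem['ci_high'][1]:.4f})")


if __name__ == "__main__":
    main()
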