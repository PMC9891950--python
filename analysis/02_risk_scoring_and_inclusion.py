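#!/usr/bin/env python
"""Score baseline cardiovascular risk and apply the study exclusions.

For each cohort: SCORE and SCORE2 at baseline with the regional
calibration, ESC three-category classification, then the four exclusion
criteria in order (baseline CVD/diabetes, baseline frailty, incomplete
risk data, loss to follow-up).  Writes scored baselines, filtered
cohorts and exclusion ledgers under results/.
"""

from pathlib import Path

import pandas as pd

from frailtraj import risk_engine
from frailtraj.frailty_index import compute_fi_panel
from frailtraj.pipeline import apply_inclusion_criteria

ROOT = Path(__file__).resolve().parent.parent / "results"
COHORTS = ROOT / "cohorts"


def main():
    for name, region in (("uk", "low"), ("us", "high")):
        cohort = pd.read_csv(COHORTS / f"{name}_cohort.csv")
        base = cohort[cohort["wave_index"] == 0]
        scored = risk_engine.score_cohort(base, region=region)
        cols = ["participant_id", "score", "score2", "score2_category"]
        scored[cols].to_csv(ROOT / f"{name}_baseline_risk.csv", index=False)

        fi_panel = compute_fi_panel(cohort)
        merged = cohort.merge(scored[cols], on="participant_id", how="left")
        filtered, ledger, flags = apply_inclusion_criteria(merged, fi_panel)
        filtered.to_csv(ROOT / f"{name}_included.csv", index=False)
        ledger.to_csv(ROOT / f"{name}_exclusion_ledger.csv", index=False)
        flags.to_csv(ROOT / f"{name}_inclusion_flags.csv", index=False)

        ok = scored["score2"].notna()
        print(f"{name}: mean SCORE2 {scored.loc[ok, 'score2'].mean():.1f}% | "
              f"category shares "
              f"{scored['score2_category'].value_counts(normalize=True).round(3).to_dict()}")
        print(ledger.to_string(index=False))


if __name__ == "__main__":
    main()
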