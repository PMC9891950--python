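#!/usr/bin/env python
"""Generate the two synthetic study cohorts.

A UK-style cohort (low-risk calibration region, chair-rise instrument,
244.0 cm walk course) and a US-style cohort (high-risk region, no chair
rises, 250.19 cm course).  Both share the three-class latent frailty
trajectory structure; cohort CSVs and ground-truth sidecars go under
results/cohorts/.
"""

from pathlib import Path

from frailtraj.synthetic_cohort import CohortSpec, generate_cohort, write_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohorts"
OUT.mkdir(parents=True, exist_ok=True)

US_SLOPES = {
    # per-year change by risk category, US-style contrasts
    "low_to_moderate": {"grip": -0.15, "pef": -3.0, "gait": -0.80, "chair": 0.0},
    "high": {"grip": -0.361, "pef": -5.526, "gait": -1.383, "chair": 0.0},
    "very_high": {"grip": -0.497, "pef": -7.577, "gait": -1.746, "chair": 0.0},
}


def main():
    uk_spec = CohortSpec(n_participants=2000, seed=101, region="low")
    us_spec = CohortSpec(n_participants=2000, seed=202, region="high",
                         function_slopes=US_SLOPES)
    for name, spec in (("uk", uk_spec), ("us", us_spec)):
        cohort, truth = generate_cohort(spec)
        write_cohort(cohort, truth, OUT / f"{name}_cohort.csv",
                     OUT / f"{name}_truth.csv")
        spec.to_file(OUT / f"{name}_spec.yaml")
        shares = truth["latent_class"].value_counts(normalize=True).sort_index()
        print(f"{name}: {cohort['participant_id'].nunique()} participants, "
              f"{len(cohort)} rows; latent class shares "
              f"{[round(s, 3) for s in shares]}")


if __name__ == "__main__":
    main()
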