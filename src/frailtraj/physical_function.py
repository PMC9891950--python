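"""Reduce repeated physical-performance trials to analysis measures.

Grip strength: best (maximum) of the dominant-hand dynamometer trials, kg.
Peak expiratory flow: maximum of three trials, L/min.
Gait speed: course length / fastest of two timed walks, cm/s; course
length is 244.0 cm in ELSA-style cohorts and 250.19 cm in HRS-style.
Timed five chair rises: single recorded time, s (ELSA-style only; lower is
better).

Each measure carries direction metadata so downstream reporting knows
whether higher or lower values indicate better performance.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from ._errors import DataError

__all__ = [
    "best_of_trials",
    "gait_speed",
    "extract_function_measures",
    "MEASURE_DIRECTIONS",
    "ELSA_WALK_COURSE_CM",
    "HRS_WALK_COURSE_CM",
]

ELSA_WALK_COURSE_CM = 244.0
HRS_WALK_COURSE_CM = 250.19

# +1: higher is better; -1: lower is better
MEASURE_DIRECTIONS = {
    "grip_kg": +1,
    "pef_l_min": +1,
    "gait_speed_cm_s": +1,
    "chair_rises_s": -1,
}


def _clean(trials: Iterable) -> np.ndarray:
    arr = np.asarray(
        [np.nan if t is None else float(t) for t in trials], dtype=float
    )
    obs = arr[~np.isnan(arr)]
    if (obs < 0).any():
        raise DataError(f"negative trial value in {list(trials)!r}")
    return obs


def best_of_trials(trials: Iterable, rule: str = "max") -> float:
    """Apply max/min over non-missing trials; NaN when none observed."""
    if rule not in ("max", "min"):
        raise DataError(f"rule must be 'max' or 'min', got {rule!r}")
    obs = _clean(trials)
    if obs.size == 0:
        return float("nan")
    return float(obs.max() if rule == "max" else obs.min())


def gait_speed(walk_times_s: Iterable, course_cm: float) -> float:
    """Walking speed in cm/s from timed walks over a fixed course.

    Uses the fastest (minimum) time; a zero or negative time is a data
    error, while an all-missing trial list yields a missing speed.
    """
    if course_cm <= 0:
        raise DataError(f"course length must be positive, got {course_cm}")
    arr = np.asarray(
        [np.nan if t is None else float(t) for t in walk_times_s], dtype=float
    )
    obs = arr[~np.isnan(arr)]
    if obs.size == 0:
        return float("nan")
    if (obs <= 0).any():
        raise DataError(f"non-positive walk time in {list(walk_times_s)!r}")
    return float(course_cm / obs.min())


def extract_function_measures(
    cohort: pd.DataFrame, walk_course_cm: float = ELSA_WALK_COURSE_CM
) -> pd.DataFrame:
    """Per participant-wave analysis measures from trial columns.

    Expects (some of) ``grip_trial1..3``, ``pef_trial1..3``,
    ``walk_time1..2``, ``chair_rises_s``; absent instruments yield missing
    measures (e.g. chair rises in HRS-style cohorts).
    """
    n = len(cohort)

    def trial_block(prefix, k):
        cols = [f"{prefix}{i}" for i in range(1, k + 1) if f"{prefix}{i}" in cohort.columns]
        if not cols:
            return None
        return cohort[cols].to_numpy(dtype=float)

    def rowwise(a, reducer):
        # nan-aware row reduction that stays silent on all-NaN rows
        res = np.full(a.shape[0], np.nan)
        some = ~np.isnan(a).all(axis=1)
        if some.any():
            res[some] = reducer(a[some], axis=1)
        return res

    out = pd.DataFrame(
        {
            "participant_id": cohort["participant_id"].to_numpy(),
            "wave_index": cohort["wave_index"].to_numpy(),
            "years_since_baseline": cohort["years_since_baseline"].to_numpy(),
        }
    )

    grip = trial_block("grip_trial", 3)
    if grip is not None:
        if np.nanmin(grip, initial=0.0) < 0:
            raise DataError("negative grip trial value")
        out["grip_kg"] = rowwise(grip, np.nanmax)
    else:
        out["grip_kg"] = np.nan

    pef = trial_block("pef_trial", 3)
    if pef is not None:
        if np.nanmin(pef, initial=0.0) < 0:
            raise DataError("negative PEF trial value")
        out["pef_l_min"] = rowwise(pef, np.nanmax)
    else:
        out["pef_l_min"] = np.nan

    walks = trial_block("walk_time", 2)
    if walks is not None:
        obs = walks[~np.isnan(walks)]
        if (obs <= 0).any():
            raise DataError("non-positive walk time")
        out["gait_speed_cm_s"] = walk_course_cm / rowwise(walks, np.nanmin)
    else:
        out["gait_speed_cm_s"] = np.nan

    if "chair_rises_s" in cohort.columns:
        cr = cohort["chair_rises_s"].to_numpy(dtype=float)
        if np.nanmin(cr, initial=0.0) < 0:
            raise DataError("negative chair-rise time")
        out["chair_rises_s"] = cr
    else:
        out["chair_rises_s"] = np.nan

    return out
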