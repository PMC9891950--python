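"""Synthetic longitudinal ageing cohorts with latent frailty-trajectory classes.

Real analyses of this kind run on registration-only panel studies (ELSA-
and HRS-style biennial surveys of adults aged >= 50).  This module
generates cohorts with the same statistical skeleton so every downstream
stage — risk scoring, frailty-index construction, trajectory modelling,
association models, predictive-utility evaluation — is exercisable and
testable without any data download:

* each participant belongs to one of a few latent trajectory classes;
  the class determines a polynomial latent frailty-index (FI) curve over
  years since baseline (clamped to [0, 1]);
* baseline covariates (age, smoking, SBP) shift by class, so a
  cardiovascular risk score computed from them genuinely predicts class
  membership;
* the 29 deficit items are drawn so that their average recovers the
  latent FI (binary items ~ Bernoulli(latent); ordinal items scaled
  binomial with matching expectation);
* physical-function outcomes decline linearly in time with per-year
  slopes set by the participant's cardiovascular risk category;
* dropout is monotone and, by default, missing-at-random given baseline
  age (a completely-at-random mode exists for mixed-model sanity checks).

With every noise SD set to zero the generator becomes deterministic given
class membership: deficit items are emitted as scale values equal to the
latent FI (compute the FI panel with ``mapped=True`` in that case) and
function trials equal their true values, so class-mean FI per wave equals
the class polynomial exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._errors import ConfigurationError, DataError
from .frailty_index import DeficitRegistry
from . import risk_engine

__all__ = ["CohortSpec", "generate_cohort", "latent_to_items", "apply_dropout",
           "write_cohort", "read_cohort", "TRUTH_COLUMNS"]

TRUTH_COLUMNS = ["participant_id", "latent_class", "true_risk_category"]


def _default_covariate_model() -> dict:
    # loosely emulates a UK-style cohort baseline: age 64 +/- 9.2, 44.3% men,
    # 12.9% current smokers, SBP 134.5 +/- 18.5, TC 6.0 +/- 1.1, HDL 1.6 +/- 0.4,
    # with class-graded shifts in age, smoking and SBP
    return {
        "age_mean_by_class": [62.0, 66.0, 70.0],
        "age_sd": 8.5,
        "age_min": 50.0,
        "prop_male": 0.443,
        "smoking_by_class": [0.10, 0.16, 0.22],
        "sbp_mean_by_class": [131.0, 137.0, 141.0],
        "sbp_sd": 18.0,
        "tc_mean": 6.0,
        "tc_sd": 1.1,
        "hdl_mean": 1.6,
        "hdl_sd": 0.4,
        "cvd_diabetes_prev_by_class": [0.08, 0.12, 0.18],
        "missing_hdl_rate": 0.03,
        # sex-specific function baselines (person-level means)
        "grip_mean": {"male": 41.0, "female": 27.0},
        "pef_mean": {"male": 455.0, "female": 270.0},
        "gait_mean": 100.0,
        "chair_mean": 11.0,
    }


def _default_function_slopes() -> dict:
    # per-year change by cardiovascular risk category; contrasts vs the
    # low-to-moderate category follow the magnitudes reported for
    # UK-style cohorts (grip kg/yr, PEF L/min/yr, gait cm/s/yr, chair s/yr)
    return {
        "low_to_moderate": {"grip": -0.15, "pef": -3.0, "gait": -0.80, "chair": 0.08},
        "high": {"grip": -0.371, "pef": -5.219, "gait": -1.586, "chair": 0.164},
        "very_high": {"grip": -0.593, "pef": -12.902, "gait": -2.204, "chair": 0.194},
    }


def _default_noise_sds() -> dict:
    return {
        # FI noise is occasion-level by design: the latent trajectory plus
        # an independent per-wave wobble, matching the conditional-
        # independence assumption of group-based trajectory models.  A
        # persistent person-level shift can be switched on (fi_person) to
        # stress-test trajectory fitting under violated assumptions.
        "fi_person": 0.0,
        "fi_wave": 0.04,
        "grip_person": 7.0,
        "grip_trial": 1.5,
        "pef_person": 85.0,
        "pef_trial": 15.0,
        "gait_person": 20.0,
        "walk_time": 0.25,    # seconds, per timed walk
        "chair_person": 3.0,
        "chair_trial": 0.5,
    }


@dataclass
class CohortSpec:
    """Generative configuration for a synthetic cohort.

    Defaults describe the demo cohort: three latent classes in proportions
    0.62 / 0.27 / 0.11 with rising FI polynomials (stable ~0.07 + 0.004/yr,
    moderate ~0.10 + 0.018/yr, accelerated quadratic from 0.14), biennial
    waves, and covariates whose class gradients make SCORE2 predictive of
    class.
    """

    n_participants: int = 2000
    n_waves: int = 7
    wave_spacing_years: float = 2.0
    class_proportions: Sequence[float] = (0.62, 0.27, 0.11)
    class_polynomials: Sequence[Sequence[float]] = (
        (0.07, 0.004),
        (0.10, 0.018),
        (0.14, 0.016, 0.0016),
    )
    covariate_model: dict = field(default_factory=_default_covariate_model)
    function_slopes: dict = field(default_factory=_default_function_slopes)
    noise_sds: dict = field(default_factory=_default_noise_sds)
    dropout_hazard: dict = field(
        default_factory=lambda: {"base": 0.05, "age_coef": 0.03, "mode": "mar"}
    )
    region: str = "low"
    seed: int = 0

    def __post_init__(self):
        props = np.asarray(self.class_proportions, dtype=float)
        if abs(props.sum() - 1.0) > 1e-12:
            raise ConfigurationError(
                f"class proportions must sum to 1, got {props.sum()!r}"
            )
        if (props < 0).any():
            raise ConfigurationError("class proportions must be non-negative")
        if len(self.class_polynomials) != len(props):
            raise ConfigurationError(
                "one polynomial per latent class is required"
            )
        if self.n_waves < 2:
            raise ConfigurationError("n_waves must be >= 2")
        if any(v < 0 for v in self.noise_sds.values()):
            raise ConfigurationError("noise SDs must be >= 0")
        base = float(self.dropout_hazard.get("base", 0.0))
        if not 0.0 <= base <= 1.0:
            raise ConfigurationError(f"dropout hazard must lie in [0,1], got {base}")

    @property
    def n_classes(self) -> int:
        return len(self.class_proportions)

    @property
    def noise_free(self) -> bool:
        return all(v == 0 for v in self.noise_sds.values())

    @classmethod
    def from_file(cls, path) -> "CohortSpec":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) if str(path).endswith((".yaml", ".yml")) else json.load(fh)
        return cls(**cfg)

    def to_file(self, path) -> None:
        cfg = asdict(self)
        cfg["class_proportions"] = list(self.class_proportions)
        cfg["class_polynomials"] = [list(p) for p in self.class_polynomials]
        with open(path, "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=False)


def latent_fi_curve(poly: Sequence[float], years: np.ndarray) -> np.ndarray:
    """Evaluate an FI polynomial in years since baseline, clamped to [0,1]."""
    vals = np.polynomial.polynomial.polyval(np.asarray(years, dtype=float),
                                            np.asarray(poly, dtype=float))
    return np.clip(vals, 0.0, 1.0)


def latent_to_items(
    latent_fi: float,
    registry: DeficitRegistry,
    rng: np.random.Generator,
    deterministic: bool = False,
) -> dict:
    """Draw raw deficit-item values whose mapped mean recovers ``latent_fi``.

    Binary items are Bernoulli(latent); ordinal items are scaled binomial
    draws over their level grid so the mapped expectation equals the
    latent value.  With ``deterministic=True`` every item is emitted as a
    scale value equal to the latent FI itself.
    """
    if not 0.0 <= latent_fi <= 1.0:
        raise DataError(f"latent FI {latent_fi} outside [0,1]")
    out = {}
    for item in registry.items:
        if deterministic:
            out[item.name] = latent_fi
        elif item.kind == "binary":
            out[item.name] = float(rng.random() < latent_fi)
        elif item.kind == "ordinal":
            levels = sorted(item.levels)  # raw levels, mapped scores equally spaced
            k = len(levels) - 1
            out[item.name] = levels[int(rng.binomial(k, latent_fi))]
        else:
            out[item.name] = latent_fi
    return out


def _draw_items_matrix(latent, registry, rng, deterministic):
    """Vectorised latent_to_items over an array of latent FI values."""
    n = latent.shape[0]
    cols = {}
    for item in registry.items:
        if deterministic:
            cols[item.name] = latent.copy()
        elif item.kind == "binary":
            cols[item.name] = (rng.random(n) < latent).astype(float)
        elif item.kind == "ordinal":
            levels = np.array(sorted(item.levels))
            k = len(levels) - 1
            cols[item.name] = levels[rng.binomial(k, latent)]
        else:
            cols[item.name] = latent.copy()
    return cols


def _truncated_normal(rng, mean, sd, lower, size):
    """Normal draws re-sampled until above ``lower`` (truncation, not clip)."""
    if sd == 0:
        return np.full(size, np.maximum(mean, lower), dtype=float)
    out = rng.normal(mean, sd, size=size)
    bad = out < lower
    while bad.any():
        out[bad] = rng.normal(
            mean[bad] if np.ndim(mean) else mean, sd, size=int(bad.sum())
        )
        bad = out < lower
    return out


def generate_cohort(spec: CohortSpec, registry: DeficitRegistry | None = None):
    """Generate a long-format cohort table plus a ground-truth sidecar.

    Returns ``(cohort, truth)``: the cohort has one row per participant-
    wave with baseline covariates, raw deficit items and function trials;
    ``truth`` carries the generator-only latent class and the risk
    category used for function slopes.  Identical spec and seed give an
    identical table.
    """
    registry = registry or DeficitRegistry.default()
    rng = np.random.default_rng(spec.seed)
    cm = spec.covariate_model
    n = spec.n_participants
    n_classes = spec.n_classes

    schema_cols = (
        ["participant_id", "wave_index", "years_since_baseline", "age", "sex",
         "current_smoking", "sbp", "tc", "hdl", "cvd_diabetes", "handedness"]
        + registry.names
        + ["grip_trial1", "grip_trial2", "grip_trial3",
           "pef_trial1", "pef_trial2", "pef_trial3",
           "walk_time1", "walk_time2", "chair_rises_s"]
    )
    if n == 0:
        empty = pd.DataFrame({c: pd.Series(dtype=float) for c in schema_cols})
        empty["sex"] = pd.Series(dtype=object)
        empty["handedness"] = pd.Series(dtype=object)
        truth = pd.DataFrame({c: pd.Series(dtype=object) for c in TRUTH_COLUMNS})
        return empty, truth

    latent_class = rng.choice(n_classes, size=n, p=np.asarray(spec.class_proportions))

    age_means = np.asarray(cm["age_mean_by_class"], dtype=float)[latent_class]
    age = _truncated_normal(rng, age_means, cm["age_sd"], cm["age_min"], n)
    sex = np.where(rng.random(n) < cm["prop_male"], "male", "female")
    smoking = rng.random(n) < np.asarray(cm["smoking_by_class"])[latent_class]
    sbp_means = np.asarray(cm["sbp_mean_by_class"], dtype=float)[latent_class]
    sbp = _truncated_normal(rng, sbp_means, cm["sbp_sd"], 80.0, n)
    tc = _truncated_normal(rng, cm["tc_mean"], cm["tc_sd"], 2.0, n)
    hdl = _truncated_normal(rng, cm["hdl_mean"], cm["hdl_sd"], 0.5, n)
    cvd_diabetes = rng.random(n) < np.asarray(
        cm["cvd_diabetes_prev_by_class"])[latent_class]
    handedness = np.where(rng.random(n) < 0.9, "right", "left")

    # risk category (from complete covariates) drives function slopes
    coeffs = risk_engine.RiskCoefficientSet.from_file()
    scales = risk_engine.CalibrationScales.from_file()
    thresholds = risk_engine.RiskThresholds.from_file()
    category = np.empty(n, dtype=object)
    for i in range(n):
        prof = risk_engine.RiskProfile(
            age=float(age[i]), sex=str(sex[i]),
            current_smoking=bool(smoking[i]), sbp=float(sbp[i]),
            tc=float(tc[i]), hdl=float(hdl[i]),
        )
        r = risk_engine.compute_score2(prof, coeffs, scales, spec.region)
        category[i] = risk_engine.categorize_risk(r, prof.age, thresholds)

    # a small fraction loses HDL (incomplete risk data at analysis time)
    hdl_missing = rng.random(n) < cm.get("missing_hdl_rate", 0.0)
    hdl = np.where(hdl_missing, np.nan, hdl)

    ns = spec.noise_sds
    det = spec.noise_free
    fi_person = rng.normal(0.0, ns["fi_person"], n) if ns["fi_person"] > 0 else np.zeros(n)

    slopes = spec.function_slopes
    grip_slope = np.array([slopes[c]["grip"] for c in category])
    pef_slope = np.array([slopes[c]["pef"] for c in category])
    gait_slope = np.array([slopes[c]["gait"] for c in category])
    chair_slope = np.array([slopes[c]["chair"] for c in category])

    grip_base = np.array([cm["grip_mean"][s] for s in sex]) + (
        rng.normal(0.0, ns["grip_person"], n) if ns["grip_person"] > 0 else 0.0)
    pef_base = np.array([cm["pef_mean"][s] for s in sex]) + (
        rng.normal(0.0, ns["pef_person"], n) if ns["pef_person"] > 0 else 0.0)
    gait_base = cm["gait_mean"] + (
        rng.normal(0.0, ns["gait_person"], n) if ns["gait_person"] > 0 else 0.0)
    chair_base = cm["chair_mean"] + (
        rng.normal(0.0, ns["chair_person"], n) if ns["chair_person"] > 0 else 0.0)

    frames = []
    pid = np.arange(n)
    polys = [np.asarray(p, dtype=float) for p in spec.class_polynomials]
    for w in range(spec.n_waves):
        t = w * spec.wave_spacing_years
        latent = np.empty(n)
        for k, poly in enumerate(polys):
            mask = latent_class == k
            latent[mask] = latent_fi_curve(poly, np.array([t]))[0]
        latent = latent + fi_person
        if ns["fi_wave"] > 0:
            latent = latent + rng.normal(0.0, ns["fi_wave"], n)
        latent = np.clip(latent, 0.0, 1.0)
        items = _draw_items_matrix(latent, registry, rng, det)

        def trials(base, slope, trial_sd, k_trials):
            true = base + slope * t
            true = np.maximum(true, 0.0)
            if trial_sd > 0:
                return [np.maximum(true + rng.normal(0.0, trial_sd, n), 0.0)
                        for _ in range(k_trials)]
            return [true.copy() for _ in range(k_trials)]

        grip_t = trials(grip_base, grip_slope, ns["grip_trial"], 3)
        pef_t = trials(pef_base, pef_slope, ns["pef_trial"], 3)
        gait_true = np.maximum(gait_base + gait_slope * t, 1.0)
        walk_true = 244.0 / gait_true  # seconds over the timed-walk course
        if ns["walk_time"] > 0:
            walk_t = [np.maximum(walk_true + rng.normal(0.0, ns["walk_time"], n), 0.1)
                      for _ in range(2)]
        else:
            walk_t = [walk_true.copy(), walk_true.copy()]
        chair_t = trials(chair_base, chair_slope, ns["chair_trial"], 1)

        frame = {
            "participant_id": pid,
            "wave_index": np.full(n, w),
            "years_since_baseline": np.full(n, t),
            "age": age, "sex": sex, "current_smoking": smoking.astype(float),
            "sbp": sbp, "tc": tc, "hdl": hdl,
            "cvd_diabetes": cvd_diabetes.astype(float),
            "handedness": handedness,
        }
        frame.update(items)
        frame.update({
            "grip_trial1": grip_t[0], "grip_trial2": grip_t[1], "grip_trial3": grip_t[2],
            "pef_trial1": pef_t[0], "pef_trial2": pef_t[1], "pef_trial3": pef_t[2],
            "walk_time1": walk_t[0], "walk_time2": walk_t[1],
            "chair_rises_s": chair_t[0],
        })
        frames.append(pd.DataFrame(frame))

    cohort = pd.concat(frames, ignore_index=True)
    cohort = cohort.sort_values(["participant_id", "wave_index"]).reset_index(drop=True)
    cohort = cohort[schema_cols]
    cohort = apply_dropout(cohort, spec.dropout_hazard, rng=rng)

    truth = pd.DataFrame({
        "participant_id": pid,
        "latent_class": latent_class,
        "true_risk_category": category,
    })
    return cohort, truth


def apply_dropout(
    cohort: pd.DataFrame,
    hazard: Mapping | float,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Impose monotone dropout: once a wave is missed, all later waves are.

    ``hazard`` is either a per-wave probability or a mapping with ``base``
    (per-wave probability), optional ``age_coef`` (log-odds shift per year
    of baseline age above 64 when mode is "mar") and ``mode`` in
    {"mar", "mcar"}.  The baseline wave is always retained.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if isinstance(hazard, (int, float)):
        hazard = {"base": float(hazard), "mode": "mcar"}
    base = float(hazard.get("base", 0.0))
    if not 0.0 <= base <= 1.0:
        raise ConfigurationError(f"dropout hazard must lie in [0,1], got {base}")
    if base == 0.0:
        return cohort
    if len(cohort) == 0:
        return cohort

    first = cohort.sort_values("wave_index").groupby("participant_id").first()
    pids = first.index.to_numpy()
    n = len(pids)
    max_wave = int(cohort["wave_index"].max())

    if hazard.get("mode", "mcar") == "mar" and base < 1.0:
        age = first["age"].to_numpy(dtype=float)
        coef = float(hazard.get("age_coef", 0.0))
        logit = np.log(base / (1.0 - base)) + coef * (age - 64.0)
        p = 1.0 / (1.0 + np.exp(-logit))
    else:
        p = np.full(n, base)

    # first missed wave per participant (baseline never missed)
    drop_wave = np.full(n, np.iinfo(np.int64).max)
    alive = np.ones(n, dtype=bool)
    for w in range(1, max_wave + 1):
        miss = alive & (rng.random(n) < p)
        drop_wave[miss] = w
        alive &= ~miss
    cutoff = pd.Series(drop_wave, index=pids)
    keep = cohort["wave_index"].to_numpy() < cutoff.loc[
        cohort["participant_id"]].to_numpy()
    return cohort.loc[keep].reset_index(drop=True)


def write_cohort(cohort: pd.DataFrame, truth: pd.DataFrame | None,
                 cohort_path, truth_path=None) -> None:
    """Write the cohort CSV; ground truth goes to a sidecar so blinded
    runs are possible."""
    cohort.to_csv(cohort_path, index=False)
    if truth is not None and truth_path is not None:
        truth.to_csv(truth_path, index=False)


def read_cohort(cohort_path, truth_path=None):
    cohort = pd.read_csv(cohort_path)
    truth = pd.read_csv(truth_path) if truth_path else None
    return cohort, truth
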