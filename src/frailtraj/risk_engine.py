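"""10-year cardiovascular risk: SCORE2 and the precedent SCORE.

SCORE2 combines age, sex, current smoking, systolic blood pressure (SBP),
total cholesterol (TC) and HDL cholesterol (HDL-C) into a 10-year risk of
fatal plus non-fatal cardiovascular disease.  The uncalibrated risk is

    r = 1 - S0 ** exp(lp)

with ``lp`` a sex-specific linear predictor on centred/scaled covariates
(including age interactions) and ``S0`` the baseline 10-year survival.  The
risk is then recalibrated to one of four regional clusters (low, moderate,
high, very high CVD risk) through

    r_cal = 1 - exp(-exp(scale1 + scale2 * ln(-ln(1 - r))))

and classified into the three ESC categories (low-to-moderate / high /
very high) using age-banded percentage cutpoints.  The precedent SCORE
equation (fatal CVD only; no HDL term) is provided as comparator.

All coefficients, baseline survivals, regional scales and category
thresholds are data files shipped under ``frailtraj/data`` — nothing is
hard-coded, so alternative coefficient sets can be swapped in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from ._errors import ConfigurationError, IncompleteDataError

__all__ = [
    "RiskProfile",
    "RiskCoefficientSet",
    "CalibrationScales",
    "RiskThresholds",
    "load_score2_coefficients",
    "load_score_coefficients",
    "load_calibration_scales",
    "load_risk_thresholds",
    "compute_score2",
    "compute_score",
    "categorize_risk",
    "score_cohort",
    "CATEGORIES",
]

CATEGORIES = ("low_to_moderate", "high", "very_high")

_DATA = resources.files("frailtraj") / "data"


def _load_yaml(path_or_default, default_name: str) -> dict:
    if path_or_default is None:
        with (_DATA / default_name).open("r") as fh:
            return yaml.safe_load(fh)
    with open(path_or_default, "r") as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class RiskProfile:
    """Baseline covariates entering the risk equations.

    ``sex`` is ``"male"`` or ``"female"``; ``hdl`` may be None for SCORE
    (which has no HDL term) but is required by SCORE2.
    """

    age: float
    sex: str
    current_smoking: bool
    sbp: float
    tc: float
    hdl: float | None = None

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise IncompleteDataError(f"sex must be 'male' or 'female', got {self.sex!r}")

    def require(self, fields) -> None:
        for f in fields:
            v = getattr(self, f)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                raise IncompleteDataError(f"risk profile missing required field {f!r}")


class RiskCoefficientSet:
    """SCORE2 coefficients: per-sex log-HR terms, S0, centring constants."""

    REQUIRED_TERMS = (
        "cage", "smoking", "csbp", "ctc", "chdl",
        "smoking_x_cage", "csbp_x_cage", "ctc_x_cage", "chdl_x_cage",
    )

    def __init__(self, config: Mapping):
        self.transforms = {k: dict(v) for k, v in config["transforms"].items()}
        self.per_sex = {}
        for sex in ("male", "female"):
            block = config[sex]
            s0 = float(block["s0_10yr"])
            if not 0.0 < s0 < 1.0:
                raise ConfigurationError(f"S0 for {sex} must lie in (0,1), got {s0}")
            coeffs = dict(block["coefficients"])
            missing = [t for t in self.REQUIRED_TERMS if t not in coeffs]
            if missing:
                raise ConfigurationError(f"missing SCORE2 terms for {sex}: {missing}")
            self.per_sex[sex] = {"s0": s0, "coefficients": coeffs}

    @classmethod
    def from_file(cls, path=None) -> "RiskCoefficientSet":
        return cls(_load_yaml(path, "score2_coefficients.yaml"))

    def linear_predictor(self, profile: RiskProfile) -> float:
        t = self.transforms
        cage = (profile.age - t["age"]["center"]) / t["age"]["scale"]
        csbp = (profile.sbp - t["sbp"]["center"]) / t["sbp"]["scale"]
        ctc = (profile.tc - t["tc"]["center"]) / t["tc"]["scale"]
        chdl = (profile.hdl - t["hdl"]["center"]) / t["hdl"]["scale"]
        smk = 1.0 if profile.current_smoking else 0.0
        c = self.per_sex[profile.sex]["coefficients"]
        return (
            c["cage"] * cage
            + c["smoking"] * smk
            + c["csbp"] * csbp
            + c["ctc"] * ctc
            + c["chdl"] * chdl
            + c["smoking_x_cage"] * smk * cage
            + c["csbp_x_cage"] * csbp * cage
            + c["ctc_x_cage"] * ctc * cage
            + c["chdl_x_cage"] * chdl * cage
        )


class CalibrationScales:
    """Regional recalibration scales: per-region, per-sex (scale1, scale2)."""

    REGIONS = ("low", "moderate", "high", "very_high")

    def __init__(self, config: Mapping):
        self.per_region = {}
        for region, block in config.items():
            for sex in ("male", "female"):
                s2 = float(block[sex]["scale2"])
                if s2 <= 0:
                    raise ConfigurationError(
                        f"scale2 must be positive for {region}/{sex}, got {s2}"
                    )
            self.per_region[region] = {
                sex: (float(block[sex]["scale1"]), float(block[sex]["scale2"]))
                for sex in ("male", "female")
            }

    @classmethod
    def from_file(cls, path=None) -> "CalibrationScales":
        return cls(_load_yaml(path, "calibration_scales.yaml"))

    @classmethod
    def identity(cls) -> "CalibrationScales":
        """scale1=0, scale2=1 for every region: calibrated == uncalibrated."""
        cfg = {
            r: {"male": {"scale1": 0.0, "scale2": 1.0},
                "female": {"scale1": 0.0, "scale2": 1.0}}
            for r in cls.REGIONS
        }
        return cls(cfg)

    def get(self, region: str, sex: str) -> tuple[float, float]:
        if region not in self.per_region:
            raise ConfigurationError(
                f"unknown region {region!r}; expected one of {sorted(self.per_region)}"
            )
        return self.per_region[region][sex]


class RiskThresholds:
    """Age-banded ESC category cutpoints (percent)."""

    def __init__(self, config: Mapping):
        self.bands = []
        for band in config["age_bands"]:
            lo, hi = float(band["min_age"]), band["max_age"]
            hi = math.inf if hi is None else float(hi)
            cut1, cut2 = float(band["cut1"]), float(band["cut2"])
            if not cut1 < cut2:
                raise ConfigurationError(
                    f"cutpoints must increase within a band, got {cut1} >= {cut2}"
                )
            self.bands.append((lo, hi, cut1, cut2))
        self.bands.sort(key=lambda b: b[0])

    @classmethod
    def from_file(cls, path=None) -> "RiskThresholds":
        return cls(_load_yaml(path, "risk_thresholds.yaml"))

    def cutpoints(self, age: float) -> tuple[float, float]:
        # bands are contiguous: the applicable band is the one with the
        # largest lower edge not exceeding the age
        chosen = None
        for lo, hi, cut1, cut2 in self.bands:
            if age >= lo:
                chosen = (cut1, cut2)
        if chosen is None:
            raise ConfigurationError(
                f"age {age} below the lowest configured threshold band "
                f"(bands start at {self.bands[0][0]})"
            )
        return chosen


def load_score2_coefficients(path=None) -> RiskCoefficientSet:
    return RiskCoefficientSet.from_file(path)


def load_calibration_scales(path=None) -> CalibrationScales:
    return CalibrationScales.from_file(path)


def load_risk_thresholds(path=None) -> RiskThresholds:
    return RiskThresholds.from_file(path)


def load_score_coefficients(path=None) -> dict:
    return _load_yaml(path, "score_coefficients.yaml")


def compute_score2(
    profile: RiskProfile,
    coeffs: RiskCoefficientSet | None = None,
    scales: CalibrationScales | None = None,
    region: str = "low",
) -> float:
    """Calibrated SCORE2 10-year CVD risk, in percent.

    Raises :class:`IncompleteDataError` when any required covariate is
    missing — this drives the study exclusion of participants without
    complete risk data.
    """
    coeffs = coeffs or RiskCoefficientSet.from_file()
    scales = scales or CalibrationScales.from_file()
    profile.require(("age", "sex", "current_smoking", "sbp", "tc", "hdl"))
    lp = coeffs.linear_predictor(profile)
    s0 = coeffs.per_sex[profile.sex]["s0"]
    r = 1.0 - s0 ** math.exp(lp)
    r = min(max(r, 1e-15), 1.0 - 1e-15)
    scale1, scale2 = scales.get(region, profile.sex)
    cal = 1.0 - math.exp(-math.exp(scale1 + scale2 * math.log(-math.log(1.0 - r))))
    return 100.0 * cal


def _score_cause_risk(age, alpha, p, w) -> float:
    # Weibull survival S(a) = exp(-exp(alpha) * (a-20)^p), exposure via S^exp(w)
    def surv(a):
        return math.exp(-math.exp(alpha) * max(a - 20.0, 0.0) ** p)

    s_now = surv(age) ** math.exp(w)
    s_10 = surv(age + 10.0) ** math.exp(w)
    if s_now <= 0.0:
        return 1.0
    return 1.0 - s_10 / s_now


def compute_score(
    profile: RiskProfile,
    score_coeffs: Mapping | None = None,
    region: str = "low",
) -> float:
    """SCORE 10-year fatal-CVD risk, in percent (no HDL term).

    Cause-specific (CHD and non-CHD) Weibull survival curves are combined
    by summing the two 10-year risks, capped at 100%.
    """
    cfg = score_coeffs or load_score_coefficients()
    profile.require(("age", "sex", "current_smoking", "sbp", "tc"))
    region_key = "low" if region == "low" else "high"
    total = 0.0
    for cause in ("chd", "non_chd"):
        b = cfg["betas"][cause]
        w = (
            b["chol"] * (profile.tc - 6.0)
            + b["sbp"] * (profile.sbp - 120.0)
            + b["smoking"] * (1.0 if profile.current_smoking else 0.0)
        )
        ab = cfg["regions"][region_key][cause][profile.sex]
        total += _score_cause_risk(profile.age, ab["alpha"], ab["p"], w)
    return 100.0 * min(total, 1.0)


def categorize_risk(
    risk_pct: float, age: float, thresholds: RiskThresholds | None = None
) -> str:
    """ESC risk category for a risk percentage at a given age.

    Boundary values are assigned to the higher category (intervals are
    left-closed at the top).
    """
    if risk_pct < 0:
        raise ConfigurationError(f"risk percentage must be >= 0, got {risk_pct}")
    thresholds = thresholds or RiskThresholds.from_file()
    cut1, cut2 = thresholds.cutpoints(age)
    if risk_pct >= cut2:
        return "very_high"
    if risk_pct >= cut1:
        return "high"
    return "low_to_moderate"


def score_cohort(
    baseline: pd.DataFrame,
    region: str = "low",
    coeffs: RiskCoefficientSet | None = None,
    scales: CalibrationScales | None = None,
    thresholds: RiskThresholds | None = None,
    score_coeffs: Mapping | None = None,
) -> pd.DataFrame:
    """Append score, score2 and score2_category columns to a baseline table.

    Expects columns ``age, sex, current_smoking, sbp, tc, hdl``.  Rows with
    incomplete risk inputs get NaN scores and a missing category rather than
    raising, so the inclusion filter can count them.
    """
    coeffs = coeffs or RiskCoefficientSet.from_file()
    scales = scales or CalibrationScales.from_file()
    thresholds = thresholds or RiskThresholds.from_file()
    score_coeffs = score_coeffs or load_score_coefficients()

    out = baseline.copy()
    score2 = np.full(len(out), np.nan)
    score = np.full(len(out), np.nan)
    category = np.array([None] * len(out), dtype=object)
    for i, row in enumerate(out.itertuples(index=False)):
        if any(pd.isna(v) for v in (row.age, row.sex, row.current_smoking,
                                    row.sbp, row.tc)):
            continue
        prof = RiskProfile(
            age=float(row.age),
            sex=str(row.sex),
            current_smoking=bool(row.current_smoking),
            sbp=float(row.sbp),
            tc=float(row.tc),
            hdl=None if pd.isna(row.hdl) else float(row.hdl),
        )
        try:
            score[i] = compute_score(prof, score_coeffs, region)
        except IncompleteDataError:
            pass
        try:
            score2[i] = compute_score2(prof, coeffs, scales, region)
            category[i] = categorize_risk(score2[i], prof.age, thresholds)
        except IncompleteDataError:
            continue
    out["score"] = score
    out["score2"] = score2
    out["score2_category"] = category
    return out
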