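"""End-to-end study pipeline.

Orchestrates the full analysis from one configuration: cohort input
(CSV or synthetic spec), risk scoring and ESC categorisation, the four
inclusion criteria, frailty-index panels, trajectory model selection and
labelling, risk-ratio and mixed-model association tables, the
predictive-utility battery, and the sensitivity analyses (26-item FI
rerun, IPW-weighted ROC, component-adjusted risk ratios, moderate-vs-
stable ROC, age-stratified ROC).  Every artefact is written as CSV or
JSON under the configured output directory together with a run manifest
(seed, package version, configuration hash); identical configuration and
seed give identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ConfigurationError, FrailtrajError
from . import association, evaluation, gbtm, physical_function, risk_engine, weighting
from .frailty_index import DeficitRegistry, compute_fi_panel, FRAILTY_THRESHOLD
from .synthetic_cohort import CohortSpec, generate_cohort, write_cohort

__all__ = ["StudyConfig", "apply_inclusion_criteria", "run_pipeline",
           "descriptive_table", "rr_table_from_counts"]


@dataclass
class StudyConfig:
    """One run of the study pipeline."""

    outdir: str = "results/run"
    cohort_csv: str | None = None        # if None, simulate from cohort_spec
    cohort_spec: dict = field(default_factory=dict)
    region: str = "low"
    registry_path: str | None = None
    fi_subset: str = "full"              # "full" (29) or "revised" (26)
    k_range: tuple = (1, 2, 3, 4, 5)
    order_range: tuple = (2,)
    gbtm_restarts: int = 3
    gbtm_censored: bool = True
    gbtm_shared_sigma: bool = True
    age_cut: float = 65.0
    min_waves: int = 2                   # loss-to-follow-up rule
    walk_course_cm: float = physical_function.ELSA_WALK_COURSE_CM
    run_sensitivity: bool = True
    run_lmm: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.region not in ("low", "moderate", "high", "very_high"):
            raise ConfigurationError(f"unknown region {self.region!r}")

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        import yaml
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(**cfg)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def apply_inclusion_criteria(
    cohort: pd.DataFrame,
    fi_baseline: pd.DataFrame,
    min_waves: int = 2,
):
    """Apply the four study exclusions, in order, at the participant level.

    1. documented CVD or diabetes at baseline (``cvd_diabetes`` flag);
    2. frailty at baseline (baseline FI >= 0.25, or baseline FI missing);
    3. incomplete data for 10-year risk estimation (any of age, sex,
       smoking, SBP, TC, HDL missing at baseline);
    4. loss to follow-up (fewer than ``min_waves`` observed waves).

    A participant matching several criteria is counted at the first.
    Returns (filtered cohort, ledger DataFrame, per-participant flags).
    """
    base = cohort[cohort["wave_index"] == 0].set_index("participant_id")
    all_ids = base.index.to_numpy()

    fi0 = fi_baseline[fi_baseline["wave_index"] == 0].set_index("participant_id")["fi"]
    fi0 = fi0.reindex(all_ids)

    crit1 = base.get("cvd_diabetes", pd.Series(0.0, index=base.index)).fillna(0.0) == 1.0
    crit2 = (fi0 >= FRAILTY_THRESHOLD) | fi0.isna()
    risk_cols = ["age", "sex", "current_smoking", "sbp", "tc", "hdl"]
    have = [c for c in risk_cols if c in base.columns]
    crit3 = base[have].isna().any(axis=1) if have else pd.Series(False, index=base.index)
    n_waves = cohort.groupby("participant_id")["wave_index"].nunique().reindex(all_ids).fillna(0)
    crit4 = n_waves < min_waves

    excluded_by = pd.Series("", index=base.index, dtype=object)
    remaining = pd.Series(True, index=base.index)
    counts = {}
    for name, crit in [
        ("cvd_or_diabetes_at_baseline", crit1),
        ("frail_at_baseline", crit2),
        ("incomplete_risk_data", crit3),
        ("loss_to_follow_up", crit4),
    ]:
        hit = remaining & crit.astype(bool)
        counts[name] = int(hit.sum())
        excluded_by[hit] = name
        remaining &= ~hit

    kept_ids = base.index[remaining]
    filtered = cohort[cohort["participant_id"].isin(kept_ids)].reset_index(drop=True)
    ledger = pd.DataFrame(
        [{"criterion": k, "n_excluded": v} for k, v in counts.items()]
        + [{"criterion": "retained", "n_excluded": int(remaining.sum())}]
    )
    flags = pd.DataFrame({
        "participant_id": all_ids,
        "included": remaining.to_numpy().astype(int),
        "excluded_by": excluded_by.to_numpy(),
    })
    return filtered, ledger, flags


def rr_table_from_counts(assignment: pd.DataFrame, outcome_col: str = "accelerated",
                         category_col: str = "score2_category") -> pd.DataFrame:
    """Events/total per risk category — the audit companion of the RR table."""
    rows = []
    for cat in risk_engine.CATEGORIES:
        sub = assignment[assignment[category_col] == cat]
        rows.append({"category": cat, "events": int(sub[outcome_col].sum()),
                     "total": int(len(sub))})
    return pd.DataFrame(rows)


def descriptive_table(df: pd.DataFrame, group_col: str,
                      continuous=(), binary=(), skewed=()) -> pd.DataFrame:
    """Two-group baseline comparison: t test for continuous, chi-square
    for binary, Wilcoxon rank-sum for skewed variables.  Reporting only."""
    groups = [g for g in pd.unique(df[group_col]) if pd.notna(g)]
    if len(groups) != 2:
        raise ConfigurationError("descriptive table expects exactly 2 groups")
    a = df[df[group_col] == groups[0]]
    b = df[df[group_col] == groups[1]]
    rows = []
    for var in continuous:
        x, yv = a[var].dropna(), b[var].dropna()
        p = stats.ttest_ind(x, yv, equal_var=False).pvalue if len(x) > 1 and len(yv) > 1 else np.nan
        rows.append({"variable": var, "test": "t",
                     f"group_{groups[0]}": f"{x.mean():.2f} ± {x.std():.2f}",
                     f"group_{groups[1]}": f"{yv.mean():.2f} ± {yv.std():.2f}", "p": p})
    for var in binary:
        tab = pd.crosstab(df[group_col], df[var])
        p = stats.chi2_contingency(tab).pvalue if tab.shape == (2, 2) else np.nan
        rows.append({"variable": var, "test": "chi2",
                     f"group_{groups[0]}": f"{a[var].mean():.3f}",
                     f"group_{groups[1]}": f"{b[var].mean():.3f}", "p": p})
    for var in skewed:
        x, yv = a[var].dropna(), b[var].dropna()
        p = stats.mannwhitneyu(x, yv).pvalue if len(x) and len(yv) else np.nan
        rows.append({"variable": var, "test": "wilcoxon",
                     f"group_{groups[0]}": f"{x.median():.3f}",
                     f"group_{groups[1]}": f"{yv.median():.3f}", "p": p})
    return pd.DataFrame(rows)


def _poisson_block(assignment, covariates=()):
    """Category RRs + linear trend + per-10% increment, Table-2 style."""
    d = assignment.copy()
    d["outcome"] = d["accelerated"].astype(float)
    cat_fit = association.fit_modified_poisson(
        d, outcome="outcome", exposure="score2_category",
        reference="low_to_moderate", covariates=list(covariates),
    )
    code = {c: i for i, c in enumerate(risk_engine.CATEGORIES)}
    d["cat_code"] = d["score2_category"].map(code).astype(float)
    trend = association.trend_and_increment(d, outcome="outcome", exposure="cat_code",
                                            covariates=list(covariates))
    per10 = association.trend_and_increment(d, outcome="outcome", exposure="score2",
                                            scale=10.0, covariates=list(covariates))
    frames = []
    cf = cat_fit.summary_frame(); cf["block"] = "category"
    tf = trend.summary_frame(); tf["block"] = "linear_trend"
    pf = per10.summary_frame(); pf["block"] = "per_10pct"
    frames = pd.concat([cf, tf, pf], ignore_index=True)
    return frames[frames["term"] != "intercept"].reset_index(drop=True)


def _fit_trajectories(fi_panel, config, label=""):
    base_spec = gbtm.GbtmSpec(
        censored=config.gbtm_censored,
        shared_sigma=config.gbtm_shared_sigma,
        n_restarts=config.gbtm_restarts,
        seed=config.seed,
    )
    fit, table = gbtm.select_model(
        fi_panel, k_range=config.k_range, order_range=config.order_range,
        spec_defaults=base_spec,
    )
    fit = gbtm.assign_and_label(fit, fi_panel)
    return fit, table


def run_pipeline(config: StudyConfig) -> dict:
    """Run the full study; returns the bundle of in-memory artefacts and
    writes everything under ``config.outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    registry = (DeficitRegistry.from_file(config.registry_path)
                if config.registry_path else DeficitRegistry.default())
    stage = "input"
    try:
        if config.cohort_csv:
            cohort = pd.read_csv(config.cohort_csv)
            truth = None
        else:
            spec = CohortSpec(**{**config.cohort_spec, "seed": config.seed})
            cohort, truth = generate_cohort(spec, registry)
            write_cohort(cohort.drop(columns=[], errors="ignore"), truth,
                         out / "cohort.csv", out / "cohort_truth.csv")

        stage = "risk_scoring"
        base = cohort[cohort["wave_index"] == 0].copy()
        scored = risk_engine.score_cohort(base, region=config.region)
        scored_cols = scored[["participant_id", "score", "score2", "score2_category"]]

        stage = "frailty_index"
        fi_panel_all = compute_fi_panel(cohort, registry, item_subset="full")

        stage = "inclusion"
        filtered, ledger, flags = apply_inclusion_criteria(
            cohort.merge(scored_cols, on="participant_id", how="left"),
            fi_panel_all, min_waves=config.min_waves,
        )
        ledger.to_csv(out / "exclusion_ledger.csv", index=False)
        flags = flags.merge(scored_cols, on="participant_id", how="left")

        stage = "fi_panel"
        fi_panel = compute_fi_panel(filtered, registry, item_subset=config.fi_subset)
        fi_panel.to_csv(out / "fi_panel.csv", index=False)

        stage = "gbtm"
        fit, candidates = _fit_trajectories(fi_panel, config)
        candidates.to_csv(out / "gbtm_candidates.csv", index=False)
        with open(out / "gbtm_fit.json", "w") as fh:
            json.dump(fit.to_dict(), fh, indent=1)
        diag = gbtm.diagnostics(fit)
        diag.to_csv(out / "gbtm_diagnostics.csv", index=False)

        stage = "assignment"
        labels = np.asarray(fit.labels, dtype=object)
        assignment = pd.DataFrame({
            "participant_id": fit.participant_ids,
            "group": fit.assignment,
            "label": labels[fit.assignment],
        })
        for k in range(fit.k_groups):
            assignment[f"posterior_{k}"] = fit.posterior[:, k]
        assignment["accelerated"] = (
            assignment["label"] == ("accelerated" if fit.k_groups == 3
                                    else fit.labels[-1])).astype(int)
        assignment = assignment.merge(
            filtered[filtered["wave_index"] == 0][
                ["participant_id", "age", "sex", "current_smoking", "sbp", "tc", "hdl"]
            ], on="participant_id", how="left",
        ).merge(scored_cols, on="participant_id", how="left")
        assignment.to_csv(out / "assignment.csv", index=False)

        stage = "risk_ratios"
        rr_table = _poisson_block(assignment)
        rr_table.to_csv(out / "rr_table.csv", index=False)
        counts = rr_table_from_counts(assignment)
        counts.to_csv(out / "rr_counts.csv", index=False)
        _audit_rr(rr_table, counts)

        stage = "lmm"
        if config.run_lmm:
            measures = physical_function.extract_function_measures(
                filtered, walk_course_cm=config.walk_course_cm)
            measures.to_csv(out / "function_measures.csv", index=False)
            lmm_data = measures.merge(
                assignment[["participant_id", "score2", "score2_category"]],
                on="participant_id", how="inner",
            )
            lmm_data = lmm_data.merge(
                filtered[["participant_id", "wave_index"]].drop_duplicates(),
                on=["participant_id", "wave_index"], how="left")
            slope_rows = []
            for meas in ("grip_kg", "pef_l_min", "gait_speed_cm_s", "chair_rises_s"):
                if lmm_data[meas].notna().sum() < 10:
                    continue
                lf = association.fit_lmm_slopes(
                    lmm_data, outcome=meas, exposure="score2_category",
                    reference="low_to_moderate",
                )
                sf = lf.summary_frame()
                sf["measure"] = meas
                sf["block"] = "category"
                slope_rows.append(sf[sf["term"].str.endswith(":time")])
            slopes = (pd.concat(slope_rows, ignore_index=True)
                      if slope_rows else pd.DataFrame())
            slopes.to_csv(out / "lmm_slopes.csv", index=False)
        else:
            slopes = pd.DataFrame()

        stage = "evaluation"
        report = evaluation.evaluate_markers(
            assignment["score"].to_numpy(),
            assignment["score2"].to_numpy(),
            assignment["accelerated"].to_numpy(),
        )
        with open(out / "eval_report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=1, default=float)
        report.decision_curve.to_csv(out / "decision_curve.csv", index=False)
        report.calibration_b.to_csv(out / "calibration_score2.csv", index=False)

        sensitivity = {}
        if config.run_sensitivity:
            stage = "sensitivity_26item"
            fi26 = compute_fi_panel(filtered, registry, item_subset="revised")
            fit26, _ = _fit_trajectories(fi26, config)
            sensitivity["fi26_group_sizes"] = fit26.group_sizes().tolist()
            sensitivity["fi29_group_sizes"] = fit.group_sizes().tolist()

            stage = "sensitivity_ipw"
            flags2 = flags.copy()
            basefull = cohort[cohort["wave_index"] == 0][
                ["participant_id", "age", "sex", "sbp", "tc", "current_smoking"]]
            flags2 = flags2.merge(basefull, on="participant_id", how="left")
            flags2["sex_male"] = (flags2["sex"] == "male").astype(float)
            wdf = weighting.ipw_weights(
                flags2.dropna(subset=["age", "sbp", "tc"]),
                covariates=("age", "sex_male", "sbp", "tc"))
            bal = weighting.balance_smd(
                flags2.dropna(subset=["age", "sbp", "tc"]),
                covariates=("age", "sex_male", "sbp", "tc"),
                weights=wdf["ipw"],
            )
            bal.to_csv(out / "balance_table.csv", index=False)
            merged = assignment.merge(
                wdf[["participant_id", "ipw"]], on="participant_id", how="inner")
            if merged["accelerated"].nunique() == 2:
                wrep = evaluation.evaluate_markers(
                    merged["score"].to_numpy(), merged["score2"].to_numpy(),
                    merged["accelerated"].to_numpy(),
                    weights=merged["ipw"].to_numpy(),
                    bootstrap_seed=config.seed,
                )
                sensitivity["weighted_auc_score2"] = wrep.auc_b["auc"]
                sensitivity["weighted_auc_score"] = wrep.auc_a["auc"]

            stage = "sensitivity_component_adjusted"
            adj = {}
            d = assignment.copy()
            d["sex_male"] = (d["sex"] == "male").astype(float)
            d["smoking"] = d["current_smoking"].astype(float)
            for comp in ("age", "sex_male", "smoking", "sbp", "tc", "hdl"):
                try:
                    f = _poisson_block(d.dropna(subset=[comp]), covariates=(comp,))
                    per10 = f[(f["block"] == "per_10pct")]["rr"].iloc[0]
                    adj[comp] = float(per10)
                except FrailtrajError:
                    adj[comp] = None
            sensitivity["per10_rr_adjusted_for"] = adj

            stage = "sensitivity_moderate_roc"
            if fit.k_groups == 3:
                sub = assignment[assignment["label"].isin(["stable", "moderate"])]
                ymod = (sub["label"] == "moderate").astype(int).to_numpy()
                if 0 < ymod.sum() < len(ymod):
                    sensitivity["moderate_vs_stable_auc_score2"] = evaluation.auc(
                        sub["score2"].to_numpy(), ymod)["auc"]

            stage = "sensitivity_age_strata"
            for name, mask in (("lt65", assignment["age"] < config.age_cut),
                               ("ge65", assignment["age"] >= config.age_cut)):
                sub = assignment[mask]
                ysub = sub["accelerated"].to_numpy()
                if 0 < ysub.sum() < len(ysub):
                    sensitivity[f"auc_score2_{name}"] = evaluation.auc(
                        sub["score2"].to_numpy(), ysub)["auc"]

        stage = "report"
        base_desc = assignment.copy()
        base_desc["smoking"] = base_desc["current_smoking"].astype(float)
        desc = descriptive_table(
            base_desc, "accelerated",
            continuous=("age", "sbp", "tc", "hdl"), binary=("smoking",),
            skewed=("score2",),
        )
        desc.to_csv(out / "baseline_table.csv", index=False)

        with open(out / "sensitivity.json", "w") as fh:
            json.dump(sensitivity, fh, indent=1, default=float)

        import importlib.metadata as im
        try:
            version = im.version("frailtraj")
        except im.PackageNotFoundError:
            version = "unknown"
        manifest = {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "package_version": version,
            "n_input_participants": int(cohort["participant_id"].nunique()),
            "n_included": int(ledger.loc[ledger["criterion"] == "retained",
                                         "n_excluded"].iloc[0]),
            "k_selected": fit.k_groups,
            "labels": list(fit.labels),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    except FrailtrajError as err:
        raise FrailtrajError(f"pipeline failed at stage {stage!r}: {err}") from err

    return {
        "cohort": cohort, "truth": truth, "ledger": ledger, "flags": flags,
        "fi_panel": fi_panel, "gbtm_fit": fit, "gbtm_candidates": candidates,
        "assignment": assignment, "rr_table": rr_table, "rr_counts": counts,
        "lmm_slopes": slopes, "eval_report": report,
        "sensitivity": sensitivity if config.run_sensitivity else {},
        "manifest": manifest,
    }


def _audit_rr(rr_table: pd.DataFrame, counts: pd.DataFrame) -> None:
    """Internal consistency: category RRs must be recomputable from the
    emitted events/total counts (ratio of proportions)."""
    by_cat = counts.set_index("category")
    e0, t0 = by_cat.loc["low_to_moderate", ["events", "total"]]
    if e0 == 0 or t0 == 0:
        return
    p0 = e0 / t0
    for cat in ("high", "very_high"):
        row = rr_table[(rr_table["block"] == "category") & (rr_table["term"] == cat)]
        if row.empty or by_cat.loc[cat, "total"] == 0:
            continue
        p1 = by_cat.loc[cat, "events"] / by_cat.loc[cat, "total"]
        expected = p1 / p0
        got = float(row["rr"].iloc[0])
        if not np.isclose(expected, got, rtol=1e-6, atol=1e-9):
            raise FrailtrajError(
                f"RR audit failed for {cat}: table {got} vs counts {expected}"
            )
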