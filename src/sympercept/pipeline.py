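"""End-to-end cohort analysis: exclusions, descriptives, the accuracy
measure, psychosocial association models, and the cumulative
explained-variance decomposition.

The pipeline mirrors a fixed analysis plan.  Comorbidity exclusions
(cardiovascular disease, generalized anxiety, panic disorder) remove
people whose dyspnea has an ambiguous relation to pulmonary function;
self-reported asthma without physician confirmation is removed to avoid
misclassification; spirometry-dependent stages use only technically valid
measurements.  The accuracy measure is fitted per disease stratum
(control vs asthma/COPD) with an optional sex-stratified variant; sex
enters the association models as a covariate either way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import models
from .acp import acp_summary, compute_acp, median_split, spearman
from .psychometrics import build_component_model
from .simulate import BATTERY_COLUMNS

__all__ = [
    "PipelineConfig",
    "filter_cohort",
    "dichotomize_dyspnea",
    "describe_cohort",
    "build_accuracy_measure",
    "associate_acp",
    "variance_decomposition",
    "run_all",
]

EXCLUSION_FLAGS = ("cvd", "gad", "pd")
COMPONENT_LABELS = {
    "C1": "negative_affect",
    "C2": "fear_of_illness",
    "C3": "worry_of_contracting_disease",
}


@dataclass
class PipelineConfig:
    """Analysis switches; defaults reproduce the primary analysis plan."""

    #: 'group' fits the accuracy model per disease stratum; 'group-sex'
    #: additionally stratifies by sex
    stratify: str = "group"
    #: include sex x compound-score interaction terms in association models
    interactions: bool = False
    #: component retention for the psychosocial PCA
    retention: str = "kaiser"
    n_components: int | None = 3
    loading_threshold: float = 0.4
    oblimin_gamma: float = 0.0
    battery_columns: list = field(default_factory=lambda: list(BATTERY_COLUMNS))

    def to_dict(self) -> dict:
        return {
            "stratify": self.stratify,
            "interactions": self.interactions,
            "retention": self.retention,
            "n_components": self.n_components,
            "loading_threshold": self.loading_threshold,
            "oblimin_gamma": self.oblimin_gamma,
            "battery_columns": list(self.battery_columns),
        }


# ---------------------------------------------------------------------------
# exclusions and descriptives
# ---------------------------------------------------------------------------

def filter_cohort(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the comorbidity and confirmation exclusions.

    Rows with CVD, GAD or PD are removed, as is self-reported asthma
    lacking physician confirmation.  Technically invalid spirometry is
    *not* dropped here: those rows stay for questionnaire-only
    descriptives and are excluded only from spirometry-dependent stages
    (the ``spirometry_valid`` flag travels with the table).  The log
    counts each reason against the rows present when that rule ran, and
    the counts sum to rows_in - rows_out.
    """
    required = list(EXCLUSION_FLAGS) + ["physician_confirmed_asthma", "asthma_copd",
                                        "spirometry_valid"]
    for col in required:
        if col not in table.columns:
            raise ValueError(f"missing required flag column: {col}")
    log = {"rows_in": int(len(table))}
    df = table
    for flag in EXCLUSION_FLAGS:
        drop = df[flag].astype(bool)
        log[f"excluded_{flag}"] = int(drop.sum())
        df = df.loc[~drop]
    unconfirmed = df["asthma_copd"].astype(bool) & ~df[
        "physician_confirmed_asthma"].astype(bool)
    log["excluded_unconfirmed_asthma"] = int(unconfirmed.sum())
    df = df.loc[~unconfirmed]
    log["rows_out"] = int(len(df))
    log["invalid_spirometry_remaining"] = int((~df["spirometry_valid"].astype(bool)).sum())
    return df.copy(), log


def dichotomize_dyspnea(scl_dyspnea) -> np.ndarray:
    """Presence of dyspnea: a report of >= 2 on the 1-5 item."""
    x = np.asarray(scl_dyspnea)
    if np.any((x < 1) | (x > 5)):
        raise ValueError("scl_dyspnea values must lie in 1..5")
    return (x >= 2).astype(int)


def _stratum_labels(df: pd.DataFrame, stratify: str) -> pd.Series:
    group = np.where(df["asthma_copd"].astype(bool), "asthma_copd", "control")
    if stratify == "group":
        return pd.Series(group, index=df.index)
    if stratify == "group-sex":
        return pd.Series(group, index=df.index) + ":" + df["sex"].astype(str)
    raise ValueError(f"unknown stratification {stratify!r}")


def describe_cohort(table: pd.DataFrame) -> dict:
    """Baseline descriptives per disease stratum.

    Categorical columns as N (%), approximately normal columns as
    mean (SD), skewed scores as median (IQR).
    """
    if len(table) == 0:
        raise ValueError("empty cohort")
    out = {}
    strata = _stratum_labels(table, "group")
    for s in ["control", "asthma_copd"]:
        sub = table.loc[strata == s]
        if len(sub) == 0:
            continue
        d: dict = {"n": int(len(sub))}
        d["female_n_pct"] = (int((sub["sex"] == "female").sum()),
                             round(100 * (sub["sex"] == "female").mean(), 1))
        d["age_mean_sd"] = (round(sub["age"].mean(), 1), round(sub["age"].std(), 1))
        d["education_n_pct"] = {
            lvl: (int((sub["education"] == lvl).sum()),
                  round(100 * (sub["education"] == lvl).mean(), 1))
            for lvl in ["low", "medium", "high"]}
        d["smoking_n_pct"] = (int(sub["smoking"].sum()),
                              round(100 * sub["smoking"].mean(), 1))
        present = dichotomize_dyspnea(sub["scl_dyspnea"])
        d["dyspnea_present_n_pct"] = (int(present.sum()),
                                      round(100 * present.mean(), 1))
        valid = sub["spirometry_valid"].astype(bool)
        d["spirometry_valid_n_pct"] = (int(valid.sum()),
                                       round(100 * valid.mean(), 1))
        fev = sub.loc[valid, "fev1pct_pred"]
        d["fev1pct_pred_mean_sd"] = (round(fev.mean(), 1), round(fev.std(), 1))
        d["weight_kg_mean_sd"] = (round(sub["weight_kg"].mean(), 1),
                                  round(sub["weight_kg"].std(), 1))
        q = sub["scl_som_sumscore"].quantile([0.25, 0.5, 0.75])
        d["scl_som_sumscore_med_iqr"] = (float(q[0.5]), (float(q[0.25]), float(q[0.75])))
        out[s] = d
    return out


# ---------------------------------------------------------------------------
# accuracy measure
# ---------------------------------------------------------------------------

def _design(df: pd.DataFrame, cols: list[str]) -> np.ndarray:
    X = df[cols].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(df)), X])


def build_accuracy_measure(table: pd.DataFrame, config: PipelineConfig | None = None
                           ) -> tuple[pd.DataFrame, dict]:
    """Fit the accuracy model per stratum and attach acp/high_flag columns.

    Per stratum (valid-spirometry rows only): a proportional-odds fit of
    the 5-level dyspnea report on FEV1%pred and body weight, the
    parallel-lines test against the multinomial (reported; its failure is
    the stated justification for preferring the multinomial), the
    multinomial fit, per-person ACP, and the stratum-median split.

    Returns the input table with ``acp``, ``acp_stratum`` and
    ``high_flag`` columns added (missing where spirometry is invalid),
    plus a report dict with full provenance.
    """
    config = config or PipelineConfig()
    df = table.copy()
    valid = df["spirometry_valid"].astype(bool)
    df["acp"] = np.nan
    df["acp_stratum"] = ""
    df["high_flag"] = np.nan
    report: dict = {"strata": {}, "n_invalid_spirometry": int((~valid).sum())}
    strata = _stratum_labels(df, config.stratify)
    for s in sorted(strata.unique()):
        mask = (strata == s) & valid
        sub = df.loc[mask]
        y = sub["scl_dyspnea"].to_numpy()
        X = _design(sub, ["fev1pct_pred", "weight_kg"])
        entry: dict = {"n": int(len(sub))}
        levels = np.unique(y)
        if len(levels) < len(np.unique(df["scl_dyspnea"])):
            entry["warning"] = (
                f"stratum {s}: only levels {levels.tolist()} observed; "
                "model fitted on observed levels")
        try:
            ordinal = models.fit_ordinal_po(X, y)
            multinom = models.fit_multinomial(X, y)
        except models.ConvergenceError as exc:
            # typically a quasi-separated singleton outcome level in a tiny
            # stratum; record the diagnostic and leave the stratum unscored
            entry["error"] = f"fit did not converge: {exc}"
            report["strata"][s] = entry
            continue
        plines = models.test_parallel_lines(ordinal, multinom)
        entry["ordinal"] = ordinal.to_dict()
        entry["multinomial"] = multinom.to_dict()
        entry["parallel_lines"] = plines.to_dict()
        entry["parallel_lines_note"] = (
            "proportional odds rejected at 0.05; multinomial model used for the ACP"
            if plines.p < 0.05 else
            "proportional odds not rejected at 0.05; multinomial ACP reported "
            "for comparability")
        acp = compute_acp(multinom, X, y)
        high, med = median_split(acp)
        df.loc[mask, "acp"] = acp
        df.loc[mask, "acp_stratum"] = s
        df.loc[mask, "high_flag"] = high
        summ = acp_summary(acp)
        summ["stratum_median"] = med[0]
        entry["acp_summary"] = summ
        entry["spearman_acp_dyspnea"] = spearman(acp, y)
        report["strata"][s] = entry
    return df, report


# ---------------------------------------------------------------------------
# psychosocial components on the cohort table
# ---------------------------------------------------------------------------

def attach_compound_scores(table: pd.DataFrame, config: PipelineConfig | None = None):
    """Run the component pipeline on the battery columns and append the
    standardized compound scores under their construct names."""
    config = config or PipelineConfig()
    missing = [c for c in config.battery_columns if c not in table.columns]
    if missing:
        raise ValueError(f"battery columns absent from table: {missing}")
    model = build_component_model(
        table[config.battery_columns],
        retention=config.retention,
        n_components=config.n_components,
        gamma=config.oblimin_gamma,
        threshold=config.loading_threshold,
    )
    df = table.copy()
    names = []
    for j, cname in enumerate(model.score_names):
        label = COMPONENT_LABELS.get(cname, cname)
        df[f"score_{label}"] = model.scores[:, j]
        names.append(f"score_{label}")
    return df, model, names


# ---------------------------------------------------------------------------
# association models
# ---------------------------------------------------------------------------

def associate_acp(table_with_scores: pd.DataFrame, config: PipelineConfig | None = None,
                  score_cols: list[str] | None = None) -> pd.DataFrame:
    """Binary logistic association of the median-split ACP with sex and the
    compound scores, per stratum (plus sex-stratified variants).

    Returns a long table of odds ratios with Wald 95% CIs; the high-ACP
    class (more accurately classified) is the modelled outcome.
    """
    config = config or PipelineConfig()
    if score_cols is None:
        score_cols = [c for c in table_with_scores.columns if c.startswith("score_")]
    if "high_flag" not in table_with_scores.columns:
        raise ValueError("high_flag column missing: run build_accuracy_measure first")
    rows = []
    df = table_with_scores.dropna(subset=["high_flag"])
    strata = _stratum_labels(df, "group")

    def _fit(sub, with_sex, label, sexlabel):
        y = sub["high_flag"].to_numpy(dtype=float)
        cols = []
        names = ["intercept"]
        if with_sex:
            cols.append((sub["sex"] == "male").to_numpy(dtype=float))
            names.append("sex_male")
        for c in score_cols:
            cols.append(sub[c].to_numpy(dtype=float))
            names.append(c)
        if config.interactions and with_sex:
            male = (sub["sex"] == "male").to_numpy(dtype=float)
            for c in score_cols:
                cols.append(male * sub[c].to_numpy(dtype=float))
                names.append(f"sex_male:{c}")
        X = np.column_stack([np.ones(len(sub))] + cols)
        fit = models.fit_logistic(X, y)
        p = fit.wald_p()
        for j, name in enumerate(names):
            if name == "intercept":
                continue
            rows.append({
                "stratum": label, "sex": sexlabel, "term": name,
                "or": fit.or_[j], "ci_low": fit.ci95[j, 0],
                "ci_high": fit.ci95[j, 1], "p": p[j], "n": int(len(sub)),
            })

    for s in ["control", "asthma_copd"]:
        sub = df.loc[strata == s]
        if len(sub) == 0:
            continue
        _fit(sub, with_sex=True, label=s, sexlabel="pooled")
        for sex in ["female", "male"]:
            ssub = sub.loc[sub["sex"] == sex]
            if len(ssub) > 0:
                _fit(ssub, with_sex=False, label=s, sexlabel=sex)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cumulative explained variance (Table-2-style)
# ---------------------------------------------------------------------------

STEP_LABELS = [
    "physiology+smoking",
    "+negative_affect",
    "+fear_of_illness",
    "+worry_of_contracting_disease",
]


def variance_decomposition(table_with_scores: pd.DataFrame,
                           config: PipelineConfig | None = None,
                           score_cols: list[str] | None = None) -> pd.DataFrame:
    """Cumulative explained variance in the three symptom outcomes.

    For each disease stratum x sex: four nested models per outcome,
    starting from FEV1%pred + body weight + smoking and adding the
    compound scores one at a time.  The 5-level dyspnea item uses a
    multinomial fit with Nagelkerke pseudo-R²; the two sumscores use
    linear R².  Each step reports the LR p-value of the addition.
    """
    config = config or PipelineConfig()
    if score_cols is None:
        score_cols = [c for c in table_with_scores.columns if c.startswith("score_")]
    base_cols = ["fev1pct_pred", "weight_kg", "smoking"]
    outcomes = [
        ("scl_item", "scl_dyspnea", "pseudo"),
        ("dyspnea_sum", "dyspnea_sumscore", "linear"),
        ("som_sum", "scl_som_sumscore", "linear"),
    ]
    df = table_with_scores.loc[table_with_scores["spirometry_valid"].astype(bool)]
    strata = _stratum_labels(df, "group-sex")
    rows = []
    for s in sorted(strata.unique()):
        sub = df.loc[strata == s]
        for model_name, ycol, metric in outcomes:
            y = sub[ycol].to_numpy()
            prev_ll = None
            prev_r2 = -np.inf
            for step in range(4):
                cols = base_cols + score_cols[:step]
                X = _design(sub, cols)
                if metric == "pseudo":
                    fit = models.fit_multinomial(X, y)
                    null = models.fit_multinomial(np.ones((len(sub), 1)), y)
                    pr2 = models.pseudo_r2(fit.loglik, null.loglik, len(sub))
                    value = pr2.nagelkerke
                    ll = fit.loglik
                    df_step = len(np.unique(y)) - 1
                else:
                    fit = models.fit_linear(X, y.astype(float))
                    value = fit.r2
                    ll = fit.loglik
                    df_step = 1
                lr_p = np.nan
                if step > 0:
                    lr_p = models.lr_test(prev_ll, ll, df_step).p
                value = max(value, prev_r2)  # guard fp wobble; nested by design
                rows.append({
                    "stratum": s.split(":")[0], "sex": s.split(":")[1],
                    "model": model_name, "step": step + 1,
                    "step_label": STEP_LABELS[step],
                    "r2_metric": metric, "value": value, "lr_p": lr_p,
                    "n": int(len(sub)),
                })
                prev_ll, prev_r2 = ll, value
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_all(table: pd.DataFrame, config: PipelineConfig | None = None) -> dict:
    """Full pipeline: filter, describe, accuracy measure, components,
    association and variance decomposition.  Pure function of the input
    table and config."""
    config = config or PipelineConfig()
    filtered, exclusion_log = filter_cohort(table)
    descriptives = describe_cohort(filtered)
    scored, component_model, score_cols = attach_compound_scores(filtered, config)
    with_acp, acp_report = build_accuracy_measure(scored, config)
    or_table = associate_acp(with_acp, config, score_cols)
    var_table = variance_decomposition(with_acp, config, score_cols)
    return {
        "config": config.to_dict(),
        "exclusion_log": exclusion_log,
        "descriptives": descriptives,
        "component_model": component_model,
        "acp_report": acp_report,
        "table": with_acp,
        "or_table": or_table,
        "variance_table": var_table,
    }
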