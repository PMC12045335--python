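"""Synthetic cohort generator.

Emulates the participant-level table the analysis pipeline consumes:
demographics, spirometry (FEV1%pred), body weight derived from BMI and
height, a 32-column psychosocial battery driven by three correlated
latent factors (negative affect, fear of illness, worry of contracting
disease), and an ordinal 5-level dyspnea report generated from a
cumulative-logit latent propensity.

The report propensity is

    L = b1 * z(-FEV1%pred) + b2 * z(weight) + shift * asthma_copd
        + w' F + logistic noise

so that with distortion weights ``w = 0`` the report is driven by
physiology alone, while positive weights let the latent psychosocial
factors distort the mapping from physiology to report — the mechanism
whose footprint the accuracy measure is designed to pick up.  Because the
report is cumulative-logit by construction, the proportional-odds
assumption holds exactly at ``npo_effect = 0`` and is broken in a
controlled way when a category-specific FEV1 term is switched on, giving
the parallel-lines test something real to detect.

Group-level calibration targets (FEV1%pred and BMI moments per disease
group, sex/group shares, and the prevalence of a dyspnea report >= 2:
about 7% in controls, 28% in the asthma/COPD group, ~10% overall) follow
the published baseline description of the Lifelines adult cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SynthConfig", "generate_cohort", "true_params", "implied_category_probs",
           "BATTERY_COLUMNS"]


def _default_factor_corr():
    return np.array([[1.0, 0.5, 0.3], [0.5, 1.0, 0.4], [0.3, 0.4, 1.0]])


# battery layout: (column name, factor block, loading, kind)
# blocks: 0 = negative affect, 1 = fear of illness, 2 = worry of contracting
# disease.  Loadings sit in the 0.6-0.8 band; binary (true/false) items get
# the top of the band because dichotomization attenuates their correlations.
def _default_battery():
    battery = []
    neo = ["anxiety", "hostility", "depression", "selfconsciousness",
           "impulsiveness", "vulnerability"]
    for i, facet in enumerate(neo):
        battery.append((f"neo_{facet}", 0, 0.60 + 0.03 * i, "neo"))
    for i in range(10):
        battery.append((f"panas_na_{i + 1}", 0, 0.62 + 0.02 * i, "panas"))
    for i in range(10):
        battery.append((f"whitely_{i + 1}", 1, 0.80, "whitely"))
    for i in range(10, 14):
        battery.append((f"whitely_{i + 1}", 2, 0.80, "whitely"))
    battery.append(("lte_sum", 2, 0.76, "lte"))
    battery.append(("ldi_sum", 2, 0.80, "ldi"))
    return battery


BATTERY_COLUMNS = [name for name, *_ in _default_battery()]


@dataclass
class SynthConfig:
    """All generative parameters; every field has a study-calibrated default."""

    n: int = 10_000
    p_female: float = 0.59
    p_asthma_copd: float = 0.121
    # FEV1%pred mean/SD per group, truncated to the plausible 16-225 window
    fev1_params: dict = field(default_factory=lambda: {
        "control": (96.7, 12.2), "asthma_copd": (85.3, 14.3)})
    bmi_params: dict = field(default_factory=lambda: {
        "control": (25.8, 4.24), "asthma_copd": (26.7, 4.93)})
    # adult Dutch stature, metres
    height_params: dict = field(default_factory=lambda: {
        "female": (1.68, 0.065), "male": (1.81, 0.07)})
    factor_corr: np.ndarray = field(default_factory=_default_factor_corr)
    battery: list = field(default_factory=_default_battery)
    #: effect of (z(-FEV1%pred), z(weight)) on the report propensity
    physio_coefs: tuple = (0.45, 0.20)
    #: contribution of the latent (NA, fear, worry) factors to the report
    distortion_weights: tuple = (0.50, 0.50, 0.35)
    #: disease-group addition to the propensity (symptom burden beyond FEV1)
    group_shift: float = 1.35
    #: cut-points mapping the latent propensity to the 1-5 report
    thresholds: tuple = (2.95, 4.25, 5.45, 6.65)
    #: category-specific FEV1 term; non-zero breaks proportional odds
    npo_effect: float = 0.0
    exclusion_rates: dict = field(default_factory=lambda: {
        "cvd": 0.088, "gad": 0.042, "pd": 0.002, "invalid_spirometry": 0.296})
    #: share of the asthma/COPD group whose asthma lacks physician confirmation
    p_unconfirmed_asthma: float = 0.03
    age_params: tuple = (42.3, 11.0)
    education_probs: tuple = (0.28, 0.41, 0.31)
    p_smoking: float = 0.215
    #: endorsement threshold (latent z) for binary health-anxiety items;
    #: median split maximizes the information a true/false item retains
    whitely_tau: float = 0.0
    #: cut-points for the five yes/no dyspnea items forming the sumscore
    sumscore_cuts: tuple = (2.4, 3.0, 3.6, 4.2, 4.8)
    #: somatization sumscore: loading on the report propensity and on NA
    som_weights: tuple = (0.6, 0.5)
    seed: int = 0

    def validate(self) -> None:
        fc = np.asarray(self.factor_corr, dtype=float)
        if fc.shape != (3, 3) or not np.allclose(fc, fc.T):
            raise ValueError("factor_corr must be a symmetric 3x3 matrix")
        if not np.allclose(np.diag(fc), 1.0):
            raise ValueError("factor_corr must have unit diagonal")
        if np.linalg.eigvalsh(fc).min() <= 0:
            raise ValueError("factor_corr must be positive definite")
        for prob in (self.p_female, self.p_asthma_copd, self.p_smoking,
                     self.p_unconfirmed_asthma, *self.exclusion_rates.values()):
            if not 0.0 <= prob <= 1.0:
                raise ValueError("proportions must lie in [0, 1]")
        th = np.asarray(self.thresholds, dtype=float)
        if np.any(np.diff(th) <= 0):
            raise ValueError("thresholds must be strictly increasing")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["factor_corr"] = np.asarray(self.factor_corr).tolist()
        return d


def _physio_reference_moments(config: SynthConfig) -> dict:
    """Analytic mixture mean/SD of FEV1%pred and weight under the config.

    Used to standardize the physiology inputs of the report propensity so
    the generative coefficients refer to population z-scores rather than
    sample-dependent ones.
    """
    pa = config.p_asthma_copd
    mc, sc = config.fev1_params["control"]
    ma, sa = config.fev1_params["asthma_copd"]
    fev_mean = (1 - pa) * mc + pa * ma
    fev_var = (1 - pa) * (sc**2 + mc**2) + pa * (sa**2 + ma**2) - fev_mean**2
    # weight = bmi * height^2, mixing over sex and group
    pf = config.p_female
    w_mean = 0.0
    w_m2 = 0.0
    for sex, psex in (("female", pf), ("male", 1 - pf)):
        mh, sh = config.height_params[sex]
        eh2 = mh**2 + sh**2
        eh4 = mh**4 + 6 * mh**2 * sh**2 + 3 * sh**4
        for grp, pgrp in (("control", 1 - pa), ("asthma_copd", pa)):
            mb, sb = config.bmi_params[grp]
            eb2 = mb**2 + sb**2
            w_mean += psex * pgrp * mb * eh2
            w_m2 += psex * pgrp * eb2 * eh4
    w_var = w_m2 - w_mean**2
    return {
        "fev1_mean": fev_mean, "fev1_sd": float(np.sqrt(fev_var)),
        "weight_mean": w_mean, "weight_sd": float(np.sqrt(w_var)),
    }


def _propensity_systematic(config, fev1, weight, asthma, factors) -> np.ndarray:
    ref = _physio_reference_moments(config)
    z_fev = (fev1 - ref["fev1_mean"]) / ref["fev1_sd"]
    z_wt = (weight - ref["weight_mean"]) / ref["weight_sd"]
    b1, b2 = config.physio_coefs
    w = np.asarray(config.distortion_weights, dtype=float)
    return (b1 * (-z_fev) + b2 * z_wt + config.group_shift * asthma
            + factors @ w), z_fev


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(config: SynthConfig) -> pd.DataFrame:
    """Draw a cohort table under the configured generative model.

    All randomness flows from ``config.seed`` through named substreams,
    so the same config yields the identical table.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    streams = {name: np.random.default_rng(child) for name, child in zip(
        ["demo", "physio", "factors", "battery", "report", "flags", "extra"],
        ss.spawn(7))}
    n = config.n
    rng = streams["demo"]
    female = rng.random(n) < config.p_female
    asthma = rng.random(n) < config.p_asthma_copd
    age = _truncnorm(rng, *config.age_params, 18, 95, n)
    education = rng.choice(np.array(["low", "medium", "high"]), size=n,
                           p=np.asarray(config.education_probs) /
                           np.sum(config.education_probs))
    smoking = rng.random(n) < config.p_smoking

    rng = streams["physio"]
    fev1 = np.empty(n)
    bmi = np.empty(n)
    for grp, mask in (("control", ~asthma), ("asthma_copd", asthma)):
        m = int(mask.sum())
        mu, sd = config.fev1_params[grp]
        fev1[mask] = _truncnorm(rng, mu, sd, 16.0, 225.0, m)
        mb, sb = config.bmi_params[grp]
        bmi[mask] = _truncnorm(rng, mb, sb, 14.0, 60.0, m)
    height = np.empty(n)
    for sex, mask in (("female", female), ("male", ~female)):
        mh, sh = config.height_params[sex]
        height[mask] = rng.normal(mh, sh, int(mask.sum()))
    weight = bmi * height**2

    rng = streams["factors"]
    chol = np.linalg.cholesky(np.asarray(config.factor_corr, dtype=float))
    factors = rng.standard_normal((n, 3)) @ chol.T

    rng = streams["battery"]
    battery = {}
    for name, block, loading, kind in config.battery:
        latent = loading * factors[:, block] + np.sqrt(1 - loading**2) * \
            rng.standard_normal(n)
        if kind == "neo":  # facet sumscore, 8 items x 1-5
            battery[name] = np.clip(np.round(20.0 + 6.0 * latent), 8, 40).astype(int)
        elif kind == "panas":  # single 5-point item
            battery[name] = np.clip(np.round(2.1 + 0.9 * latent), 1, 5).astype(int)
        elif kind == "whitely":  # true/false statement
            battery[name] = (latent > config.whitely_tau).astype(int)
        elif kind == "lte":  # count of threatening experiences, 0-12
            battery[name] = np.clip(np.round(1.9 + 1.5 * latent), 0, 12).astype(int)
        elif kind == "ldi":  # long-term difficulties sum, 0-24
            battery[name] = np.clip(np.round(6.0 + 3.0 * latent), 0, 24).astype(int)
        else:
            raise ValueError(f"unknown battery kind {kind!r}")

    rng = streams["report"]
    systematic, z_fev = _propensity_systematic(config, fev1, weight,
                                               asthma.astype(float), factors)
    noise = rng.logistic(0.0, 1.0, n)
    L = systematic + noise
    th = np.asarray(config.thresholds, dtype=float)
    if config.npo_effect != 0.0:
        # person- and category-specific thresholds; monotone by construction
        th_eff = th[None, :] + config.npo_effect * np.arange(4)[None, :] * \
            z_fev[:, None]
        th_eff = np.maximum.accumulate(th_eff, axis=1)
        scl_dyspnea = 1 + (L[:, None] > th_eff).sum(axis=1)
    else:
        scl_dyspnea = 1 + (L[:, None] > th[None, :]).sum(axis=1)

    # five yes/no dyspnea items -> sumscore 0-5 (shared systematic part,
    # independent item noise)
    cuts = np.asarray(config.sumscore_cuts, dtype=float)
    item_noise = rng.logistic(0.0, 1.0, (n, len(cuts)))
    dyspnea_sum = ((systematic[:, None] + item_noise) > cuts[None, :]).sum(axis=1)

    # 12-item somatization sumscore: shares the report propensity and loads
    # extra on the NA factor
    ws, wna = config.som_weights
    som_latent = ws * systematic + wna * factors[:, 0] + rng.standard_normal(n)
    som_sd = np.sqrt(ws**2 * np.var(systematic) + wna**2 + 1.0)
    scl_som = np.clip(np.round(16.0 + 3.4 * som_latent / som_sd), 12, 60).astype(int)

    rng = streams["flags"]
    cvd = rng.random(n) < config.exclusion_rates["cvd"]
    gad = rng.random(n) < config.exclusion_rates["gad"]
    pd_flag = rng.random(n) < config.exclusion_rates["pd"]
    spiro_valid = rng.random(n) >= config.exclusion_rates["invalid_spirometry"]
    confirmed = np.ones(n, dtype=bool)
    confirmed[asthma] = rng.random(int(asthma.sum())) >= config.p_unconfirmed_asthma

    df = pd.DataFrame({
        "id": np.arange(1, n + 1),
        "sex": np.where(female, "female", "male"),
        "age": np.round(age, 1),
        "asthma_copd": asthma.astype(int),
        "physician_confirmed_asthma": confirmed.astype(int),
        "cvd": cvd.astype(int),
        "gad": gad.astype(int),
        "pd": pd_flag.astype(int),
        "spirometry_valid": spiro_valid.astype(int),
        "fev1pct_pred": np.round(fev1, 2),
        "weight_kg": np.round(weight, 1),
        "smoking": smoking.astype(int),
        "education": education,
        "scl_dyspnea": scl_dyspnea.astype(int),
        "dyspnea_sumscore": dyspnea_sum.astype(int),
        "scl_som_sumscore": scl_som,
    })
    for name, *_ in config.battery:
        df[name] = battery[name]
    # ground-truth latent factors, for recovery tests only (dropped by the
    # pipeline's codebook)
    df["_factor_na"] = factors[:, 0]
    df["_factor_fear"] = factors[:, 1]
    df["_factor_worry"] = factors[:, 2]
    return df


def true_params(config: SynthConfig) -> dict:
    """The exact generative parameters, for parameter-recovery assertions."""
    config.validate()
    ref = _physio_reference_moments(config)
    return {
        "physio_coefs": tuple(config.physio_coefs),
        "distortion_weights": tuple(config.distortion_weights),
        "group_shift": config.group_shift,
        "thresholds": tuple(config.thresholds),
        "factor_corr": np.asarray(config.factor_corr).tolist(),
        "loadings": {name: (block, loading) for name, block, loading, _ in
                     config.battery},
        "physio_reference": ref,
        "distortion_var": float(
            np.asarray(config.distortion_weights)
            @ np.asarray(config.factor_corr)
            @ np.asarray(config.distortion_weights)),
    }


def implied_category_probs(config: SynthConfig, fev1, weight, asthma_copd,
                           n_quad: int = 61) -> np.ndarray:
    """Analytic category probabilities P(report = k | physiology, group).

    Marginalizes the latent-factor contribution (normal with variance
    w' Phi w) out of the cumulative-logit model by Gauss-Hermite
    quadrature.  Rows are observations, columns categories 1..5.
    """
    config.validate()
    if config.npo_effect != 0.0:
        raise NotImplementedError("analytic surface only for npo_effect = 0")
    fev1 = np.atleast_1d(np.asarray(fev1, dtype=float))
    weight = np.atleast_1d(np.asarray(weight, dtype=float))
    asthma_copd = np.atleast_1d(np.asarray(asthma_copd, dtype=float))
    systematic, _ = _propensity_systematic(
        config, fev1, weight, asthma_copd, np.zeros((len(fev1), 3)))
    tau = np.sqrt(true_params(config)["distortion_var"])
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    weights = weights / weights.sum()
    th = np.asarray(config.thresholds, dtype=float)
    # P(Y<=k|x) = E_g sigmoid(theta_k - c - tau g)
    z = th[None, :, None] - systematic[:, None, None] - tau * nodes[None, None, :]
    cum = (weights[None, None, :] / (1.0 + np.exp(-z))).sum(axis=2)
    cum = np.column_stack([np.zeros(len(fev1)), cum, np.ones(len(fev1))])
    return np.diff(cum, axis=1)
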