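"""Readers, writers, codebook validation and report assembly.

Cohort tables travel as UTF-8 comma-separated text with a mandatory
header row; every analysis column is declared in a codebook (JSON) that
names its role, type, admissible range and missing token.  The run
manifest is deterministic JSON (sorted keys, no timestamps): the same
input, config and seed produce byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import BATTERY_COLUMNS

__all__ = [
    "default_codebook",
    "read_cohort",
    "write_cohort",
    "write_codebook",
    "read_codebook",
    "config_hash",
    "assemble_report",
    "write_manifest",
]

_FLAGS = ["asthma_copd", "physician_confirmed_asthma", "cvd", "gad", "pd",
          "spirometry_valid", "smoking"]


def default_codebook() -> dict:
    """Codebook matching the synthetic cohort layout."""
    cb: dict = {
        "id": {"role": "id", "type": "integer"},
        "sex": {"role": "sex", "type": "categorical", "levels": ["male", "female"]},
        "age": {"role": "age", "type": "continuous", "range": [18, 120]},
        "fev1pct_pred": {"role": "fev1pct_pred", "type": "continuous",
                         "range": [16, 225]},
        "weight_kg": {"role": "weight_kg", "type": "continuous", "range": [20, 300]},
        "education": {"role": "education", "type": "categorical",
                      "levels": ["low", "medium", "high"]},
        "scl_dyspnea": {"role": "scl_dyspnea", "type": "ordinal", "range": [1, 5]},
        "dyspnea_sumscore": {"role": "dyspnea_sumscore", "type": "integer",
                             "range": [0, 5]},
        "scl_som_sumscore": {"role": "scl_som_sumscore", "type": "integer",
                             "range": [12, 60]},
    }
    for f in _FLAGS:
        cb[f] = {"role": f, "type": "flag"}
    for col in BATTERY_COLUMNS:
        cb[col] = {"role": "psychosocial_item", "type": "integer"}
    for col in cb.values():
        col.setdefault("missing_token", "")
    return cb


REQUIRED_ROLES = [
    "sex", "asthma_copd", "physician_confirmed_asthma", "cvd", "gad", "pd",
    "spirometry_valid", "fev1pct_pred", "weight_kg", "smoking", "scl_dyspnea",
    "dyspnea_sumscore", "scl_som_sumscore",
]


def write_codebook(codebook: dict, path) -> None:
    Path(path).write_text(json.dumps(codebook, indent=2, sort_keys=True) + "\n")


def read_codebook(path) -> dict:
    return json.loads(Path(path).read_text())


def read_cohort(path, codebook: dict | None = None) -> pd.DataFrame:
    """Read and validate a cohort CSV against a codebook.

    Missing tokens become NaN; range violations are rejected with the
    offending row and column named.
    """
    codebook = codebook or default_codebook()
    roles = {spec.get("role") for spec in codebook.values()}
    for role in REQUIRED_ROLES:
        if role not in roles:
            raise ValueError(f"codebook maps no column to required role: {role}")
    df = pd.read_csv(path, dtype="object", keep_default_na=False)
    unmapped = [c for c in REQUIRED_ROLES if c not in df.columns]
    if unmapped:
        raise ValueError(f"input lacks required columns: {unmapped}")
    out = {}
    n_missing = 0
    for col in df.columns:
        spec = codebook.get(col)
        if spec is None:
            continue  # undeclared columns are dropped
        raw = df[col].astype(str)
        miss = raw == str(spec.get("missing_token", ""))
        n_missing += int(miss.sum())
        ctype = spec["type"]
        if ctype == "categorical":
            vals = raw.where(~miss, other=pd.NA)
            bad = vals.dropna()[~vals.dropna().isin(spec["levels"])]
            if len(bad):
                raise ValueError(
                    f"column {col!r}: unknown level {bad.iloc[0]!r} at row "
                    f"{int(bad.index[0])}")
            out[col] = vals
        else:
            vals = pd.to_numeric(raw.where(~miss, other=np.nan), errors="coerce")
            if (vals.isna() & ~miss).any():
                row = int(vals.index[(vals.isna() & ~miss)][0])
                raise ValueError(f"column {col!r}: non-numeric value at row {row}")
            if "range" in spec:
                lo, hi = spec["range"]
                bad = vals.dropna()[(vals.dropna() < lo) | (vals.dropna() > hi)]
                if len(bad):
                    raise ValueError(
                        f"column {col!r}: value {bad.iloc[0]} out of range "
                        f"[{lo}, {hi}] at row {int(bad.index[0])}")
            if ctype in ("flag", "ordinal", "integer") and vals.notna().all():
                vals = vals.astype(int)
            out[col] = vals
    result = pd.DataFrame(out)
    result.attrs["n_missing_tokens"] = n_missing
    return result


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort table as CSV, omitting private (underscored) columns."""
    cols = [c for c in df.columns if not c.startswith("_")]
    df[cols].to_csv(path, index=False)


def config_hash(config: dict) -> str:
    """Stable hash of a config dict (canonical JSON, sha256)."""
    blob = json.dumps(config, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), 10)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


def assemble_report(artifacts: dict, seed: int | None = None) -> dict:
    """Build the run manifest from pipeline artifacts.

    Records the config hash, seed, exclusion log, model summaries, ACP
    summaries, odds-ratio table and variance table; everything needed to
    regenerate the human-readable summary without re-running models.
    """
    cm = artifacts.get("component_model")
    manifest = {
        "config": artifacts["config"],
        "config_hash": config_hash(artifacts["config"]),
        "seed": seed,
        "exclusion_log": artifacts["exclusion_log"],
        "descriptives": _jsonable(artifacts["descriptives"]),
        "acp_report": _jsonable(artifacts["acp_report"]),
        "or_table": _jsonable(artifacts["or_table"].to_dict(orient="records")),
        "variance_table": _jsonable(
            artifacts["variance_table"].to_dict(orient="records")),
    }
    if cm is not None:
        manifest["components"] = _jsonable({
            "kmo": cm.kmo,
            "bartlett": cm.bartlett.to_dict(),
            "n_components": cm.n_components,
            "var_explained": cm.var_explained,
            "alphas": cm.alphas,
            "phi": cm.phi,
            "retained_map": cm.retained_map,
            "pattern": cm.pattern,
            "items": cm.items,
        })
    return manifest


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")


def render_summary(manifest: dict) -> str:
    """Human-readable run summary (baseline table and variance table)."""
    lines = ["# Run summary", "", f"config hash: {manifest['config_hash']}", ""]
    lines.append("## Exclusions")
    for k, v in manifest["exclusion_log"].items():
        lines.append(f"  {k}: {v}")
    lines.append("")
    lines.append("## Baseline characteristics")
    for s, d in manifest["descriptives"].items():
        lines.append(f"  [{s}] n={d['n']}")
        for k, v in d.items():
            if k != "n":
                lines.append(f"    {k}: {v}")
    if "components" in manifest:
        c = manifest["components"]
        lines.append("")
        lines.append("## Psychosocial components")
        lines.append(f"  KMO: {c['kmo']:.3f}; Bartlett p: {c['bartlett']['p']:.3g}")
        lines.append(f"  components: {c['n_components']}; "
                     f"variance explained: {['%.1f%%' % (100 * v) for v in c['var_explained']]}")
        lines.append(f"  alphas: {c['alphas']}")
    lines.append("")
    lines.append("## Accuracy measure (ACP)")
    for s, e in manifest["acp_report"]["strata"].items():
        a = e["acp_summary"]
        lines.append(
            f"  [{s}] median={a['median']:.3f} IQR=({a['iqr'][0]:.3f}, "
            f"{a['iqr'][1]:.3f}) frac<=0.5={a['frac_at_or_below_half']:.3f}")
        pl = e["parallel_lines"]
        lines.append(
            f"        parallel lines: X2({pl['df']})={pl['statistic']:.1f}, "
            f"p={pl['p']:.3g}")
    lines.append("")
    lines.append("## Cumulative explained variance")
    for row in manifest["variance_table"]:
        lines.append(
            f"  {row['stratum']}/{row['sex']} {row['model']} step{row['step']} "
            f"({row['step_label']}): {100 * row['value']:.1f}%")
    return "\n".join(lines) + "\n"
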