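"""Actual category probability (ACP): a per-person symptom-perception
accuracy score.

The ACP of a participant is the fitted multinomial model's probability of
that participant's *observed* outcome category given their physiological
predictors.  A high ACP means the physiology alone would have classified
the person into the dyspnea level they actually reported; a low ACP marks
a mismatch between physiology and report.  The score is dichotomized at
the median of its own stratum ("split on the respective medians"), giving
a more-accurately / less-accurately classified contrast for downstream
association models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import MultinomialFit, predict_category_probs

__all__ = ["AcpResult", "compute_acp", "median_split", "acp_summary", "spearman"]


@dataclass
class AcpResult:
    """Per-participant ACP values with stratum medians and high/low flags.

    ``high_flag`` is 1 when ``acp > stratum_median`` (strict: ties at the
    median go to the low class, keeping the "more accurately classified"
    class conservative).
    """

    acp: np.ndarray
    stratum: np.ndarray
    stratum_median: dict
    high_flag: np.ndarray
    frac_below_half: dict
    tie_rule: str = "high_flag = (acp > stratum_median); ties -> low"

    def to_frame(self, ids=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "stratum": self.stratum,
                "acp": self.acp,
                "stratum_median": [self.stratum_median[s] for s in self.stratum],
                "high_flag": self.high_flag,
            }
        )
        if ids is not None:
            df.insert(0, "id", np.asarray(ids))
        return df


def compute_acp(fit: MultinomialFit, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """ACP values: predicted probability of each observed outcome category.

    With an intercept-only model this reduces exactly to the empirical
    share of each participant's category.
    """
    y = np.asarray(y)
    cats = np.asarray(fit.categories)
    # fit.categories is (ref, others); build a lookup
    pos = {c: j for j, c in enumerate(cats.tolist())}
    try:
        col = np.array([pos[v] for v in y.tolist()])
    except KeyError as exc:
        raise ValueError(f"outcome level {exc.args[0]!r} not in fitted categories") from None
    P = predict_category_probs(fit, X)
    return P[np.arange(len(y)), col]


def median_split(
    acp_values: np.ndarray, strata: np.ndarray | None = None
) -> tuple[np.ndarray, dict]:
    """Dichotomize ACP at each stratum's own median.

    Returns the 0/1 high flags and a dict of per-stratum medians.  A
    stratum of size < 2 is flagged all-low (with its single value as the
    median), since a split is not meaningful there.
    """
    acp_values = np.asarray(acp_values, dtype=float)
    if strata is None:
        strata = np.zeros(len(acp_values), dtype=int)
    strata = np.asarray(strata)
    high = np.zeros(len(acp_values), dtype=int)
    medians: dict = {}
    for s in np.unique(strata):
        m = strata == s
        if m.sum() == 0:
            raise ValueError(f"empty stratum {s!r}")
        med = float(np.median(acp_values[m]))
        medians[s.item() if hasattr(s, "item") else s] = med
        if m.sum() >= 2:
            high[m] = (acp_values[m] > med).astype(int)
    return high, medians


def acp_summary(acp_values: np.ndarray) -> dict:
    """Distribution summary: median, IQR, share at/below 0.5, histogram.

    Quartiles use linear interpolation between order statistics; the
    low-accuracy share uses ``acp <= 0.5``.
    """
    acp_values = np.asarray(acp_values, dtype=float)
    if acp_values.size == 0:
        raise ValueError("empty ACP vector")
    q1, med, q3 = np.quantile(acp_values, [0.25, 0.5, 0.75], method="linear")
    counts, edges = np.histogram(acp_values, bins=20, range=(0.0, 1.0))
    return {
        "n": int(acp_values.size),
        "median": float(med),
        "iqr": (float(q1), float(q3)),
        "frac_at_or_below_half": float(np.mean(acp_values <= 0.5)),
        "histogram": {"counts": counts.tolist(), "edges": edges.tolist()},
    }


def spearman(x: np.ndarray, y: np.ndarray) -> dict:
    """Spearman rank correlation with large-sample t-approximation p-value.

    Pearson correlation of average (midrank) ranks, as implemented in
    scipy; undefined when either variable has zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("inputs must have equal length >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("zero variance in ranks: Spearman correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p)}
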