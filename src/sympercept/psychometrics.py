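"""Principal components of the psychosocial battery.

Implements the component-reduction step of the pipeline: sampling-adequacy
diagnostics (Kaiser-Meyer-Olkin, Bartlett sphericity), PCA of the item
correlation matrix with direct-oblimin rotation (gradient-projection
algorithm; gamma = 0 gives direct quartimin), the >= 0.4 single-loading
item-retention rule, unit-weighted standardized compound scores, and
Cronbach's alpha per component.

Rotation is oblique on purpose: negative affect, fear of illness and
health worry are correlated constructs, and an orthogonal rotation would
distort their loading pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import TestResult

__all__ = [
    "ComponentModel",
    "kmo",
    "bartlett_sphericity",
    "pca_oblimin",
    "assign_items",
    "compound_scores",
    "cronbach_alpha",
    "build_component_model",
]

REMOVED = "removed"


@dataclass
class ComponentModel:
    """PCA + oblimin solution with retention map and compound scores.

    ``pattern`` holds the rotated pattern loadings (unique contributions),
    ``structure = pattern @ phi`` the item-component correlations, ``phi``
    the component intercorrelations.  ``retained_map`` maps each item name
    to a component index or ``"removed"``.
    """

    items: list
    eigenvalues: np.ndarray
    pattern: np.ndarray
    structure: np.ndarray
    phi: np.ndarray
    var_explained: np.ndarray
    retained_map: dict = field(default_factory=dict)
    scores: np.ndarray | None = None
    score_names: list = field(default_factory=list)
    alphas: dict = field(default_factory=dict)
    kmo: float | None = None
    bartlett: TestResult | None = None
    rotation_converged: bool = True

    @property
    def n_components(self) -> int:
        return self.pattern.shape[1]

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"C{j + 1}" for j in range(self.n_components)]
        return pd.DataFrame(self.pattern, index=self.items, columns=cols)


def _corr_matrix(items: np.ndarray) -> np.ndarray:
    items = np.asarray(items, dtype=float)
    if items.ndim != 2 or items.shape[1] < 2:
        raise ValueError("item table must be 2-D with >= 2 items")
    sd = items.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance item in battery")
    return np.corrcoef(items, rowvar=False)


def kmo(item_table) -> float:
    """Kaiser-Meyer-Olkin measure of sampling adequacy (overall).

    Ratio of summed squared off-diagonal correlations to the same plus
    summed squared anti-image partial correlations.  Values above 0.7
    are conventionally considered adequate for component analysis; any
    2-item battery gives exactly 0.5 because partial and marginal
    correlations coincide.
    """
    items = np.asarray(item_table, dtype=float)
    if items.shape[1] < 2:
        raise ValueError("KMO requires >= 2 items")
    R = _corr_matrix(items)
    try:
        S = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        raise ValueError("singular item correlation matrix") from None
    d = np.sqrt(np.diag(S))
    Q = -S / np.outer(d, d)  # anti-image partial correlations
    off = ~np.eye(len(R), dtype=bool)
    r2 = np.sum(R[off] ** 2)
    q2 = np.sum(Q[off] ** 2)
    return float(r2 / (r2 + q2))


def bartlett_sphericity(item_table) -> TestResult:
    """Bartlett test that the item correlation matrix is the identity.

    statistic = -(n - 1 - (2p + 5)/6) * ln|R|, df = p(p-1)/2.
    """
    items = np.asarray(item_table, dtype=float)
    n, p = items.shape
    if n <= p:
        raise ValueError("Bartlett test requires n > p")
    R = _corr_matrix(items)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("non-positive determinant of correlation matrix")
    stat = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    stat = max(stat, 0.0)
    df = p * (p - 1) // 2
    return TestResult(statistic=float(stat), df=int(df), p=float(stats.chi2.sf(stat, df)))


# ---------------------------------------------------------------------------
# oblimin rotation (gradient projection, oblique)
# ---------------------------------------------------------------------------

def _oblimin_criterion(L: np.ndarray, gamma: float) -> tuple[float, np.ndarray]:
    """Direct-oblimin criterion value and gradient wrt loadings."""
    p, k = L.shape
    L2 = L**2
    M = np.ones((k, k)) - np.eye(k)
    C = np.eye(p) - (gamma / p) * np.ones((p, p))
    inner = C @ L2 @ M
    f = np.sum(L2 * inner) / 4.0
    G = L * inner
    return f, G


def oblimin_rotate(
    A: np.ndarray,
    gamma: float = 0.0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Oblique gradient-projection rotation minimizing the oblimin criterion.

    Parameters
    ----------
    A : (p, k) unrotated loadings.
    gamma : oblimin family parameter; 0 = direct quartimin (default).

    Returns (pattern, phi, converged) with pattern = A @ inv(T).T and
    phi = T'T, T having unit-norm columns.
    """
    A = np.asarray(A, dtype=float)
    p, k = A.shape
    if k == 1:
        return A.copy(), np.ones((1, 1)), True
    T = np.eye(k)
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _oblimin_criterion(L, gamma)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    converged = False
    for _ in range(max_iter):
        Gp = G - T * (T * G).sum(axis=0)  # project onto the oblique manifold
        s = np.sqrt(np.sum(Gp**2))
        if s < tol:
            converged = True
            break
        al *= 2.0
        improved = False
        for _half in range(30):
            X = T - al * Gp
            X = X / np.sqrt((X**2).sum(axis=0))
            Ti_t = np.linalg.inv(X)
            L_t = A @ Ti_t.T
            f_t, Gq_t = _oblimin_criterion(L_t, gamma)
            if f_t < f - 0.5 * s**2 * al:
                improved = True
                break
            al *= 0.5
        if not improved:
            # step size exhausted: no further descent along the projected
            # gradient, accept the current point as converged
            converged = True
            break
        T, Ti, L, f, Gq = X, Ti_t, L_t, f_t, Gq_t
        G = -(L.T @ Gq @ Ti).T
    phi = T.T @ T
    return L, phi, converged


def _order_and_sign(pattern, phi, eigenvalues_k):
    """Deterministic component order (descending SS structure loadings) and sign."""
    structure = pattern @ phi
    ss = (structure**2).sum(axis=0)
    order = np.argsort(-ss)
    pattern = pattern[:, order]
    phi = phi[np.ix_(order, order)]
    ev = eigenvalues_k[order] if eigenvalues_k is not None else None
    # flip each component so its loading sum is positive
    signs = np.where(pattern.sum(axis=0) >= 0, 1.0, -1.0)
    pattern = pattern * signs
    phi = phi * np.outer(signs, signs)
    return pattern, phi, ev


def pca_oblimin(
    item_table,
    retention: str = "kaiser",
    n_components: int | None = None,
    gamma: float = 0.0,
    item_names: list | None = None,
) -> ComponentModel:
    """PCA of the item correlation matrix with direct-oblimin rotation.

    ``retention='kaiser'`` keeps components with eigenvalue > 1;
    ``retention='fixed_k'`` keeps ``n_components``.  Adequacy statistics
    (KMO/Bartlett) are computed and attached but do not gate the fit — a
    warning-level decision left to the caller.
    """
    if isinstance(item_table, pd.DataFrame):
        if item_names is None:
            item_names = list(item_table.columns)
        items = item_table.to_numpy(dtype=float)
    else:
        items = np.asarray(item_table, dtype=float)
    p = items.shape[1]
    if item_names is None:
        item_names = [f"item{i + 1}" for i in range(p)]
    R = _corr_matrix(items)
    eigvals, eigvecs = np.linalg.eigh(R)
    eigvals = eigvals[::-1]
    eigvecs = eigvecs[:, ::-1]
    if retention == "kaiser":
        k = int(np.sum(eigvals > 1.0))
    elif retention == "fixed_k":
        if n_components is None:
            raise ValueError("fixed_k retention requires n_components")
        k = int(n_components)
    else:
        raise ValueError(f"unknown retention rule {retention!r}")
    if k < 1:
        raise ValueError("no components retained")
    A = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    pattern, phi, conv = oblimin_rotate(A, gamma=gamma)
    if not conv:
        raise RuntimeError("oblimin rotation did not converge")
    pattern, phi, _ = _order_and_sign(pattern, phi, eigvals[:k])
    structure = pattern @ phi
    var_explained = eigvals[:k] / p
    model = ComponentModel(
        items=list(item_names),
        eigenvalues=eigvals,
        pattern=pattern,
        structure=structure,
        phi=phi,
        var_explained=var_explained,
        rotation_converged=conv,
    )
    model.kmo = kmo(items)
    model.bartlett = bartlett_sphericity(items)
    return model


def assign_items(pattern: np.ndarray, threshold: float = 0.4, item_names=None) -> dict:
    """Single-loading retention rule.

    An item is kept iff exactly one component carries an absolute pattern
    loading >= threshold; kept items map to that component's index, all
    others map to ``"removed"`` (cross-loaders and weak loaders alike).
    """
    pattern = np.asarray(pattern, dtype=float)
    if not np.isfinite(pattern).all():
        raise ValueError("non-finite pattern loadings")
    if pattern.ndim == 1:
        pattern = pattern[None, :]
    p = pattern.shape[0]
    if item_names is None:
        item_names = [f"item{i + 1}" for i in range(p)]
    out = {}
    for i, name in enumerate(item_names):
        hits = np.flatnonzero(np.abs(pattern[i]) >= threshold)
        out[name] = int(hits[0]) if len(hits) == 1 else REMOVED
    return out


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=0)
    return (x - x.mean(axis=0)) / sd


def compound_scores(
    item_table,
    retained_map: dict,
    pattern: np.ndarray | None = None,
    item_names: list | None = None,
) -> tuple[np.ndarray, list]:
    """Standardized unit-weighted compound scores per component.

    Each retained item is z-scored, sign-aligned with its pattern loading
    (so reverse-keyed items do not cancel), averaged within component, and
    the average re-standardized to mean 0 / SD 1.
    """
    if isinstance(item_table, pd.DataFrame):
        if item_names is None:
            item_names = list(item_table.columns)
        items = item_table.to_numpy(dtype=float)
    else:
        items = np.asarray(item_table, dtype=float)
    if item_names is None:
        item_names = [f"item{i + 1}" for i in range(items.shape[1])]
    name_to_col = {n: j for j, n in enumerate(item_names)}
    comps = sorted({c for c in retained_map.values() if c != REMOVED})
    if not comps:
        raise ValueError("retained map assigns no items to any component")
    scores = np.zeros((items.shape[0], len(comps)))
    for out_j, c in enumerate(comps):
        members = [n for n, cc in retained_map.items() if cc == c]
        if not members:
            raise ValueError(f"component {c} has no retained items")
        cols = [name_to_col[n] for n in members]
        block = items[:, cols]
        sd = block.std(axis=0, ddof=0)
        keep = sd > 0
        if not keep.all():
            block = block[:, keep]
            cols = [c_ for c_, k_ in zip(cols, keep) if k_]
        z = _zscore(block)
        if pattern is not None:
            signs = np.sign(np.asarray(pattern)[cols, c])
            signs[signs == 0] = 1.0
            z = z * signs
        comp = z.mean(axis=1)
        scores[:, out_j] = _zscore(comp[:, None])[:, 0]
    return scores, comps


def cronbach_alpha(items_of_component) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum(item variances)/variance(total))."""
    items = np.asarray(items_of_component, dtype=float)
    if items.ndim != 2 or items.shape[1] < 2:
        raise ValueError("alpha requires >= 2 items")
    k = items.shape[1]
    item_var = items.var(axis=0, ddof=1)
    total_var = items.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("zero total-score variance: alpha undefined")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


def build_component_model(
    item_table,
    retention: str = "kaiser",
    n_components: int | None = None,
    gamma: float = 0.0,
    threshold: float = 0.4,
) -> ComponentModel:
    """Run the full component pipeline: PCA + oblimin, retention rule,
    compound scores, and per-component Cronbach's alpha."""
    if isinstance(item_table, pd.DataFrame):
        names = list(item_table.columns)
        items = item_table.to_numpy(dtype=float)
    else:
        items = np.asarray(item_table, dtype=float)
        names = [f"item{i + 1}" for i in range(items.shape[1])]
    model = pca_oblimin(items, retention=retention, n_components=n_components,
                        gamma=gamma, item_names=names)
    model.retained_map = assign_items(model.pattern, threshold=threshold, item_names=names)
    scores, comps = compound_scores(items, model.retained_map,
                                    pattern=model.pattern, item_names=names)
    model.scores = scores
    model.score_names = [f"C{c + 1}" for c in comps]
    name_to_col = {n: j for j, n in enumerate(names)}
    for c in comps:
        members = [name_to_col[n] for n, cc in model.retained_map.items() if cc == c]
        if len(members) >= 2:
            # alpha on z-scored, sign-aligned items (composites are built that way)
            block = _zscore(items[:, members])
            signs = np.sign(model.pattern[members, c])
            signs[signs == 0] = 1.0
            model.alphas[f"C{c + 1}"] = cronbach_alpha(block * signs)
    return model
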