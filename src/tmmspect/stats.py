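"""Chemometrics and inference for the steady-state metabolite tables.

PCA score plots separate the CONTROL / TERT / ALT metabolic profiles; the
PLS-DA variable-importance-in-projection (VIP) screen with the >1.0 rule
names the discriminating metabolites; Welch's unequal-variance t test with
Holm-Sidak step-down correction supplies the univariate confirmation.

The VIP scores satisfy the algebraic identity sum_j VIP_j^2 = p (number of
variables) because the PLS weight vectors are unit-normalized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PCAResult",
    "VIPResult",
    "WelchResult",
    "pca_scores",
    "plsda_vip",
    "welch_t",
    "holm_sidak",
    "group_welch_tests",
]


def _numeric_matrix(table: pd.DataFrame) -> Tuple[np.ndarray, list]:
    cols = [c for c in table.columns if c != "group"]
    X = table[cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("table contains missing or non-finite values")
    return X, cols


def _scale(X: np.ndarray, cols: Sequence[str], scaling: str) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    if scaling == "center":
        return Xc
    if scaling == "autoscale":
        sd = X.std(axis=0, ddof=1)
        dead = np.where(sd == 0)[0]
        if dead.size:
            raise ValueError(
                f"zero-variance column under autoscale: {cols[dead[0]]!r}"
            )
        return Xc / sd
    raise ValueError(f"scaling must be 'center' or 'autoscale', got {scaling!r}")


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray


def pca_scores(
    table: pd.DataFrame,
    scaling: str = "autoscale",
    n_components: Optional[int] = None,
) -> PCAResult:
    """PCA of a samples x metabolites table via SVD.

    Scores use a deterministic sign convention: within each component the
    loading entry of largest magnitude is made positive. Explained-variance
    fractions over all components sum to 1.
    """
    X, cols = _numeric_matrix(table)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 metabolites")
    Z = _scale(X, cols, scaling)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    k = len(s) if n_components is None else min(n_components, len(s))
    # deterministic sign: largest-|loading| entry positive per component
    for a in range(k):
        j = int(np.argmax(np.abs(Vt[a])))
        if Vt[a, j] < 0:
            Vt[a] *= -1
            U[:, a] *= -1
    scores = U[:, :k] * s[:k]
    evr = s**2 / np.sum(s**2)
    pc_names = [f"PC{a + 1}" for a in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=table.index, columns=pc_names),
        loadings=pd.DataFrame(Vt[:k].T, index=cols, columns=pc_names),
        explained_variance_ratio=evr[:k],
    )


@dataclass
class VIPResult:
    """Per-metabolite VIP scores and the >1.0 discriminating flags."""

    scores: pd.Series
    n_components: int
    discriminating: pd.Series

    def __post_init__(self) -> None:
        p = self.scores.size
        total = float((self.scores**2).sum())
        if not np.isclose(total, p, rtol=1e-6):
            raise ValueError(f"VIP identity violated: sum VIP^2 = {total}, p = {p}")


def _indicator(labels: Sequence[str]) -> np.ndarray:
    """Group-indicator response: one centered column for two groups, one
    column per group otherwise."""
    labels = np.asarray(labels)
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ValueError("need two or more groups")
    if len(groups) == 2:
        Y = (labels == groups[1]).astype(float)[:, None]
    else:
        Y = np.stack([(labels == g).astype(float) for g in groups], axis=1)
    return Y - Y.mean(axis=0)


def plsda_vip(
    table: pd.DataFrame,
    labels: Optional[Sequence[str]] = None,
    n_components: int = 2,
) -> VIPResult:
    """PLS-DA variable importance in projection via NIPALS.

    X is autoscaled; Y is the centered group indicator. With SS_a the
    Y-variance explained by component a and w_a the unit weight vector,
    VIP_j = sqrt(p * sum_a SS_a w_ja^2 / sum_a SS_a). Metabolites with
    VIP > 1.0 are flagged discriminating.
    """
    if labels is None:
        if "group" not in table.columns:
            raise ValueError("labels required when the table has no 'group' column")
        labels = table["group"].to_numpy()
    X, cols = _numeric_matrix(table)
    Z = _scale(X, cols, "autoscale")
    Y = _indicator(labels)
    rank = np.linalg.matrix_rank(Z)
    if n_components > rank:
        raise ValueError(f"n_components {n_components} exceeds rank {rank}")

    p = Z.shape[1]
    W = np.zeros((p, n_components))
    ss = np.zeros(n_components)
    Xa, Ya = Z.copy(), Y.copy()
    for a in range(n_components):
        u = Ya[:, 0].copy()
        t_old = np.zeros(Z.shape[0])
        for _ in range(500):
            w = Xa.T @ u
            norm = np.linalg.norm(w)
            if norm == 0:
                raise ValueError("NIPALS collapsed: zero weight vector")
            w /= norm
            t = Xa @ w
            q = Ya.T @ t / (t @ t)
            u = Ya @ q / (q @ q) if (q @ q) > 0 else t
            if np.linalg.norm(t - t_old) <= 1e-12 * max(np.linalg.norm(t), 1.0):
                break
            t_old = t
        pvec = Xa.T @ t / (t @ t)
        Xa = Xa - np.outer(t, pvec)
        Ya = Ya - np.outer(t, q)
        W[:, a] = w
        ss[a] = (t @ t) * float(q @ q)  # Y-variance explained by component a

    total = ss.sum()
    if total == 0:
        raise ValueError("no Y variance explained; labels may be degenerate")
    vip = np.sqrt(p * (W**2 @ ss) / total)
    scores = pd.Series(vip, index=cols, name="VIP")
    return VIPResult(
        scores=scores,
        n_components=n_components,
        discriminating=scores > 1.0,
    )


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def welch_t(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Unpaired t test assuming unequal variances (Welch-Satterthwaite)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = x.size, y.size
    se2 = vx / nx + vy / ny
    if se2 == 0:
        return WelchResult(t=0.0, df=float(nx + ny - 2), p=1.0)
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p=float(p))


def holm_sidak(
    pvalues: Sequence[float], alpha: float = 0.05
) -> Tuple[np.ndarray, np.ndarray]:
    """Holm-Sidak step-down adjusted p-values and rejection flags.

    Sorted ascending, adj_(i) = 1 - (1 - p_(i))^(m - i + 1), made monotone
    non-decreasing by a running maximum; hypotheses are rejected step-down
    while the adjusted p stays below alpha. Results are returned in the
    original order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    reject_sorted = np.zeros(m, dtype=bool)
    for i in range(m):
        if adj_sorted[i] < alpha:
            reject_sorted[i] = True
        else:
            break
    adj = np.empty(m)
    reject = np.empty(m, dtype=bool)
    adj[order] = np.minimum(adj_sorted, 1.0)
    reject[order] = reject_sorted
    return adj, reject


def group_welch_tests(
    table: pd.DataFrame,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-metabolite Welch tests between two groups with Holm-Sidak
    correction; returns t, df, raw and adjusted p, and rejection flags."""
    if "group" not in table.columns:
        raise ValueError("table must have a 'group' column")
    cols = [c for c in table.columns if c != "group"]
    a = table[table["group"] == group_a]
    b = table[table["group"] == group_b]
    if a.empty or b.empty:
        raise ValueError(f"missing group {group_a!r} or {group_b!r}")
    results = {c: welch_t(a[c], b[c]) for c in cols}
    raw_p = np.array([results[c].p for c in cols])
    adj, reject = holm_sidak(raw_p, alpha=alpha)
    return pd.DataFrame(
        {
            "t": [results[c].t for c in cols],
            "df": [results[c].df for c in cols],
            "p": raw_p,
            "p_adj": adj,
            "reject": reject,
        },
        index=cols,
    )
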