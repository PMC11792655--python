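"""Canonical correlation between interpersonal-trait and behavioral blocks,
with a permutation significance test, plus game-behavior rank correlations.

The first canonical pair maximizes corr(X w_x, Y w_y) over weight vectors;
it is computed from the SVD of Q_x' Q_y where Q_x, Q_y are orthonormal bases
of the column-centered blocks.  Loadings are reported as structure
correlations (variable vs canonical variate), with the sign convention that
the loading of the first behavioral column (accuracy) is nonnegative, so
larger canonical scores mean better performance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: trait-block columns in canonical order
TRAIT_VARS = ["empathic_concern", "perspective_taking", "fantasy",
              "personal_distress", "independent_sc", "interdependent_sc",
              "friend_months", "closeness", "likability", "familiarity"]
#: behavior-block columns (friend-match performance)
BEHAVIOR_VARS = ["accuracy", "rt_ms", "d_prime", "beta"]


@dataclass
class CanonicalResult:
    rho: float
    x_weights: np.ndarray
    y_weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    x_scores: np.ndarray
    y_scores: np.ndarray
    n: int
    p_perm: float | None = None
    n_perm: int | None = None


def _standardize(M: np.ndarray, names) -> np.ndarray:
    M = np.asarray(M, float)
    sd = M.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd < 1e-12)
    if len(zero):
        bad = [names[i] if names is not None else str(i) for i in zero]
        raise ValueError(f"constant columns cannot enter CCA: {bad}")
    return (M - M.mean(axis=0)) / sd


def canonical_correlation(X, Y, x_names=None, y_names=None) -> CanonicalResult:
    """First canonical correlation, weights, and structure loadings.

    Requires more subjects than variables in either block and full column
    rank in both; rank-deficient blocks raise naming the collinear columns.
    """
    if isinstance(X, pd.DataFrame):
        x_names = list(X.columns)
        X = X.to_numpy(float)
    if isinstance(Y, pd.DataFrame):
        y_names = list(Y.columns)
        Y = Y.to_numpy(float)
    n, p = X.shape
    q = Y.shape[1]
    if Y.shape[0] != n:
        raise ValueError("X and Y must have the same number of rows")
    if n <= max(p, q):
        raise ValueError(f"need n > max(p, q): n={n}, p={p}, q={q}")
    Xs = _standardize(X, x_names)
    Ys = _standardize(Y, y_names)

    qx, rx = np.linalg.qr(Xs)
    qy, ry = np.linalg.qr(Ys)
    for r, names, block in ((rx, x_names, "X"), (ry, y_names, "Y")):
        small = np.flatnonzero(np.abs(np.diag(r)) < 1e-8 * np.abs(np.diag(r)).max())
        if len(small):
            bad = [names[i] if names is not None else str(i) for i in small]
            raise ValueError(f"rank-deficient {block} block; collinear "
                             f"columns: {bad}")
    u, s, vt = np.linalg.svd(qx.T @ qy)
    rho = float(np.clip(s[0], 0.0, 1.0))
    wx = np.linalg.solve(rx, u[:, 0])
    wy = np.linalg.solve(ry, vt[0, :])
    xs = Xs @ wx
    ys = Ys @ wy

    # sign convention: first behavioral loading (accuracy) nonnegative
    if np.corrcoef(Ys[:, 0], ys)[0, 1] < 0:
        wx, wy, xs, ys = -wx, -wy, -xs, -ys
    x_load = np.array([np.corrcoef(Xs[:, j], xs)[0, 1] for j in range(p)])
    y_load = np.array([np.corrcoef(Ys[:, j], ys)[0, 1] for j in range(q)])
    return CanonicalResult(rho=rho, x_weights=wx, y_weights=wy,
                           x_loadings=x_load, y_loadings=y_load,
                           x_scores=xs, y_scores=ys, n=n)


def permutation_pvalue(X, Y, n_perm: int = 1000, seed: int = 0
                       ) -> CanonicalResult:
    """Permutation test of the first canonical correlation.

    Rows of Y are permuted; p = (#{rho_perm >= rho_obs} + 1) / (n_perm + 1).
    """
    import warnings

    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p-values are coarse",
                      stacklevel=2)
    res = canonical_correlation(X, Y)
    Ya = Y.to_numpy(float) if isinstance(Y, pd.DataFrame) else np.asarray(Y, float)
    Xa = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(Ya))
        if canonical_correlation(Xa, Ya[perm]).rho >= res.rho:
            count += 1
    res.p_perm = (count + 1) / (n_perm + 1)
    res.n_perm = n_perm
    return res


def game_correlations(diff_accuracy, games: pd.DataFrame,
                      game_cols=("trust_send", "pgg_contribution"),
                      n_boot: int = 2000, seed: int = 0) -> pd.DataFrame:
    """Spearman rho (with bootstrap 95% CI) between the friend-minus-self
    accuracy difference and each game's contribution."""
    x = np.asarray(diff_accuracy, float)
    if len(np.unique(x)) == 1:
        raise ValueError("constant accuracy difference")
    rng = np.random.default_rng(seed)
    rows = []
    for col in game_cols:
        y = games[col].to_numpy(float)
        if len(np.unique(y)) == 1:
            raise ValueError(f"constant game column {col}")
        rho, p = stats.spearmanr(x, y)
        idx = rng.integers(0, len(x), size=(n_boot, len(x)))
        boots = np.array([stats.spearmanr(x[i], y[i]).statistic for i in idx])
        lo, hi = np.nanpercentile(boots, [2.5, 97.5])
        rows.append({"game": col, "rho": float(rho), "p": float(p),
                     "ci_lo": float(lo), "ci_hi": float(hi), "n": len(x)})
    return pd.DataFrame(rows)


def behavior_block(trials: pd.DataFrame, label: str = "friend") -> pd.DataFrame:
    """Assemble the behavioral CCA block for one label: accuracy, RT, d', beta
    of the matching condition, one row per subject."""
    from .behavior import response_efficiency, sdt_indices

    eff = response_efficiency(trials).set_index("subject")
    sdt = sdt_indices(trials)
    sdt = sdt[sdt["label"] == label].set_index("subject")
    out = pd.DataFrame({
        "accuracy": eff[f"acc_{label}"],
        "rt_ms": eff[f"rt_{label}"],
        "d_prime": sdt["d_prime"],
        "beta": sdt["beta"],
    })
    return out.reset_index()
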