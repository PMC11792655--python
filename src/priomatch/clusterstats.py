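"""Cluster-based permutation statistics on time x electrode maps, point-by-
point brain-behavior correlation with a consecutive-run criterion, and group
moderation of the power-drift coupling.

The cluster test follows the max-mass permutation scheme: paired t-values at
every (channel, time) point, supra-threshold points grouped into signed
clusters under channel-adjacency x consecutive-time connectivity, observed
cluster masses (summed t) compared against the distribution of the maximum
absolute cluster mass over sign-flip permutations (two-sided, signs pooled).
Permutation p-values use the add-one rule (b + 1) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from .montage import MONTAGE_30


# ---------------------------------------------------------------------------
# channel adjacency
# ---------------------------------------------------------------------------

DEFAULT_ADJ_THRESHOLD = 0.41  # schematic montage units; median degree ~ 4


@dataclass
class Adjacency:
    """Symmetric, irreflexive channel neighbor structure."""

    ch_names: list
    neighbors: list  # list of sorted index arrays

    @property
    def median_degree(self) -> float:
        return float(np.median([len(n) for n in self.neighbors]))

    def as_flat(self):
        """(indices, indptr) CSR-style arrays for the numba kernel."""
        indptr = np.zeros(len(self.neighbors) + 1, dtype=np.int64)
        for i, nb in enumerate(self.neighbors):
            indptr[i + 1] = indptr[i] + len(nb)
        indices = np.concatenate([np.asarray(nb, dtype=np.int64)
                                  for nb in self.neighbors]) if indptr[-1] \
            else np.empty(0, dtype=np.int64)
        return indices, indptr


def make_adjacency(montage: dict = MONTAGE_30,
                   threshold: float = DEFAULT_ADJ_THRESHOLD) -> Adjacency:
    """Channel adjacency from 2D montage positions and a distance threshold."""
    names = list(montage)
    pos = np.array([montage[ch] for ch in names], float)
    d = np.sqrt(((pos[:, None] - pos[None]) ** 2).sum(-1))
    nb = []
    for i in range(len(names)):
        sel = np.flatnonzero((d[i] <= threshold) & (np.arange(len(names)) != i))
        if len(sel) == 0:
            raise ValueError(f"channel {names[i]} has no neighbor at "
                             f"threshold {threshold}")
        nb.append(np.sort(sel))
    return Adjacency(ch_names=names, neighbors=nb)


# ---------------------------------------------------------------------------
# clustering kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _cluster_masses(tmap, tcrit, adj_idx, adj_ptr, labels_out):
    """Signed supra-threshold clusters of a (n_ch, n_t) t-map.

    Fills labels_out with cluster ids (0 = subthreshold) and returns a
    (masses, max_abs_mass) pair; connectivity = channel adjacency at the same
    time point + consecutive time at the same channel, same sign only.
    """
    n_ch, n_t = tmap.shape
    labels_out[:] = 0
    masses = np.zeros(256)
    n_clusters = 0
    max_abs = 0.0
    stack = np.empty(n_ch * n_t, dtype=np.int64)
    for c0 in range(n_ch):
        for t0 in range(n_t):
            v = tmap[c0, t0]
            if labels_out[c0, t0] != 0 or (-tcrit <= v <= tcrit) or np.isnan(v):
                continue
            sign = 1.0 if v > 0 else -1.0
            n_clusters += 1
            if n_clusters >= masses.shape[0]:
                grown = np.zeros(masses.shape[0] * 2)
                grown[:masses.shape[0]] = masses
                masses = grown
            mass = 0.0
            top = 0
            stack[top] = c0 * n_t + t0
            top += 1
            labels_out[c0, t0] = n_clusters
            while top > 0:
                top -= 1
                node = stack[top]
                c = node // n_t
                t = node % n_t
                mass += tmap[c, t]
                # temporal neighbors
                for tn in (t - 1, t + 1):
                    if 0 <= tn < n_t and labels_out[c, tn] == 0:
                        w = tmap[c, tn]
                        if not np.isnan(w) and sign * w > tcrit:
                            labels_out[c, tn] = n_clusters
                            stack[top] = c * n_t + tn
                            top += 1
                # spatial neighbors
                for k in range(adj_ptr[c], adj_ptr[c + 1]):
                    cn = adj_idx[k]
                    if labels_out[cn, t] == 0:
                        w = tmap[cn, t]
                        if not np.isnan(w) and sign * w > tcrit:
                            labels_out[cn, t] = n_clusters
                            stack[top] = cn * n_t + t
                            top += 1
            masses[n_clusters - 1] = mass
            if abs(mass) > max_abs:
                max_abs = abs(mass)
    return masses[:n_clusters], max_abs


@njit(cache=True)
def _perm_max_masses(diffs, s2, signs, tcrit, adj_idx, adj_ptr):
    """Max absolute cluster mass per sign-flip permutation (vector of len
    n_perm); diffs is (n_subj, n_ch, n_t), s2 the per-point sum of squares."""
    n_perm = signs.shape[0]
    n = diffs.shape[0]
    n_ch = diffs.shape[1]
    n_t = diffs.shape[2]
    out = np.empty(n_perm)
    labels = np.zeros((n_ch, n_t), dtype=np.int64)
    tmap = np.empty((n_ch, n_t))
    for p in range(n_perm):
        for c in range(n_ch):
            for t in range(n_t):
                m = 0.0
                for s in range(n):
                    m += signs[p, s] * diffs[s, c, t]
                m /= n
                var = (s2[c, t] / n - m * m) * n / (n - 1.0)
                if var <= 1e-300:
                    tmap[c, t] = np.nan
                else:
                    tmap[c, t] = m / np.sqrt(var / n)
        _, mx = _cluster_masses(tmap, tcrit, adj_idx, adj_ptr, labels)
        out[p] = mx
    return out


@dataclass
class ClusterResult:
    clusters: list          # list of dicts: mass, sign, p_perm, n_points, extent
    tmap: np.ndarray
    labels: np.ndarray
    tcrit: float
    n_permutations: int
    perm_max: np.ndarray

    @property
    def significant(self):
        return [c for c in self.clusters if c["p_perm"] < 0.05]


def cluster_permutation(diffs: np.ndarray, adjacency: Adjacency,
                        alpha_forming: float = 0.05, n_perm: int = 1000,
                        seed: int = 0, times_ms: np.ndarray | None = None
                        ) -> ClusterResult:
    """Two-sided cluster-based permutation test of per-subject difference maps.

    ``diffs``: (n_subjects, n_channels, n_times) condition differences.  The
    cluster-forming threshold is the two-sided critical paired t at
    ``alpha_forming``; the null is the max absolute cluster mass over
    within-subject sign flips.  Points with degenerate variance get an
    undefined t and never join clusters.
    """
    diffs = np.asarray(diffs, float)
    n = diffs.shape[0]
    if n < 2:
        raise ValueError("need at least two subjects")
    if diffs.shape[1] != len(adjacency.ch_names):
        raise ValueError("diffs channel axis does not match adjacency")
    tcrit = float(stats.t.ppf(1.0 - alpha_forming / 2.0, n - 1))

    m = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tmap = m / (sd / np.sqrt(n))
    tmap[sd <= 1e-150] = np.nan

    adj_idx, adj_ptr = adjacency.as_flat()
    labels = np.zeros(tmap.shape, dtype=np.int64)
    masses, _ = _cluster_masses(tmap, tcrit, adj_idx, adj_ptr, labels)

    rng = np.random.default_rng(seed)
    signs = rng.choice(np.array([-1.0, 1.0]), size=(n_perm, n))
    s2 = (diffs ** 2).sum(axis=0)
    perm_max = _perm_max_masses(diffs, s2, signs, tcrit, adj_idx, adj_ptr)

    clusters = []
    for ci, mass in enumerate(masses, start=1):
        b = int(np.sum(perm_max >= abs(mass)))
        pts = np.argwhere(labels == ci)
        info = {"mass": float(mass), "sign": 1 if mass > 0 else -1,
                "p_perm": (b + 1) / (n_perm + 1), "n_points": len(pts),
                "channels": sorted({adjacency.ch_names[c] for c, _ in pts})}
        if times_ms is not None:
            info["t_start_ms"] = float(times_ms[pts[:, 1].min()])
            info["t_end_ms"] = float(times_ms[pts[:, 1].max()])
        clusters.append(info)
    clusters.sort(key=lambda c: -abs(c["mass"]))
    return ClusterResult(clusters=clusters, tmap=tmap, labels=labels,
                         tcrit=tcrit, n_permutations=n_perm, perm_max=perm_max)


def bonferroni_bands(p: float, n_bands: int = 3) -> float:
    """Bonferroni correction across the analysis frequency bands."""
    return min(1.0, p * n_bands)


# ---------------------------------------------------------------------------
# point-by-point coupling
# ---------------------------------------------------------------------------

def pointwise_correlation(signals: np.ndarray, scalars: np.ndarray,
                          times_ms: np.ndarray, run_length: int = 100,
                          alpha: float = 0.05) -> dict:
    """Rank correlation at every time point with a consecutive-run criterion.

    ``signals``: (n_subjects, n_times) differential time series; ``scalars``:
    per-subject scalar (e.g. differential drift rate).  Reports maximal runs
    of >= run_length consecutive points with p < alpha (uncorrected), plus
    the rho and p time series.
    """
    signals = np.asarray(signals, float)
    scalars = np.asarray(scalars, float)
    n = len(scalars)
    if n < 5:
        raise ValueError("need at least five subjects")
    if np.std(scalars) < 1e-15:
        raise ValueError("constant scalar: correlation undefined")
    ry = stats.rankdata(scalars)
    rx = np.apply_along_axis(stats.rankdata, 0, signals)
    ryc = ry - ry.mean()
    rxc = rx - rx.mean(axis=0)
    denom = np.sqrt((rxc ** 2).sum(axis=0) * (ryc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rxc * ryc[:, None]).sum(axis=0) / denom
        tstat = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho ** 2, 1e-15))
    p = 2.0 * stats.t.sf(np.abs(tstat), n - 2)

    sig = p < alpha
    runs = []
    start = None
    for i, s in enumerate(np.append(sig, False)):
        if s and start is None:
            start = i
        elif not s and start is not None:
            if i - start >= run_length:
                runs.append({"i_start": start, "i_end": i - 1,
                             "t_start_ms": float(times_ms[start]),
                             "t_end_ms": float(times_ms[i - 1]),
                             "mean_rho": float(np.nanmean(rho[start:i]))})
            start = None
    return {"rho": rho, "p": p, "runs": runs, "times_ms": np.asarray(times_ms)}


def window_correlation(diff_power: np.ndarray, diff_drift: np.ndarray) -> dict:
    """Spearman rho between window-mean differential power and drift."""
    x = np.asarray(diff_power, float)
    y = np.asarray(diff_drift, float)
    if len(x) < 5:
        raise ValueError("need at least five paired observations")
    if len(np.unique(x)) == 1 or len(np.unique(y)) == 1:
        raise ValueError("ties-only input: rank correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p), "n": len(x)}


def group_moderation(diff_power: np.ndarray, diff_drift: np.ndarray,
                     group_labels) -> dict:
    """Interaction test of the power-drift slope between two groups.

    Fits diff_drift ~ diff_power * group by OLS and tests the interaction
    term; reports F, dfs, p and partial eta^2.
    """
    import statsmodels.api as sm

    g = pd.Series(group_labels)
    levels = sorted(g.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    if min((g == lv).sum() for lv in levels) < 3:
        raise ValueError("each group needs at least three subjects")
    x = np.asarray(diff_power, float)
    y = np.asarray(diff_drift, float)
    gind = (g == levels[1]).to_numpy(float)
    X = np.column_stack([np.ones_like(x), x, gind, x * gind])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix")
    fit = sm.OLS(y, X).fit()
    t_int = fit.tvalues[3]
    f = float(t_int ** 2)
    df1, df2 = 1, int(fit.df_resid)
    p = float(fit.pvalues[3])
    eta = f * df1 / (f * df1 + df2)
    return {"F": f, "df1": df1, "df2": df2, "p": p, "partial_eta_sq": eta,
            "slopes": {levels[0]: float(fit.params[1]),
                       levels[1]: float(fit.params[1] + fit.params[3])}}
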