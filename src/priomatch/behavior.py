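"""Behavioral analyses: response efficiency, FP/SP classification, bootstrap
condition means, signal detection indices, and mixed-design ANOVA.

Response efficiency E = mean correct RT / accuracy (ms; lower is better).
The self-minus-friend difference in E on matching trials classifies subjects:
a positive difference defines the friend-prioritization (FP) group, and the
equally many most negative differences form the self-prioritization (SP)
control group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

LABELS = ("self", "friend", "stranger")


def _scorable(trials: pd.DataFrame) -> pd.DataFrame:
    """Drop no-response ('slow') trials; they enter neither RT nor accuracy."""
    return trials[trials["response"].isin(["yes", "no"])]


def response_efficiency(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject response efficiency on matching trials.

    Returns one row per subject with mean correct RT, accuracy and
    E = RT/accuracy per label, plus diff_score = E_self - E_friend (ms).
    Cells with zero accuracy get undefined (NaN) efficiency and are excluded
    from classification downstream.
    """
    t = _scorable(trials)
    t = t[t["match"] == "match"]
    rows = []
    for subject, sub in t.groupby("subject", sort=True):
        row = {"subject": subject}
        if "group_truth" in sub.columns:
            row["group_truth"] = sub["group_truth"].iloc[0]
        for lab in LABELS:
            cell = sub[sub["label"] == lab]
            if cell.empty:
                raise ValueError(f"subject {subject}: no {lab}-match trials")
            acc = cell["accuracy"].mean()
            corr = cell[cell["accuracy"] == 1.0]
            rt = corr["rt_ms"].mean() if len(corr) else np.nan
            row[f"rt_{lab}"] = rt
            row[f"acc_{lab}"] = acc
            row[f"eff_{lab}"] = rt / acc if acc > 0 else np.nan
        row["diff_score"] = row["eff_self"] - row["eff_friend"]
        rows.append(row)
    return pd.DataFrame(rows)


def classify_groups(eff: pd.DataFrame) -> pd.DataFrame:
    """Assign FP/SP groups from differential efficiency scores.

    FP = every subject with diff_score > 0 (strictly); SP = the same number
    of subjects with the most negative scores; everyone else (including
    exact zeros and undefined scores) is unassigned.  Ties at the SP
    selection boundary are broken by subject id.
    """
    ok = eff.dropna(subset=["diff_score"])
    if len(ok) < 2:
        raise ValueError("need at least two subjects with defined diff_score")
    fp = ok[ok["diff_score"] > 0]
    neg = ok[ok["diff_score"] < 0].sort_values(
        ["diff_score", "subject"], kind="stable")
    if len(fp) == 0:
        raise ValueError("no subject with diff_score > 0: FP group is empty")
    if len(neg) < len(fp):
        raise ValueError(
            f"cannot select SP group: need {len(fp)} subjects with negative "
            f"diff_score but only {len(neg)} available")
    sp = neg.head(len(fp))
    out = eff[["subject", "diff_score"]].copy()
    out["group"] = "unassigned"
    out.loc[out["subject"].isin(fp["subject"]), "group"] = "FP"
    out.loc[out["subject"].isin(sp["subject"]), "group"] = "SP"
    return out


def bootstrap_condition_means(trials: pd.DataFrame, n_boot: int = 1000,
                              seed: int = 0, by_group: str | None = None
                              ) -> pd.DataFrame:
    """Bootstrap distribution of (mean accuracy, mean RT) per condition.

    Subject-level matching-condition means are resampled with replacement
    ``n_boot`` times per (group x label) cell, mirroring the scatter display
    of the bootstrapped population means.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    t = _scorable(trials)
    t = t[t["match"] == "match"]
    gcol = by_group if by_group is not None else None
    keys = ["subject", "label"] + ([gcol] if gcol else [])
    per_subj = t.groupby(keys, sort=True).agg(
        acc=("accuracy", "mean"),
        rt=("rt_ms", lambda x: x[t.loc[x.index, "accuracy"] == 1.0].mean()),
    ).reset_index()
    rng = np.random.default_rng(seed)
    rows = []
    group_levels = per_subj[gcol].unique() if gcol else [None]
    for g in group_levels:
        for lab in LABELS:
            cell = per_subj[per_subj["label"] == lab]
            if gcol:
                cell = cell[cell[gcol] == g]
            if cell.empty:
                raise ValueError(f"empty condition: label={lab}, group={g}")
            acc = cell["acc"].to_numpy()
            rt = cell["rt"].to_numpy()
            idx = rng.integers(0, len(cell), size=(n_boot, len(cell)))
            rows.append(pd.DataFrame({
                "group": g if gcol else "all", "label": lab,
                "boot": np.arange(n_boot),
                "mean_accuracy": acc[idx].mean(axis=1),
                "mean_rt_ms": rt[idx].mean(axis=1),
            }))
    return pd.concat(rows, ignore_index=True)


def sdt_indices(trials: pd.DataFrame, correction: str = "half_count"
                ) -> pd.DataFrame:
    """Signal-detection sensitivity and bias per (subject, label).

    Hits are "yes" responses on matching trials, false alarms "yes" on
    non-matching trials.  d' = Phi^-1(H) - Phi^-1(F) and
    beta = exp((Phi^-1(F)^2 - Phi^-1(H)^2) / 2).  Extreme rates (0 or 1) are
    corrected by 1/(2N) ("half_count", default) or by the log-linear
    (N+0.5)/(N+1) rule ("loglinear").
    """
    if correction not in ("half_count", "loglinear"):
        raise ValueError("correction must be 'half_count' or 'loglinear'")
    t = _scorable(trials)
    rows = []
    for (subject, lab), sub in t.groupby(["subject", "label"], sort=True):
        m = sub[sub["match"] == "match"]
        nm = sub[sub["match"] == "nonmatch"]
        if m.empty or nm.empty:
            raise ValueError(f"subject {subject}, label {lab}: need both "
                             "match and nonmatch trials")
        if correction == "loglinear":
            h = (np.sum(m["response"] == "yes") + 0.5) / (len(m) + 1.0)
            f = (np.sum(nm["response"] == "yes") + 0.5) / (len(nm) + 1.0)
        else:
            h = np.sum(m["response"] == "yes") / len(m)
            f = np.sum(nm["response"] == "yes") / len(nm)
            h = min(max(h, 1.0 / (2 * len(m))), 1.0 - 1.0 / (2 * len(m)))
            f = min(max(f, 1.0 / (2 * len(nm))), 1.0 - 1.0 / (2 * len(nm)))
        zh, zf = stats.norm.ppf(h), stats.norm.ppf(f)
        rows.append({"subject": subject, "label": lab, "hit_rate": h,
                     "fa_rate": f, "d_prime": zh - zf,
                     "beta": float(np.exp((zf ** 2 - zh ** 2) / 2.0))})
    return pd.DataFrame(rows)


def partial_eta_sq_ci(f_obs: float, df1: float, df2: float,
                      conf: float = 0.90) -> tuple[float, float]:
    """CI for partial eta^2 by inversion of the noncentral-F distribution."""
    alpha = 1.0 - conf

    def _lam(prob):
        # find lambda with ncf.cdf(f_obs; df1, df2, lam) = prob
        if stats.ncf.cdf(f_obs, df1, df2, 0.0) < prob:
            return 0.0
        lo, hi = 0.0, 10.0
        while stats.ncf.cdf(f_obs, df1, df2, hi) > prob:
            hi *= 2.0
            if hi > 1e8:
                return hi  # effectively infinite noncentrality (eta -> 1)
        from scipy.optimize import brentq
        return brentq(lambda l: stats.ncf.cdf(f_obs, df1, df2, l) - prob, lo, hi)

    lam_lo = _lam(1.0 - alpha / 2.0)
    lam_hi = _lam(alpha / 2.0)
    conv = lambda l: l / (l + df1 + df2 + 1.0)
    return conv(lam_lo), conv(lam_hi)


def mixed_anova(data: pd.DataFrame, dv: str, within: str, between: str,
                subject: str = "subject", ci: float = 0.90) -> dict:
    """Mixed-design ANOVA (within x between) with partial eta^2 CIs and
    Bonferroni-corrected pairwise contrasts of the within factor per group.

    Returns {"anova": DataFrame, "pairwise": DataFrame}; the anova table has
    one row per effect with F, df1, df2, p, partial eta^2 and its CI.
    """
    import pingouin as pg

    counts = data.groupby([subject, within]).size()
    if counts.nunique() > 1:
        raise ValueError("within-factor design must be balanced")
    if data[within].nunique() < 2 or data[between].nunique() < 2:
        raise ValueError("need >=2 levels of both factors")
    aov = pg.mixed_anova(data=data, dv=dv, within=within, between=between,
                         subject=subject)
    rows = []
    for _, r in aov.iterrows():
        f, d1, d2 = r["F"], r["DF1"], r["DF2"]
        lo, hi = partial_eta_sq_ci(f, d1, d2, ci) if np.isfinite(f) else (np.nan, np.nan)
        pcol = "p-unc" if "p-unc" in aov.columns else "p_unc"
        rows.append({"effect": r["Source"], "F": f, "df1": d1, "df2": d2,
                     "p": r[pcol], "partial_eta_sq": r["np2"],
                     f"eta_ci_lo_{int(ci*100)}": lo,
                     f"eta_ci_hi_{int(ci*100)}": hi})
    pw = pg.pairwise_tests(data=data, dv=dv, within=within, between=between,
                           subject=subject, padjust="bonf")
    return {"anova": pd.DataFrame(rows), "pairwise": pw}
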