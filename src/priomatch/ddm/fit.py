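"""Hierarchical Bayesian DDM fitting, DIC model comparison and posterior
contrasts.

``fit_hddm`` estimates group- and subject-level (v, a, z, t0) under a
:class:`~priomatch.ddm.models.DDMSpec` dependency structure with a 5% uniform
outlier mixture in the trial likelihood.  Groups (FP vs SP) partition the
subjects, so each group is sampled as an independent sub-chain and deviances
add.  DIC uses the classic form DIC = Dbar + p_D with p_D = Dbar - D(theta_bar)
evaluated at the posterior-mean subject parameters.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _sampler
from .models import DDMSpec, LABELS, MATCH_LEVELS
from .wfpt import SERIES_ERR

RHAT_WARN = 1.1

#: MCMC presets: (n_samples, burn_in)
PRESETS = {"desk": (2000, 500), "paper": (10000, 1000)}


def split_rhat(x: np.ndarray) -> float:
    """Split R-hat of a single chain (first vs second half)."""
    n = len(x) // 2
    halves = np.stack([x[:n], x[n : 2 * n]])
    m, nn = halves.shape
    cm = halves.mean(axis=1)
    w = halves.var(axis=1, ddof=1).mean()
    b = nn * cm.var(ddof=1)
    if w <= 0:
        return 1.0
    var_plus = (nn - 1) / nn * w + b / nn
    return float(np.sqrt(var_plus / w))


@dataclass
class DDMPosterior:
    """Posterior draws and summaries of one hierarchical DDM fit."""

    spec: DDMSpec
    groups: list
    #: (param, cell_name, group) -> group-level mean draws, post burn-in
    mu_draws: dict
    #: group -> DataFrame of subject-level posterior means (columns labelled)
    subject_means: dict
    dic: float
    dbar: float
    p_d: float
    rhat: dict
    n_samples: int
    burn_in: int
    seed: int
    data_hash: str
    converged: bool = True

    def cell_key(self, param: str, label: str = "all", match: str = "all",
                 group=None) -> tuple:
        """Resolve a (param, label, match, group) request to a draws key."""
        if group is None:
            group = self.groups[0]
        cell = self.spec.cell_index(param, _some_label(label), _some_match(match))
        name = self.spec.cell_name(param, cell)
        return (param, name, group)

    def draws(self, param, label="all", match="all", group=None) -> np.ndarray:
        key = self.cell_key(param, label, match, group)
        if key not in self.mu_draws:
            raise KeyError(f"no posterior cell {key}")
        return self.mu_draws[key]

    def summary(self) -> pd.DataFrame:
        rows = []
        for (param, cell, group), d in sorted(self.mu_draws.items()):
            lo, hi = np.percentile(d, [2.5, 97.5])
            rows.append(dict(param=param, cell=cell, group=group,
                             mean=d.mean(), sd=d.std(ddof=1),
                             ci2_5=lo, ci97_5=hi,
                             rhat=self.rhat[(param, cell, group)]))
        return pd.DataFrame(rows)


def _some_label(label):
    return label if label in LABELS else LABELS[0]


def _some_match(match):
    return match if match in MATCH_LEVELS else MATCH_LEVELS[0]


def _data_hash(trials: pd.DataFrame) -> str:
    cols = trials[["subject", "label", "match", "response", "rt_ms"]]
    return hashlib.sha1(
        pd.util.hash_pandas_object(cols, index=False).values.tobytes()
    ).hexdigest()[:12]


def _prepare_group(trials: pd.DataFrame, spec: DDMSpec):
    """Build flat numba arrays for one group's trials (responses only)."""
    t = trials[trials["response"].isin(["yes", "no"])].copy()
    if t.empty:
        raise ValueError("no scorable trials in group")
    subjects = sorted(t["subject"].unique())
    smap = {s: i for i, s in enumerate(subjects)}
    t["_s"] = t["subject"].map(smap)
    t = t.sort_values(["_s"], kind="stable").reset_index(drop=True)

    rt = (t["rt_ms"].to_numpy(float)) / 1000.0
    cc = (t["response"] == "yes").to_numpy().astype(np.int64)
    sidx = t["_s"].to_numpy(np.int64)
    ptr = np.searchsorted(sidx, np.arange(len(subjects) + 1))

    ncv, nca, ncz, nct0 = (spec.n_cells(p) for p in ("v", "a", "z", "t0"))
    off_a, off_z, off_t0 = ncv, ncv + nca, ncv + nca + ncz
    ncol = off_t0 + nct0
    ctype = np.concatenate([
        np.zeros(ncv), np.ones(nca), 2 * np.ones(ncz), 3 * np.ones(nct0)
    ]).astype(np.int64)

    lab = t["label"].to_numpy()
    mat = t["match"].to_numpy()
    jv = np.array([spec.cell_index("v", l, m) for l, m in zip(lab, mat)], np.int64)
    ja = off_a + np.array([spec.cell_index("a", l, m) for l, m in zip(lab, mat)], np.int64)
    jz = off_z + np.array([spec.cell_index("z", l, m) for l, m in zip(lab, mat)], np.int64)
    jt0 = off_t0 + np.array([spec.cell_index("t0", l, m) for l, m in zip(lab, mat)], np.int64)

    # per-subject, per-column RT bound for t0 cells: each t0 cell is bounded
    # by the smallest RT among the trials it governs (not the global minimum,
    # which may belong to another cell)
    n_subj = len(subjects)
    minrt_col = np.full((n_subj, ncol), np.inf)
    for s in range(n_subj):
        sl = slice(ptr[s], ptr[s + 1])
        for j in range(off_t0, ncol):
            in_cell = jt0[sl] == j
            if in_cell.any():
                minrt_col[s, j] = rt[sl][in_cell].min()
            else:
                minrt_col[s, j] = rt[sl].min()
    log_unif = float(np.log(0.5 / max(rt.max() - max(rt.min() - 1e-3, 0.0), 0.1)))

    # crude but deterministic initial values
    theta0 = np.zeros((n_subj, ncol))
    mu0 = np.zeros(ncol)
    for j in range(ncol):
        if ctype[j] == 0:
            # start match-cells positive, nonmatch negative when resolvable
            name = spec.cell_name("v", j)
            mu0[j] = 1.0 if name.endswith("match") and not name.endswith("nonmatch") else -1.0
            if name == "all":
                mu0[j] = 0.0
        elif ctype[j] == 1:
            mu0[j] = 1.5
        elif ctype[j] == 2:
            mu0[j] = 0.5
        else:
            mu0[j] = 0.6 * minrt_col[:, j].min()
    theta0[:] = mu0
    for j in range(off_t0, ncol):
        theta0[:, j] = np.minimum(theta0[:, j], 0.8 * minrt_col[:, j])
    sig0 = np.full(ncol, 0.2)
    sig0[ctype == 2] = 0.05
    sig0[ctype == 3] = 0.05

    names = []
    for j in range(ncol):
        p = ("v", "a", "z", "t0")[ctype[j]]
        base = {"v": 0, "a": off_a, "z": off_z, "t0": off_t0}[p]
        names.append((p, spec.cell_name(p, j - base)))

    return dict(rt=rt, cc=cc, sidx=sidx, ptr=ptr.astype(np.int64), jv=jv,
                ja=ja, jz=jz, jt0=jt0, ctype=ctype, minrt_col=minrt_col,
                theta0=theta0, mu0=mu0, sig0=sig0, log_unif=log_unif,
                subjects=subjects, names=names)


def fit_hddm(trials: pd.DataFrame, spec: DDMSpec, n_samples: int = 2000,
             burn_in: int = 500, seed: int = 0) -> DDMPosterior:
    """Fit the hierarchical DDM by slice-within-Gibbs MCMC.

    ``trials`` needs columns subject, label, match, response ('yes'/'no';
    other values are treated as non-responses and dropped), rt_ms, and an
    optional ``group`` column partitioning subjects (required when the spec
    carries a group factor and more than one group is present).
    """
    if n_samples <= burn_in:
        raise ValueError("n_samples must exceed burn_in")
    has_group = "group" in trials.columns
    groups = sorted(trials["group"].unique()) if has_group else ["all"]
    if spec.hierarchical:
        for g in groups:
            sub = trials[trials["group"] == g] if has_group else trials
            if sub["subject"].nunique() < 2:
                raise ValueError(f"hierarchical fit needs >=2 subjects in group {g!r}")

    mu_draws, rhat, subject_means = {}, {}, {}
    dbar_total, dmean_total = 0.0, 0.0
    rng = np.random.SeedSequence(seed)
    sub_seeds = rng.generate_state(len(groups)) % (2**31 - 1)

    for gi, g in enumerate(groups):
        sub = trials[trials["group"] == g] if has_group else trials
        prep = _prepare_group(sub, spec)
        mu_d, sig_d, dev, theta_mean = _sampler.run_chain(
            prep["rt"], prep["cc"], prep["sidx"], prep["jv"], prep["ja"],
            prep["jz"], prep["jt0"], prep["ptr"], prep["ctype"],
            prep["minrt_col"], prep["theta0"], prep["mu0"], prep["sig0"],
            spec.outlier_prob, prep["log_unif"], SERIES_ERR,
            n_samples, burn_in, int(sub_seeds[gi]))
        dbar_total += dev.mean()
        dmean_total += float(_sampler.full_deviance(
            theta_mean, prep["rt"], prep["cc"], prep["sidx"], prep["jv"],
            prep["ja"], prep["jz"], prep["jt0"], spec.outlier_prob,
            prep["log_unif"], SERIES_ERR))
        for j, (p, cell) in enumerate(prep["names"]):
            mu_draws[(p, cell, g)] = mu_d[:, j]
            rhat[(p, cell, g)] = split_rhat(mu_d[:, j])
        subject_means[g] = pd.DataFrame(
            theta_mean, index=prep["subjects"],
            columns=[f"{p}_{cell}" for p, cell in prep["names"]])

    p_d = dbar_total - dmean_total
    dic = dbar_total + p_d
    bad = [k for k, r in rhat.items() if r > RHAT_WARN]
    converged = not bad
    if bad:
        warnings.warn(f"split R-hat > {RHAT_WARN} for {len(bad)} group-level "
                      f"parameters, e.g. {bad[:3]}", stacklevel=2)
    return DDMPosterior(spec=spec, groups=groups, mu_draws=mu_draws,
                        subject_means=subject_means, dic=float(dic),
                        dbar=float(dbar_total), p_d=float(p_d), rhat=rhat,
                        n_samples=n_samples, burn_in=burn_in, seed=seed,
                        data_hash=_data_hash(trials), converged=converged)


def compare_models(posteriors) -> pd.DataFrame:
    """Rank fitted models by DIC (ascending; winner first)."""
    posteriors = list(posteriors)
    if not posteriors:
        raise ValueError("no posteriors to compare")
    hashes = {p.data_hash for p in posteriors}
    if len(hashes) > 1:
        raise ValueError("posteriors were fitted on different datasets")
    tab = pd.DataFrame({
        "model_id": [p.spec.model_id for p in posteriors],
        "dic": [p.dic for p in posteriors],
        "dbar": [p.dbar for p in posteriors],
        "p_d": [p.p_d for p in posteriors],
        "converged": [p.converged for p in posteriors],
    }).sort_values("dic", kind="stable").reset_index(drop=True)
    tab["delta_dic"] = tab["dic"] - tab["dic"].iloc[0]
    return tab


def p_bayes(posterior: DDMPosterior, first, second, direction: str = ">") -> float:
    """Posterior probability of a directional group-level contrast.

    ``first``/``second`` are (param, label, match, group) tuples understood by
    :meth:`DDMPosterior.draws`; e.g. ``p_bayes(post, ('v','friend','match','FP'),
    ('v','self','match','FP'))`` is the fraction of draws with
    v(friend-match) > v(self-match) in the FP group.
    """
    if direction not in (">", "<"):
        raise ValueError("direction must be '>' or '<'")
    d1 = posterior.draws(*first)
    d2 = posterior.draws(*second)
    if direction == ">":
        return float(np.mean(d1 > d2))
    return float(np.mean(d1 < d2))


@dataclass
class NeuralRegressionSpec:
    """Trial-by-trial regression of a standardized covariate onto v or a."""

    target: str = "v"  # 'v' or 'a'
    covariate: str = "n1_uv"
    label: str | None = None   # restrict to one label condition
    match: str | None = "match"

    def __post_init__(self):
        if self.target not in ("v", "a"):
            raise ValueError("target must be 'v' or 'a'")


@dataclass
class RegressionPosterior:
    spec: NeuralRegressionSpec
    beta_draws: np.ndarray
    mu_draws: np.ndarray  # columns [base, beta, other, z, t0]
    subject_means: pd.DataFrame
    p_beta_neg: float
    p_beta_pos: float
    seed: int


def fit_neural_regression(trials: pd.DataFrame, spec: NeuralRegressionSpec,
                          n_samples: int = 1500, burn_in: int = 400,
                          seed: int = 0, outlier_prob: float = 0.05
                          ) -> RegressionPosterior:
    """Hierarchical fit of e.g. v_trial = v0 + beta * covariate.

    The covariate is standardized (mean 0, sd 1) across the included trials
    before fitting; a constant covariate is unidentifiable and raises.
    """
    t = trials[trials["response"].isin(["yes", "no"])].copy()
    if spec.label is not None:
        t = t[t["label"] == spec.label]
    if spec.match is not None:
        t = t[t["match"] == spec.match]
    if spec.covariate not in t.columns or t[spec.covariate].isna().any():
        raise ValueError(f"covariate {spec.covariate!r} missing on included trials")
    x = t[spec.covariate].to_numpy(float)
    if np.std(x) < 1e-12:
        raise ValueError("constant covariate: slope is unidentifiable")
    t["_x"] = (x - x.mean()) / x.std()

    subjects = sorted(t["subject"].unique())
    smap = {s: i for i, s in enumerate(subjects)}
    t["_s"] = t["subject"].map(smap)
    t = t.sort_values("_s", kind="stable").reset_index(drop=True)
    rt = t["rt_ms"].to_numpy(float) / 1000.0
    cc = (t["response"] == "yes").to_numpy().astype(np.int64)
    sidx = t["_s"].to_numpy(np.int64)
    ptr = np.searchsorted(sidx, np.arange(len(subjects) + 1)).astype(np.int64)
    xcov = t["_x"].to_numpy(float)
    minrt = np.array([rt[ptr[s]:ptr[s + 1]].min() for s in range(len(subjects))])
    log_unif = float(np.log(0.5 / max(rt.max() - max(rt.min() - 1e-3, 0.0), 0.1)))

    target_a = spec.target == "a"
    mu0 = np.array([1.5 if target_a else 1.0, 0.0, 1.0 if target_a else 1.5,
                    0.5, 0.6 * minrt.min()])
    theta0 = np.tile(mu0, (len(subjects), 1))
    theta0[:, 4] = np.minimum(theta0[:, 4], 0.8 * minrt)
    sig0 = np.array([0.2, 0.2, 0.2, 0.05, 0.05])

    seed_ = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31 - 1))
    mu_draws, theta_mean = _sampler.run_regression_chain(
        rt, cc, xcov, ptr, minrt, theta0, mu0, sig0, target_a,
        outlier_prob, log_unif, SERIES_ERR, n_samples, burn_in, seed_)
    beta = mu_draws[:, 1]
    cols = (["a0", "beta", "v", "z", "t0"] if target_a
            else ["v0", "beta", "a", "z", "t0"])
    return RegressionPosterior(
        spec=spec, beta_draws=beta, mu_draws=mu_draws,
        subject_means=pd.DataFrame(theta_mean, index=subjects, columns=cols),
        p_beta_neg=float(np.mean(beta < 0)), p_beta_pos=float(np.mean(beta > 0)),
        seed=seed)


def posterior_to_json(post: DDMPosterior) -> str:
    """JSON summary (means, CIs, R-hat, DIC) of a fitted posterior."""
    summ = post.summary()
    return json.dumps({
        "model_id": post.spec.model_id,
        "dic": post.dic, "dbar": post.dbar, "p_d": post.p_d,
        "n_samples": post.n_samples, "burn_in": post.burn_in,
        "seed": post.seed, "converged": post.converged,
        "params": summ.to_dict(orient="records"),
    }, indent=1)
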