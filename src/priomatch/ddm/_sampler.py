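"""Numba MCMC core for the hierarchical DDM: componentwise slice-within-Gibbs.

Model (per group of subjects):
  trial likelihood  L = (1 - p_out) * WFPT(rt - t0 | v, a, z) + p_out * U
  subject effects   theta[s, j] ~ Normal(mu[j], sig[j]) truncated to the
                    parameter domain (a > 0, 0 < z < 1, 0 <= t0 < min rt)
  group means       v ~ N(0, 2^2); a ~ Gamma(2, 1); z ~ Beta(2, 2);
                    t0 ~ U(0, min rt)
  group sds         sig[j] ~ HalfNormal (scale per parameter type)

The truncation-normalization constant of the subject prior is ignored in the
group-level conditionals (the domain constraints are rarely binding at the
posterior; see the methods note).

Parameter columns are laid out [v cells | a cells | z cells | t0 cells];
``ctype`` gives the parameter type of each column (0=v, 1=a, 2=z, 3=t0).
All updates are univariate slice samples (stepping-out + shrinkage).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .wfpt import wfpt_logp

# parameter-type constants
_V, _A, _Z, _T0 = 0, 1, 2, 3

_STEP = np.array([0.6, 0.3, 0.10, 0.05])       # slice step width per type
_SIG_PRIOR = np.array([0.5, 0.3, 0.10, 0.10])  # HalfNormal scale per type
_MAX_STEPOUT = 16


@njit(cache=True)
def _trial_loglik(rt_t, cc_t, v, a, z, t0, p_out, log_unif, err):
    lw = wfpt_logp(rt_t - t0, cc_t == 1, v, a, z, err)
    if p_out <= 0.0:
        return lw
    w = 0.0 if lw == -np.inf else math.exp(lw)
    dens = (1.0 - p_out) * w + p_out * math.exp(log_unif)
    if dens <= 0.0:
        return -np.inf
    return math.log(dens)


@njit(cache=True)
def _in_domain(x, ptype, rt_bound):
    # rt_bound: the subject's minimum RT over the trials this t0 cell governs
    if ptype == _A:
        return x > 0.05
    if ptype == _Z:
        return 0.01 < x < 0.99
    if ptype == _T0:
        return 0.0 <= x < rt_bound
    return -30.0 < x < 30.0


@njit(cache=True)
def _subject_logp(x, s, j, ptype, theta, mu, sig, rt, cc, jv, ja, jz, jt0,
                  ptr, minrt_col, p_out, log_unif, err):
    """Conditional log-posterior of theta[s, j] = x."""
    if not _in_domain(x, ptype, minrt_col[s, j]):
        return -np.inf
    d = (x - mu[j]) / sig[j]
    lp = -0.5 * d * d
    for t in range(ptr[s], ptr[s + 1]):
        if ptype == _V:
            if jv[t] != j:
                continue
            v = x; a = theta[s, ja[t]]; z = theta[s, jz[t]]; t0 = theta[s, jt0[t]]
        elif ptype == _A:
            if ja[t] != j:
                continue
            v = theta[s, jv[t]]; a = x; z = theta[s, jz[t]]; t0 = theta[s, jt0[t]]
        elif ptype == _Z:
            if jz[t] != j:
                continue
            v = theta[s, jv[t]]; a = theta[s, ja[t]]; z = x; t0 = theta[s, jt0[t]]
        else:
            if jt0[t] != j:
                continue
            v = theta[s, jv[t]]; a = theta[s, ja[t]]; z = theta[s, jz[t]]; t0 = x
        lp += _trial_loglik(rt[t], cc[t], v, a, z, t0, p_out, log_unif, err)
        if lp == -np.inf:
            return -np.inf
    return lp


@njit(cache=True)
def _mu_logprior(x, ptype, rt_bound):
    if ptype == _V:
        return -x * x / 8.0
    if ptype == _A:  # Gamma(2, 1)
        if x <= 0.0:
            return -np.inf
        return math.log(x) - x
    if ptype == _Z:  # Beta(2, 2)
        if x <= 0.0 or x >= 1.0:
            return -np.inf
        return math.log(x) + math.log(1.0 - x)
    if x < 0.0 or x >= rt_bound:
        return -np.inf
    return 0.0


@njit(cache=True)
def _mu_logp(x, j, ptype, theta, sig, n_subj, mu_bound_j):
    lp = _mu_logprior(x, ptype, mu_bound_j)
    if lp == -np.inf:
        return lp
    for s in range(n_subj):
        d = (theta[s, j] - x) / sig[j]
        lp -= 0.5 * d * d
    return lp


@njit(cache=True)
def _sig_logp(x, j, ptype, theta, mu, n_subj):
    if x <= 1e-4:
        return -np.inf
    sc = _SIG_PRIOR[ptype]
    lp = -x * x / (2.0 * sc * sc)
    for s in range(n_subj):
        d = (theta[s, j] - mu[j]) / x
        lp += -0.5 * d * d - math.log(x)
    return lp


@njit(cache=True)
def _slice_subject(x0, lp0, s, j, ptype, theta, mu, sig, rt, cc, jv, ja, jz,
                   jt0, ptr, minrt_col, p_out, log_unif, err, w):
    """One slice-sampling update; returns (x_new, logp_new)."""
    y = lp0 + math.log(np.random.random())
    L = x0 - w * np.random.random()
    R = L + w
    for _ in range(_MAX_STEPOUT):
        if _subject_logp(L, s, j, ptype, theta, mu, sig, rt, cc, jv, ja, jz,
                         jt0, ptr, minrt_col, p_out, log_unif, err) <= y:
            break
        L -= w
    for _ in range(_MAX_STEPOUT):
        if _subject_logp(R, s, j, ptype, theta, mu, sig, rt, cc, jv, ja, jz,
                         jt0, ptr, minrt_col, p_out, log_unif, err) <= y:
            break
        R += w
    for _ in range(100):
        x1 = L + np.random.random() * (R - L)
        lp1 = _subject_logp(x1, s, j, ptype, theta, mu, sig, rt, cc, jv, ja,
                            jz, jt0, ptr, minrt_col, p_out, log_unif, err)
        if lp1 > y:
            return x1, lp1
        if x1 < x0:
            L = x1
        else:
            R = x1
    return x0, lp0


@njit(cache=True)
def _slice_mu(x0, j, ptype, theta, sig, n_subj, mu_bound_j, w):
    lp0 = _mu_logp(x0, j, ptype, theta, sig, n_subj, mu_bound_j)
    y = lp0 + math.log(np.random.random())
    L = x0 - w * np.random.random()
    R = L + w
    for _ in range(_MAX_STEPOUT):
        if _mu_logp(L, j, ptype, theta, sig, n_subj, mu_bound_j) <= y:
            break
        L -= w
    for _ in range(_MAX_STEPOUT):
        if _mu_logp(R, j, ptype, theta, sig, n_subj, mu_bound_j) <= y:
            break
        R += w
    for _ in range(100):
        x1 = L + np.random.random() * (R - L)
        if _mu_logp(x1, j, ptype, theta, sig, n_subj, mu_bound_j) > y:
            return x1
        if x1 < x0:
            L = x1
        else:
            R = x1
    return x0


@njit(cache=True)
def _slice_sig(x0, j, ptype, theta, mu, n_subj, w):
    lp0 = _sig_logp(x0, j, ptype, theta, mu, n_subj)
    y = lp0 + math.log(np.random.random())
    L = x0 - w * np.random.random()
    R = L + w
    for _ in range(_MAX_STEPOUT):
        if _sig_logp(L, j, ptype, theta, mu, n_subj) <= y:
            break
        L -= w
    for _ in range(_MAX_STEPOUT):
        if _sig_logp(R, j, ptype, theta, mu, n_subj) <= y:
            break
        R += w
    for _ in range(100):
        x1 = L + np.random.random() * (R - L)
        if _sig_logp(x1, j, ptype, theta, mu, n_subj) > y:
            return x1
        if x1 < x0:
            L = x1
        else:
            R = x1
    return x0


@njit(cache=True)
def full_deviance(theta, rt, cc, sidx, jv, ja, jz, jt0, p_out, log_unif, err):
    ll = 0.0
    for t in range(rt.shape[0]):
        s = sidx[t]
        ll += _trial_loglik(rt[t], cc[t], theta[s, jv[t]], theta[s, ja[t]],
                            theta[s, jz[t]], theta[s, jt0[t]], p_out,
                            log_unif, err)
    return -2.0 * ll


@njit(cache=True)
def run_chain(rt, cc, sidx, jv, ja, jz, jt0, ptr, ctype, minrt_col, theta0,
              mu0, sig0, p_out, log_unif, err, n_iter, n_burn, seed):
    """Run one Gibbs chain; returns (mu_draws, sig_draws, dev_trace,
    theta_mean) where draws cover the post-burn-in sweeps."""
    np.random.seed(seed)
    n_subj = ptr.shape[0] - 1
    ncol = ctype.shape[0]
    theta = theta0.copy()
    mu = mu0.copy()
    sig = sig0.copy()
    # group-mean t0 bound: the smallest RT any subject contributes to a cell
    mu_bound = np.empty(ncol)
    for j in range(ncol):
        mu_bound[j] = minrt_col[:, j].min()

    n_keep = n_iter - n_burn
    mu_draws = np.empty((n_keep, ncol))
    sig_draws = np.empty((n_keep, ncol))
    dev_trace = np.empty(n_keep)
    theta_mean = np.zeros((n_subj, ncol))

    for it in range(n_iter):
        for s in range(n_subj):
            for j in range(ncol):
                ptype = ctype[j]
                lp0 = _subject_logp(theta[s, j], s, j, ptype, theta, mu, sig,
                                    rt, cc, jv, ja, jz, jt0, ptr, minrt_col,
                                    p_out, log_unif, err)
                xn, _ = _slice_subject(theta[s, j], lp0, s, j, ptype, theta,
                                       mu, sig, rt, cc, jv, ja, jz, jt0, ptr,
                                       minrt_col, p_out, log_unif, err,
                                       _STEP[ptype])
                theta[s, j] = xn
        for j in range(ncol):
            ptype = ctype[j]
            mu[j] = _slice_mu(mu[j], j, ptype, theta, sig, n_subj,
                              mu_bound[j], _STEP[ptype])
            sig[j] = _slice_sig(sig[j], j, ptype, theta, mu, n_subj, 0.15)
        if it >= n_burn:
            k = it - n_burn
            mu_draws[k] = mu
            sig_draws[k] = sig
            dev_trace[k] = full_deviance(theta, rt, cc, sidx, jv, ja, jz, jt0,
                                         p_out, log_unif, err)
            theta_mean += theta
    theta_mean /= n_keep
    return mu_draws, sig_draws, dev_trace, theta_mean


# ---------------------------------------------------------------------------
# trial-by-trial covariate regression chain
# ---------------------------------------------------------------------------

# column layout for the regression model: [base, beta, other, z, t0] where
# base/other are (v, a) for target v and (a, v) for target a
_REG_NCOL = 5


@njit(cache=True)
def _reg_trial_ll(rt_t, cc_t, x_t, th_s, target_a, p_out, log_unif, err):
    if target_a:
        a = th_s[0] + th_s[1] * x_t
        v = th_s[2]
    else:
        v = th_s[0] + th_s[1] * x_t
        a = th_s[2]
    if a <= 0.05:
        return -np.inf
    return _trial_loglik(rt_t, cc_t, v, a, th_s[3], th_s[4], p_out, log_unif, err)


@njit(cache=True)
def _reg_subject_logp(x, s, j, theta, mu, sig, rt, cc, xcov, ptr, minrt,
                      target_a, p_out, log_unif, err):
    base_is_a = (j == 0 and target_a) or (j == 2 and not target_a)
    if base_is_a and x <= 0.05:
        return -np.inf
    if j == 3 and not (0.01 < x < 0.99):
        return -np.inf
    if j == 4 and not (0.0 <= x < minrt[s]):
        return -np.inf
    d = (x - mu[j]) / sig[j]
    lp = -0.5 * d * d
    old = theta[s, j]
    theta[s, j] = x
    for t in range(ptr[s], ptr[s + 1]):
        lp += _reg_trial_ll(rt[t], cc[t], xcov[t], theta[s], target_a,
                            p_out, log_unif, err)
        if lp == -np.inf:
            break
    theta[s, j] = old
    return lp


@njit(cache=True)
def _reg_mu_logprior(x, j, target_a, minrt_all):
    base_is_a = (j == 0 and target_a) or (j == 2 and not target_a)
    if base_is_a:
        if x <= 0.0:
            return -np.inf
        return math.log(x) - x
    if j == 1:  # slope
        return -x * x / 2.0
    if j == 3:
        if x <= 0.0 or x >= 1.0:
            return -np.inf
        return math.log(x) + math.log(1.0 - x)
    if j == 4:
        if x < 0.0 or x >= minrt_all:
            return -np.inf
        return 0.0
    return -x * x / 8.0


@njit(cache=True)
def run_regression_chain(rt, cc, xcov, ptr, minrt, theta0, mu0, sig0,
                         target_a, p_out, log_unif, err, n_iter, n_burn, seed):
    """Hierarchical chain for e.g. v_trial = v0 + beta * covariate."""
    np.random.seed(seed)
    n_subj = ptr.shape[0] - 1
    theta = theta0.copy()
    mu = mu0.copy()
    sig = sig0.copy()
    minrt_all = minrt.min()
    steps = np.array([0.4, 0.3, 0.3, 0.08, 0.05])
    sig_priors = np.array([0.5, 0.5, 0.3, 0.10, 0.10])

    n_keep = n_iter - n_burn
    mu_draws = np.empty((n_keep, _REG_NCOL))
    theta_mean = np.zeros((n_subj, _REG_NCOL))

    for it in range(n_iter):
        for s in range(n_subj):
            for j in range(_REG_NCOL):
                x0 = theta[s, j]
                lp0 = _reg_subject_logp(x0, s, j, theta, mu, sig, rt, cc,
                                        xcov, ptr, minrt, target_a, p_out,
                                        log_unif, err)
                y = lp0 + math.log(np.random.random())
                w = steps[j]
                L = x0 - w * np.random.random()
                R = L + w
                for _ in range(_MAX_STEPOUT):
                    if _reg_subject_logp(L, s, j, theta, mu, sig, rt, cc,
                                         xcov, ptr, minrt, target_a, p_out,
                                         log_unif, err) <= y:
                        break
                    L -= w
                for _ in range(_MAX_STEPOUT):
                    if _reg_subject_logp(R, s, j, theta, mu, sig, rt, cc,
                                         xcov, ptr, minrt, target_a, p_out,
                                         log_unif, err) <= y:
                        break
                    R += w
                for _ in range(100):
                    x1 = L + np.random.random() * (R - L)
                    if _reg_subject_logp(x1, s, j, theta, mu, sig, rt, cc,
                                         xcov, ptr, minrt, target_a, p_out,
                                         log_unif, err) > y:
                        theta[s, j] = x1
                        break
                    if x1 < x0:
                        L = x1
                    else:
                        R = x1
        for j in range(_REG_NCOL):
            # mu update
            x0 = mu[j]
            lp0 = _reg_mu_logprior(x0, j, target_a, minrt_all)
            for s in range(n_subj):
                d = (theta[s, j] - x0) / sig[j]
                lp0 -= 0.5 * d * d
            y = lp0 + math.log(np.random.random())
            w = steps[j]
            L = x0 - w * np.random.random()
            R = L + w
            for _ in range(_MAX_STEPOUT):
                lpL = _reg_mu_logprior(L, j, target_a, minrt_all)
                if lpL > -np.inf:
                    for s in range(n_subj):
                        d = (theta[s, j] - L) / sig[j]
                        lpL -= 0.5 * d * d
                if lpL <= y:
                    break
                L -= w
            for _ in range(_MAX_STEPOUT):
                lpR = _reg_mu_logprior(R, j, target_a, minrt_all)
                if lpR > -np.inf:
                    for s in range(n_subj):
                        d = (theta[s, j] - R) / sig[j]
                        lpR -= 0.5 * d * d
                if lpR <= y:
                    break
                R += w
            for _ in range(100):
                x1 = L + np.random.random() * (R - L)
                lp1 = _reg_mu_logprior(x1, j, target_a, minrt_all)
                if lp1 > -np.inf:
                    for s in range(n_subj):
                        d = (theta[s, j] - x1) / sig[j]
                        lp1 -= 0.5 * d * d
                if lp1 > y:
                    mu[j] = x1
                    break
                if x1 < x0:
                    L = x1
                else:
                    R = x1
            # sig update
            x0 = sig[j]
            sc = sig_priors[j]

            def _slp(x):
                if x <= 1e-4:
                    return -np.inf
                out = -x * x / (2.0 * sc * sc)
                for s in range(n_subj):
                    d = (theta[s, j] - mu[j]) / x
                    out += -0.5 * d * d - math.log(x)
                return out

            lp0 = _slp(x0)
            y = lp0 + math.log(np.random.random())
            L = x0 - 0.15 * np.random.random()
            R = L + 0.15
            for _ in range(_MAX_STEPOUT):
                if _slp(L) <= y:
                    break
                L -= 0.15
            for _ in range(_MAX_STEPOUT):
                if _slp(R) <= y:
                    break
                R += 0.15
            for _ in range(100):
                x1 = L + np.random.random() * (R - L)
                if _slp(x1) > y:
                    sig[j] = x1
                    break
                if x1 < x0:
                    L = x1
                else:
                    R = x1
        if it >= n_burn:
            mu_draws[it - n_burn] = mu
            theta_mean += theta
    theta_mean /= n_keep
    return mu_draws, theta_mean
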