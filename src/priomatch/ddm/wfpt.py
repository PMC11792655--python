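"""Wiener first-passage-time density for the two-boundary drift diffusion model.

The decision process is a Brownian motion with drift ``v`` (diffusion
coefficient 1) started at relative position ``z`` between an absorbing lower
boundary at 0 and an upper boundary at ``a``.  A "yes" response corresponds to
absorption at the upper boundary, a "no" response to the lower one, and the
observed response time is the first-passage time plus a non-decision offset
``t0``.

The density is evaluated with the classic dual series expansion: a small-time
expansion (sum over image charges) and a large-time expansion (sine series),
switching to whichever needs fewer terms for the requested truncation error.
The lower-boundary density is the canonical form; the upper boundary follows
from the reflection (v, z) -> (-v, 1 - z).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# Truncation tolerance of the series expansion.
SERIES_ERR = 1e-7


@njit(cache=True)
def _fpt_lower(t, v, a, w, err):
    """Density of absorption at the LOWER boundary at decision time t > 0.

    w is the relative starting point (0 < w < 1); diffusion coefficient 1.
    """
    if t <= 0.0:
        return 0.0
    tt = t / (a * a)  # time in units of a^2

    # number of terms required by each expansion (Navarro & Fuss bounds)
    if math.pi * tt * err < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * tt * err) / (math.pi * math.pi * tt))
        if kl < 1.0 / (math.pi * math.sqrt(tt)):
            kl = 1.0 / (math.pi * math.sqrt(tt))
    else:
        kl = 1.0 / (math.pi * math.sqrt(tt))

    if 2.0 * math.sqrt(2.0 * math.pi * tt) * err < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * tt * math.log(2.0 * math.sqrt(2.0 * math.pi * tt) * err))
        if ks < math.sqrt(tt) + 1.0:
            ks = math.sqrt(tt) + 1.0
    else:
        ks = 2.0

    p = 0.0
    if ks < kl:  # small-time expansion
        K = int(math.ceil(ks))
        lo = -((K - 1) // 2)
        hi = (K - 1) // 2 + (K - 1) % 2
        for k in range(lo, hi + 1):
            p += (w + 2.0 * k) * math.exp(-((w + 2.0 * k) ** 2) / (2.0 * tt))
        p /= math.sqrt(2.0 * math.pi * tt * tt * tt)
    else:  # large-time expansion
        K = int(math.ceil(kl))
        for k in range(1, K + 1):
            p += k * math.exp(-(k * k) * (math.pi * math.pi) * tt / 2.0) * math.sin(
                k * math.pi * w
            )
        p *= math.pi

    return p * math.exp(-v * a * w - v * v * t / 2.0) / (a * a)


@njit(cache=True)
def wfpt_logp(t, upper, v, a, z, err):
    """Log first-passage density at decision time t (rt - t0 already applied).

    upper: True for the upper ("yes") boundary.  Returns -inf for t <= 0 or
    parameters outside the domain.
    """
    if t <= 0.0 or a <= 0.0 or z <= 0.0 or z >= 1.0:
        return -np.inf
    if upper:
        d = _fpt_lower(t, -v, a, 1.0 - z, err)
    else:
        d = _fpt_lower(t, v, a, z, err)
    if d <= 0.0:
        return -np.inf
    return math.log(d)


def wfpt_logpdf(rt, boundary_hit, v, a, z, t0, err=SERIES_ERR):
    """Log Wiener first-passage density of a response.

    Parameters
    ----------
    rt : float
        Response time in seconds.
    boundary_hit : {"upper", "lower"}
        Which boundary was hit ("upper" = yes response).
    v, a, z, t0 : float
        Drift rate (1/s), boundary separation, relative starting point in
        (0, 1), and non-decision time (s).

    Returns
    -------
    float
        Log density; ``-inf`` when ``rt <= t0`` (zero likelihood, no raise).
    """
    if not (np.isfinite(v) and np.isfinite(a) and np.isfinite(z) and np.isfinite(t0)):
        raise ValueError("DDM parameters must be finite")
    if a <= 0 or not (0 < z < 1) or t0 < 0:
        raise ValueError(f"parameters outside domain: a={a}, z={z}, t0={t0}")
    if boundary_hit not in ("upper", "lower"):
        raise ValueError(f"boundary_hit must be 'upper' or 'lower', got {boundary_hit!r}")
    return float(wfpt_logp(rt - t0, boundary_hit == "upper", v, a, z, err))


def wfpt_pdf(rt, boundary_hit, v, a, z, t0, err=SERIES_ERR):
    """Wiener first-passage density (linear scale); 0 when rt <= t0."""
    lp = wfpt_logpdf(rt, boundary_hit, v, a, z, t0, err)
    return float(np.exp(lp))


def absorption_probability(v, a, z):
    """Closed-form probability of absorption at the upper boundary.

    P(upper) = (1 - exp(-2 v z a)) / (1 - exp(-2 v a)) for v != 0, else z.
    """
    a = float(a)
    z = float(z)
    if a <= 0 or not (0 < z < 1):
        raise ValueError("require a > 0 and 0 < z < 1")
    if abs(v) < 1e-12:
        return z
    num = -np.expm1(-2.0 * v * z * a)
    den = -np.expm1(-2.0 * v * a)
    return float(num / den)


def mean_decision_time_v0(a, z):
    """Mean first-passage time at zero drift from absolute start w = z*a.

    E[T] = w (a - w) with diffusion coefficient 1.
    """
    w = z * a
    return float(w * (a - w))


@njit(cache=True)
def _simulate_fpt(v, a, x0, dt, max_t, bridge):
    """One first-passage simulation; returns (decision_time, hit) with
    hit = 1 upper, 0 lower, -1 not absorbed by max_t."""
    x = x0
    t = 0.0
    sdt = math.sqrt(dt)
    # crossings are reported at the step midpoint: the within-step crossing
    # instant is unobserved and roughly uniform, so t - dt/2 removes the
    # O(dt) first-passage-time bias of reporting step ends
    while t < max_t:
        xn = x + v * dt + sdt * np.random.normal()
        t += dt
        if xn >= a:
            return t - 0.5 * dt, 1
        if xn <= 0.0:
            return t - 0.5 * dt, 0
        if bridge:
            # Brownian-bridge probability of an unobserved within-step crossing
            pu = math.exp(-2.0 * (a - x) * (a - xn) / dt)
            pd = math.exp(-2.0 * x * xn / dt)
            u = np.random.random()
            if u < pu:
                return t - 0.5 * dt, 1
            if u < pu + pd:
                return t - 0.5 * dt, 0
        x = xn
    return max_t, -1


@njit(cache=True)
def simulate_fpt_batch(n, v, a, z, dt, max_t, bridge, seed):
    """Simulate n first-passage times; returns (times, hits) arrays."""
    np.random.seed(seed)
    times = np.empty(n)
    hits = np.empty(n, dtype=np.int64)
    x0 = z * a
    for i in range(n):
        t, h = _simulate_fpt(v, a, x0, dt, max_t, bridge)
        times[i] = t
        hits[i] = h
    return times, hits
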