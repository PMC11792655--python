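"""Synthetic cohorts for the shape-label matching task.

The generator produces data with known ground truth for every downstream
stage: behavioral trials by forward simulation of the drift diffusion model,
stimulus-locked EEG epochs built from ERP component templates plus a
non-phase-locked alpha/low-beta oscillation whose single-trial power is
coupled to the trial's drift rate, and trait/economic-game tables sharing a
latent factor with each subject's friend-priority magnitude.

Defaults mirror the study's task design: 110 trials in each of the six
(label x match) conditions, 100 ms stimulus exposure, a 1100 ms response
deadline, and fixation intervals of 900-1700 ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .montage import CHANNELS, MONTAGE_30, resolve_cluster
from .ddm.wfpt import _simulate_fpt

LABELS = ("self", "friend", "stranger")
MATCH_LEVELS = ("match", "nonmatch")


@dataclass(frozen=True)
class TaskDesign:
    """Constants of the shape-label matching task."""

    labels: tuple = LABELS
    match_levels: tuple = MATCH_LEVELS
    trials_per_condition: int = 110
    stim_duration_ms: float = 100.0
    response_deadline_ms: float = 1100.0
    fixation_range_ms: tuple = (900.0, 1700.0)
    feedback_duration_ms: float = 500.0

    def __post_init__(self):
        if self.trials_per_condition <= 0:
            raise ValueError("trials_per_condition must be positive")
        if not self.fixation_range_ms[0] < self.fixation_range_ms[1]:
            raise ValueError("fixation range must be (min, max) with min < max")
        if self.response_deadline_ms <= self.stim_duration_ms:
            raise ValueError("deadline must exceed stimulus duration")


@dataclass
class SubjectTruth:
    """Ground-truth DDM parameters and coupling gain of one subject."""

    subject_id: str
    latent_group: str  # 'FP', 'SP' or 'neutral'
    v_map: dict        # (label, match) -> drift rate, 1/s
    a_map: dict        # label -> boundary separation
    z_map: dict        # label -> relative starting point in (0, 1)
    t0_map: dict       # match level -> non-decision time, s
    coupling_gain: float = 0.0
    sv: float = 0.0    # trial-to-trial drift sd (not stated in the study; 0)

    def validate(self):
        vals = list(self.v_map.values()) + list(self.a_map.values()) \
            + list(self.z_map.values()) + list(self.t0_map.values())
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite DDM parameters")
        if any(a <= 0 for a in self.a_map.values()):
            raise ValueError("boundary separation must be positive")
        if any(not 0 < z < 1 for z in self.z_map.values()):
            raise ValueError("starting point must lie in (0, 1)")
        if any(t0 < 0 for t0 in self.t0_map.values()):
            raise ValueError("non-decision time must be nonnegative")

    @property
    def friend_priority(self) -> float:
        """v(friend, match) - v(self, match): positive for FP-like subjects."""
        return self.v_map[("friend", "match")] - self.v_map[("self", "match")]


@njit(cache=True)
def _sim_trials_numba(v_arr, a_arr, z_arr, t0_arr, sv_arr, n_arr, dt,
                      deadline_s, bridge, seed):
    """Simulate all conditions of one subject; returns rt (s) and response
    (1 yes / 0 no / -1 no response)."""
    np.random.seed(seed)
    ntot = n_arr.sum()
    rts = np.full(ntot, np.nan)
    resp = np.full(ntot, -1, dtype=np.int64)
    k = 0
    for c in range(n_arr.shape[0]):
        for _ in range(n_arr[c]):
            vi = v_arr[c]
            if sv_arr[c] > 0.0:
                vi += sv_arr[c] * np.random.normal()
            budget = deadline_s - t0_arr[c]
            if budget > 0.0:
                t, h = _simulate_fpt(vi, a_arr[c], z_arr[c] * a_arr[c], dt,
                                     budget, bridge)
                if h >= 0:
                    rts[k] = t + t0_arr[c]
                    resp[k] = h
            k += 1
    return rts, resp


def simulate_ddm_trials(truth: SubjectTruth, design: TaskDesign = TaskDesign(),
                        outlier_prob: float = 0.0, seed: int = 0,
                        dt: float = 0.001, bridge: bool = True) -> pd.DataFrame:
    """Forward-simulate one subject's trials.

    "Yes" responses are absorptions at the upper boundary, "no" at the lower;
    RT = decision time + t0.  Trials not absorbed before the response deadline
    get response "none" (the task shows "slow" feedback).  A fraction
    ``outlier_prob`` of responded trials is replaced by contaminants with
    uniform RT on [t0, deadline] and a random button.
    """
    truth.validate()
    if not 0.0 <= outlier_prob <= 0.5:
        raise ValueError("outlier_prob must lie in [0, 0.5]")
    conds = [(l, m) for l in design.labels for m in design.match_levels]
    v = np.array([truth.v_map[c] for c in conds])
    a = np.array([truth.a_map[l] for l, _ in conds])
    z = np.array([truth.z_map[l] for l, _ in conds])
    t0 = np.array([truth.t0_map[m] for _, m in conds])
    sv = np.full(len(conds), truth.sv)
    n = np.full(len(conds), design.trials_per_condition, dtype=np.int64)

    ss = np.random.SeedSequence([seed, 0x5157])
    sim_seed = int(ss.generate_state(1)[0] % (2**31 - 1))
    rts, resp = _sim_trials_numba(v, a, z, t0, sv, n, dt,
                                  design.response_deadline_ms / 1000.0,
                                  bridge, sim_seed)

    rows = np.repeat(np.arange(len(conds)), design.trials_per_condition)
    tab = pd.DataFrame({
        "subject": truth.subject_id,
        "group_truth": truth.latent_group,
        "label": [conds[i][0] for i in rows],
        "match": [conds[i][1] for i in rows],
        "response": np.where(resp == 1, "yes", np.where(resp == 0, "no", "none")),
        "rt_ms": rts * 1000.0,
        "v_true": v[rows],
        "coupling_gain": truth.coupling_gain,
    })

    rng = np.random.default_rng(ss.spawn(1)[0])
    if outlier_prob > 0:
        responded = np.flatnonzero(tab["response"] != "none")
        n_out = int(round(outlier_prob * len(responded)))
        if n_out:
            pick = rng.choice(responded, size=n_out, replace=False)
            lo = t0[rows[pick]] * 1000.0
            tab.loc[pick, "rt_ms"] = rng.uniform(lo, design.response_deadline_ms)
            tab.loc[pick, "response"] = rng.choice(["yes", "no"], size=n_out)

    correct = ((tab["match"] == "match") & (tab["response"] == "yes")) | (
        (tab["match"] == "nonmatch") & (tab["response"] == "no"))
    tab["accuracy"] = np.where(tab["response"] == "none", np.nan,
                               correct.astype(float))
    order = rng.permutation(len(tab))
    tab = tab.iloc[order].reset_index(drop=True)
    tab["trial_index"] = np.arange(len(tab))
    return tab


# between-subject sds and baseline parameter values of the generator,
# chosen to yield realistic task performance (mean RT ~0.6 s, accuracy ~0.9,
# few responses beyond the 1100 ms deadline)
_COHORT_DEFAULTS = dict(
    v_match_base=2.2, v_nonmatch=-2.0, v_stranger_penalty=0.6,
    a_base={"self": 1.35, "friend": 1.45, "stranger": 1.50},
    z_bias=0.06,  # starting-point advantage of the prioritized label
    t0={"match": 0.28, "nonmatch": 0.32},
    sd_v=0.10, sd_a=0.08, sd_z=0.02, sd_t0=0.015,
)


def generate_cohort(n_fp: int, n_sp: int, effect_size_v: float = 0.8,
                    seed: int = 0, noise_sd: float = 0.10,
                    coupling_gain: float = 0.0,
                    design: TaskDesign = TaskDesign(),
                    outlier_prob: float = 0.02,
                    simulate: bool = True, dt: float = 0.001):
    """Generate FP and SP subpopulations and (optionally) their pooled trials.

    FP subjects have v(friend, match) - v(self, match) = +effect_size_v plus
    between-subject noise; SP subjects the reverse; stranger drift is lowest
    in both.  SP subjects additionally start closer to the "yes" boundary for
    self than friend shapes (initial predilection), FP subjects do not.

    Returns (truths, trials) — ``trials`` is None when ``simulate`` is False.
    """
    if n_fp < 1 or n_sp < 1:
        raise ValueError("need at least one subject per subpopulation")
    if effect_size_v <= 0:
        raise ValueError("effect_size_v must be positive")
    c = _COHORT_DEFAULTS
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0507]))
    truths = []
    for i in range(n_fp + n_sp):
        fp = i < n_fp
        gid = "FP" if fp else "SP"
        u = (effect_size_v if fp else -effect_size_v) + rng.normal(0, noise_sd)
        base = c["v_match_base"] + rng.normal(0, c["sd_v"])
        v_map = {
            ("self", "match"): base - u / 2.0,
            ("friend", "match"): base + u / 2.0,
            ("stranger", "match"): base - abs(u) / 2.0 - c["v_stranger_penalty"]
            + rng.normal(0, c["sd_v"] / 2),
        }
        for lab in LABELS:
            v_map[(lab, "nonmatch")] = c["v_nonmatch"] + rng.normal(0, c["sd_v"])
        a_map = {lab: max(0.8, c["a_base"][lab] + rng.normal(0, c["sd_a"]))
                 for lab in LABELS}
        zb = 0.0 if fp else c["z_bias"]
        z_map = {
            "self": np.clip(0.50 + zb + rng.normal(0, c["sd_z"]), 0.2, 0.8),
            "friend": np.clip(0.50 + rng.normal(0, c["sd_z"]), 0.2, 0.8),
            "stranger": np.clip(0.50 + rng.normal(0, c["sd_z"]), 0.2, 0.8),
        }
        t0_map = {m: max(0.12, c["t0"][m] + rng.normal(0, c["sd_t0"]))
                  for m in MATCH_LEVELS}
        truths.append(SubjectTruth(
            subject_id=f"{gid.lower()}{i + 1:03d}", latent_group=gid,
            v_map=v_map, a_map=a_map, z_map=z_map, t0_map=t0_map,
            coupling_gain=coupling_gain if fp else 0.0))

    trials = None
    if simulate:
        sub_seeds = np.random.SeedSequence([seed, 0x7A1A]).generate_state(len(truths))
        parts = [simulate_ddm_trials(tr, design, outlier_prob,
                                     seed=int(s % (2**31 - 1)), dt=dt)
                 for tr, s in zip(truths, sub_seeds)]
        trials = pd.concat(parts, ignore_index=True)
    return truths, trials


# ---------------------------------------------------------------------------
# EEG synthesis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ERPTemplate:
    name: str
    peak_ms: float
    half_width_ms: float   # FWHM of the Gaussian bump
    polarity: int          # +1 or -1
    amplitude_uv: float    # mean amplitude over `window_ms` at cluster channels
    window_ms: tuple       # analysis window the amplitude is referred to
    cluster: tuple         # electrode cluster carrying weight 1

    def spatial_weights(self) -> np.ndarray:
        """Weight 1 on cluster channels, Gaussian falloff elsewhere."""
        cl = resolve_cluster(self.cluster)
        pos = np.array([MONTAGE_30[ch] for ch in CHANNELS])
        cpos = np.array([MONTAGE_30[ch] for ch in cl])
        d = np.sqrt(((pos[:, None, :] - cpos[None, :, :]) ** 2).sum(-1)).min(1)
        w = np.exp(-(d ** 2) / (2 * 0.25 ** 2))
        w[[CHANNELS.index(ch) for ch in cl]] = 1.0
        return w


def default_templates() -> list[ERPTemplate]:
    """Template inventory matching the study's component definitions."""
    return [
        ERPTemplate("N1", 125, 60, -1, 2.0, (100, 150), ("FCZ", "FZ", "CZ")),
        ERPTemplate("posteriorN1", 157, 40, -1, 1.5, (147, 167), ("TP7", "T5")),
        ERPTemplate("P2", 210, 80, +1, 3.0, (180, 240),
                    ("FC3", "FC4", "FCZ", "C3", "C4", "CZ", "CP3", "CP4", "CPZ")),
        ERPTemplate("N2", 270, 80, -1, 2.0, (240, 300),
                    ("P4", "PZ", "T4", "T6", "TP8", "C4", "CZ", "CP4", "CPZ")),
        ERPTemplate("P3", 340, 90, +1, 3.0, (320, 360),
                    ("P3", "PZ", "TP7", "T5", "CP3", "O1", "O2", "OZ")),
        ERPTemplate("LPP", 620, 220, +1, 2.5, (500, 700),
                    ("FZ", "FC3", "FC4", "FCZ", "C3", "C4", "CZ", "CPZ")),
    ]


@dataclass(frozen=True)
class OscSpec:
    """Non-phase-locked oscillation: amplitude-modulated sinusoid, random
    phase (and band-random frequency) per trial."""

    fmin_hz: float = 8.0
    fmax_hz: float = 18.0
    base_amp_uv: float = 4.0
    erd_depth: float = -0.30       # post-stimulus power change, fraction
    window_ms: tuple = (200.0, 800.0)
    ramp_ms: float = 50.0
    cluster: tuple = ("F7", "F3", "FZ", "FT7", "FC3", "C3", "T3")
    enabled: bool = True

    def spatial_weights(self) -> np.ndarray:
        cl = resolve_cluster(self.cluster)
        pos = np.array([MONTAGE_30[ch] for ch in CHANNELS])
        cpos = np.array([MONTAGE_30[ch] for ch in cl])
        d = np.sqrt(((pos[:, None, :] - cpos[None, :, :]) ** 2).sum(-1)).min(1)
        w = np.exp(-(d ** 2) / (2 * 0.25 ** 2))
        w[[CHANNELS.index(ch) for ch in cl]] = 1.0
        return w


def synthesize_epochs(trials: pd.DataFrame, templates=None,
                      osc_spec: OscSpec = OscSpec(), fs: float = 1000.0,
                      epoch_window=(-500.0, 800.0), noise_sd: float = 1.0,
                      seed: int = 0, pink_sd: float = 0.0):
    """Build multichannel epochs for each trial row.

    Each epoch is the sum of Gaussian-windowed ERP component bumps (scaled so
    that the window-mean at cluster channels equals the template's
    ``amplitude_uv``), a non-phase-locked band oscillation whose post-stimulus
    power is a decreasing function of the trial's generative drift when the
    subject's ``coupling_gain`` (column ``coupling_gain``) is positive, and
    Gaussian noise.

    Returns an :class:`priomatch.erp.EpochArray`.
    """
    from .erp import EpochArray  # local import to avoid a cycle

    if templates is None:
        templates = default_templates()
    t0_ms, t1_ms = epoch_window
    for tpl in templates:
        if not (t0_ms <= tpl.peak_ms <= t1_ms):
            raise ValueError(f"template {tpl.name} peak {tpl.peak_ms} ms "
                             f"outside epoch window {epoch_window}")
    n_t = int(round((t1_ms - t0_ms) * fs / 1000.0))
    times = t0_ms + np.arange(n_t) * 1000.0 / fs
    n_trials = len(trials)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xEE6]))

    data = np.zeros((n_trials, len(CHANNELS), n_t))

    # phase-locked components (identical across trials)
    erp = np.zeros((len(CHANNELS), n_t))
    for tpl in templates:
        sd = tpl.half_width_ms / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        bump = np.exp(-((times - tpl.peak_ms) ** 2) / (2 * sd ** 2))
        # scale so the discrete window-mean equals amplitude_uv exactly
        w0, w1 = tpl.window_ms
        wmask = (times >= w0 - 1e-9) & (times <= w1 + 1e-9)
        peak_scale = tpl.amplitude_uv / bump[wmask].mean()
        erp += tpl.polarity * peak_scale * np.outer(tpl.spatial_weights(), bump)
    data += erp[None]

    if osc_spec.enabled:
        w_sp = osc_spec.spatial_weights()
        w0, w1 = osc_spec.window_ms
        ramp = max(osc_spec.ramp_ms, 1e-9)
        envelope_shape = np.clip(
            np.minimum((times - w0) / ramp, (w1 - times) / ramp), 0.0, 1.0)
        v = trials["v_true"].to_numpy(float) if "v_true" in trials else \
            np.zeros(n_trials)
        vc = v - v.mean()
        gain = trials["coupling_gain"].to_numpy(float) if "coupling_gain" in trials \
            else np.zeros(n_trials)
        power_ratio = np.clip(1.0 + osc_spec.erd_depth - gain * vc, 0.05, None)
        freqs = rng.uniform(osc_spec.fmin_hz, osc_spec.fmax_hz, n_trials)
        phases = rng.uniform(0, 2 * np.pi, n_trials)
        for i in range(n_trials):
            amp_t = osc_spec.base_amp_uv * (
                1.0 + (np.sqrt(power_ratio[i]) - 1.0) * envelope_shape)
            osc = amp_t * np.sin(2 * np.pi * freqs[i] * times / 1000.0 + phases[i])
            data[i] += np.outer(w_sp, osc)

    if noise_sd > 0:
        data += rng.normal(0, noise_sd, size=data.shape)
    if pink_sd > 0:
        white = rng.normal(0, 1, size=data.shape)
        f = np.fft.rfftfreq(n_t, 1.0 / fs)
        f[0] = f[1]
        pink = np.fft.irfft(np.fft.rfft(white, axis=-1) / np.sqrt(f), n=n_t, axis=-1)
        pink *= pink_sd / pink.std()
        data += pink

    return EpochArray(data=data, fs=fs, tmin_ms=t0_ms,
                      ch_names=list(CHANNELS), metadata=trials.reset_index(drop=True))


# ---------------------------------------------------------------------------
# traits and economic games
# ---------------------------------------------------------------------------

def generate_model_recovery_cohort(n_per_group: int = 3,
                                   trials_per_condition: int = 30,
                                   seed: int = 0,
                                   label_effects: bool = True,
                                   outlier_prob: float = 0.02
                                   ) -> pd.DataFrame:
    """Cohort for DIC model-recovery studies.

    With ``label_effects`` every dependency of the full model carries a
    clearly resolvable effect (drift, boundary and starting point differ by
    label, non-decision time by match, drifts by group); without it the label
    dependencies are flat, so a reduced model should win on parsimony.  The
    deadline is non-binding so the fitted likelihood matches the generative
    process.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x3DE1]))
    design = TaskDesign(trials_per_condition=trials_per_condition,
                        response_deadline_ms=3000.0)
    parts = []
    for g, sgn in (("FP", 1.0), ("SP", -1.0)):
        for i in range(n_per_group):
            u = sgn * 0.9
            if label_effects:
                v_map = {("self", "match"): 2.2 - u / 2 + rng.normal(0, .1),
                         ("friend", "match"): 2.2 + u / 2 + rng.normal(0, .1),
                         ("stranger", "match"): 1.2 + rng.normal(0, .1),
                         ("self", "nonmatch"): -1.8 + rng.normal(0, .1),
                         ("friend", "nonmatch"): -2.4 + rng.normal(0, .1),
                         ("stranger", "nonmatch"): -1.5 + rng.normal(0, .1)}
                a_map = {"self": 1.2 + rng.normal(0, .05),
                         "friend": 1.5 + rng.normal(0, .05),
                         "stranger": 1.75 + rng.normal(0, .05)}
                z_map = {"self": 0.60 + rng.normal(0, .02),
                         "friend": 0.50 + rng.normal(0, .02),
                         "stranger": 0.40 + rng.normal(0, .02)}
            else:
                v_map = {(l, "match"): 2.0 + rng.normal(0, .1)
                         for l in LABELS}
                v_map.update({(l, "nonmatch"): -2.0 + rng.normal(0, .1)
                              for l in LABELS})
                a_map = {l: 1.4 + rng.normal(0, .05) for l in LABELS}
                z_map = {l: 0.5 + rng.normal(0, .02) for l in LABELS}
            t0_map = {"match": 0.25 + rng.normal(0, .01),
                      "nonmatch": 0.33 + rng.normal(0, .01)}
            truth = SubjectTruth(f"{g.lower()}{i}", g, v_map, a_map, z_map,
                                 t0_map)
            tab = simulate_ddm_trials(
                truth, design, outlier_prob=outlier_prob,
                seed=int(rng.integers(2**31 - 1)))
            tab["group"] = g
            parts.append(tab)
    return pd.concat(parts, ignore_index=True)


#: trait name -> (loading on the shared factor, scale center, scale sd, bounds)
_TRAIT_SPEC = {
    "empathic_concern": (0.80, 14.0, 4.0, (0, 28)),
    "perspective_taking": (0.30, 14.0, 4.0, (0, 28)),
    "fantasy": (0.20, 14.0, 4.0, (0, 28)),
    "personal_distress": (-0.20, 14.0, 4.0, (0, 28)),
    "independent_sc": (-0.10, 60.0, 10.0, (15, 105)),
    "interdependent_sc": (0.30, 60.0, 10.0, (15, 105)),
    "friend_months": (0.00, 60.0, 20.0, (1, 200)),
    "closeness": (0.70, 4.5, 1.1, (1, 7)),
    "likability": (0.75, 4.5, 1.1, (1, 7)),
    "familiarity": (0.40, 4.5, 1.1, (1, 7)),
}

_GAME_LOADING = 0.25  # on the shared factor; calibrated for a weak (~0.14)
# rank correlation with differential accuracy at canonical_rho ~ 0.6

TRUST_ENDOWMENT = 10
PGG_ENDOWMENT = 80


def generate_traits_and_games(cohort, canonical_rho: float = 0.33,
                              seed: int = 0, anchor=None) -> pd.DataFrame:
    """Trait scales and one-shot game contributions for a cohort.

    A latent factor f correlates at ``canonical_rho`` with each subject's
    standardized friend-priority magnitude; trait scales and game
    contributions load on f.  By default the priority magnitude is the
    ground-truth drift difference; pass ``anchor`` (an array aligned with
    ``cohort``) to tie f to an observed behavioral score instead — with a
    latent anchor the canonical correlation recoverable from measured
    behavior is attenuated by behavioral sampling noise.  Trust-game sends
    are bounded by the 10-unit endowment, public-goods contributions by the
    80-unit endowment.
    """
    if not 0.0 <= canonical_rho < 1.0:
        raise ValueError("canonical_rho must lie in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7247]))
    if anchor is not None:
        u = np.asarray(anchor, float)
        if len(u) != len(cohort):
            raise ValueError("anchor must align with the cohort")
    else:
        u = np.array([t.friend_priority for t in cohort], float)
    su = u.std()
    u = (u - u.mean()) / (su if su > 0 else 1.0)
    f = canonical_rho * u + math.sqrt(1.0 - canonical_rho ** 2) * \
        rng.normal(size=len(u))

    out = {"subject": [t.subject_id for t in cohort],
           "group_truth": [t.latent_group for t in cohort]}
    for name, (lam, center, sd, (lo, hi)) in _TRAIT_SPEC.items():
        zval = lam * f + math.sqrt(max(1.0 - lam ** 2, 0.0)) * rng.normal(size=len(u))
        out[name] = np.clip(center + sd * zval, lo, hi).round(1)
    for name, endow in (("trust_send", TRUST_ENDOWMENT),
                        ("pgg_contribution", PGG_ENDOWMENT)):
        zval = _GAME_LOADING * f + math.sqrt(1 - _GAME_LOADING ** 2) * \
            rng.normal(size=len(u))
        out[name] = np.clip(np.round(endow * (0.5 + 0.18 * zval)), 0, endow)
    return pd.DataFrame(out)
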