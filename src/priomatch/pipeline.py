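"""End-to-end pipeline driver: simulate -> behavior -> ddm -> erp -> tf ->
cluster -> couple -> cca, with per-stage seeds, resumable stage outputs and a
JSON report.

Every stage writes its artifacts into the output directory and is skipped on
re-run when its outputs already exist (delete a stage's output to recompute
from that stage on).  All outputs are stamped with the config hash and the
stage seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, cca, clusterstats, io, synth, timefreq
from . import erp as erpmod
from .ddm import fit as ddmfit
from .ddm import models as ddmmodels

log = logging.getLogger("priomatch")


@dataclass
class PipelineConfig:
    """Configuration of the full pipeline.

    The 'paper' MCMC/permutation preset encodes 10000 samples / 1000 burn-in,
    1000 permutations and 1000 bootstraps; the 'desk' preset scales the
    stochastic stages down for interactive runs and tests.
    """

    n_fp: int = 6
    n_sp: int = 6
    effect_size_v: float = 0.8
    coupling_gain: float = 0.5
    canonical_rho: float = 0.33
    trials_per_condition: int = 110
    eeg_fs: float = 1000.0
    eeg_noise_sd: float = 2.0
    eeg_max_trials_per_condition: int = 40
    preset: str = "desk"
    seed: int = 0
    out_dir: str = "prio_out"

    @property
    def mcmc(self):
        return ddmfit.PRESETS[self.preset]

    @property
    def n_perm(self):
        return 1000 if self.preset == "paper" else 200

    @property
    def n_boot(self):
        return 1000 if self.preset == "paper" else 200

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha1(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)

    def config_hash(self) -> str:
        return hashlib.sha1(json.dumps(
            dataclasses.asdict(self), sort_keys=True).encode()).hexdigest()[:10]


def _stamp(cfg: PipelineConfig, stage: str) -> dict:
    return {"config_hash": cfg.config_hash(), "stage": stage,
            "seed": cfg.stage_seed(stage)}


def run_pipeline(cfg: PipelineConfig, force: bool = False) -> dict:
    """Run (or resume) every stage; returns the report dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": cfg.config_hash(),
                    "seed": cfg.seed, "stages": {}}
    design = synth.TaskDesign(trials_per_condition=cfg.trials_per_condition)

    # ---- simulate -------------------------------------------------------
    trials_path = out / "trials.tsv"
    truths_path = out / "truths.json"
    if force or not trials_path.exists():
        log.info("stage simulate")
        truths, trials = synth.generate_cohort(
            cfg.n_fp, cfg.n_sp, cfg.effect_size_v,
            seed=cfg.stage_seed("simulate"), coupling_gain=cfg.coupling_gain,
            design=design)
        io.write_trials(trials, trials_path)
        io.write_json({"stamp": _stamp(cfg, "simulate"),
                       "subjects": [dataclasses.asdict(t) | {
                           "v_map": {f"{l}|{m}": v for (l, m), v in t.v_map.items()}}
                           for t in truths]}, truths_path)
    trials = io.read_trials(trials_path)
    report["stages"]["simulate"] = {"n_trials": len(trials),
                                    "n_subjects": trials["subject"].nunique()}

    # ---- behavior -------------------------------------------------------
    beh_path = out / "behavior.json"
    if force or not beh_path.exists():
        log.info("stage behavior")
        eff = behavior.response_efficiency(trials)
        groups = behavior.classify_groups(eff)
        sdt = behavior.sdt_indices(trials)
        boots = behavior.bootstrap_condition_means(
            trials, n_boot=cfg.n_boot, seed=cfg.stage_seed("behavior"),
            by_group="group_truth")
        io.write_table(eff, out / "efficiency.tsv")
        io.write_table(groups, out / "groups.tsv")
        io.write_table(sdt, out / "sdt.tsv")
        io.write_table(boots, out / "bootstrap_means.tsv")
        n_fp = int((groups["group"] == "FP").sum())
        io.write_json({"stamp": _stamp(cfg, "behavior"),
                       "n_fp": n_fp,
                       "n_sp": int((groups["group"] == "SP").sum()),
                       "recovery": float(
                           (groups.merge(eff[["subject"]].assign(
                               truth=trials.groupby("subject")["group_truth"].first().values),
                               on="subject")
                            .query("group != 'unassigned'")
                            .eval("group == truth")).mean())},
                      beh_path)
    report["stages"]["behavior"] = io.read_json(beh_path)

    groups = io.read_table(out / "groups.tsv")
    assigned = groups[groups["group"] != "unassigned"]
    trials_g = trials.merge(assigned[["subject", "group"]], on="subject")

    # ---- ddm ------------------------------------------------------------
    ddm_path = out / "ddm.json"
    if force or not ddm_path.exists():
        log.info("stage ddm")
        n_samples, burn = cfg.mcmc
        spec = ddmmodels.make_spec(1)
        post = ddmfit.fit_hddm(trials_g, spec, n_samples=n_samples,
                               burn_in=burn, seed=cfg.stage_seed("ddm"))
        contrasts = {}
        for g in post.groups:
            contrasts[g] = {
                "p_self_lt_friend_v": ddmfit.p_bayes(
                    post, ("v", "self", "match", g),
                    ("v", "friend", "match", g), "<"),
                "p_match_lt_nonmatch_t0": ddmfit.p_bayes(
                    post, ("t0", "self", "match", g),
                    ("t0", "self", "nonmatch", g), "<"),
            }
        (out / "ddm_posterior.json").write_text(ddmfit.posterior_to_json(post))
        # subject-level drift estimates for the coupling stage
        drift = []
        for g in post.groups:
            sm = post.subject_means[g]
            v_f = sm.filter(like="v_friend-match").iloc[:, 0] \
                if any("friend-match" in c for c in sm.columns) else sm.iloc[:, 0]
            v_s = sm.filter(like="v_self-match").iloc[:, 0] \
                if any("self-match" in c for c in sm.columns) else sm.iloc[:, 0]
            drift.append(pd.DataFrame({"subject": sm.index,
                                       "group": g,
                                       "diff_drift": v_f - v_s}))
        io.write_table(pd.concat(drift, ignore_index=True),
                       out / "subject_drift.tsv")
        io.write_json({"stamp": _stamp(cfg, "ddm"), "dic": post.dic,
                       "converged": post.converged, "contrasts": contrasts},
                      ddm_path)
    report["stages"]["ddm"] = io.read_json(ddm_path)

    # ---- erp + tf + cluster + couple ------------------------------------
    eeg_path = out / "eeg.json"
    if force or not eeg_path.exists():
        log.info("stage eeg (erp/tf)")
        rng = np.random.default_rng(cfg.stage_seed("eeg"))
        comp_rows, band_rows = [], []
        subj_diff_maps = {"FP": [], "SP": []}
        subj_power_series = {"FP": [], "SP": []}
        window = (-500.0, 800.0)
        fam = timefreq.build_wavelets(fs=cfg.eeg_fs)
        osc = synth.OscSpec()
        band = "alpha_low_beta"
        for subject, sub in trials_g.groupby("subject", sort=True):
            keep = sub[(sub["match"] == "match") &
                       (sub["label"].isin(["self", "friend"])) &
                       (sub["accuracy"] == 1.0)]
            keep = keep.groupby("label", group_keys=False, sort=False).head(
                cfg.eeg_max_trials_per_condition)
            ep = synth.synthesize_epochs(
                keep, fs=cfg.eeg_fs, epoch_window=window,
                noise_sd=cfg.eeg_noise_sd, osc_spec=osc,
                seed=int(rng.integers(2**31 - 1)))
            ep = erpmod.epoch_and_baseline(ep)
            ep, _ = erpmod.reject_artifacts(ep)
            ct = erpmod.component_table(ep, by=("label",))
            ct.insert(0, "subject", subject)
            comp_rows.append(ct)

            induced = timefreq.remove_phase_locked(ep, by=("label",))
            tfr = timefreq.tf_power(induced, fam)
            norm = timefreq.ers_erd(tfr)
            fi = norm.band_index(band)
            bandmap = norm.power[:, :, fi, :].mean(axis=2)
            lab = norm.metadata["label"].to_numpy()
            diff = bandmap[lab == "self"].mean(axis=0) - \
                bandmap[lab == "friend"].mean(axis=0)
            g = sub["group"].iloc[0]
            subj_diff_maps[g].append(diff)
            ci = [norm.ch_names.index(c) for c in
                  erpmod.COMPONENT_REGISTRY["N1"].cluster]  # frontal cluster
            subj_power_series[g].append(diff[ci].mean(axis=0))
            band_rows.append({"subject": subject, "group": g})
        comp = pd.concat(comp_rows, ignore_index=True)
        io.write_table(comp, out / "components.tsv")

        adjacency = clusterstats.make_adjacency()
        times = np.arange(window[0], window[1], 1000.0 / cfg.eeg_fs)
        tmask = (times >= 0) & (times <= 800)
        cluster_out = {}
        series = {}
        for g in ("FP", "SP"):
            if len(subj_diff_maps[g]) >= 2:
                maps = np.stack(subj_diff_maps[g])[:, :, tmask]
                res = clusterstats.cluster_permutation(
                    maps, adjacency, n_perm=cfg.n_perm,
                    seed=cfg.stage_seed(f"cluster-{g}"),
                    times_ms=times[tmask])
                cluster_out[g] = res.clusters[:3]
                series[g] = np.stack(subj_power_series[g])[:, tmask]
        io.write_json({"stamp": _stamp(cfg, "eeg"),
                       "clusters": cluster_out,
                       "subjects": band_rows}, eeg_path)
        np.save(out / "power_series.npy",
                {g: s for g, s in series.items()}, allow_pickle=True)
    report["stages"]["eeg"] = {"clusters": io.read_json(eeg_path)["clusters"]}

    # ---- couple ---------------------------------------------------------
    couple_path = out / "couple.json"
    if force or not couple_path.exists():
        log.info("stage couple")
        drift = io.read_table(out / "subject_drift.tsv")
        series = np.load(out / "power_series.npy", allow_pickle=True).item()
        eeg_meta = io.read_json(eeg_path)
        subj_by_group = pd.DataFrame(eeg_meta["subjects"])
        times = np.arange(0.0, 800.0, 1000.0 / cfg.eeg_fs)
        couple = {}
        window_means, drifts, glabels = [], [], []
        for g, ser in series.items():
            subs = subj_by_group.query("group == @g")["subject"]
            d = drift.set_index("subject").loc[subs, "diff_drift"].to_numpy()
            if len(d) < 5:
                couple[g] = {"skipped": f"only {len(d)} subjects"}
                continue
            # drift difference is friend - self; power diff is self - friend
            run_len = max(10, int(0.1 * cfg.eeg_fs))
            pw = clusterstats.pointwise_correlation(ser, d, times,
                                                    run_length=run_len)
            wmask = (times >= 542) & (times <= 668)
            wmean = ser[:, wmask].mean(axis=1)
            wc = clusterstats.window_correlation(wmean, d)
            couple[g] = {"n_runs": len(pw["runs"]), "runs": pw["runs"][:3],
                         "window_rho": wc["rho"], "window_p": wc["p"]}
            window_means.append(wmean)
            drifts.append(d)
            glabels += [g] * len(d)
        if len(series) == 2 and len(window_means) == 2 and \
                min(len(w) for w in window_means) >= 3:
            mod = clusterstats.group_moderation(
                np.concatenate(window_means), np.concatenate(drifts), glabels)
            couple["moderation"] = {k: mod[k] for k in
                                    ("F", "df1", "df2", "p", "partial_eta_sq")}
        io.write_json({"stamp": _stamp(cfg, "couple"), **couple}, couple_path)
    report["stages"]["couple"] = io.read_json(couple_path)

    # ---- cca ------------------------------------------------------------
    cca_path = out / "cca.json"
    if force or not cca_path.exists():
        log.info("stage cca")
        truths_json = io.read_json(truths_path)["subjects"]
        cohort = [synth.SubjectTruth(
            subject_id=t["subject_id"], latent_group=t["latent_group"],
            v_map={tuple(k.split("|")): v for k, v in t["v_map"].items()},
            a_map=t["a_map"], z_map=t["z_map"], t0_map=t["t0_map"],
            coupling_gain=t["coupling_gain"]) for t in truths_json]
        traits = synth.generate_traits_and_games(
            cohort, cfg.canonical_rho, seed=cfg.stage_seed("cca"))
        io.write_table(traits, out / "traits.tsv")
        beh = cca.behavior_block(trials)
        merged = traits.merge(beh, on="subject").dropna()
        res = cca.permutation_pvalue(merged[cca.TRAIT_VARS],
                                     merged[cca.BEHAVIOR_VARS],
                                     n_perm=cfg.n_perm,
                                     seed=cfg.stage_seed("cca-perm"))
        eff = io.read_table(out / "efficiency.tsv").set_index("subject")
        diff_acc = (eff["acc_friend"] - eff["acc_self"]).loc[traits["subject"]]
        gc = cca.game_correlations(diff_acc.to_numpy(), traits,
                                   seed=cfg.stage_seed("cca-games"))
        io.write_table(gc, out / "game_correlations.tsv")
        io.write_json({"stamp": _stamp(cfg, "cca"), "rho": res.rho,
                       "p_perm": res.p_perm,
                       "y_loadings": res.y_loadings.tolist()}, cca_path)
    report["stages"]["cca"] = io.read_json(cca_path)

    io.write_json(report, out / "report.json")
    return report
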