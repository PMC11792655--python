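# priomatch

Analysis pipeline for **friend-prioritization vs self-prioritization** in the
shape-label matching task, with a synthetic-data generator so that every
stage is testable end to end without any recorded data.

In the shape-label matching task, participants learn arbitrary pairings
between geometric shapes and person labels (*self*, *friend*, *stranger*) and
then judge, under a 1100 ms deadline, whether a displayed word–shape pair
matches the learned assignment (110 trials per label × match condition).
Most people respond faster and more accurately to self–shape pairs, but a
subpopulation shows the reverse — *friend-prioritization*.  This package
implements the full inference chain used to detect and characterize the two
subpopulations:

- **behavior** — response efficiency *E* = RT/accuracy; the self-minus-friend
  difference in *E* classifies the friend-prioritization (FP, diff > 0) and
  self-prioritization (SP, the equally many most negative diffs) groups;
  bootstrap condition means; signal detection indices
  *d′* = Φ⁻¹(H) − Φ⁻¹(F) and β = exp[(Φ⁻¹(F)² − Φ⁻¹(H)²)/2];
  mixed-design ANOVA with partial η² CIs.
- **ddm** — hierarchical Bayesian drift-diffusion modelling with the Wiener
  first-passage-time likelihood (Navarro–Fuss dual series), a 5% uniform
  outlier mixture, a 15-model factor-dependency space over
  (v, a, z, t₀), DIC model comparison, directional posterior contrasts
  (P_Bayes), and trial-by-trial regression of ERP amplitudes onto drift rate
  or boundary separation.
- **erp / timefreq** — epoching, ±70 µV artifact rejection, component
  amplitude/latency extraction in the published windows and electrode
  clusters (N1, posterior N1, P2, N2, P3, LPP); Morlet wavelet
  time-frequency analysis (f₀/σ_f = 5, 1–40 Hz) of induced
  (non-phase-locked) activity with ERS/ERD baseline normalization.
- **clusterstats** — 2D time × electrode cluster-based permutation tests
  (max-mass null, sign-flip permutations), point-by-point power–drift
  correlations with a 100 ms consecutive-run criterion, and group moderation
  of the coupling.
- **cca** — canonical correlation between interpersonal-trait and behavioral
  blocks with a permutation test, plus economic-game correlations.
- **synth** — forward DDM trial simulation (Euler–Maruyama with
  Brownian-bridge absorption), EEG epochs built from component templates
  plus a drift-coupled alpha/low-beta oscillation, and trait/game tables
  sharing a latent factor with friend-priority.

## Worked example

```python
from priomatch import behavior
from priomatch.synth import generate_cohort
from priomatch.ddm import fit_hddm, make_spec, p_bayes

truths, trials = generate_cohort(n_fp=6, n_sp=6, effect_size_v=0.8, seed=7)
eff = behavior.response_efficiency(trials)
groups = behavior.classify_groups(eff)
print(groups["group"].value_counts().to_dict())

fit = fit_hddm(trials.rename(columns={"group_truth": "group"}),
               make_spec(1), n_samples=2000, burn_in=500, seed=7)
print(round(p_bayes(fit, ("v", "friend", "match", "FP"),
                    ("v", "self", "match", "FP"), ">"), 3))
```

prints

```
{'FP': 6, 'SP': 6}
1.0
```

— all 6 latent-FP subjects have positive efficiency differences and are
classified FP (with the 6 most self-prioritizing as SP), and the fitted
posterior puts probability 1.0 on the drift rate for friend–shape matches
exceeding that for self–shape matches in the FP group, the signature of
friend-prioritized evidence accumulation.

The same chain runs from a shell:

```bash
prio simulate --n-fp 6 --n-sp 6 --seed 7 --out out/
prio behavior --trials out/trials.tsv --out out/
prio ddm fit --trials out/trials.tsv --model 1 --seed 7 --out out/ddm
prio run --preset desk --out prio_out   # full pipeline, resumable
```

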