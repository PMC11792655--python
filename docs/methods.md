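# Methods

## Task model and behavioral indices

The shape-label matching task presents a word–shape pair for 100 ms; a
response ("yes" = the pair matches the learned assignment) must arrive
within 1100 ms of onset, after which the trial is scored "slow" and excluded
from both the RT mean and the accuracy numerator.  There are 110 trials per
(label ∈ {self, friend, stranger}) × (match ∈ {match, nonmatch}) cell,
900–1700 ms fixation intervals, and 500 ms feedback.

Response efficiency is E = mean correct RT / accuracy (ms) on matching
trials.  The classification rule is strict: diff = E_self − E_friend > 0
defines the FP group; a diff of exactly zero is unassigned; the SP group is
the |FP| most negative diffs, ties at the selection boundary broken by
subject id (deterministic).  Signal-detection rates use hits = "yes" on
match, false alarms = "yes" on nonmatch; extreme rates (0 or 1) are replaced
by 1/(2N) and 1 − 1/(2N) (the log-linear (k+0.5)/(N+1) rule is available as
an option).  Whether RTs entering efficiency should be trimmed is not
settled; the default is untrimmed correct-trial means.

The mixed-design ANOVA is delegated to pingouin; the 90% CI for partial η²
inverts the noncentral-F distribution in the noncentrality parameter.

## Drift diffusion model

The decision variable is a Brownian motion with drift v and diffusion
coefficient 1 between absorbing boundaries at 0 and a, started at relative
position z ∈ (0, 1); "yes" = upper boundary, RT = first-passage time + t₀.
The likelihood is the Navarro–Fuss dual series (small-time image sum /
large-time sine series, automatic switch, truncation error 10⁻⁷), with the
upper-boundary density obtained by the (v, z) → (−v, 1−z) reflection.  Each
trial's likelihood is mixed with a uniform contaminant over the observed RT
range (weight 0.05, random button), which absorbs slow outliers.

**Model space.**  The full model (Model 1) lets v depend on label × match,
a and z on label, and t₀ on match; every parameter is additionally split by
group (FP vs SP are modelled as separate populations fitted jointly).
Models 2–15 toggle the four within-subject condition dependencies off
one-by-one and in combination (4 singles, 6 pairs, 4 triples; the model
with all four dropped is excluded), in a fixed documented order; Model 7 is
pinned to the structure of earlier work on this task (v per label × match,
t₀ per match, constant a and z).  Because group membership partitions
subjects, each group is sampled as an independent sub-chain and deviances
add.  v always retains the match factor: matching and non-matching pairs
drive evidence toward opposite boundaries, so a match-free drift is not a
meaningful reduction.

**Inference.**  Componentwise slice sampling within Gibbs (stepping-out +
shrinkage), JIT-compiled.  Hierarchy: subject effects θ_s ~ Normal(μ, σ)
truncated to the domain (a > 0.05, z ∈ (0.01, 0.99), 0 ≤ t₀ < min subject
RT); the truncation normalization is ignored in the group-level
conditionals, a standard approximation that is accurate while the
constraints are non-binding (they are, at the posteriors reached here).
Priors: μ_v ~ N(0, 2²), μ_a ~ Gamma(2, 1), μ_z ~ Beta(2, 2),
μ_t₀ ~ U(0, min RT); σ ~ Half-Normal with scales (0.5, 0.3, 0.1, 0.1) for
(v, a, z, t₀).  Each t₀ cell is bounded by the smallest RT among the trials
that cell governs — bounding by the subject's global minimum RT would let a
fast match (or outlier) trial clamp the non-matching t₀ below its true
value.  Convergence is monitored by split R-hat on every group-level
mean; values above 1.1 set a warning flag on the posterior rather than
failing silently.  DIC = D̄ + p_D with p_D = D̄ − D(θ̄), θ̄ the posterior
mean of the subject-level parameters.  The "paper-scale" preset is
10 000 samples / 1 000 burn-in; the desk preset (2 000 / 500) is the default
for interactive use and testing.  Whether z is relative or absolute is a
convention choice; relative z is used throughout.

Trial-by-trial neural regression replaces the drift (or boundary) with
v_trial = v₀ + β·x, where x is the standardized single-trial covariate
(e.g. N1 amplitude); v₀ and β carry the same Normal hierarchy, and
P_Bayes(β < 0) is the fraction of post-burn-in draws below zero.

## EEG analyses

Epochs are baseline-corrected per trial and channel (−200…0 ms for ERP
analyses) and trials exceeding ±70 µV at any electrode are rejected.
Component definitions (window, cluster, polarity): N1 100–150 ms at
FCz/Fz/Cz (−); posterior N1 147–167 ms at TP7/T5 (−); P2 180–240 ms at
FC3/FC4/FCz/C3/C4/Cz/CP3/CP4/CPz (+); N2 240–300 ms at
P4/Pz/T4/T6/TP8/C4/Cz/CP4/CPz (−); P3 320–360 ms at
P3/Pz/TP7/T5/CP3/O1/O2/Oz (+); LPP 500–700 ms at
Fz/FC3/FC4/FCz/C3/C4/Cz/CPz (+).  Window endpoints are inclusive at sample
resolution.  Old temporal electrode names are mapped T3→T7, T4→T8, T5→P7,
T6→P8.  LPP peak latencies near 690 ms sit at the edge of the 500–700 ms
amplitude window, so the latency search window extends to 800 ms — an
interpretation, flagged here.

Time-frequency analysis uses complex Morlet wavelets
w(t, f₀) = A exp(−t²/2σ_t²) exp(2iπf₀t) on a 1–40 Hz grid (1 Hz steps) with
constant ratio f₀/σ_f = 5.  The temporal width follows σ_t = 1/(2πσ_f)
(the standard spectral–temporal relation for this wavelet family; only the
ratio is prescribed) and A = (σ_t√π)^(−1/2) gives unit kernel energy.
Kernels are truncated at ±4σ_t; convolution is FFT-based with explicit
edge-validity masks (±2σ_t) instead of padding, so edge power is flagged
rather than biased.  Phase-locked activity is removed by subtracting each
condition's mean waveform from its member trials before decomposition.
Power P(t) = Re[TF]² + Im[TF]² is normalized as ERS/ERD = (P(t) − P₀)/P₀
with P₀ the −300…−100 ms baseline mean, computed per trial then averaged
(the on-average alternative is available).  Because the baseline starts at
−300 ms, time-frequency epochs are cut −500…+800 ms — longer than ERP
epochs — so the baseline is edge-valid down to 8 Hz; below ~8 Hz no epoch
of this length can have an edge-valid baseline, and the code warns rather
than silently normalizing.  The analysis bands are delta/theta 2–7 Hz,
alpha/low-beta 8–18 Hz, beta 19–29 Hz; statistics run on 0–800 ms.

## Cluster statistics and coupling

Channel adjacency comes from schematic 2D montage positions with a distance
threshold chosen so the median neighbor count is ≈4–5 (no adjacency rule is
prescribed by the analysis itself).  The cluster test computes paired
t-values at every (channel, time) point, groups same-sign supra-threshold
points (two-sided t at α = .05) under channel adjacency × consecutive-time
connectivity, and compares each observed cluster's summed t against the
distribution of the maximum absolute cluster mass over 1 000 within-subject
sign-flip permutations (signs pooled, i.e. one two-sided null; a per-sign
null is a defensible alternative).  P-values use (b+1)/(n_perm+1), so the
smallest attainable p is 1/(n_perm+1).  Points with degenerate variance get
an undefined t and never join clusters.  Bonferroni correction across the
three frequency bands multiplies cluster p by 3.

Point-by-point coupling rank-correlates a per-subject differential power
time series with a per-subject scalar (differential drift) at every sample
and reports maximal runs of at least 100 ms of consecutively significant
(p < .05, uncorrected) points — the "successive 100 time points" criterion
at the native 1 000 Hz rate, converted to samples at other rates.  Window
coupling is Spearman's rho on the 542–668 ms mean.  Group moderation fits
diff_drift ~ diff_power × group by OLS and tests the interaction.

## Canonical correlation

Both blocks are column-standardized; the first canonical pair comes from
the SVD of Q_x'Q_y (QR orthonormal bases), loadings are structure
correlations, and the sign convention forces the accuracy loading
nonnegative so larger canonical scores mean better friend-match
performance.  Significance is a permutation test on the rows of Y with the
add-one rule.  The trait block is the 4 IRI subscales, 2 self-construal
scores, and 4 friendship indices; the behavior block is accuracy, RT, d′
and β of friend-match trials.  Pearson-based CCA is the default (the robust
projection-pursuit variant used by some packages is out of scope).

## Synthetic-data generator

Forward trials are simulated by Euler–Maruyama at dt = 1 ms with diffusion
coefficient 1, augmented by a Brownian-bridge within-step absorption check
(crossings are detected with the exact bridge probability and reported at
the step midpoint).  This removes the O(√dt) first-passage bias of naive
Euler, which would otherwise dominate density cross-checks; pure Euler is
available via `bridge=False`.  Trials not absorbed before the deadline
become "slow" no-responses.  Outlier contaminants replace a chosen fraction
of responded trials with uniform RTs on [t₀, deadline] and a random button,
mirroring the fitting stage's mixture.  Trial-to-trial drift variability is
exposed (`sv`) but defaults to 0, as no value is established for this task.

Cohort defaults place baseline performance at realistic task levels (mean
RT ≈ 0.6 s, accuracy ≈ 0.9, few deadline misses): matching drift base 2.2,
non-matching −2.0, stranger penalty 0.6, boundaries 1.35/1.45/1.50 for
self/friend/stranger, t₀ = 0.28/0.32 s for match/nonmatch, and a
starting-point advantage for self (z + 0.06) in SP subjects only.  FP
subjects get v(friend, match) − v(self, match) = +effect_size (default 0.8)
plus Normal(0, 0.1) between-subject noise; SP subjects the reverse.
Because responded trials are deadline-censored, fitting the (censoring-
blind) likelihood to deadline-limited data inflates low drift rates
slightly; parameter-recovery studies therefore use a non-binding deadline,
while contrast-based checks (which are robust to the shared bias) use the
real task design.

EEG epochs are the sum of (i) Gaussian-bump component templates scaled so
their window-mean at cluster electrodes equals the stated amplitude
exactly, (ii) an amplitude-modulated sinusoid at a per-trial random
frequency in 8–18 Hz and random phase (hence non-phase-locked), whose
post-stimulus power is (1 + ERD − gain·(v_trial − v̄)) — a 30% default
desynchronization, deepened on high-drift trials when the coupling gain is
positive — and (iii) white Gaussian noise (a 1/f component is optional).
The generator ties the *group-mean* induced-power contrast to the drift
contrast; in real data the group-mean contrast and the between-subject
coupling can dissociate, which this phenomenological model does not emulate.
Passing coupling tests therefore shows the statistics detect a planted
coupling, not that real data behave this way.  Head-model forward
simulation is out of scope; spatial weights are Gaussian falloffs around
the cluster electrodes.

Trait and game tables share one latent factor f with the cohort's
friend-priority magnitude at a chosen correlation.  With f anchored on the
latent drift difference, the canonical correlation recoverable from
measured behavior is attenuated by behavioral sampling noise; anchoring on
an observed behavioral composite (the `anchor` argument) makes the
parameter calibrate the observable canonical correlation, and is what the
calibration studies use.  Trait loadings put empathic concern, closeness
and likability highest; game contributions load weakly (0.25) so their
rank correlations with differential accuracy land near 0.15 when the
shared factor is strong.  Trust sends and public-goods contributions are
integer-rounded and clipped to the 10- and 80-unit endowments.

## Problem sizes and numerical choices

Recovery and calibration studies run at sizes chosen to be decisive yet
desk-friendly: drift-contrast recovery uses 20 subjects per group at the
task's full 110 trials/condition with the desk MCMC preset; DIC model
recovery uses 3 subjects per group × 30 trials/condition × 500 sweeps over
all 15 models and 10 replicates (strong effects: boundary 1.2/1.5/1.75,
starting point 0.60/0.50/0.40 by label, t₀ 0.25/0.33 by match, ±0.9 group
drift effects); cluster type-I calibration uses 200 null datasets of 20
subjects × 30 channels × 200 timepoints at 1 000 permutations; CCA
calibration uses 200 null replicates and an n = 400 recovery cohort.  The
moderation power study follows the prescribed calibration — slopes −0.2 vs
0.0 at n = 216 per group — with residual sd 0.7 chosen analytically for
≈85% power at α = .05.

Degenerate inputs fail loudly and specifically: zero-accuracy efficiency
cells are flagged undefined, empty FP groups and SP shortfalls raise with
counts, constant covariates and rank-deficient CCA blocks raise naming the
column, all-rejected epochs raise with the peak amplitude seen.

## Known limitations

- The deviance used in DIC conditions on subject-level parameters
  (the conditional focus); marginal-likelihood criteria would rank
  differently in principle.
- The censoring-blind likelihood biases drift estimates upward by a few
  percent on deadline-limited data (see above); the published analyses
  share this property.
- The enumeration of the 14 reduced models is a documented convention; the
  original supplementary table is not reproduced here.
- Inter-trial variability parameters (sv, st, sz) and RT-quantile fitting
  methods are deliberately not implemented.
- The EEG generator is phenomenological: no volume conduction, no ocular
  artifacts (artifact rejection is exercised with planted amplitude
  spikes), no 1/f background by default.
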