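# Methods

## The model

Each of N = 68 cortical regions (a Desikan–Killiany-scale parcellation) is a
Stuart–Landau oscillator — the normal form of a supercritical Hopf bifurcation —
extended with an adaptive angular-frequency state. Writing z_j for the complex
amplitude and ω_j for the angular frequency of region j:

    dz_j/dt = (A + iω_j − |z_j|²) z_j + G Σ_i C_ij (z_i − z_j) + β η_j
    dω_j/dt = ω°_j − F ω_j + M Σ_i C_ij arg(z_i)

* **A** (dimensionless, searched −0.2…0.2): global bifurcation parameter. For
  A < 0 every region is a damped stable focus whose fluctuations are
  noise-driven; for A > 0 it is a self-sustained limit cycle of radius √A.
* **G** (≥ 0, searched 0.005…0.05): global coupling on the row-normalized
  structural connectome C (each region's incoming weights sum to 1, so the
  coupling term pulls z_j toward the weighted mean of its neighbours).
* **F** (1/s, searched 0…1): feedback pulling ω_j toward ω°_j/F. At F = 0 the
  frequency state has no restoring force and may drift over a run; the
  integrator logs a warning but proceeds (the state stays finite over the
  configured durations).
* **M** (rad/s per rad, searched 0.10…0.49): modulation of ω_j by the mean
  phase of structural neighbours, using the principal value arg(z) ∈ (−π, π].
* **β** (noise SD, fixed 0.02): complex additive white noise, independent real
  and imaginary increments of SD β√dt per step, entering the amplitude
  equation only; the frequency equation is deterministic.
* **ω°_j** (rad/s): region-specific intrinsic frequency, drawn uniformly from
  the empirically reported resting-state range [0.098, 0.221] rad/s, or
  estimated from data as the Welch spectral peak (segment min(T, 64), 50%
  overlap, cosine taper) inside 0.008–0.1 Hz, median across subjects.

Re{z} is the simulated BOLD-like observable; Im{z} is a hidden state.

### Integration

Euler–Maruyama at dt = 0.05 s, far below the fastest intrinsic period
(2π/0.221 ≈ 28 s). Initial z_j uniform on a disk of radius 0.1 (seeded),
initial ω_j = ω°_j. Runs last 420 s (a 7-minute scan) with the first 60 s
discarded as transient and states sampled every TR = 2 s, giving 181 samples.
Fixed points of the radial dynamics are preserved exactly by the Euler map, but
the iω rotation inflates the discrete-time limit-cycle radius by ≈ dt·ω²/2
(0.2014 instead of 0.2000 at dt = 0.05, ω = 0.15); analytic checks therefore
integrate at dt = 0.005, where the radius is correct to < 10⁻⁴. Halving dt
moves seed-averaged amplitudes by well under 2%.

## Connectome

Group-consensus connectomes are emulated by a pseudo-subject model: each of
100 pseudo-subjects expresses a symmetric Bernoulli(0.7) edge set with positive
log-normal weights; edges present in strictly more than 60% of pseudo-subjects
survive; surviving weights are averaged, rank-mapped onto a Gaussian with
μ = 0.5, σ = 0.15 (average ranks on ties, r → μ + σΦ⁻¹((r − 0.5)/n), clipped
below at 10⁻⁶ so couplings stay positive), and finally row-normalized.
Resampling precedes normalization. Ledger-worthy consequences: the
un-normalized matrix is symmetric, the normalized one generally is not.

## Fitting

FC is the Pearson correlation of band-passed (0.008–0.1 Hz, full-length DCT
windowing: orthonormal type-II forward, zero out-of-band coefficients,
type-III inverse; the DC coefficient falls outside the band so the mean is
removed) regional signals, Fisher z-transformed (arctanh, inputs clipped at
|r| = 0.999999, diagonal set to 0). Model fit between two FCs is the Pearson
correlation of their strict upper triangles.

Every grid point of the 41×10×11×14 = 63,140-point search space (or a reduced
grid) is simulated once; its Fisher-z FC and Kuramoto metrics form the grid
bank, cached on disk keyed by a content hash of grid, connectome, frequencies
and configuration. `n_ensemble > 1` averages several noise realizations per
point, approximating the model's expected FC. Per-point seeds derive from
(master seed, grid index, replicate), so results are identical for any worker
count.

The Monte-Carlo fit draws round(threshold·n) subjects without replacement
(round half-up: 30% of 42 → 13), averages their Fisher-z FCs entrywise, and
records the grid point with the highest upper-triangle correlation — ties
resolve to the lexicographically smallest (A, G, F, M) with a logged warning.
500 iterations at each threshold 30/50/70% are pooled into one distribution of
1500 selected points (50 per threshold in the scaled-down recovery study).

Mode detection scales selected parameter vectors by their axis steps,
partitions the unique points by deterministic 2-means (farthest-pair
initialization, Lloyd updates), and represents each cluster by its most
frequently selected grid point (ties → lowest lexicographic). A single
selected point raises "unimodal solution; no stratification possible".
**Labeling rule:** DEP1 is the representative with the smaller bifurcation
parameter A (ties: larger F, then larger M), matching the published parameter
ordering of the two subtypes (DEP1: smaller A and G, larger F and M). We do
not label by simulated metastability: under the equations above the
smaller-A mode has *lower* Kuramoto metastability and synchrony (see
"Dynamics metrics" below), so a metastability rule would systematically swap
the labels.

Subjects are assigned to the subtype whose model FC their own FC better
matches; exact ties go to DEP1 with a warning.

## Dynamics metrics

R(t) = |mean_j exp(iθ_j(t))| with θ_j = arg(z_j) for simulated trajectories
(Hilbert analytic-signal phases of band-passed series for empirical BOLD-only
input, flagged in provenance). Synchrony is the time mean of R, metastability
its population SD. Both are also z-scored against the metric evaluated at
every Monte-Carlo-selected grid point (one entry per record), the
reconstruction of the resampling reference distribution.

A caveat this package measures and documents rather than hides: simulated at
the two published subtype parameter sets, the supercritical DEP2 point
(A = 0.020, G = 0.035) exhibits consistently *higher* synchrony (~0.14 vs
~0.11) and metastability (~0.068 vs ~0.057) than the subcritical DEP1 point
(A = −0.090, G = 0.010), across noise seeds, phase conventions (arg(z) vs
Hilbert), sampling resolutions and coupling orientations. The corresponding
published direction is the opposite; it was derived from z-scores against an
empirical resampling distribution that cannot be reconstructed from the
printed equations. The acceptance test for that ordering is expected to fail
and is left failing.

## Synthetic cohort

The generator emulates the trial's structure: 42 subjects, 20 DEP1 / 22 DEP2,
allocated 10/10/10/12 over sham/active arms (each subtype's active fraction is
round(n·22/42)), ages ~N(29, 9.4²) clipped to 18–59, balanced sex.

**Subject FCs.** Two modes:

* `resimulate` (default): every subject is simulated at its subtype's
  (optionally jittered) parameters with a unique noise seed.
* `shared`: one model FC realization per subtype — typically the grid bank's
  FC at the truth point — shared by all subjects of that subtype.

Either way each subject's Fisher-z FC receives an independent symmetric
Gaussian perturbation of SD 0.05. The packaged end-to-end recovery study uses
the `shared` mode, for a measured reason: with G ≤ 0.05 on a row-normalized
connectome the oscillators never phase-lock (their frequency dispersion far
exceeds the coupling), so a 7-minute, TR = 2 s simulation yields an FC
dominated by random tone-phase offsets and estimation noise; FCs re-simulated
at the *same* parameters correlate at only ~0.01 across seeds, which is
indistinguishable from between-parameter correlations. Under `resimulate`,
therefore, no method could recover the generating parameters or labels from
single-subject FCs — the data simply carry almost no parameter signal. The
`shared` mode plants a fixed model FC per subtype and tests what the pipeline
is actually responsible for: Monte-Carlo resampling, bimodal mode detection,
representative selection and subject assignment under per-subject FC noise.
Passing the recovery study consequently validates the statistical machinery,
not the physical identifiability of the oscillator parameters from short
scans — and says nothing about real fMRI, where between-subject FC similarity
arises from shared anatomy and physiology outside this model.

**Behavior.** Ordinal items arise from a latent Gaussian severity per item:
score = clip(round(K/2 + latent), 0, K) — rounding is equally-spaced
thresholding. Baseline latents are shift·1[DEP1] + e with e ~ N(0, 1) (the
default shifts mark the items the trial reported as discriminating subtypes at
baseline, |shift| 0.6–0.8); follow-up latents share the baseline noise with
test–retest correlation ρ = 0.7 and subtract an extra improvement
gain·1[active]·1[DEP2] (defaults 0.8–1.0 on the items the trial reported as
treatment-responsive). TMT is continuous on the log₁₀-seconds scale
(~N(1.75/1.85, 0.2²), same ρ). `null_effects()` zeroes every shift for
calibration studies. Item change scores then have SD ≈ 0.9, which puts the
power of a 2-point interaction effect at n = 42 near 0.99.

## Clinical statistics

* Pearson chi-squared on the 2×2 treatment-by-subtype table without
  continuity correction (the worked 10/10/10/12 table gives 0.0868 → 0.09 at
  2 dp, p = 0.768; a continuity correction would not reproduce it).
* Change = follow-up − baseline per item; improvement = −change (all scales
  score severity); improvement-vs-sham subtracts the sham group's median
  improvement per item. Missing cells drop the subject for that item (logged).
* Balanced bootstrap: within each arm the smaller subtype cell is resampled
  with replacement up to the larger cell's size.
* Logistic models (binary subtype on a scale's baseline items) are fitted by
  IRLS (max 100 iterations, tol 10⁻⁸); 1000 case-resampling replicates give
  percentile 95% CIs on the odds-ratio scale. Replicates that fail to
  converge or separate (|coef| > 15 on ordinal predictors) are dropped and
  counted; > 50% dropped raises "unstable model".
* Linear model: change ~ treatment + subtype + treatment:subtype + baseline +
  age + sex by OLS, percentile bootstrap CI for the interaction; bootstrap
  replicates with rank-deficient resampled designs are dropped and counted.
* Nested ANOVA: full model = intercept + treatment + subtype-within-sham +
  subtype-within-active + age + sex; F-test of the two nested columns
  (df1 = 2, df2 = residual df of the data supplied — not forced to any
  published value).

Calibration, measured on null cohorts (no injected effects): the interaction
CI covers 0 in ~94% of 400 repeats for the continuous TMT outcome (discrete
ordinal sums sit nearer 93%, the usual mild undercoverage of the percentile
bootstrap at n = 42), and nested-ANOVA null p-values pass a KS uniformity
check comfortably. The calibration checks use the TMT change score as the
cleanest continuous null outcome.

## Problem sizes and tolerances

The packaged recovery study uses the 108-point reduced grid whose axes contain
both published truth points exactly (A: −0.09…0.075/0.055, G:
0.010…0.035/0.0125, F: 0.4…0.7/0.15, M: 0.43…0.49/0.03), 3 thresholds × 50
Monte-Carlo iterations, and the default 420 s / TR 2 s simulations — a
configuration chosen so the whole study, including the 108 grid simulations,
completes in about a minute on one CPU while keeping every step of the full
procedure. Calibration uses 400 (coverage) and 300 (KS) null cohorts with
1000-replicate bootstraps. Grid values are rounded to 10 decimals so
arithmetic-sequence points compare exactly; Fisher-z clipping at
|r| = 0.999999; 2-means runs at most 100 Lloyd iterations (it converges in a
handful on the small unique-point sets seen in practice).

## Known limitations

* The oscillator parameters are not identifiable from single 7-minute
  simulated scans (see "Synthetic cohort"); the recovery study therefore
  validates the fitting machinery, not short-scan parameter identifiability.
* The published direction of the subtype metastability/synchrony difference is
  not reproduced by the printed equations (see "Dynamics metrics").
* Between-subtype FC similarity in real data (~0.95) reflects shared anatomy
  absent from the model; simulated FCs at the two truth points are nearly
  orthogonal, and the generator does not attempt to mimic that shared
  component.
* Hemodynamic convolution, delay coupling, regional heterogeneity beyond ω°_j,
  and fMRI preprocessing are all out of scope.
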