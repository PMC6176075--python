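# Methods

This note records the models, estimators, numerical conventions and design
choices behind `megconn`, and what its validation experiments do and do not
demonstrate.

## Analysis chain

### Band-pass filtering and epoching

Bands are theta (4–8 Hz), alpha (8–12), beta (12–30) and gamma (30–45).
Filters are order-1500 Hamming-window FIR band-passes (`scipy.signal.firwin`;
even order ⇒ type I, so DC and Nyquist gain are exactly representable as
zero), applied forward and backward (`filtfilt`) for zero net phase shift;
the effective magnitude response is the squared single-pass response. Edges
are mirror-padded by one filter length and trimmed, so the first epoch is
not contaminated by the start-up transient; recordings must exceed three
filter lengths.

Epochs are consecutive, non-overlapping 4-s segments from the start of the
recording (any trailing partial segment is dropped). Artifact rejection is
deliberately simple: a trial is rejected when any per-channel |z| (relative
to whole-recording channel statistics) exceeds 5. Real MEG cleaning (tSSS,
ICA, EOG) is out of scope; what matters downstream is the trial-count
bookkeeping, which is exercised in full. Exactly 20 of the surviving trials
are selected uniformly at random (seeded) to equalize trial counts across
subjects; subjects with fewer than 20 clean trials are excluded and logged.

### LCMV beamformer

The scalar spatial filter for source *s* with leadfield column *l_s* is
`w_s = (l_s' C_r⁻¹ l_s)⁻¹ l_s' C_r⁻¹`, where `C` is the mean of per-trial
sensor covariances and `C_r = C + reg·(tr C / n_sensors)·I` with
`reg = 0.15`. The "15%" convention scales the loading by the mean sensor
variance (the Fieldtrip convention); the regularization baseline is
configurable because other conventions exist. Unit gain `w_s·l_s = 1` holds
to machine precision by construction and is asserted to 1e-6 in the
validation suite. Mixed sensor types are handled by scaling each type's
leadfield row-block to unit Frobenius norm and applying the same factors to
the data; without diagonal loading the beamformer output is algebraically
invariant to such joint rescaling (the loading term is exactly why
unnormalized mixed types would be problematic). A vector (3-orientation)
beamformer is not implemented: synthetic leadfields have one column per
source.

ROI representative series are the first principal component of the member
source series, computed on trial-concatenated, column-centered data; the
component sign is fixed so that its correlation with the mean member series
is non-negative. PLV is invariant to this sign ambiguity (a π phase offset
leaves |mean phasor| unchanged), which the tests assert to 1e-10. In
synthetic mode the source grid coincides with the ROI set (one node per
ROI) unless a multi-node ROI map is supplied.

### Phase-locking value

Instantaneous phase is the argument of the analytic signal
(`scipy.signal.hilbert`) of the band-filtered series, per trial. The PLV of
a pair is `|T⁻¹ Σ exp(iΔφ)|` per trial, averaged over the 20 trials; the
first and last 5% of each trial are excluded to limit Hilbert edge effects
(configurable). Averaging per trial rather than over concatenated trials is
the default because it matches the 20 × 4 s design; both conventions are
implemented. PLV is bounded in [0, 1], symmetric, and invariant to constant
phase offsets — all asserted. For T iid uniform phase differences the
expected resultant is `√π/(2√T)` (≈ 0.0140 at T = 4000), the estimator's
noise floor; the validation suite checks the measured floor against this
closed form to 10%.

No leakage-corrected metric (imaginary PLV, PLI, orthogonalized envelopes)
is provided: the package targets between-group contrasts, where static
linear leakage affects both groups equally.

### Link ANCOVA and network-based statistics

Each ROI pair is tested with the linear model `FC ~ 1 + group + age`; the
group effect is the drop-one F,
`F = (SSE_red − SSE_full) / (SSE_full/(n−3)) ~ F(1, n−3)`, equivalent to
the type II/III ANCOVA F for one binary factor plus one covariate.
Implementation uses Frisch–Waugh residualization against `[1, age]`, which
is algebraically identical to refitting per link and lets a whole
permutation batch be computed with one matrix product per chunk; the tests
verify agreement with an explicit normal-equations oracle to 1e-10 and with
`statsmodels` type-II ANOVA. Constant links yield F = 0, p = 1 (logged);
rank-deficient designs are rejected. The F statistic is invariant to affine
rescaling of age and FC, asserted numerically.

Supra-threshold links (p < 0.005) are assembled into connected components
separately for diminished- and enhanced-direction links (direction = sign
of the age-adjusted group coefficient), guaranteeing sign homogeneity
within a component. Components need at least `round(0.10 · n_rois)` nodes
(7 for the 72-ROI model; rounding, not ceiling, so that 7 of 72 counts as
"at least 10%"). The component statistic is the sum of link F values. The
permutation test shuffles group labels only (ages stay with their
subjects), re-runs the entire link-level analysis, records the maximum
component statistic per permutation (0 when none forms), and reports
`p_fwer = #(null ≥ observed)/n_perm` — ties count against the observed
statistic, no small-sample correction by default (a `(b+1)/(n+1)` toggle
exists). Cross-band multiplicity is deliberately not corrected.

### Downstream biomarkers

Subnetwork strength is the unweighted per-subject mean PLV over the
subnetwork's links. The strength ANCOVA reuses the link contract. Spearman
correlations use mid-ranks with the two-sided t approximation and are
reported uncorrected — they are exploratory descriptives. The LOO logistic
classifier fits an unpenalized single-feature model by Newton–Raphson
(step tolerance 1e-10, max 100 iterations, no random element) on each
n−1 training fold and thresholds the held-out probability at 0.5; the
positive class is the "deleterious" group. Perfectly separated folds fall
back to a midpoint-threshold rule on the feature (logged); constant
features predict the training majority. Confusion-derived metrics follow
the standard definitions (sensitivity = TP/(TP+FN) for the positive class,
specificity = TN/(TN+FP), PPV, NPV); the accuracy interval is
Clopper–Pearson 95% by default, which is the method that reproduces the
published interval (0.705, 0.953) for 31/36 correct — Wilson is offered
and verifiably does not match. `confusion_from_rates` reconstructs integer
confusion counts from printed sensitivity/specificity and group sizes,
which determines every other printed metric; this is how the package's
validation pins the published classification table without raw data.

A note on the published metric prose: the verbal definitions of PPV/NPV in
the source study's text are inconsistent with the standard definitions its
own table satisfies; the standard definitions are implemented.

## Synthetic cohort generator

The generator emulates the study design the analysis targets: 36 older
participants (20 reference "Val/Val", 16 test "Val/Met"), 72 cortical ROIs,
20 × 4 s of band-limited resting activity per subject at 1000 Hz (any rate;
see below), an age covariate uniform on 60–80 years and independent of
group by default, and a planted antero-posterior subnetwork with weaker
phase coupling in the test group.

### Oscillator and coupling model

ROI *r* carries `x_r(t) = cos(2π f_c t + θ_r + δ_r(t))` with *f_c* the band
center and δ_r a stationary Gaussian phase deviation with variance `v_r`
(rad²) and coherence time τ (AR(1) latents). Coupling on a planted link is
linear phase mixing through a shared latent: both ROIs load a common
unit-variance latent with variance fraction κ, so the pair's phase
difference has variance `v_i + v_j − 2κ√(v_i v_j)` and the model PLV is
`exp(−(v_i + v_j − 2κ√(v_i v_j))/2)`. κ = 1 gives identical phases
(PLV = 1 exactly), κ = 0 independent oscillators, and expected PLV is
increasing in κ — limiting behaviours that are all under test. Hub ROIs
with several planted links remain well-defined as long as Σκ ≤ 1 per node
(validated; per-subject draws are renormalized if jitter pushes a node over
budget).

Because the deviation is parametrized by variance plus coherence time, the
PLV operating point depends on trial duration in seconds but not on the
sampling rate; this was verified within ~1.3% between 250 and 1000 Hz and
is what allows the Monte-Carlo experiments to run at reduced rates without
re-calibration.

AR(1) latent realizations, and each ROI's total deviation, are standardized
to their exact target power per recording. Without this, the finite-sample
power wobble of each realization leaks into between-subject connectivity
variance as an uncontrolled shared component; with it, between-subject
structure is exactly the configured jitter structure.

### Calibration and dispersion

Defaults are calibrated by bisection against the measured (trial-averaged)
PLV at the 20 × 4 s design: baseline variance `v0 = 2.2325` gives unplanted
pairs PLV ≈ 0.110, and couplings `κ_A = 0.1416`, `κ_B = 0.0536` give
planted-link PLV ≈ 0.149 and 0.123 — the published group operating point
(strength gap ≈ 0.026). `calibrate_baseline` / `calibrate_coupling` rerun
this for any other trial design.

Between-subject dispersion enters as log-normal jitter of the deviation
variance: a global per-subject factor (sd 0.006; overall synchrony level)
and a per-subject × ROI factor (sd 0.005; regional SNR). Coherence time is
2.5 ms. These three values were chosen, with the planted gap fixed at the
published 0.026, so that (a) the measured between-subject strength SD lands
near the published strength SDs (≈ 0.010), (b) candidate components form
under null permutations at a realistic rate — the global factor makes many
links move together when a permutation aligns with it, which is what gives
the maximal-statistic null a proper tail — and (c) those same shared-
variance clusters remain rare enough not to routinely contaminate a
detected subnetwork. Single-link PLV dispersion in real MEG (published
per-link SDs 0.007–0.041) is larger than the generator's (≈ 0.004–0.006):
the generator omits per-link measurement noise sources (leakage, head
position, sensor noise after beamforming), and its coherence time is
shorter than cortical gamma so that 4-s trials contain enough independent
phase samples for PLV estimates stable at the planted gap. Passing the
power/recovery experiment therefore shows the chain recovers the planted
effect under idealized dispersion, not that a real 36-subject cohort would
yield the same power.

### Planted subnetwork

The default planted subnetwork is the complete bipartite motif between the
two lateral superior occipital hubs and six frontal/prefrontal ROIs
(superior frontal, orbital superior frontal, supplementary motor, gyrus
rectus, anterior cingulate): 8 nodes, 12 links, every link antero-posterior,
hubs not directly connected — the two-hub fan-out topology this analysis is
designed to detect.

### Sensors, metadata, determinism

Sensor data are `leadfield · sources + white Gaussian noise`; the default
synthetic leadfield has unit-norm Gaussian columns, with an optional
two-sensor-type mode (second block scaled ×100) solely to exercise
normalization. Cognitive scores are
`intercept + score_effect · (model subnetwork strength, centered) + noise`,
giving the downstream correlations a known positive sign; because strength
differs by group, the generated scores also separate the groups more than
typical real neuropsychological tables do — a documented side effect of the
single-factor score model. An optional confounded mode
(`age_group_gap`, `age_fc_slope`) makes connectivity decline with age and
the groups differ in age, to verify that the ANCOVA covariate absorbs a
pure age artifact (tested). All randomness flows from one root seed through
a fixed `SeedSequence` spawning order (latents, leadfield, per-subject
signal streams, sensor noise); equal configs give byte-identical cohorts.

### Phase-level fast path vs the full pipeline

The Monte-Carlo experiments compute PLV directly from the generated phases
(`cohort_plv_stack`), skipping filtering, mixing and beamforming: under
label permutation the two routes test the same exchangeability, and the
planted-gap calibration is defined at the phase level. The full
sensor-level chain is exercised separately (pipeline tests and examples).
Note that the two routes sit at different PLV operating points: the gamma
FIR passband (15 Hz) is narrower than the oscillators' phase-noise
bandwidth, so filtered signals show higher background phase locking and a
compressed planted contrast, with larger estimation variance (effective
coherence time after filtering ≈ 1/(π·bandwidth) ≈ 21 ms).

## Validation experiments and their problem sizes

* **FWER calibration**: 200 null cohorts (planted couplings equal), full
  20 × 4 s design at 125 Hz, 500 permutations, α = 0.05. The null must use
  the same trial design as the power experiment because the shared-variance
  fraction — and with it the rate at which candidate components form at
  all — depends on trial length. Expected: rejection fraction within the
  binomial band around the nominal 0.05 (the maximal-statistic test is
  exact under exchangeability, so the rate cannot exceed ≈ 0.05 except by
  sampling noise; the generator's shared variance keeps it from
  undershooting).
* **Power/recovery**: 50 planted cohorts at 250 Hz, 500 permutations;
  detection = some diminished-direction subnetwork with p_fwer < 0.05,
  recovery = additionally link-set Jaccard > 0.7 against the planted 12
  links. Contamination by false supra-threshold links that happen to touch
  the detected component is expected at a low rate (random-graph chaining
  of the ~6 same-direction false positives among 2556 links); measured
  recovery ≈ 0.9.
* **LOO null behaviour**: 1000 label-shuffled simulations. The exact-MLE
  LOO logistic scores *below* the majority-class rate (measured ≈ 0.47 vs
  20/36 ≈ 0.56): in each training fold the slope fitted to pure noise
  anti-correlates with the held-out subject — the standard pessimistic
  leave-one-out bias. Only an intercept-only classifier attains the
  majority rate. This is a property of the procedure, verified
  fold-for-fold against an independent implementation, and is asserted as
  such (below the majority rate, above 0.40).
* **Estimator analytics**: PLV = 1 for locked pairs (exact); Rayleigh floor
  to 10%; LCMV unit gain to 1e-6 and source recovery correlation > 0.9 at
  SNR 10 (20 sensors / 5 sources); ANCOVA F vs normal-equations oracle to
  1e-10 over 100 random datasets; Spearman vs brute-force mid-ranks.

## Known limitations

* No head modelling, MRI anatomy, 1/f background, artifact simulation, or
  vector beamforming; the forward model is an explicit input.
* The generator's per-link dispersion is idealized (see above); its
  oscillators are broader-band than real cortical gamma.
* Which four additional regions the 72-parcel atlas model excludes relative
  to a 76-parcel cortical AAL subset is not fixed by the source material;
  the packaged label list is a default, and every API accepts an explicit
  list.
* Permutation p-values are reported with the plain `b/n` proportion; with
  `n_perm` permutations the smallest reportable value is 0 (< 1/n_perm).
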