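# Methods

This note records the modelling and numerical choices behind the package:
what each stage computes, which knobs matter, what the synthetic data do
and do not emulate, and where the design was genuinely open.

## Timescale estimators

**Autocorrelation.** The sample autocorrelation uses the biased estimator
(the same 1/N factor in the lag-m autocovariance and in the variance).
This guarantees r(0) = 1 exactly and |r(m)| ≤ 1 for all lags, at the price
of shrinking high-lag values toward zero; since the windows of interest
cross their thresholds at small lags relative to N, the shrinkage is
immaterial here.  The default maximum lag is N − 2, i.e. every lag whose
sum still contains at least two products.

**ACW crossing rule.** ACW-0 (ACW-50) is the first lag m ≥ 1 with
r(m) ≤ 0 (≤ 0.5), reported as m·dt.  No sub-lag interpolation is applied:
the window is a discrete, exactly reproducible statistic.  The cost is lag
quantisation — at TR = 2.16 s and 145 volumes the observable windows are a
handful of multiples of 2.16 s.  Two consequences surface in testing: the
correlation between measured log-ACW-0 and a continuously varying latent
timescale saturates around |r| ≈ 0.45, and a first crossing can jump
between distant lags when the autocorrelation merely grazes the threshold.
Both are properties of the chosen statistic, not estimation errors; the
continuous MF does not share them.  When no computed lag crosses the
threshold the functions return NaN ("not reached") and log a warning; the
per-unit sweep (`metric_map`) propagates such sentinels without aborting.

**Median frequency.** A raw periodogram (rectangular window, mean removed,
no segment averaging) is restricted to the analysis band, inclusive of the
edge bins; MF is the smallest bin frequency at which the cumulative
in-band power reaches half the total, ties resolved toward the lower
frequency.  MF is scale-free, so the density normalisation is irrelevant.
For band-limited white noise the estimator converges to the band midpoint
(0.12 Hz for 0.01–0.23 Hz) but carries substantial sampling noise: the
per-realisation standard deviation is ≈40 periodogram bins at N = 2¹⁴,
and the zero-phase Butterworth band edges displace the deterministic
equal-area point by ≈+0.0007 Hz.  Tests of this property therefore use an
absolute tolerance (±0.005 Hz) rather than bin-level agreement.

**Band limiting.** A zero-phase (forward–backward) 4th-order Butterworth
band-pass, 0.01–0.23 Hz at TR = 2.16 s, stands in for the original
preprocessing filter.  The contracts it must satisfy — in-band sinusoid
amplitude within 5%, DC and far out-of-band content attenuated by ≥90% —
are tested rather than any particular filter identity.  The lower edge
keeps ≥3 cycles in a 145-sample series; the upper edge sits just below the
Nyquist frequency (0.2315 Hz).

## Topographic similarity

For a scope (network or whole cortex) the subjects × parcels table of one
metric is correlated parcel-by-parcel across subjects (Pearson), giving an
N×N matrix per state.  Fisher's z = atanh(r) is applied off-diagonal, with
|r| = 1 clipped to 1 − 10⁻¹² (logged) to keep z finite.  The summary is
the median of the strictly-upper triangle; parcels with zero
across-subject variance become NaN rows/columns and drop out of the
median.  States are compared by a paired t test over the aligned
upper-triangle z values.  Treating each parcel pair as an observation
follows the field's convention but ignores the pairs' strong mutual
dependence — with 1000 parcels there are ~500k pairs and the t statistic
becomes enormous; the implementation logs this caveat and the t should be
read descriptively.  Testing on the r scale instead of z is available via
the `scale` argument.

## Statistical conventions

Paired two-sided t tests compare per-subject state means; the Bonferroni
correction multiplies p by the number of planned contrasts per family
(n = 2: awake-rest vs sleep-rest, sleep-rest vs sleep-stimulus) and caps
at 1, preserving the usual 0.05/0.01/0.001 star thresholds.  The sign
convention is t = mean(first − second)/SE, so prolongation in the second
state prints a negative t.  Identical paired samples return (t = 0,
p = 1); constant non-zero differences raise (t is unbounded there).
Normality is screened per state with Shapiro–Wilk and variance homogeneity
across states with the mean-centred Levene test; constant samples are
flagged, not fatal.  The model analysis uses the two-sided Wilcoxon
signed-rank per region, zeros dropped (Pratt handling available), with no
correction across the 29 regions; below 5 non-zero pairs the test is
reported as not available rather than computed.

## Synthetic dataset generator

The generator emulates only what the analysis consumes: per-parcel
band-limited signals whose spectral tilt differs by state and whose
across-subject structure carries a shared subject factor.  Each parcel
signal is white noise shaped by a one-pole low-pass at cutoff c, then
band-passed, with

    log c = log c_state + a_state·u_subject + ε_parcel,
    u_subject ~ N(0,1) shared across parcels,  ε_parcel ~ N(0, 0.15)

Defaults: c_awake = 0.08 Hz, c_sleep_rest = 0.045 Hz, c_sleep_stim =
0.09 Hz; a_awake = 0.15, a_sleep_rest = 0.1, a_sleep_stim = 0.5.  The
cutoff ordering produces longer ACW-0 / lower MF in sleep rest and the
reverse under stimulation; the large stimulated-state subject factor
raises inter-parcel topographic similarity, with the awake factor set
between the two so the three states order as the analysis expects.  These
are calibration choices of the generator (stored in each report's
`run_info`), not empirical claims.  Cutoffs pushed outside the band by the
subject effect are re-jittered (bounded retries) and finally clipped just
inside the band with a warning — relevant only for the large stimulated
subject factor.  Dimensions default to the study layout: 17 subjects,
145 volumes, TR = 2.16 s, 1000 parcels in seven networks (visual 162,
somatomotor 194, dorsal attention 122, ventral attention 121, limbic 60,
frontoparietal 129, default-mode 212).  All randomness flows from one
master seed through a seed tree; regeneration is bit-identical.

Not emulated: hemodynamics, spatial autocorrelation beyond the shared
subject factor, scanner artifacts, motion, physiological noise, EEG-based
sleep staging.  Passing tests on these data therefore demonstrate that the
pipeline recovers the statistical structure it assumes — not that real
sleep fMRI satisfies those assumptions.  A voxel mode (shared parcel
signal + voxel noise) exists solely to exercise the voxel→parcel
aggregation and the NIfTI file path.

## Rate-network model

Each of the 29 regions holds an excitatory and an inhibitory population
with rectified-linear f-I curves; long-range projections are excitatory
only, weighted by the FLN connectivity, and all excitatory drives scale
with the region's hierarchy value through (1 + η·h).  Parameters follow
the published macaque large-scale circuit: τ_E = 20 ms, τ_I = 10 ms,
β_E = 0.066, β_I = 0.351 Hz/pA, w_EE = 24.3, w_EI = 19.7, w_IE = 12.2,
w_II = 12.5, μ_EE = 33.7, μ_IE = 25.3 pA/Hz, η = 0.68.  Background
currents default to zero (configurable); the system then fluctuates around
the rectified origin, driven by the V1 noise.

**Connectivity.**  Reference FLN and hierarchy tables can be read from
delimited files (`io.read_fln`, `io.read_hierarchy`; CLI `--fln
--hierarchy`).  Without them, a synthetic fallback builds
FLN_ij = scale·logistic(slope·(h_i − h_j)) with slope 2 and scale 0.05 on
evenly spaced hierarchy values — feedforward-dominant, zero diagonal.  The
scale was chosen once from the linearised spectrum: 0.05 keeps the
slowest network mode clearly stable in both the awake (max Re λ ≈ −2.2/s)
and the slowed sleep configuration (≈ −0.6/s), while 0.15 is already
unstable.  The resulting timescale hierarchy (V1 fastest, prefrontal
slowest) is qualitative; region-level quantities such as
significant-decrease counts depend on the true anatomy and are not
comparable to results obtained with the reference matrix.

**Integration.**  Euler–Maruyama, dt = 1 ms, 300 s with the first 50 s
discarded.  Noise enters as a current with the stated per-step SD (unit
variance into V1, 10⁻⁵ elsewhere); a √dt scaling is available via
`sqrt_dt_noise` for step-size studies.  Per-step injection means the
continuous-time noise power is tied to the 1 ms step — the convention the
printed protocol implies — so changing dt changes the noise process unless
the √dt flag is used.  Divergence (non-finite or unbounded state) raises
immediately, naming the step; the paired-run driver excludes divergent
runs and aborts above 10% failures.  Under the default parameters no run
diverges.

**States and stimuli.**  Sleep raises τ_E to 60 ms, slowing excitation
relative to the unchanged inhibition.  Stimuli add a deterministic
waveform to V1's excitatory input only, amplitude 1.0 (the scale of the
V1 noise): a 25 Hz sine; 3 sines at 25/50/75 Hz; 5 sines at
5/25/50/75/100 Hz (equal amplitudes, zero phases); or a linear 20→100 Hz
chirp swept across the retained 250 s (start frequency held during the
transient).  Whether inhibitory populations also receive the stimulus is
unknown; the default is no.  Each run index reuses one noise realisation
across all three conditions (common random numbers), making the
30-run per-region Wilcoxon comparisons paired.

**Timescale readout.**  ACW-0 is computed on the excitatory rates with the
same biased-ACF first-crossing estimator as the empirical pipeline, at
1 ms lag resolution over the retained 250 s, reported in milliseconds.

**Step-size robustness.**  Comparing dt = 1 ms against 0.5 ms on coupled
noise paths (the coarse step injecting the average of its two fine-step
currents) leaves the rate trajectories highly correlated (> 0.92 per
region) and moves the median ACW-0 of most regions by well under 10%;
isolated regions whose autocorrelation grazes zero can flip their first
crossing between distant lags, which is the discontinuity of the
statistic, not integrator error.

## Pipeline and reproducibility

The empirical pipeline runs: band-pass → per-parcel ACW-0/ACW-50/MF →
network and cortex means per subject → assumption checks → the two planned
contrasts per family with Bonferroni(2) → similarity matrices and their
rest-vs-stimulus comparison → ACW–MF correlations → the fully-asleep
subject-subset direction check (qualitative, no tests, defaulting to 4 of
17 subjects chosen deterministically from the master seed).  The primary
contrast table always holds (7 networks + cortex) × 2 metrics × 2
contrasts = 32 rows.  Reports carry the package version, the generator
spec, and a configuration hash, but no timestamps; all numbers are written
with a fixed format, so a rerun with the same configuration and seed is
byte-identical.

Problem sizes in the test suite are chosen per test: estimator oracles run
at N ≤ 512; pipeline properties use a 20-parcel, 6-subject fixture, with
the full 17 × 1000 layout exercised in the acceptance tests (5 master
seeds); the null calibration uses 200 replicates of a single 60-parcel
network; the model acceptance tests run the full printed protocol (300 s,
1 ms, 30 paired runs), while model unit tests use shortened simulations
(30–60 s) that preserve every qualitative property.

## Known limitations

- ACW quantisation at TR = 2.16 s with 145 volumes (see above); MF is the
  sharper instrument at this series length.
- The similarity t test inherits the field's non-independence of parcel
  pairs; its p values are nominal.
- The synthetic generator's single spectral mechanism cannot distinguish
  alternative physiological causes of timescale change; it is a test
  harness, not a forward model.
- Without the reference macaque FLN/hierarchy tables the model's
  region-resolved counts are specific to the synthetic connectivity;
  direction-level conclusions (sleep slows all regions, a V1 stimulus
  shortens most) are robust to that choice.
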