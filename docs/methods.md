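# Methods

`gcfmri` implements Granger-causality (GC) analysis of ROI-averaged fMRI
time series, together with a synthetic visuomotor-network BOLD generator
so that every stage of the pipeline can be exercised end to end without
scanner data. This note records the models, the conventions behind the
numerics, and the limits of what the synthetic experiments demonstrate.

## Autoregressive modelling

All series are treated as zero-mean: the preparation step removes the DC
value and the linear drift per run by OLS (`timeseries.detrend`), and
the fitting routines re-centre each run defensively. A d-variate VAR(p)

    x(t) = Σ_{k=1..p} A_k x(t−k) + ε(t)

is fitted by ordinary least squares over rows p+1..n with no intercept.
Multiple runs contribute their own rows; lagged predictors never cross a
run boundary. Residual covariance is the residual cross-product divided
by the number of regressed rows. Collinear designs resolve by the
minimum-norm least-squares solution and are flagged.

Model order is selected by BIC,

    BIC(p) = n_eff · ln det Σ̂(p) + (d²p) · ln n_eff ,

searched over 1..20 or the largest order the sample permits (every run
must retain at least one regressed row and the least squares must remain
determined). All candidate orders are scored on the common sample (rows
p_max+1..n of each run) so the criteria are comparable; this also makes
the selection invariant to rescaling the data. Ties break toward the
smaller order. For a pair analysis, orders are selected per series
univariately and combined with the minimum rule; the same order is used
for the restricted and full models of a nested comparison (required for
validity) and for the conditional variant (an override is exposed).

## Granger causality and inference

For source x and target y at order p,

    G_{x→y} = ln( var ε_y / var ε_{y,x} ),

the log-ratio of the univariate-restricted to bivariate-full residual
variance of y. Because the models are nested, the ratio is ≥ 1 and G ≥ 0;
numerically negative values within 1e-10 are floored at zero, and larger
negatives are possible only for rank-truncated collinear designs (where
"no additional predictive information", i.e. G = 0, is the meaningful
reading — e.g. a source that is an exact copy of the target). The
conditional variant adds the remaining ROI series z to both models,
removing influence that is mediated through, or shared with, z. The
influence difference ΔG = G_{x→y} − G_{y→x} summarises the dominant
direction of a pair and is antisymmetric by construction.

Parametric inference refers ((n−p)/p)(exp(G) − (n−2p)/(n−p)) to an
F(p, n−2p) distribution (at G = 0 the statistic is identically 1). It
assumes independent samples, which BOLD series violate, so the primary
inference is non-parametric.

## AAFT surrogates and permutation inference

Surrogates follow Theiler's amplitude-adjusted Fourier transform: the
input is rank-remapped onto a sorted Gaussian reference, the Gaussian
copy's Fourier phases are randomised under conjugate symmetry (DC and
Nyquist untouched), and the original amplitudes are restored in the new
rank order. The surrogate's marginal distribution is therefore exactly
that of the input (a permutation) and its autocorrelation approximately
so, while any phase relationship with other series is destroyed.
Surrogates are generated per run.

The p-value of a statistic is the fraction of surrogates in which the
statistic recomputed with an AAFT copy of the *source* series strictly
exceeds the observed value; ties do not count, p = 0 is formatted as
"< 1/N". For the influence difference, the putative source is replaced
in both directed terms; target and conditioning series are always left
intact (replacing conditioning series as well would test a different,
broader null). Defaults are 1000 permutations for bivariate GC
and 100 for conditional GC. Group inference pools exceedance counts over
subjects and divides by the total permutation count — a fixed-effect
analysis; no random-effects variant is provided.

Ensemble statistics are assembled from Gram blocks accumulated run by
run and solved batched over surrogates (the target-side lagged design is
fixed across the ensemble), with a pseudo-inverse fallback for singular
Gram matrices. Equivalence with the plain per-model path is enforced by
tests to machine precision. One master seed drives everything;
per-subject/per-pair sub-seeds are derived by CRC-hashing the labels, so
results are reproducible regardless of execution order.

## Hemodynamics

The hemodynamic response is estimated by a FIR-basis GLM: one regressor
per peristimulus lag spanning a 6-s pre-stimulus baseline and a 24-s
post-stimulus window, plus DC and linear-drift columns. Baseline noise
is the SD of the raw series over the pre-stimulus intervals; the
dSPM-style statistic divides the estimate by it. ROI selection keeps
locations whose mean statistic over 4–7 s post-stimulus exceeds 4.0.

Timing indices of a response: time-to-peak (TTP) is the lag of the
maximum; time-to-half (TTH) the rising half-peak crossing (linear
interpolation between grid points); FWHM the width between the two
half-peak crossings around the peak (absence of the falling crossing is
an error, not an extrapolation); onset is the first time the response
exceeds 10% of peak and stays above it until the peak — a convention,
since onset has no universal definition, so only qualitative agreement
with published onsets is claimed.

## Synthetic cohort

The generator emulates a rapid event-related visuomotor experiment:
23 subjects × 4 runs × 240 s at dt = 0.1 s, 24 stimuli of 500 ms per run
with ISIs uniform on 3–16 s (the whole ISI vector is redrawn until the
run accommodates all events). Five ROIs form a feedforward network:
V→PPC→PreM→M chain (lags 0.1/0.1/0.2 s, gains 0.9) with direct V→S
(0.3 s) and V→M (0.4 s) shortcuts — cumulative lag under 0.4 s,
consistent with sub-400-ms reaction times. V's neuronal activity is the
stimulus boxcar; downstream ROIs receive gain-scaled lag-shifted input
plus a small local innovation (SD 0.05 of the stimulus amplitude) so
directed influence has a genuinely stochastic component.

Each ROI's BOLD is its neuronal series convolved with a region-specific
kernel plus AR(1) noise (φ = 0.3). The kernel family is a double-gamma
difference (main lobe minus a 0.15-weighted undershoot delayed ~5 s);
its two gamma parameters are calibrated by nested Brent root-finding so
the *measured* TTP and FWHM hit the requested values (published
group-average timing per ROI and hemisphere, TTP 3.6–4.5 s, FWHM
4.3–5.1 s) within 0.1 s and 0.3 s; calibration failure raises rather
than approximating. Noise SD defaults to 0.08, placing the evoked peak
(≈ 0.40–0.63) at 5–8 × the instrumental noise SD. Note that the dSPM
statistic measured against the raw pre-stimulus baseline saturates near
3 in this design regardless of noise level, because overlapping response
tails from preceding stimuli (mean ISI 9.5 s, response width ≈ 15 s)
dominate the baseline variance; the 5–8 regime therefore refers to the
instrumental-noise ratio.

What the generator does *not* emulate: physiological (cardiac or
respiratory) noise, inter-subject or inter-trial variability of
hemodynamic timing and coupling strength, nonlinearities of the
BOLD response, or image-space reconstruction effects. Consequences for
interpretation are discussed below.

## The sampling-rate experiment

For each target TR (an integer multiple of 0.1 s) the cohort is either
decimated (pure sample discarding) or decimated and SINC-reinterpolated
back to the original length (frequency-domain zero-padding with an even
Nyquist split; exactly grid-preserving; periodic-boundary ringing is
accepted), the latter controlling for the number of observations. Per
subject: detrend per run, re-select orders per ROI (orders shrink with
TR, so re-selection rather than reuse is required), compute pairwise
influence differences with AAFT surrogate nulls, then pool across
subjects. Edges with group p ≤ 0.05 are "strong", 0.05 < p ≤ 0.1
"trend"; a pair analysed as (x, y) with p near 1 is evidence for y→x
(the reverse-direction p is 1 − p). Directed-pair GC surrogate p-values
are optional in the sweep (`directed_surrogates=True`) since they double
its cost and the influence difference is the primary inference; directed
entries always carry g values.

The scaled cohort used by the test suite and the acceptance script is
8 subjects × 2 runs with 200 surrogates, completing the full sweep in
minutes; paper-scale settings (23 × 4, 1000 surrogates) are plain
parameter choices away.

## What the in-silico experiments do and do not show

At the native 0.1-s sampling the pipeline recovers every true
feedforward edge at group p ≤ 0.05 and flags no reversed edge, and the
SINC-interpolated 2-s control collapses to no significant edges —
artificially restoring series length does not restore the information
lost to coarse sampling. Plain decimation to 2 s reduces, but does not
always reduce *strictly*, the number of significant edges: the
region-specific kernel timing (inter-regional TTP gaps up to ~0.9 s)
plus the neuronal lags give stimulus-response latency asymmetries of
0.5–1.3 s that remain genuinely detectable at TR = 2 s in a cohort with
no inter-subject variability and no physiological noise. Real data are
far less favourable at TR = 2 s; this gap between the clean simulation
and empirical practice is expected and documented rather than hidden by
re-tuning the generator.

Similarly, the conditional pass conditions on the mediator's *BOLD* — a
noisy, hemodynamically convolved proxy of the mediating neuronal
signal — so conditioning suppresses the indirect edge of a chain
strongly in magnitude (conditional g typically ~4× below bivariate g)
but not always below the significance threshold. On neuronal-level VAR
chains, where the mediator is observed directly, suppression is
essentially complete (covered by oracle tests).

## Numerical conventions and degenerate inputs

- Residual "power"/"variance": sum of squared residuals over regressed
  rows divided by their count; GC is invariant to the shared normaliser.
- Decimation keeps the first sample by default (offset 0); the offset is
  exposed to probe sampling-phase sensitivity.
- Sample k of a run is at time k·dt from run start (0-based).
- Zero-variance series, length/dt mismatches, infeasible orders and
  empty windows raise `InvalidInputError`; an impossible negative GC on
  a well-conditioned fit raises `InternalConsistencyError`.
- Surrogate p-values live on the grid {0, 1/N, ..., 1}; no +1
  continuity correction is applied (the count/N definition is used
  literally).
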