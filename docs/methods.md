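# Methods

`affectfuse` implements a joint EEG–fMRI analysis of music-induced affect
and a synthetic-data generator that reproduces the statistical structure
that analysis assumes. This note documents the models, the parameters
that matter, the numerical choices, and what the synthetic validation
does and does not show.

## The paradigm being emulated

A session consists of 40 s trials of three types. In *music only* trials
the participant listens without moving; in *music + reporting* trials they
listen while continuously reporting their felt valence and arousal with a
joystick in the two-dimensional circumplex space; in *reporting only*
trials no music plays and they re-track the joystick trace recorded in an
earlier music + reporting trial of the same piece (a movement and visual
control). Every excerpt targets one of 9 circumplex regions
({low, neutral, high} valence × arousal) for its first 20 s half and a
different region for the second half. The trial order is pseudo-random
under the constraint that a reporting-only trial always follows the
music + reporting trial whose trace it replays.

## Synthetic-data generator

All randomness flows from one top-level seed; per-stage generators are
derived deterministically from it, so identical (seed, config) gives
bit-identical data.

**Latent affect.** The latent valence/arousal trajectory is the per-half
circumplex target (amplitude 0.35 by default) plus stationary order-1
autoregressive noise (time constant 8 s, SD 0.45 by default), clipped to
[−1, 1]. The AR(1) choice is the simplest coloured-noise model that
reproduces the slowly drifting traces real continuous reports show. No
targets apply during reporting-only trials — no music, no induced affect.

**Reports.** The reported trace is the latent state passed through a
causal first-order low-pass follower (time constant `report_lag`, default
1.5 s — a joystick behaves as a lagged tracker), plus Gaussian report
noise (SD 0.08), clipped. During reporting-only trials the reported trace
is the *replayed* record of the source trial, not the current latent
state — exactly the property the exclusion contrast exploits.

The latent-noise SD is the knob that sets the target→report correlation.
Because clipping and the lag make the mapping analytically awkward, the
package calibrates it by Monte-Carlo bisection
(`calibrate_latent_noise`): the observed sub-trial correlation is driven
to the requested value (0.30 for the headline studies, the magnitude of
the behavioural coupling this design produces). Reaching r ≈ 0.3
requires latent noise several times the target amplitude — affect is
mostly *not* stimulus-driven, which is what makes the downstream
label-based analyses non-trivial.

**EEG.** Each of the nine 10/20 channels (F3, F4, FP1, FP2, F7, F8, Fz,
C3, C4) is a sum of four band-limited rhythms (delta 1–4 Hz, theta
4–8 Hz, alpha 8–12 Hz, beta 13–20 Hz; amplitudes 6/5/10/6 µV) plus white
noise (3 µV). Band sources are *constant-envelope* oscillations:
band-passed noise divided by its Hilbert envelope. This models cortical
rhythms as coherent oscillators whose phase and instantaneous frequency
wander over the band, and — crucially for the feature model — makes the
windowed band power respond to the imposed amplitude modulation rather
than to the sampling noise of a stochastic source (raw filtered noise has
only ≈ 2·bandwidth·window degrees of freedom per window, which at 2 s
windows would drown the couplings in estimation noise).

Valence coupling: the alpha and beta amplitudes at F3 (left) are scaled by
√(1 + d) and at F4 (right) by √(1 − d), with drive

    d = 0.95 · tanh(g₀ · (v + σ(v) · η(t))),   σ(v) = g_H · ((1 − v)/2)²

where v is latent valence, g₀ = 0.4 is the valence gain and
g_H = 4 the disorder gain. Band *power* therefore scales as (1 ± d), so
the left-minus-right Laplacian band power is positively and monotonically
coupled to valence (tanh keeps the modulation bounded without hard
clipping). η(t) is a slow constant-envelope oscillation (frequency
drifting over 0.08–0.2 Hz): at low valence σ(v) is large and the
asymmetry wanders over its range within a trial; a constant-envelope
wander pushes the within-trial marginal towards its range edges, which
raises its histogram entropy, whereas Gaussian wander would leave the
marginal Gaussian and the entropy unchanged. Complementarily, high
valence adds sparse exponential-amplitude power bursts (rate 0.1 Hz,
gain scaled by ((1 + v)/2)², independently per hemisphere): heavy-tailed
excursions stretch the trial's range while the bulk stays tight, lowering
the histogram entropy. Together these give the two directional effects
the analyses look for — greater alpha/beta asymmetry and lower asymmetry
entropy for high-valence trials — through mechanisms acting on the shape
of the asymmetry distribution, the only thing a histogram entropy with
per-trial auto-ranged bins can see.

**BOLD.** The volume is an abstract grid (12³ in the recovery studies)
with a 3 mm isotropic diagonal affine; anatomy is out of scope. Cubic
regions of interest are driven by one of five drivers: latent valence,
latent arousal, the *measured* asymmetry regressor, the *measured*
per-trial entropy regressor, or a movement boxcar that is ON during both
reporting trial types. Driver series on the TR grid are convolved with
the canonical HRF, standardised, scaled by the ROI amplitude (BOLD units
per SD), and added to per-voxel Legendre drift (default order 2,
coefficient SD 0.5) plus white Gaussian noise (SD 1). EEG-coupled ROIs
follow features extracted from the generated EEG itself — the generative
analogue of the EEG-informed-fMRI assumption that the measured feature,
not an unobservable ideal, drives the haemodynamics. A zero-amplitude
null ROI is always retained for type-I-error checks.

## Feature extraction

The chain is: common average reference → zero-phase 3rd-order Butterworth
band-pass 1–45 Hz → surface Laplacians centred on F3 and F4 (references
FP1/2, F7/8, Fz, C3/4) → per-band zero-phase 3rd-order Butterworth →
mean-squared amplitude in 2 s windows (step 2 s for band statistics,
0.25 s when the series feeds entropy estimation, so a 20 s window holds
≥ 80 power samples) → left-minus-right difference. All filtering is
forward–backward (effective order 6, zero phase) so no group delay
misaligns EEG-derived regressors against the fMRI clock. The asymmetry is
a difference of band *powers* (µV²); an amplitude variant is a
config-level choice away but power is the default. The delta band is
nominally 0–4 Hz; with the 1 Hz broadband high-pass its effective band is
1–4 Hz.

## Entropy

Shannon entropy H = −Σ P log₂ P in bits, with P estimated by an
equal-width histogram (default 16 bins) spanning the min–max of the
estimation window and 0·log 0 := 0. A constant window is a single
degenerate occupied bin, 0 bits. Per-trial estimates use per-trial
auto-ranged bins, so they measure distributional *shape*, not scale.
The regressor embedding is a per-trial boxcar carrying each music trial's
entropy; for the GLM the boxcar values are centred across trials
(standard parametric-modulation practice) so the regressor encodes
entropy *differences* between trials and is not collinear with the
task-on indicator. A trailing sliding-window mode exists as well. Bin
count and window are declared defaults, not inferred quantities.

## Statistics

Sub-trials are the two 20 s halves of each music trial; the behavioural
coupling is the Pearson correlation between mean reported and targeted
affect per sub-trial (the circumplex axes are treated as approximately
linear scales). Trials are labelled high/low valence by the sign of mean
reported valence (> 0 is high; exactly 0 is low), or by a median split
where balanced groups are needed. Band-wise high-vs-low comparisons use
the two-sample Kolmogorov–Smirnov test on per-trial mean asymmetry,
corrected across bands by step-down Holm–Bonferroni (adjusted
p₍ᵢ₎ = maxⱼ≤ᵢ min(1, (m−j+1)·p₍ⱼ₎)). A "paired" KS variant is not a
standard procedure; the two-sample test on pooled per-trial values is the
reading implemented.

## GLM mapping

The canonical HRF is the double-gamma
Γ(t; 6, 1) − Γ(t; 16, 1)/6 over 32 s, peak-normalised. Effects of
interest are HRF-convolved and standardised; confounds enter as passed
(the movement confound is supplied HRF-convolved, because the generative
movement signal lives in haemodynamic space and an unconvolved boxcar
could not absorb it); Legendre polynomials up to order 3 model drift,
with the constant absorbed by an explicit intercept. Voxelwise ordinary
least squares with dof = n − rank(X); F-contrasts by the
extra-sum-of-squares form with p from the F distribution; exactly-fitted
voxels are treated as noiseless (F = 0 for a zero effect rather than a
0/0). Family-wise error control is Bonferroni by default, with a
Freedman–Lane max-statistic permutation alternative (residuals of the
reduced model are permuted and the max F over voxels re-computed);
random-field theory is deliberately not used — it needs smoothness
estimation that is meaningless on a desk-scale abstract grid, and both
methods control the same error rate. Clusters are 26-connected components
(6-connectivity available) reported with voxel count, peak coordinate in
mm through the affine, peak F and Bonferroni-corrected peak p.

## Fusion analyses and the exclusion contrast

Asymmetry series are co-registered to the first volume, low-pass filtered
below the volume-rate Nyquist (0.25 Hz at TR 2 s, zero-phase 3rd-order
Butterworth), linearly resampled at volume times, then HRF-convolved
inside the design (convolution and resampling commute within the
anti-alias tolerance; windowed envelopes start half a window late, so up
to one window of edge tolerance is allowed before a span error).

Set A holds voxels co-varying with the masked affect reports during music
trials (the generator's continuous trace plays the role of the reports
copied from music+reporting to music-only trials); set B holds voxels
co-varying with the reporting task alone — its effects are the reports
masked to reporting-only trials plus the joystick-use boxcar over all
reporting trials, with no movement confound since movement is what B must
capture; C = A \ B exactly. The fusion analyses substitute the asymmetry
or entropy regressor for the affect regressor in A and exclude the same
B. The affect maps use FWE α = 0.05 and the EEG-informed maps α = 0.01,
matching the two significance regimes of the analyses they implement; α
is always an explicit argument, never silently defaulted. Band choice
for fusion is data-driven (bands whose KS+Holm test rejects), with an
override.

For specificity questions (does each measure map to its own region?) the
fusion design can include the companion EEG regressor as a confound
(`FusionConfig.partial_companion`). The asymmetry and entropy regressors
share variance through their common dependence on valence, so the
marginal maps legitimately overlap; the partial design attributes to each
measure only its unique variance, which is the estimand of a double
dissociation. The default (marginal) design leaves the companion out.

## Validation studies and their problem sizes

The studies in `affectfuse.experiments` run at deliberate desk scale:
128 Hz EEG (any rate above the beta Nyquist behaves identically up to
filter discretisation), 6³ volumes with 15 trials for the 500-replicate
null calibration, 10³ volumes with 12 trials for the 20-replicate
dissociation, and 12³ volumes with 12 trials for the 20-replicate
recovery study. Recovery amplitudes are calibrated per replicate from
the *analysis* design and the *generative* signal through the noncentral
F distribution, with the part of the signal outside the design span
priced into the residual variance (a mean-matched approximation to the
doubly noncentral F); the movement ROI uses the achievable-power cap of
its design, since what matters there is detection, not near-certain
per-voxel power.

What passing these studies shows: the estimators are numerically correct
against independent oracles; the full chain's false-positive behaviour is
nominal under the null; couplings of the kind the generator injects are
recovered with the claimed sensitivity and specificity. What it does not
show: robustness to real-data pathologies the generator deliberately
omits — scanner and ballistocardiogram artifacts, head motion, volume
conduction and reference effects beyond the nine modelled channels,
anatomical variability, or between-participant heterogeneity (runs are
pooled; no random-effects level). Conclusions about real recordings
require the upstream cleaning this package scopes out.

## Known limitations

- The entropy–valence mechanism is one concrete hypothesis (oscillatory
  gain wander plus valence-scaled bursts) chosen to realise the observed
  direction of the effect; other mechanisms could produce the same
  phenomenology.
- Histogram entropy with auto-ranged bins is scale-free by construction;
  analyses that want scale sensitivity should pass fixed bin edges.
- Bonferroni is conservative under spatial correlation; the permutation
  alternative is exact but costs n_permutations GLM refits.
- The exclusion contrast is a hard set difference: a voxel genuinely
  involved in both affect and reporting is removed from C (each piece
  being heard twice mitigates, but does not eliminate, this in the
  emulated design).
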