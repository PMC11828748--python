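# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `gaitrhythm`, in the
spirit of a model-documentation page: what is computed, under which
assumptions, and what the defaults mean.

## Event model

A hoof impact is defined as a positive peak of the hoof's sagittal (x)
displacement *relative to the withers*. The rationale: at touch-down
the hoof is maximally protracted with respect to the trunk, after which
stance carries it backward in the horse frame. Subtracting the withers
removes the animal's travel through the capture volume, so the
normalized signal is periodic with the limb's motion cycle and
translation-invariant.

Peak detection (`events.detect_impacts`) requires a prominence of 0.3 ×
the signal's peak-to-peak range, a half-prominence width of ≥ 2 samples
(rejecting one-sample noise spikes), and a separation of at least a
quarter of the typical inter-peak spacing estimated in a first pass.
Peak times are refined by the vertex of the parabola through the three
samples around the discrete maximum; at 120 Hz the frame period
(8.3 ms) is coarse relative to the ratio category windows, and the
refinement reduces timing error to well under a millisecond on smooth
signals.

### Interval definitions and the HFI direction

FHI/HHI are successive same-limb impact intervals; IHI are successive
intervals of the time-sorted merged fore+hind train. HFI is implemented
as the **lag from a fore impact to the first hind impact inside that
fore cycle**, paired with that cycle's FHI so the relative phase
HFI/FHI is a per-cycle quantity in (0, 1). This direction is the only
one consistent with the expected phase structure of the three gaits —
relative phase ≈ ¾ for walk and canter and ≈ ½ for trot, and similar
fore→hind lags for trot and canter at their respective tempos. The
opposite (hind→following-fore) lag would put walk and canter near ¼ and
make trot's lag far exceed canter's, contradicting both the gait
diagrams and the coordination literature.

Near-simultaneous fore/hind impacts (closer than one sample) are
excluded as ties rather than ordered arbitrarily — ordering them would
fabricate near-zero IHI entries. Fore cycles without an interior hind
impact are dropped from the HFI sequence; both exclusions are counted
per trial and surfaced in the `trial_counters` table.

## Filtering

Butterworth low-pass, order 4, applied forward–backward (zero phase,
effective order 8), cutoff 15 Hz for hoof markers and 5 Hz for the
withers. Zero-phase application is mandatory because the measurand is
event *timing*; a causal filter would lag every impact by a
cutoff-dependent amount. The filter order and the odd-reflection edge
padding (one settling length, the `sosfiltfilt` default) are package
choices, exposed via `FilterSpec`; short straight-track passes make
edge handling material, hence the hard error when a trial is shorter
than three settling lengths. Normalization subtracts the 5 Hz-filtered
withers from the 15 Hz-filtered hooves, in that order (filter, then
normalize); both operations are linear, so the order is immaterial up
to numerical tolerance, which the test suite verifies.

## Ratio categories

r_k = t_k/(t_k + t_{k+1}). The on-integer band around a category center
c is |r − c| ≤ 0.056 (0.444–0.556 around 1:1) and the off-integer
flanks extend a further 0.044 (0.400–0.444 and 0.556–0.600), the
conventional cutoffs of the bioacoustics literature from which the
method is borrowed. Only the 1:1 band is defined by that convention;
this package translates the same absolute widths to the 0.25 and 0.75
centers for IHI analysis — the minimal assumption, configurable via
`CategoryWindows`. Band boundaries are closed on the on-integer edges
and open on the outer off-integer edge, so a ratio at exactly
c ± 0.100 is unclassified. Ratios are never formed across trial
boundaries: the (t_k, t_{k+1}) pair must come from the same pass.

Deviance |r_k − 0.5| (accuracy) is summarized by the location of the
maximum of its Gaussian kernel density (fixed bandwidth 0.00194663,
4096-point grid spanning the data range ± 3 bandwidths, ties broken
toward the smallest abscissa for reproducibility); the peak height is
reported alongside. Deviance and spread are computed on FHI- and
HHI-derived ratios only; IHI ratios feed the density visualization and
category counts. Spread is the interquartile range under the
linear-interpolation (type-7) quantile convention; the convention is
pinned because IQR values differ across conventions. Relative-phase
density modes use a fixed bandwidth of 0.01, roughly half the smallest
between-gait phase separation of interest.

## Statistical protocol

**Wilcoxon stage.** Per hoof × saddle × gait cell, a paired two-sided
signed-rank test of on- vs off-integer counts across horses: exact null
distribution for ≤ 25 non-zero differences (the permutation
distribution handles tied ranks), tie-corrected normal approximation
otherwise. Cells where every difference is zero return an undefined,
flagged result — no p-value is fabricated.

**Beta mixed models.** Responses in (0, 1) (deviance mode, spread,
relative phase, rescaled durations) are modelled as Beta(μφ, (1−μ)φ)
with logit(μ) = x'β + u_horse, u ~ N(0, σ²). The marginal likelihood
integrates u by adaptive Gauss–Hermite quadrature (default 11 nodes):
per horse, the integrand's mode is found by damped Newton iterations
with analytic first and second derivatives, and the nodes are centered
and scaled there. (β, log φ, log σ) are estimated by BFGS with a
Nelder–Mead polish on non-convergence; standard errors come from the
numerical observed information. The implementation reproduces an
independent beta-GLMM implementation (R glmmTMB) to ~3 decimal places
on a reference dataset, which the test suite checks, and collapses
analytically to the fixed-effects beta regression as σ → 0.

Boundary responses are shrunk into the open interval by
(y(n−1)+0.5)/n. Duration responses (the FHI~HFI model) are mapped into
(0, 1) by dividing by 1.05 × the observed maximum; the scale factor is
recorded in the run manifest so coefficients remain interpretable. The
1.05 headroom keeps the largest observation away from the upper
boundary, where the beta log-likelihood degenerates.

Model selection minimizes AIC among converged candidates, breaking ties
toward fewer parameters; each chosen model is tested against the
random-intercept-only null by likelihood ratio (χ² = 2Δℓ, df = Δk).
Pairwise comparisons are Wald z tests of estimated-marginal-mean
differences on the logit scale (balanced reference grid over the other
categorical factors, numeric covariates at their mean), adjusted by
Holm's method. Holm is used instead of the Tukey single-step adjustment
deliberately: it is distribution-free, exact to implement, and
conservative; the choice is recorded in output metadata.

## Synthetic cohort

The generator emulates the study design the method targets: 13 ridden
horses × 3 gaits × 2 saddle conditions, 4 short passes of 5 motion
cycles per cell (a ~12 m track does not yield long recordings), 120 Hz.

* **Footfall templates.** Per unit fore-cycle with the fore impact at
  phase 0: walk and canter place the ipsilateral hind impact at phase
  0.75 (fore→hind lag ¾ cycle, hind→next-fore ¼ — the 3:1/1:3 IHI
  structure), trot at 0.5 (antiphase). Canter's suspension is
  represented only through this timing; trunk flight dynamics do not
  feed the analysis.
* **Tempo.** Mean cycle durations 1.10 s (walk), 0.70 s (trot), 0.60 s
  (canter) — typical preferred-speed values for ridden horses — with
  stride lengths 1.8/2.5/3.5 m setting waveform amplitudes only.
* **Jitter.** Cycle durations are i.i.d. log-normal with CV
  `jitter_cv` (default 0.02): multiplicative jitter keeps durations
  positive and the CV interpretable as interstride variability.
* **Horse effects.** Per-horse log-normal tempo multiplier (SD 0.05)
  and Gaussian ipsilateral phase perturbation (SD 0.005), drawn once
  per horse; ipsilateral footfall timing is highly consistent across
  sound horses, hence the small phase SD.
* **Noise.** Additive white Gaussian noise, SD 5 mm, on every marker
  coordinate.
* **Saddle.** A pure metadata label with zero simulated effect, so the
  saddle factor is null by construction and type-I-error behaviour can
  be checked.
* **Waveform.** Each hoof's withers-relative sagittal position is
  A·cos(2π·g(p)) with p the cycle phase and g a monotone time-warp,
  g(p) = p + α sin(2πp), α set from the duty factor. The warp carries
  the stance/swing asymmetry mid-cycle while keeping g′ continuous
  across the impact, so the waveform's unique per-cycle maximum falls
  *exactly* at the scheduled impact and parabolic peak refinement is
  unbiased — the property the event definition requires. A spline
  through stance/swing key points was rejected because periodic splines
  can overshoot and displace the maximum off the scheduled impact. No
  claim of biomechanical fidelity is made beyond impact timing.
* **Measured-phase presets.** `phase_overrides` lets a cohort use
  empirical rather than idealized phases (e.g. walk 0.76, canter 0.744,
  trot 0.515) — by default the idealized template phases are used.

What the generator does **not** emulate: four-limb footfall sequences
(only the right ipsilateral pair is simulated, as analyzed), ground
reaction forces, rider and saddle mechanics, marker occlusion patterns,
soft-tissue artifact, speed drift within a pass, and any correlation
structure between successive cycle durations (jitter is i.i.d.).
Passing tests therefore demonstrate that the *pipeline* recovers known
timing structure under realistic noise — not that real horses behave
like the generator.

## Problem sizes and determinism

Simulation-backed checks run at desk scale, chosen to keep the full
suite comfortably re-runnable on one CPU: the cohort analyses use the
full 13 × 3 × 2 × 4-trial design (~300 trials); estimator-calibration
checks use 100 parameter-recovery replicates (13 groups × 30
observations) and 200 null replicates for the likelihood-ratio test's
type-I error; monotonicity and phase-recovery checks use 10 seeded
replicates per condition. Every stochastic component consumes an
explicit seed; a fixed seed yields bit-identical trajectories, tables
and manifests, which the tests assert.

## Known limitations

* Only two limbs: interlimb results characterize the ipsilateral pair,
  not the full footfall pattern (no diagonal-advanced-placement
  analysis).
* The beta mixed model supports a single random intercept; random
  slopes or crossed effects are out of scope.
* The C3D reader depends on the optional `ezc3d` library and a
  user-supplied label alias table; only point data and residual-based
  occlusion flags are consumed.
* Gap handling is linear interpolation up to 5 consecutive frames;
  longer occlusions reject the trial rather than risk inventing a peak.
* Category windows beyond {1:3, 1:1, 3:1} are configurable but not
  exercised by the test suite.
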