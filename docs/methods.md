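# Methods

`frontostriatal` re-implements, as a tested pipeline on synthetic data, the
analysis chain of a combined task-fMRI + DTI study of the human
fronto-basal volitional saccade network: three behavioral task designs, a
physiological-noise-corrected pre-whitened GLM with Monte-Carlo
cluster-extent inference, FIR peri-stimulus time-course estimation with
ROI statistics, deterministic FACT tractography, and a bespoke
fiber-selection procedure producing cortico-striatal probability maps and
connectograms. Because the original human data are not available, every
stage is exercised on phantoms with planted ground truth; what the tests
establish is that the *procedures* are implemented correctly and recover
known structure, not any empirical claim about brains.

## Task designs

* **Task 1** (event-related pro/antisaccades): trials of 12 s — fixation,
  colored cue at +3 s, peripheral target at +6 s (3.8° or 14.8°, left or
  right), return step at +12 s. Every nominal event time receives an
  independent uniform jitter on [−0.5, +0.5] s. The jitter distribution
  (uniform) and its per-event independence are our choices; only the
  ±500 ms range is prescribed. The side letter in event labels encodes
  the *saccade direction* (for antisaccades the stimulus is mirrored).
  Trial factors (task × side × amplitude) are balanced so that each
  factor's level counts differ by at most 1 for any trial count, then
  shuffled by the run seed.
* **Task 2**: 12 cycles of 20 s visual stimulation + 20 s rest = 480 s.
* **Task 3**: repeating 20 s blocks of horizontal saccades, vertical
  saccades, and fixation.

## Physiological nuisance regression (RETROICOR)

Cardiac phase is linear between R peaks,
φ_c(t) = 2π (t − t_k)/(t_{k+1} − t_k). R peaks are detected with an
amplitude threshold at 50 % of the maximum excursion above the median and
a 250 ms refractory window — sufficient for spike-like synthetic ECG;
half-truncated spikes at the very edges of a recording have no local
maximum and are not detectable. Respiratory phase uses the
histogram-equalized transfer φ_r(t) = π H(R(t)) · sign(dR/dt) with a
100-bin amplitude histogram, wrapped to [0, 2π); the derivative sign is
taken from a lightly smoothed copy of the belt signal (σ = 0.2 s). The
nuisance matrix holds cos(mφ) and sin(mφ) for m = 1..5 and both
modalities: 20 columns. Phases are sampled at volume onset + TR/2 (the
middle-slice convention); the sampling time within the volume is a
documented default, not a prescribed value.

## GLM engine

The canonical HRF is the double-gamma
h(t) ∝ g(t; 6, 1) − (1/6) g(t; 16, 1) (gamma densities; response mode at
5 s, undershoot centered near 15 s), normalized to unit peak amplitude on
a dense internal grid so samples on any volume grid are mutually
consistent. Event regressors convolve Dirac trains (boxcars for blocks)
with h on a 16× oversampled grid (kernel support 32 s) and sample at
volume onsets. Task-1 model 1 has 12 event regressors (8 targets + 4
returns), model 2 adds the 2 cues; block designs get one boxcar per
active label. Jittered onsets enter at their realized times.

Fitting is the standard two-pass pre-whitened least squares:

1. discrete-cosine high-pass columns for periods above 128 s
   (K = ⌊2·n·TR/cutoff⌋) are appended;
2. a first OLS pass yields residual lag-1 autocorrelations; the
   projection-induced bias — the expected lag-1 autocorrelation
   tr(MAM)/tr(M) of projected white noise, with M the residual-forming
   matrix and A the symmetrized lag operator — is subtracted, without
   which heavy designs deflate ρ̂ by up to ~0.09 at desk scale;
3. per-voxel AR(1) whitening (first row scaled by √(1−ρ²), then
   ρ-differencing) of data and design, and a refit. ρ is quantized to a
   0.01 grid so all voxels sharing a value are solved together; this is
   a vectorization device, accurate to half a quantization step.

Contrasts use t = c'β̂ / √(σ̂² c'(X̃'X̃)⁻¹c) with df = n − p; the group
stage is a voxel-wise one-sample t across participants (df = n−1),
zero-variance voxels masked NaN. Spatial smoothing is a separable
Gaussian at 4 mm FWHM with periodic boundary handling, which keeps the
normalized kernel mass on the grid and so preserves the image mean
exactly; phantoms keep background margins, so wrap-around has no
practical effect.

## Cluster-extent inference

Clusters are connected components (18-connectivity by default;
configurable — the convention is our choice) of voxels above the
one-sided t(df) quantile of p = 0.001. The minimum extent k_min is
calibrated by Monte Carlo: each null iteration draws df + 1 Gaussian
white-noise images, smooths each to the analysis FWHM, and forms their
one-sample t-field — i.e. the null emulates the group analysis itself —
then k_min is the smallest k whose familywise crossing fraction is ≤ α.
A single smoothed Gaussian field thresholded at a t quantile is *not*
used: at desk-scale df the t quantile (e.g. t(12) at p=.001 ≈ 3.93) is
far stricter than the Gaussian quantile, virtually no null field crosses,
and the calibration degenerates. Extent values are data/configuration
dependent by design and are not fixed constants.

## FIR time courses (PSTH)

Per condition (pro/anti × leftward/rightward, amplitudes pooled), an
indicator regressor per 0.5 s bin covers post-target offsets [0, 12) s,
with high-pass columns and a baseline appended. Coefficients are
estimated by least squares on an independent column subset selected
incrementally (nuisance columns first, Gram–Schmidt with
re-orthogonalization, relative tolerance 1e-8): bins never sampled, or
aliased onto a sampling pattern linearly dependent on other bins (this
happens when overlapping windows share their only sampled volumes), are
reported NaN rather than silently mis-attributed. Coefficients are
scaled to percent of each voxel's run mean. In a saturated rapid design
the curve's common offset is only weakly identified against the
baseline; differences between conditions — the quantities the statistics
use — are unaffected.

ROI statistics, computed on per-participant ROI-mean curves:

* **Peak anti vs pro**: one-sample (paired) t over participants of
  anti − pro at the peak bin of the grand-mean curve, directions
  averaged; one-sided p for anti > pro.
* **Lateralization**: the leftward − rightward antisaccade difference in
  the left ROI tested against the same difference in the right ROI at
  3.15 s and 5.25 s (nearest 0.5 s bin; these timepoints fall on the
  volume grid, not bin centers, so nearest-bin matching is the
  documented resolution). Positive t = ipsilateral preference. The
  paired variant is the default (the participants are the same in both
  ROIs); a two-sample variant is available.

## Tractography (FACT)

FA follows the eigenvalue form √(3/2)·‖λ−λ̄‖/‖λ‖. Tracking is
deterministic fiber assignment by continuous tracking: within a voxel
the path runs straight along that voxel's principal eigenvector to the
voxel boundary, then adopts the next voxel's eigenvector with the sign
chosen for continuity. Eight seeds per voxel sit at the centers of a
fixed 2×2×2 sub-voxel grid; every voxel with FA ≥ 0.2 is seeded and each
seed is propagated bidirectionally. Termination: entering a voxel with
FA < 0.2; a turn exceeding 53° (continue at equality); the mean angle
between the running direction and the principal axes of the 6 face
neighbors (angles measured between *lines*, i.e. orientation-invariant)
exceeding 90° — at the default threshold this criterion is deliberately
permissive and rarely fires; the neighborhood (6 vs 26) and the
line-angle convention are documented choices, as no standard definition
exists. A step cap (2000) guards against degenerate oscillation at voxel
boundaries. No minimum-length filter is applied.

## Fiber connectivity

* **Selection**: a fiber is kept for a striatal ROI (mask dilated 2 mm,
  spherical element in world mm) iff at least one of its points lies in
  the ROI *and* the FA of the voxel containing that point is < 0.3 — the
  low-FA requirement separates fibers terminating in striatal gray
  matter from white-matter fibers skimming the surface. "Any
  intersecting point" is the default; a "first intersecting point"
  variant exists. FA is looked up at the nearest voxel, no
  interpolation.
* **Prolongation**: each end is extended 3 steps of 2 mm, each step
  along the normalized mean of the 4 most recent segment vectors
  (updated per step): 6 mm of smooth extension per end, compensating for
  early termination short of cortical gray matter. Fibers with fewer
  than 5 points are returned unchanged with a warning.
* **Midsagittal cut**: points beyond x = 0 (configurable plane) are
  removed from the first crossing on, with an interpolated point exactly
  on the plane appended.
* **Probability map**: per participant, the binary map of voxels
  traversed by ≥ 1 fiber (segments densified at half-voxel steps),
  dilated 3 voxels (face-connected iterations), smoothed at 4 mm FWHM,
  then averaged over participants; values stay in [0, 1].
* **Connectogram**: for each (cortical cluster dilated 4 mm, striatal
  ROI) pair, the number of participants with at least one connecting
  fiber; fiber multiplicity within a participant never matters. The
  processing order is select → prolong → cut → count.

## Synthetic data: what it emulates, and what not

BOLD runs are baseline (100) + per-region HRF-convolved condition
responses in percent signal change + low-frequency drift + physiological
pulsatility + AR(1) noise, on a 24×24×18 grid of 2 mm voxels (a
desk-scale analogue of a 2 mm acquisition; the world origin is centered
so the midsagittal plane is x = 0). Choices, made once:

* Default planted amplitudes: prosaccades 1.0 %, antisaccades 1.5× that
  (ipsilateral 1.5 %, contralateral 1.2 % in the antisaccade-FEF pair);
  weaker anti preference (1.2 vs 1.0) in the SEF; task-unspecific 1.0 %
  responses in motor-FEF and 0.8 % in putamen. The absolute percent
  scale is a free parameter (the unit is not directly meaningful);
  values in the ~1 % range are typical of event-related 3 T responses.
* Noise: AR(1) ρ = 0.3, stationary SD 1 (i.e. 1 % of baseline,
  temporal SNR ≈ 100); between-participant response scaling 1 ± 0.2 SD.
* Drift: a random combination of the 3 slowest discrete-cosine basis
  functions of the run (periods > 128 s, unit-peak scaled, per-voxel
  coefficient SD 1). Planting drift inside the high-pass null space is
  deliberate: the filter is designed to remove exactly this band, so
  drift never masquerades as a task effect and test failures indicate
  implementation bugs rather than spectral leakage. Real scanner drift
  is not band-limited this way — leakage of off-basis drift through the
  finite DCT basis is a few percent of the drift amplitude, and a test
  documents that magnitude separately.
* Physio: ECG spikes (width 15 ms) at 1 Hz with Gaussian beat jitter
  (SD 2 % of the interval), respiration a 0.25 Hz sinusoid with slow
  amplitude modulation; pulsatility is injected as per-voxel random
  combinations of the RETROICOR basis built from the same trace's true
  peak times, so exact-phase projection removes it identically — this
  isolates phase-estimation error as the only source of residual
  pulsatility downstream.
* Tensors: tubular bundles around polylines; in-bundle voxels get an
  axially symmetric tensor along the local tangent with the target FA
  and fixed trace 2.1e-3 mm²/s (one free parameter removed; the
  λ2/λ1 ratio solves a quadratic in FA); background is isotropic-shaped
  at the background FA. Striatal "gray matter" voxels are set to
  FA 0.25 — above the 0.2 tracking floor so fibers enter, below the
  0.3 selection ceiling so they count as terminating.
* The connectivity phantom plants, per hemisphere, a motor-FEF ↔ putamen
  bundle ending inside the putamen, and a decoy bundle passing straight
  through the caudate at white-matter FA (0.8) — ground truth is
  putamen connected, caudate not, and the decoy specifically exercises
  the FA < 0.3 skimming rule.

Not emulated: head motion, susceptibility distortion, slice-timing
errors, realistic ECG morphology, spatially correlated noise, non-tubular
or kissing/crossing-dominated fiber configurations, and any
between-region variation in HRF shape. Passing tests therefore certify
procedure correctness and statistical calibration under these
assumptions, not robustness to real-data artifacts (which the original
acquisition pipeline handles upstream of this package's scope).

## Full-study orchestration

`run_full_study` spawns per-participant sub-seeds from the master seed
via `numpy.random.SeedSequence` (values kept below 2³¹), simulates a
cohort (default 12 participants, 40-trial runs, 229 volumes at
TR 2.1 s), runs first-level GLMs with estimated-phase RETROICOR columns,
the group t-test, Monte-Carlo extent calibration (default 1000
iterations) and cluster labeling, the FIR/PSTH statistics in the
antisaccade-FEF pair, and the complete DTI chain, writing every
intermediate in a standard format (TSV, NIfTI, JSON-lines, TRK) plus a
JSON report stamped with the config hash and seed. Reports are
byte-identical across reruns with the same configuration. Problem sizes
(grid, cohort, volumes, iteration counts) are the package's desk-scale
defaults and are all configurable.

## Known limitations

* The R-peak detector assumes spike-like ECG; it is not intended for
  real electrocardiograms.
* AR(1) whitening with the bias-corrected estimator still under-corrects
  slightly (≈ −0.02 at ρ = 0.3 after high-pass filtering, because the
  filter genuinely removes autocorrelated low-frequency power).
* The FACT neighborhood-angle criterion has no field-standard
  definition; results with thresholds below 90° depend on our line-angle
  convention.
* Cluster inference assumes stationary smoothness equal to the applied
  kernel; residual-smoothness estimation from data is not implemented.
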