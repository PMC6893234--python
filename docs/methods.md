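# Methods

This note documents the models, numerical choices, and limitations behind
the `diametric` pipeline, in the spirit of a statistical software methods
appendix. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from elsewhere.

## Measurement chain

### fALFF

For each voxel series x(t) sampled at interval TR over N volumes:

1. remove the least-squares linear trend (no band-pass filtering);
2. take the DFT; the amplitude at bin k is |X_k| (the square root of the
   power), with natural bin frequencies f_k = k / (N·TR);
3. fALFF = Σ|X_k| over bins with low ≤ f_k ≤ high, divided by Σ|X_k| over
   all bins with 0 < f_k ≤ 1/(2·TR).

Band edges are inclusive; the default band is 0.008–0.09 Hz. Zero-variance
voxels yield NaN (detection threshold: residual amplitude below 1e-10 of
the series scale, which absorbs detrending round-off on constant or purely
linear series). fALFF is invariant to positive rescaling and to any added
linear trend, and bounded in [0, 1]; these invariants are property-tested.

Because amplitudes (not powers) are summed, mean fALFF of white noise is
close to, but not exactly, the in-band bin fraction; the test suite checks
the white-noise mean against an independent periodogram-based Monte-Carlo
estimate rather than against the naive bin count.

A note on test anchors: a "pure in-band sinusoid" only has fALFF ≈ 1 when
its frequency sits exactly on a DFT bin and its phase makes it orthogonal
to the removed linear trend; otherwise spectral leakage moves several
percent of the amplitude sum out of band. The analytic anchors therefore
use a bin-aligned cosine centered on the series midpoint.

Mixed repetition times are supported by design: fALFF is computed per run
against that run's own Nyquist. This has a measurable consequence
discussed under *Calibration* below.

### Denoising and connectivity

The nuisance model contains, per run: the top principal-component time
courses (default 5 per tissue) of the voxel×time matrix inside one-voxel-
eroded white-matter and CSF masks, extracted from unsmoothed data with
per-voxel detrending and variance normalization; six motion parameters and
their backward differences (first row zero); one indicator column per
outlier volume; and a linear trend. A volume is an outlier if any of the
x/y/z translations steps more than 0.5 mm from the previous frame (volume
0 exempt) or its global mean intensity deviates more than 3 population SDs
from the run mean. Global signal regression is excluded on purpose: it
manufactures negative correlations and would make the anticorrelation
readout uninterpretable.

Filtering order: an ideal DFT band-pass (zeroed bins outside the inclusive
band; DC removed) is applied to the voxel data and to every confound
column, then each voxel is residualized on the filtered confounds by
ordinary least squares (minimum-norm solution when columns are collinear,
with a warning). Residuals are orthogonal to the filtered confounds to
1e-6. With filtering disabled (`band=None`) an intercept is added and
outlier indicators zero their volumes exactly — the classical scrubbing
identity. That identity cannot survive filtering: a filtered indicator is
no longer an indicator, so under the simultaneous filter-then-regress
order the flagged volumes are attenuated, not exactly zeroed. Both modes
are tested for the property each one actually guarantees.

Smoothing (Gaussian, FWHM 8 mm, σ = FWHM/√(8 ln 2), per volume) is applied
to runs entering fALFF and FC maps, never to tissue-signal extraction.

Seed FC: unweighted mean series over the seed voxels, Pearson r against
every voxel, then z = atanh(r) with |r| clipped at 1 − 1e-7 so perfect
correlation maps to a large finite value instead of infinity.

### PDA

PDA = (mean of CEN ROI z-scores) − (mean of DMN ROI z-scores), one scalar
per session. ROI z-scores are (v − mean)/sd (sample sd, ddof 1) across a
*reference set* of sessions: all baseline sessions of both groups for the
trait analysis, the meditators' three conditions for state analyses
(configurable). ROIs enter network means with equal weight by default;
voxel-count weighting is available. The formula does not force positivity;
PDA > 0 exactly when mean CEN activity exceeds mean DMN activity.

## Synthetic cohort generator

The generator emulates what the analysis assumes, not real physiology:

* **Nodes**: spheres (default radius 2 voxels on a 24³ grid of 4 mm
  voxels) — two DMN, two CEN, one WM and one CSF compartment. Spheres may
  not overlap and must fit the grid.
* **Network signals**: independent Gaussian series are passed through one
  shared ideal 0.008–0.09 Hz filter, standardized, mixed by the Cholesky
  factor of the target correlation matrix (within-network r 0.7,
  DMN–CEN r −0.5 by default), and re-standardized. Mixing after a shared
  filter preserves the target correlation in expectation; the second
  standardization matters — without it the first Cholesky column has
  exactly unit sample variance while the others do not, which measurably
  biased null PDA contrasts (≈ +6 SE over 200 cohorts) before it was
  removed.
* **Amplitudes**: each node's series is scaled by in_band_amplitude × a
  group/condition multiplier, plus independent broadband noise (amplitude
  0.25). Default multipliers encode the study conditions: controls 1.0;
  meditators 0.8 in both networks at baseline (trait deficit), CEN raised
  ×1.5 over their baseline during meditation (to 1.2) and ×1.25 after
  (to 1.0). No published effect sizes exist in raw fALFF units, so the
  magnitudes were chosen once for detectability at n = 16 and are recorded
  in the truth ledger, never hard-coded in tests.
* **Acquisitions** mirror the design: rest 2.0 s TR / 151 volumes before
  and after a meditation block at 1.5 s TR / 804 volumes.
* **Confounds**: WM/CSF series leak (coefficient 0.15) into every gray
  node; a linear drift (amplitude 1 noise-SD peak-to-peak) is added
  everywhere; motion is a slow 6-parameter random walk (step 0.02 mm).
  Spikes occur per volume with probability 0.02 (volume 0 exempt) as
  persistent >0.5 mm position steps plus a matched one-volume global
  intensity jump, so both outlier rules are exercised and a spike is
  flagged at exactly one volume.
* **Practice hours** are drawn per meditator (normal, mean 1677 h, SD
  367 h, floor 100 h); optionally the per-subject cross-network
  correlation is modulated linearly in standardized hours (clipped to the
  positive-semidefinite region |r| < (1 + within-r)/2) for dose-response
  recovery studies.

Determinism: all randomness flows from one `SeedSequence`; identical
design + seed reproduces every run bit-for-bit.

What the generator does *not* model: hemodynamic response shapes,
cardiac/respiratory noise, spatial autocorrelation beyond node spheres,
anatomical geometry, registration error. Passing recovery tests therefore
demonstrates the measurement chain's correctness on data satisfying its
assumptions, not robustness to violations found in real BOLD.

## Inference

* **Permutation tests**: paired contrasts use the sign-flip null on a
  paired t statistic; unpaired contrasts permute group labels under a
  pooled-variance t. Sampled nulls report p = (b+1)/(m+1); when fewer
  distinct relabelings exist than requested permutations the null is
  enumerated exactly and p = b/m (the identity relabeling is already
  counted), making p a multiple of 1/2^n for n paired subjects.
* **TFCE**: TFCE(v) = Σ_h e(h,v)^E · h^H · dh with H = 2, E = 0.5 and
  6-connected clusters. The height integral is evaluated *exactly*: e(h)
  is piecewise constant between the map's distinct values, so closed-form
  cell integrals over those breakpoints reproduce the continuum definition
  to machine precision (an isolated suprathreshold voxel enhances to
  v³/3 exactly). A fixed-step mode (`dh` or `n_steps`) remains for large
  maps. Negative tails are enhanced on the negated map. Within
  permutation, the max-TFCE statistic gives FWE-style voxel p-values.
* **Cluster-size FDR**: clusters are formed where the observed directional
  statistic exceeds the pooled permutation-null height-threshold quantile;
  each cluster's size is compared to the null distribution of the maximum
  cluster size, and Benjamini–Hochberg adjustment runs across clusters.
  Every report labels which correction produced it.
* **Repeated measures**: a linear mixed model (fixed condition effects,
  random subject intercept) fitted by maximum likelihood; the condition
  test is the likelihood ratio χ² with k−1 df against the intercept-only
  model. Several optimizers are tried and the best likelihood kept — the
  ML surface can be flat in the variance ratio. For balanced complete
  data with an interior optimum the statistic has the closed form
  n(k−1)·ln(SSW_null/SSW_full), which the tests use as an independent
  oracle (agreement to 1e-4); at the σ_b² = 0 boundary the constrained ML
  differs from that formula, which is correct behavior, not error. Tukey
  post-hoc contrasts use the studentized range on the model's marginal
  means with residual df (n−1)(k−1); the between-group median-split
  comparison uses an OLS likelihood-ratio χ² and Tukey–Kramer with
  harmonic sample sizes.
* **Covariate correlations**: Pearson R with a covariate-shuffling
  permutation p (two-sided on |R|), or the parametric t-based p; map
  inputs get voxelwise R with max-|R| FWE permutation p.

## Calibration and the mixed-TR interaction

The paired permutation test is calibrated on null cohorts using the
TR-matched paired contrast (baseline vs post-meditation rest, both 2 s /
151 volumes): empirical type-I error at α = 0.05 over 1000 cohorts falls
within [0.03, 0.07].

The baseline-vs-meditation contrast mixes repetition times, and there the
test is *conservative*, for a reason worth recording. With broadband noise
present, the in-band amplitude share depends on the Nyquist frequency, so
mean fALFF shifts systematically between TR 2 s and TR 1.5 s sessions.
Pooled z-scoring then sees a strongly bimodal per-ROI distribution; its
variance normalization couples the paired differences across subjects
(their sum is nearly pinned by the normalization constraint), deflating
the observed t far below its sign-flip null. The consequence is loss of
power, never inflated false positives; the designed state effect is still
detected in well over 80% of cohorts at n = 16. Analysts using pooled
z-scoring across acquisitions with different TRs should be aware the same
interaction applies to real data.

## Problem sizes and defaults

The demo pipeline (`demo_config`) uses 8 controls + 8 meditators, 200
volumes per run on a 24³ grid, 500 permutations — chosen as the smallest
design in which every stage (trait-ROI derivation included) has realistic
behavior while a full run completes in well under a minute on one CPU.
Validation studies use: 1000 null cohorts (calibration), 50 cohorts of
n = 16 at 200 volumes (state-effect recovery, both effect and null arms),
20 runs of 800 volumes (anticorrelation recovery), 20 random 12³ maps
(TFCE oracle), 50 random datasets (mixed-model oracle). The acceptance
script uses the same studies at 400/30/30/10-size arms to keep its runtime
to a few minutes.

## Known limitations

* No spatial resampling: all inputs must share one voxel grid.
* The trait-ROI derivation stage is wired as the FC seed source, but using
  trait-contrast-derived ROIs to then display the trait contrast is
  circular; validation uses generator-truth masks for extraction and
  tests the derivation stage for mechanics (Dice against truth spheres,
  fallback path, component splitting) only.
* Satterthwaite degrees of freedom are not implemented; Tukey post-hoc
  uses the balanced-design residual df.
* The ideal DFT band-pass assumes stationarity and wraps circularly; no
  taper is applied (the fALFF path is deliberately unfiltered, matching
  its definition).
* Rotational head motion does not enter the 0.5 mm displacement rule by
  default (translations only); a conversion at an effective head radius
  can be added by callers building their own outlier configs.
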