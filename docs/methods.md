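# Methods

## The detection problem

`timelock` tests whether a brain region's BOLD signal contains a component
locked to a block-design stimulus, without assuming any response shape.  A
block design alternating `on` seconds of stimulation with `off` seconds of
rest concentrates every task-locked waveform — sustained, delayed, transient,
or negative — at the fundamental frequency `f0 = 1/(on + off)` and its
harmonics.  The test statistic is therefore the periodogram power of the
region-averaged signal at `f0`, averaged across subjects, and the question
"is this region activated?" becomes "is this power larger than expected under
rest?".

For the reference protocol (30 s on / 30 s off, 7 cycles, TR = 3 s, 5 dummy
volumes) the arithmetic is exact: 145 acquired volumes over 435 s; 140
analysis samples after dummy removal; `f0 = 1/60 Hz ≈ 0.0167 Hz`, which falls
exactly on bin 7 of the 140-sample frequency grid (`f0 · N · TR = 7`), so the
single-bin statistic captures the full task component with no spectral
leakage.  Dummy volumes are removed *before* analysis precisely so that the
record spans an integer number of cycles and this exactness holds; an
off-grid record length raises a leakage flag in `resolve_target`.

## Signal extraction

Gray-matter regions are integer labels of a parcellation; their signal is the
unweighted mean over label voxels.  White-matter bundles are represented by
tract-density maps (streamline count per voxel); their signal is the
density-weighted mean with weights `w_v = d_v / Σ d_v` over density-positive
voxels inside the brain mask.  Density weighting concentrates the signal in
the deep bundle core, which suppresses partial-volume contamination from
cortex at bundle terminations.  Density-positive voxels outside the mask are
excluded with a warning (the mask is the trust boundary).  No spatial
smoothing, detrending, nuisance regression or filtering is applied anywhere;
a single-voxel impulse affects only regions containing that voxel, and the
test suite asserts this.

All volumes must share a grid (shape equal; affines equal within 1e-4
absolute).  No resampling or registration is performed — inputs are expected
co-registered.

## Spectral estimator

The estimator is the plain rectangular-window periodogram (via
`scipy.signal.periodogram`): with the sample mean removed,
`PSD[k] = c_k |X_k|² / (fs N)` one-sided, `c_k = 2` at interior bins and 1 at
DC and the (even-N) Nyquist bin.  Mean subtraction does not affect the target
bin (k = 7) but makes the Parseval identity clean:
`Σ_k PSD[k] · fs/N = Var(x)` (population convention), which the suite checks
to 1e-8.  Power at the single nearest bin is used, not a band, and no taper
is applied.  The second harmonic (2·f0) is ignored; this costs sensitivity
for strongly non-sinusoidal responses but keeps the statistic single-valued.

## Bootstrap null and inference

The null distribution of "subject-averaged power at `f0`" is built from
resting-state runs.  For each of `B` replicates, one cube of `edge³` voxels
(default 13, i.e. 39 mm at 3 mm isotropic; desk-scale studies use 5) is drawn
uniformly per subject from all centers whose cube lies inside the grid with
at least 50% of voxels in the brain mask; the cube's in-mask mean series is
reduced to its periodogram power at the target bin, and the across-subject
mean forms one null value.  One cube per subject per replicate, independent
across subjects and replicates, so the null value has exactly the sampling
unit of the observed statistic (a 12-subject average).  The bootstrap loop
computes single-bin power by direct DFT projection rather than a full
periodogram; a test pins this fast path to the public
`sample_cube_signal` → `periodogram_psd` route bit-for-bit.

p-values are one-sided with the resampling convention
`p = (1 + #{null ≥ observed}) / (B + 1)`, so `p > 0` always.  Within one
task, all GM and WM regions form a single family corrected by
Benjamini–Hochberg step-up FDR (via `statsmodels`); a region is called
time-locked when `q < 0.01`.

### Spatial-unit caveat

With voxelwise-independent noise, the power of an `n`-voxel mean scales as
`1/n`.  The cube null is therefore exchangeable with a region statistic only
when cubes and regions average comparable voxel counts.  The calibration
study enforces this exactly by sampling inside a homogeneous volume (mask
covering the whole grid: every cube complete, observed cube-regions at fixed
locations exchangeable with null replicates); measured type-I error at raw
`p < 0.01` is 0.004–0.010 across seeds.  Inside a bounded brain mask the
≥50%-coverage rule admits partial cubes that average fewer voxels and carry
more power, biasing region-level calls conservative; the recovery study runs
in that regime (labels of ~130 voxels vs 5-voxel cubes with ≤125) and its
non-responder false-discovery rate stays well below the nominal level.  On
real data, spatial noise correlation — absent from this simulator by default
— performs the unit matching implicitly; passing these studies validates the
machinery, not the spatial correlation structure of any particular scanner.

## Epoch-averaged responses

For visualization and shape comparison, each task signal is converted to
percent change about its run mean, `100·(x − x̄)/x̄`, cut into cycles aligned
to stimulus onset (sample 0 = first post-dummy volume), and averaged across
cycles; group curves are pointwise means across subjects with individual
curves retained.  Percent-about-mean was chosen because the baselines of
different regions differ and the y-axis convention must be comparable across
regions; no per-epoch re-anchoring is applied.

## Synthetic data

The generator provides the statistical structure the analysis assumes and
nothing anatomical:

- **Atlas**: the brain mask is an ellipsoid filling 90% of the grid; GM
  labels tile its outer shell (radius fraction > 0.62) as contiguous
  angular-sorted patches of near-equal size; each WM bundle is a
  Gaussian-profile tube (σ = 10% of grid extent, truncated at 2.5σ) through
  the deep interior, so density peaks at the tube core as streamline density
  peaks in deep white matter.  Bundles may overlap; labels never do.
  Construction fails loudly when any region would get fewer than 8 voxels.
- **Responses**: ground truth is the block regressor (on-period first)
  convolved at 1/30-TR resolution with a double-gamma kernel (peak 6 s,
  undershoot 16 s, peak:undershoot 6 — the canonical default, stated
  explicitly because the analysis itself is model-free), with shape
  modifiers: pure convolution (`sustained`), onset+offset impulses
  (`transient_onset_offset`), a time shift (`delayed`, default 6 s), sign
  flip (`negative`), within-block ramp (`ramp`).  The curve is scaled so its
  peak equals the requested percent amplitude; scaling is exactly linear in
  amplitude.  The kernel support (32 s) is shorter than the 60 s cycle, so
  responses are periodic after the first cycle.
- **Runs**: baseline 100 inside the mask (so percent change and raw units
  coincide), responders multiplied by `1 + r/100` during task samples,
  dummies at baseline.  Noise is stationary AR(1) Gaussian per voxel
  (marginal σ, lag-1 coefficient `ar1`) plus an optional per-voxel linear
  drift; voxels are independent by default with an optional Gaussian spatial
  smoothing of the noise field for null-robustness experiments.  Noise
  streams are keyed on (scenario seed, subject index, condition) through a
  counter-based generator, so any single run is reproducible in isolation.
- **Inter-subject variability**: each subject's amplitudes are jittered by a
  uniform ±20% factor by default.

What the simulator deliberately omits: anatomy, physiological (cardiac /
respiratory) noise, motion, multi-echo acquisition, and spatially correlated
noise by default.  Passing tests on this generator shows the estimator,
null, and decision machinery are correct under the stated noise model — not
that the method is robust to artifacts it never sees.

## Study parameters

Desk-scale problem sizes used by the validation studies (chosen once, as the
package's reference configuration): grids 24³ (calibration, recovery) and
16³ (epoch fidelity); 12 subjects; σ = 1 on baseline 100 (i.e. 1% noise);
`ar1 = 0.3`, a realistic BOLD autocorrelation at TR 3 s; B = 2,000 bootstrap
replicates; cube edge 5; 30 GM labels + 6 bundles with 8 sustained 1%
responders in the recovery study (GM-only responders keep truth labels
unambiguous, since bundles can share voxels); 500 null regions and 20
recovery repetitions.  The bundled demo uses a 20³ grid, 8 labels + 4
bundles, B = 500 and cube edge 7.

## Numerical choices and degenerate inputs

- Grid equality: shapes exact, affines within 1e-4 absolute (absorbs float
  serialization noise).
- `resolve_target` excludes the DC bin, errors when `f0` exceeds Nyquist,
  and flags leakage beyond 1% of the bin spacing.
- Constant signals yield an all-zero spectrum (mean removal), hence p = 1.
- BH adjusted values are capped at 1 and mapped back to input order; ties
  are handled by the step-up minimum.
- All result tables are sorted by (tissue, region_id) and serialized with 12
  significant digits, making repeated runs byte-identical.
- Degenerate inputs error early: 3D files where 4D is required, runs shorter
  than dummies+2, empty labels, all-zero density maps, cubes leaving the
  grid or with <50% mask coverage, empty p-value or result lists.

## Known limitations

- Single-bin testing ignores harmonics; transient responses lose power.
- The null's ≥50% coverage rule makes region calls conservative near mask
  boundaries at desk scale (see the spatial-unit caveat).
- No registration/resampling: misaligned inputs are rejected, not fixed.
- The FDR family is all regions of one task; nothing corrects across tasks.
- Subject runs are assumed independent; no within-subject session structure.
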