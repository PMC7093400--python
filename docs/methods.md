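# Methods

## Forward model

Sensors are axial gradiometers: pairs of coaxial point coils separated by
a 50 mm baseline, the conventional axial spacing (the channel output is
the field difference projected on the coil axis, in tesla; no division by
baseline). 160 channels are laid out by a deterministic equal-area
golden-angle spiral over a spherical-cap helmet (radius 0.12 m, 55 % of
the sphere's area) — a stand-in for the unpublished coil-level layout of
whole-head axial systems. Coils are treated as points; coil-winding
integration is a documented simplification.

The conductor is a homogeneous sphere (default radius 0.09 m, a typical
adult head). The field of a current dipole follows the Sarvas closed
form; the radial source direction is exactly silent, so every 3-column
lead-field block has rank 2, and field strength decays toward the center
— the physical mechanism behind deep-focus difficulty. An
overlapping-spheres variant fits one sphere per channel to digitized
scalp points, weighted by `exp(-angular distance / sigma)` with
sigma = 30°, chosen so neighboring channels share scalp support; on a
perfectly spherical scalp it degenerates to the global fit.

The source space is a cubic lattice (default 7 mm spacing) clipped
strictly inside the sphere with a 5 mm margin, offset half a spacing so
no voxel sits at the (singular) center. 34 region labels produced by
deterministic farthest-point seeding stand in for a sublobar anatomical
atlas; they are a partition of comparable-sized parcels, not anatomy.

## Inverse model

sLORETA on the volume grid with unconstrained (3-axis) dipole moments.
The minimum-norm kernel is computed in noise-whitened sensor space with
the SNR-based regularization `lambda^2 = trace(L L') / (n_channels *
snr^2)` (default snr = 3, the common minimum-norm convention; the
clinical software's value is unpublished). Noise covariance is pooled
from the 100 baseline windows and shrunk 10 % toward its diagonal.
Standardization divides each voxel's 3-vector estimate by the 3×3
diagonal block of the resolution matrix; because radial silence makes
those blocks rank 2 in a sphere, a ridge of 1e-12 × (mean block trace)
is added before inversion. Standardized power is non-negative,
invariant to rescaling the noise covariance, and exhibits zero
localization error on noiseless single tangential dipoles — verified
exhaustively on a ≤ 500-voxel grid. No claim is made about multi-source
accuracy.

## cDS pipeline

Zero-phase 4th-order Butterworth band-pass, 10–50 Hz. IED windows are
the annotated onset→offset spans; the 1-s pre/post-IED intervals are
treated as an exclusion buffer around baselines (switchable
interpretation), and baseline windows are exactly 100 ms, 100 of them.
Each window's sLORETA power is time-averaged; IED vs. BL maps are
compared voxelwise by permutation (statistic = plain difference of group
means, two-sided, 1,000 randomizations, add-one p-values; exhaustive
enumeration replaces sampling automatically when the group sizes permit).
Cases with fewer than three IEDs are refused, mirroring the clinical
exclusion. Benjamini–Hochberg FDR yields q-values; the threshold ladder
{0.05, 0.01, 0.005, 0.001, 5e-4, 1e-4} is walked until the significant
voxels span a single region (or the last non-empty mask is taken). Ties
at the argmax break to the lowest voxel index.

**Intensity map.** The "maximum intensity voxel" is taken on the
*studentized* IED−BL contrast (voxelwise t-map) restricted to the
significant mask, not on the raw mean IED power map. Under realistic
noise the raw power map is dominated by the per-voxel noise floor, and
with a broad significance mask the argmax then lands on noise voxels;
the studentized contrast measures the spike-evoked excess in units of
its own sampling variability, which is also what clinical statistical
map displays show. The permutation statistic itself remains the plain
mean difference.

## ECD comparator

Two-stage deterministic fit per 5-ms snapshot: a linear least-squares
moment solve at every voxel of a coarse scan grid, then Nelder-Mead
refinement of the position (max 500 iterations, position clamped inside
the sphere), with the moment re-solved linearly at each step. Fit times
run from spike onset to offset inclusive (a 50-ms window gives 11 fits).
GOF = 100 × (1 − residual SS / measured SS). Acceptance is strict
GOF > 70 % and inclusive 50–500 nAm; white-matter or extra-axial
positions are *not* excluded. Per spike, the accepted fit with the best
GOF is kept; the modal sublobar region of those best fits is the
diagnosis unless the mode is tied or its count falls below
max(2, 25 % of best fits) — the quantification adopted for the
qualitative "evenly scattered" rule. A single global sphere is used for
dipole fitting, the convention for clinical ECD.

## Synthetic data generator

One spike source per case: a fixed tangential orientation at a grid
voxel, driven by a deterministic biphasic waveform (difference of two
Gaussians, sharp positive lobe σ = duration/12 then slower negative lobe
σ = duration/6, equal-area so the integral is ≈ 0; > 99 % of its energy
falls in 10–50 Hz at the default 80-ms duration). Defaults mirror the
clinical recording protocol: 160 channels, 5,000 Hz sampling, 4-minute
sessions, 5 sessions, moment 200 nAm (a mid-range interictal spike).
Background activity is 200 dipoles at random grid locations with
tangential orientations and 1/f-shaped time courses, plus sensor white
noise at one third of the background RMS.

**SNR definition.** Because every analysis band-passes to 10–50 Hz and
the 1/f background lives mostly below 10 Hz, SNR is defined in-band:
(peak spike RMS across channels) / (10–50 Hz noise RMS), enforced
exactly by scaling the generated noise. Default snr = 4 for a
superficial source — roughly a clearly visible single interictal spike.
Alternatively an absolute noise floor (`noise_rms_t`) can be fixed; the
benchmark sets it so the *median superficial* source reaches the
configured SNR, and deep sources then face the lower effective SNR
(≈ 0.4–0.5×) that lead-field attenuation imposes in real recordings.
Deep sources are drawn at 2.5–4 cm eccentricity (mesial/basal
structures; voxels nearer the center are almost silent in a sphere and
are not plausible spike generators), superficial ones above 6 cm.

What the generator does *not* emulate: extended/propagating cortical
patches, sleep architecture, cardiac/ocular artifacts, multifocal
epilepsy, or real sensor spectra. Passing tests therefore demonstrate
the statistical machinery and its depth behavior under the stated noise
model, not clinical performance.

## Benchmark and concordance

The depth benchmark simulates deep and superficial case arms under one
shared absolute noise floor and runs both pipelines on every case.
Concordance is scored the way the clinic defines it — the diagnosed
sublobar region must lie inside the "resected area" — modeled as the
set of regions intersecting a 2-cm-radius ball around the true source
(clinical resections span several sublobar parcels). "No focus
available" never counts as concordant. Arms are compared with Fisher's
exact test and a diagnostic odds ratio.

## Evaluation layer

Concordance rates are percentages rounded to 1 decimal; odds ratios and
CIs to 3 significant figures; p-values to 3 decimals — the printing
conventions of the clinical report being reproduced. Fisher's exact test
is two-sided by probability ordering (the dominant software convention).
The DOR confidence interval uses the Woolf log-normal method,
exp(ln DOR ± 1.96·SE) with SE = √(1/a+1/b+1/c+1/d); this choice
reproduces all four published CIs from the packaged table, which is the
evidence it is the method the original analysis used. Zero cells trigger
a 0.5 continuity correction to all four cells, flagged in the report.
Undefined ratios (zero denominators) are reported as not computable
rather than zero.

## Problem sizes

Full clinical scale (7 mm grid ≈ 7,500 voxels; 5 × 240 s at 5,000 Hz)
is supported but a single case then costs on the order of ten minutes on
one core. The test suite and `scripts/acceptance.py` use scaled study
conditions that preserve the regime: 12 mm grid (≈ 1,500 voxels, 34
regions), 1,000 Hz sampling, two 60-s sessions, 10 IEDs per session,
100 baselines, 1,000 permutations. The zero-localization sweep uses an
18 mm grid (≈ 430 voxels) to keep the exhaustive per-voxel check fast.

## Known limitations

* Spherical conductor and point coils; no BEM/FEM, no anatomy.
* Region labels are a geometric partition, not an atlas; region-level
  scores are not comparable across different grids.
* The permutation p-value floor with 1,000 randomizations is ≈ 1e-3, so
  the lower rungs of the threshold ladder only engage for very strong
  effects.
* The single-dipole comparator is evaluated on single-dipole simulated
  sources — a best case for ECD; the measured deep-arm gap is therefore
  conservative relative to clinical reality, where extended sources
  degrade ECD further.
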