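# Methods notes

This package re-creates, at desk scale and on fully synthetic inputs, an
analysis chain for a preoperative tDCS/motor-training study: resting-state
connectivity of individualized M1 seeds before and after an intervention,
voxel-wise connectivity contrasts with cluster inference, and a
phantom-specific finite-element model of the stimulation field whose ROI
mean is regressed against connectivity change. This note records the
models, the parameter choices that matter, and what the synthetic data do
and do not establish.

## Synthetic resting BOLD

Each subject's resting signal is generated as

* latent unit-variance Gaussian sources, one per region, mixed by the
  Cholesky factor of the target correlation matrix (pre-session matrix
  `R`; post-session `R + Δ`, default Δ = +0.15 on the left–right M1
  pair);
* every voxel of a 6-mm-radius spherical region carries its region's
  source;
* plus spatially smoothed Gaussian voxel noise (white noise filtered
  with a 6-mm-FWHM kernel and rescaled to SD `noise_sd`), which gives the
  images genuine local correlation structure for LCOR;
* plus an optional common-mode linear drift and a 100-unit baseline.

`noise_sd` defaults to 0.2 relative to the unit-variance sources. The
value was fixed by a planting-fidelity argument: the ROI-mean series of a
~19-voxel region retains a noise-mean variance of roughly
`0.43 · noise_sd²` after smoothing, which attenuates the realized
inter-ROI correlation by about 1% at r = 0.6 — small against the ±0.02
calibration the generator is held to (empirical mean of the sample r over
200 seeds at 300 volumes). Noisier settings remain available per
configuration but are not the calibrated default.

The default grid is 24 × 24 × 18 voxels at 4-mm isotropic resolution —
a deliberate stand-in for a 64 × 64 × 30 acquisition matrix — with two
runs of 75 volumes (TR 2 s) per session mirroring a two-runs-of-5-minutes
protocol at half length. Sessions and runs draw from independent child
streams of one subject seed, so Δ = 0 makes pre and post independent
draws from the identical model.

Task runs add a boxcar (20-s alternating blocks, a configurable choice —
the emulated protocol states only ~4-minute runs of alternating blocks)
convolved with the canonical double-gamma HRF (peak 6 s, undershoot 16 s,
peak:undershoot 6:1), spatially weighted by a Gaussian profile around the
activation locus and scaled so the peak voxel carries the stated percent
signal change over baseline.

What the generator does **not** emulate: scanner drift beyond a linear
term, physiological cycles, slice timing, spatial inhomogeneity, realistic
anatomy, or between-subject variance in the planted effect. Passing tests
therefore demonstrate the correctness and calibration of the analysis
code under its own assumptions, not robustness to real acquisition
artifacts.

## Denoising

Volumes are flagged as outliers when the global-signal z-score exceeds 5
or framewise displacement (sum of absolute parameter changes, rotations
converted to arc length at 50-mm radius) exceeds 0.9 mm — conservative
art-style defaults, both configurable since the emulated protocol does
not state them. The confound model per run is: 6 motion parameters, their
first backward differences, 5 aCompCor components (principal component
time courses of the demeaned noise-ROI voxel × time matrix; the border
shell of the synthetic grid stands in for white-matter/CSF masks), one
indicator column per flagged volume, and a discrete-cosine basis spanning
frequencies below 0.009 Hz. Everything is removed in a single OLS with
intercept, which makes high-pass filtering and nuisance regression
commute by construction (the recipe is idempotent on its own output, and
per-voxel variance can only decrease). Runs are denoised and z-scored
separately, then concatenated in time for connectivity; run handling is a
package choice since the protocol does not state one.

## Connectivity metrics

Correlations are computed on the standardized residual series. IC uses a
truncated SVD: with row-standardized X, the correlation matrix is
`C = X Xᵀ = U S² Uᵀ`, so IC is the row norm of `U_K S_K² / sqrt(N)` and
the N × N matrix is never formed. K = min(64, rank); on desk-scale grids
the rank (bounded by time points) is usually below 64, where the
truncated and exact computations coincide to floating-point accuracy.
The self-correlation term y = x is included, as the defining sum is
written. IC maps are z-scored across in-mask voxels per session before
group contrasts ("normalized" maps); raw maps are also available — which
rescaling the reference toolbox applies is not documented, and a
session-level z-score is the choice that removes session scale from a
between-session comparison.

LCOR weights are evaluated on millimetre offsets through the affine
(anisotropic voxels handled correctly) and truncated at 3σ, where the
Gaussian has fallen to ~1% of its peak; the truncation radius is
configurable.

Seed spheres contain every voxel whose centre lies within 6 mm of the
peak ("6-mm spherical ROI" is read as radius 6 mm, the volumetric-toolbox
convention). Peak selection skips voxels outside the anatomically allowed
mask in descending-t order and breaks ties toward the lower linear index,
so it is fully deterministic.

## Group statistics

ROI metrics use the one-tailed paired t (directional hypothesis of
increased connectivity), preceded by a Shapiro–Wilk screen (scipy's
implementation of the standard algorithm). The EF regression is a simple
OLS with `p` from `t = r·sqrt((n−2)/(1−r²))`, two-tailed.

Voxel-wise contrasts use sign-flip permutation cluster inference instead
of any parametric second-level machinery: under a symmetric null,
flipping the sign of whole subject difference maps is exact for a paired
design. Suprathreshold voxels (two-tailed p < 0.005 by default; the
threshold's sidedness is configurable since conventions differ) are
grouped by 26-connectivity; each cluster's p is the proportion of
permutations whose *largest* cluster is at least as big (a max-statistic
null, so the per-cluster p-values are family-wise valid by construction),
followed by Benjamini–Hochberg across clusters. The permutation seed is
explicit; 500–1000 permutations are the practical defaults.

## Electric-field model

Head phantoms are concentric spheres — skin 92, bone 85, CSF 78, GM 75,
WM 67 mm outer radii, loosely adult-sized — with optional nested tumor
compartments (edema ⊃ non-enhancing ⊃ enhancing ⊃ necrosis) replacing
brain tissue. Conductivities (S/m): WM 0.126, GM 0.276, CSF 1.65, bone
0.01, skin 0.465, air 2.5e−14, gel 0.3, electrode 5.9e7, enhancing tumor
0.170, non-enhancing 0.332, necrosis 1.0, edema 1.185. Gel and electrode
entries are retained for volumetric electrodes even though the default
model applies electrodes as boundary conditions only.

Each labelled voxel is split into 5 tetrahedra with the pattern mirrored
on alternating voxel parity, which makes shared faces conform and
conserves volume exactly; phantom grids use even dimensions so the mm
origin falls on a mesh node and the mesh is point-symmetric (useful for
antisymmetry checks). The P1 stiffness matrix is assembled per element
and solved with Jacobi-preconditioned conjugate gradients to a 1e−10
relative residual (sparse LU for small systems or as fallback). Electrode
pads are grown on the scalp surface face by face in order of angular
distance from the montage direction until the requested pad area
(5 × 7 cm² → 35 cm²) is covered; C3 and FP1 map to fixed unit directions
on the phantom (45° left of vertex; 18° left of anterior on the equator).
Two electrode models are provided: cathode grounded (Dirichlet V = 0,
the default gauge for montage runs) and both-pads-Neumann with the gauge
fixed by pinning the central node — the latter matches the analytic
validation solution, which injects current at both electrodes.

The oracle is the interior Legendre series for a homogeneous insulated
sphere with surface current source and sink, generalized from point
electrodes to uniform spherical caps (the cap's Legendre coefficients are
`(P_{n−1} − P_{n+1})(cos θ₀)/2` of the uniform density), truncated when
terms stop contributing at 1e−10 relative. At the default 4-mm mesh the
FEM potential agrees with the series within ~1% of the potential scale at
interior probes, layer-integrated current is conserved to solver
precision, and the solution is exactly linear in the injected current.
With 2 mA through 35-cm² pads the default phantom carries a mean brain
field of ≈0.24 V/m — inside the 0.05–0.5 V/m envelope expected for
conventional tDCS. ROI field means are restricted to brain-labelled
voxels by default (a 6-mm cortical sphere on a coarse grid otherwise
catches high-field skull voxels); whether to restrict further to grey
matter is configurable.

Known limitations: isotropic conductivities only; staircase (voxel)
geometry rather than smoothed surfaces, which inflates coarse-mesh
surface fields somewhat; boundary-condition electrodes rather than meshed
gel/electrode volumes; phantom anatomy is spherical by design.

## Pipeline and reproducibility

`run_study` executes generate → denoise → seeds → connectivity → group
statistics → phantom FEM → EF regression. All per-stage randomness
derives from the master seed by seed-sequence hashing of
(seed, stage, subject), so reports are bit-identical across runs of the
same configuration; the report carries a config hash, the master seed and
the package version, and validates against the JSON schema shipped in
`pipeline.REPORT_SCHEMA`. Per-subject phantoms vary skull radius and
tumor size with the subject stream so the EF regression has genuine
predictor variance.

Problem sizes in the shipped tests and acceptance script are the
package's desk-scale choices: operating-characteristic replicates use
12-subject cohorts on 16 × 16 × 12 grids with 2 × 60 volumes and the
interhemispheric readout; cluster calibration uses 200 simulated null
studies of 12 smooth-noise difference maps on 10 × 10 × 8 grids with
200 permutations; the FEM oracle uses a 90-mm sphere at 4-mm voxels with
20 interior probes. At these sizes the planted +0.15 effect is detected
in ≳95% of replicates, null cohorts reject at the nominal 5%, and no
family-wise cluster inflation is observed.
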