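# Methods

This note records the models, numerical choices and study conditions behind
`sepmap`, and what the synthetic validation does and does not demonstrate.

## Forward model

The quasi-static EEG forward problem is the Poisson equation
`∇·(σ∇φ) = −∇·j` with conductivity σ (S/m) on a regular isotropic voxel
grid and insulating boundary at the head surface.  Capacitive effects are
neglected: at SEP frequencies the solution is effectively frequency
independent, and frequency enters only through the Cole–Cole evaluation of
tissue conductivity (default 10 Hz).

**Discretization (SPFD).**  Potentials are unknowns at voxel *nodes*
(corners).  The edge between two adjacent nodes carries a conductance
`g = h · mean(σ)` over the up-to-four voxels sharing that edge (h is the
voxel edge length in meters).  Each node's equation balances the edge
currents; rows sum to zero (pure Neumann operator).  Air voxels contribute
σ = 0, so nodes entirely in air drop out of the system and no explicit
boundary rows are needed.  The system is symmetric positive semidefinite
with the constant vector in its null space; right-hand sides are nodal
current injections that sum to zero, so the system is consistent.

**Elementary dipoles.**  A dipole of moment p at a voxel along axis a is a
monopole pair ±I with I = p/h.  By default the pair is *distributed*: ±I/4
on each of the voxel's four edges parallel to a.  This centers the dipole
on the voxel and makes it the exact discrete adjoint of voxel-center field
sampling (below), so reciprocity holds to solver tolerance rather than to
discretization accuracy.  A single corner-edge pair is available via
`distributed=False`.

**Solver.**  Geometric multigrid V-cycles with red-black SOR smoothing
(relaxation factor 1.5, two pre- and two post-sweeps), up to six levels.
Coarse operators are re-assembled from 2×2×2 box-averaged conductivity with
doubled spacing; levels stop when a grid dimension becomes odd or smaller
than four voxels.  Residuals are restricted by the transpose of trilinear
prolongation (weights summing to 8, so restricted residuals keep their
meaning as currents); the coarsest level is relaxed with 200 SOR sweeps;
the restricted right-hand side is re-centered on the conducting nodes to
keep the singular Neumann hierarchy consistent.  Iterations stop when
`‖b − Aφ‖₂/‖b‖₂ ≤ 1e-6` (configurable); non-convergence raises an error
carrying the residual history.  The gauge is fixed afterwards by zeroing
the potential at the reference node.  On the 64³ three-layer test sphere
the default configuration converges in ~12 V-cycles (~1 s on one CPU).

**Derived fields.**  The voxel-center gradient of the nodal potential is
the mean of the four parallel edge differences per axis (the central
difference at the voxel center); current density is `j = −σ∇φ`.

## Lead fields by reciprocity

For electrode m (reference r), inject current I at m and −I at r, solve
once, and sample `−E_m/I = ∇φ_m/I` at the source voxels: this is row m of
the M×3N gain matrix L (V per A·m), with the reference row identically
zero.  Columns are voxel-major, component-minor (x, y, z).  M−1 solves
replace the 3N solves of the brute-force construction, which is retained
(guarded to ≤10⁴ columns) as the validation oracle: with the distributed
dipole convention the two constructions agree to ~1e-7 relative Frobenius
discrepancy at solver tolerance 1e-8.  No depth weighting or smoothing is
applied to L.

## Inverse methods

**OMP.**  Greedy selection on unit-normalized dictionary columns (most
correlated with the residual), least-squares re-fit of all active columns
against the raw dictionary, residual refresh; stops at the component budget
K = 5 (focal SEP generators), at machine-scale residual, or when the
relative residual improves by less than 1 % (configurable saturation).
When the data are common-average referenced (zero-sum), the dictionary is
re-referenced the same way before matching.  A voxel-block variant selects
a voxel's full 3-column subspace instead of single columns
(`block_selection=True`).  Columns that would make the active set rank
deficient are skipped with a warning.

**Two-stage reconstruction.**  OMP coefficients are dipole moments, not a
field; the cortical current density is reconstructed by re-running the SPFD
with a unit elementary dipole per selected component and superposing the
weighted fields, restricted to the gray-matter mask.

**Point extraction.**  The summary coordinate of a sparse estimate defaults
to the strongest selected voxel (vector norm of its component weights);
alternatives are the |weight|-centroid and the magnitude peak of the
two-stage reconstruction (one forward solve per component, so not the
default in cohort loops).  For standardized maps it is the argmax voxel,
ties resolved to the lowest linear index.

**sLORETA baseline.**  Gain and data are put in the common-average
reference (centering matrix H); the minimum-norm estimate is
`ĵ = Lᵀ(LLᵀ + λH)⁺ φ` and each voxel's 3-vector is standardized by the
inverse of its 3×3 resolution block `[Lᵀ(LLᵀ+λH)⁺L]_vv`.  Default
`λ = trace(LLᵀ)/(M·SNR²)` with SNR = 3.  With noiseless single-source data
and small λ the standardized power peaks exactly at the true voxel (the
zero-localization-error property, verified over an entire phantom source
space), while the un-standardized minimum-norm power shows the familiar
superficial bias.

## Preprocessing

2 kHz sampling; 500 ms epochs with a 100 ms pre-stimulus baseline
(1000 samples, 200 pre-stimulus).  Zero-phase 4th-order Butterworth
band-pass 3–299 Hz plus Q = 35 notches at 60/120/180/240 Hz (filter order,
phase handling and Q are implementation choices recorded in the output
metadata; only the frequencies are protocol constants).  Per-trial,
per-channel baseline correction over the pre-stimulus interval; the first
3 ms after stimulus onset (6 samples) are flagged as stimulation artifact
and excluded from any later window average rather than interpolated.  The
analysis topography is the per-channel mean over 20 ± 3 ms (13 samples),
common-average referenced; a peak-sample variant is available behind a
flag.  Identical defaults apply to every stimulation condition.

## Phantoms and the synthetic cohort

**Geometry.**  Concentric spheres, conductivity assigned by voxel-center
containment (deterministic, oracle-checkable; no partial-volume
averaging).  Desk-scale defaults: 40³–64³ grids at 2 mm spacing with
brain/skull/scalp layers 28/32/36 mm at 0.33/0.02/0.1 S/m (scalp 0.1 S/m
avoids overestimating the stratum corneum).  The gray-matter source shell
is the 45–85 % radial band of the innermost layer.  Full-head 0.5 mm
resolution is configuration-reachable but not a test default.  The
smoothly varying model class is produced by Gaussian smoothing restricted
to the head support with a boundary-renormalized kernel, so air stays at
exactly 0 S/m.

**Electrodes.**  A deterministic 65-label 10/10-style spherical table (and
a golden-spiral layout for arbitrary counts), snapped to the nearest
outer-surface grid node; snapping beyond one voxel diagonal or two labels
on one node are errors.  Only count and topology matter on a sphere — no
fiducial-based scalp geometry is implied.

**SEP simulation.**  Scalp epochs are the lead-field projection of each
planted dipole times its time course (default: unit Gaussian bump peaking
at 20 ms, σ = 2 ms, zero before stimulus) plus i.i.d. Gaussian sensor
noise; the pre-stimulus segment contains noise only.  Evoked SNR is
defined on the trial- and window-averaged topography:
`noise_sd = rms(clean) · sqrt(n_trials · n_window) / 10^(SNR/20)`.

**Cohort study conditions** (chosen once): 24 spiral electrodes on the
40³ phantom; five tangential 20 nA·m finger sources spaced 4 mm along a
lateral–medial arc at 65 % of the brain radius; 16 virtual subjects per
cohort; 24 trials per condition at 10 dB evoked SNR; per-subject source
jitter uniform in ±1 voxel per axis as a stand-in for anatomical
variability.  The cohort loop runs baseline correction, averaging,
windowing, common-average referencing and OMP for every subject × finger;
the band-pass/notch stage is omitted there because the simulated noise is
white with no line component (the filters are exercised by their own
tests).  Per-finger coordinates are averaged across subjects before the
ordering regression (finger index 1–5; Pearson R, two-tailed p from the
t distribution with n−2 df; sample SD throughout; no multiple-comparison
correction — two predefined axes).

## Analytic oracle

For a dipole inside multi-layer concentric spheres, each harmonic degree n
has radial solutions `a ρⁿ + b ρ^-(n+1)` per layer; continuity of potential
and radial current at interfaces plus the insulating outer boundary give a
(2L−1)-dimensional linear system per degree, solved with per-layer
normalized basis functions so all entries stay O(1) up to n ≈ 100.  The
series (default 60 terms, tail-ratio stopping) is evaluated with Legendre
recurrences; electrodes are projected radially onto the outer surface
(legitimate because the radial derivative vanishes there).  The
homogeneous-sphere closed form (generating-function sums) and the
equal-conductivity multilayer reduction serve as independent cross-checks
at 1e-6 relative accuracy.  Forward solutions are compared by
`RDM = ‖a/‖a‖ − b/‖b‖‖` and `MAG = ‖b‖/‖a‖` on common-average referenced
vectors.

## What the tests show — and what they do not

The sphere phantoms validate the numerics end to end: discretization and
solver (RDM ≈ 0.011, |ln MAG| ≈ 0.003 against the analytic solution at
2 mm), reciprocity, sparse recovery, the sLORETA zero-error property, and
the recoverability of a planted somatotopic gradient under sensor noise
(~95 % of cohorts reach |R| ≥ 0.95 on the planted axis under the default
conditions).  They do not emulate realistic cortical folding, skull
inhomogeneity, correlated (biological) noise, bad channels, or co-registration
error, so passing them bounds numerical—not anatomical—accuracy; absolute
mm errors on human data cannot be inferred from these phantoms.

## Known limitations

- Isotropic conductivity only; no anisotropic tensors or complex
  admittance solves.
- Multigrid coarsening requires even grid dimensions per level; odd grids
  fall back to fewer levels (worst case: plain SOR on the fine grid).
- The sLORETA implementation forms the dense resolution matrix and is
  intended for baseline comparisons at phantom scales (≲ 10⁴ columns), not
  for 60 000-dipole cortical grids.
- The 10/10 layout is a spherical-angle approximation; real cap geometry
  requires fiducials that a sphere does not have.
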