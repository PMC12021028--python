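# Methods

`ciliacoat` re-implements, as a tested library, the quantitative analyses
used to characterize the ciliary glycocalyx of *Chlamydomonas reinhardtii*:
locating coat particles (FMG1 "scales") in cryo-electron tomograms of intact
cilia, quantifying the structural-repeat architecture of the mucin-like coat
protein, and measuring gliding motility and flow-driven cell detachment.
Because the original raw data (tomograms, TIRF movies, microfluidic
recordings) are not desk-scale inputs, every analysis ships with a
synthetic-data generator whose ground truth makes the pipeline falsifiable.
This note records the models, the defaults and why, and what the synthetic
conditions do and do not establish about real data.

## Coordinate and orientation conventions

Volumes are `(z, y, x)` arrays, 0-based and voxel-centered, with an
isotropic voxel size in Å. Orientations are ZYZ intrinsic Euler angles in
degrees (RELION convention): `R = Rz(rot) · Ry(tilt) · Rz(psi)` maps
template-frame vectors to world frame. Particle tables store 0-based voxel
coordinates in memory; the STAR dialect on disk is 1-based, converted
explicitly on read/write.

## Tomogram phantom

The phantom emulates what a binned cryo-tomogram of a cilium shows: a
tubular membrane (Gaussian shell of thickness ~50 Å around a smooth, gently
bowed centerline), nine parallel rods standing in for axonemal doublets
(visual realism only — no algorithm consumes them), and a coat of small
particles placed on outward surface normals inside the band `[d_in, d_out]`
from the membrane. The particle template is an asymmetric L-shaped blob
(three fused Gaussians in a 17³ box, peak normalized to 1) so that
orientation is identifiable; an odd box size keeps the rotation center on a
voxel, which makes the generator's rendering and the matcher's correlation
share one center convention. Imaging is additive Gaussian noise (σ expressed
as a fraction of the template peak) followed by a binary Fourier missing
wedge.

Defaults: 128³ voxels at 10 Å, tube radius 300 Å, coat band 50–250 Å,
50 particles with ≥120 Å spacing, noise σ = 0.3·peak, wedge ±60° (2°
increments, matching dose-symmetric acquisition from −60° to +60°). The
acquisition geometry (±60°/2°), the coat's scale-like appearance, and the
voxel-size scale are taken from the imaging conditions of the source
experiments; the coat band offsets and particle spacing are not published
numbers — they are free phantom parameters chosen to give a plausibly dense,
resolvable coat at this voxel size.

The missing wedge is a binary mask: coefficients whose direction in the
(x, z) plane lies further than the tilt range from the x axis are zeroed
(tilt axis y; no CTF, no dose weighting). The unsampled fraction of Fourier
space inside the Nyquist sphere is analytically `(90° − range)/90°` — the
check used in the tests. The mask depends only on the range; the increment
is carried for provenance.

## Membrane shell mask

The membrane is fitted per cross-sectional slice as a closed periodic cubic
spline (scipy `splprep`, `per=True`) through membrane points — clicked
points in real use, generator truth here. Points are angle-sorted about
their centroid first, so click order does not matter. Contours from fitted
slices are re-parameterized to arc-length-uniform control points with a
common starting azimuth and winding direction, then interpolated
control-point-wise (linearly) to unfitted slices; outside the fitted range
the nearest fitted contour is used.

The "offset by a defined amount" step is implemented with a distance field,
not analytic normal displacement: per slice, the unsigned distance of every
voxel center to the densely resampled contour is computed exactly (KD-tree
against 4096 curve samples), and a voxel joins the shell iff it lies outside
the contour and its distance is in `[d_in, d_out]`. This is robust to
concave contours, where normal offsetting self-intersects. A half-space mode
(`dist ≥ d_in`, no outer bound) is provided because a band versus half-space
choice is an open design point; the band is the default since the coat is a
visibly bounded layer. Default offsets d_in = 50 Å, d_out = 250 Å bracket a
plausible coat band and are configuration, not measurements.

## Template matching and overlap filtering

Scoring is Roseman-style locally normalized masked cross-correlation,
computed with FFTs: for each orientation of a deterministic SO(3) grid, the
rotated template is correlated with the volume, and the volume's mean and
variance under the rotated template's binarized footprint normalize the
score to a true correlation coefficient in [−1, 1]. Per masked voxel the
maximum over orientations and its argmax orientation are kept. When the
volume carries a missing wedge, the same binary wedge filter is applied to
each rotated template before scoring, so reference and data share the
anisotropy. The published pipeline used a GPU template matcher whose exact
score and wedge weighting are not public; this implementation targets
behavioral (recovery) equivalence on phantoms with known truth, not
numerical identity with that tool.

The rotation grid stacks tilt rings spaced by the nominal step, scales the
azimuth count per ring with sin(tilt) for near-uniform covering, samples the
in-plane angle at the step everywhere, and removes the duplicate rotations
of the degenerate rings by quaternion comparison. At a 20° step this yields
1908 orientations with ≥ 9.7° minimum pairwise separation. A 20° step is
the practical floor for an L-shaped template at this noise level and runs a
128³ volume in ~3–4 minutes on one CPU.

Peaks are 26-connected local maxima above a score threshold (default 0.4,
chosen on phantom recovery at the study noise level), greedily pruned with
an exclusion radius (default 6 voxels). Sub-voxel positions come from a
separable parabolic fit to the score map around each peak. The overlap
filter then visits candidates in descending score — ties broken by
(z, y, x), then orientation index, making every greedy stage deterministic —
and accepts a candidate iff at most `overlap_threshold` (default 0.2) of its
binarized rotated-template footprint (10% of template max; both thresholds
are configuration since "predicted density" and "significant overlap" are
not quantified in the source) is already claimed by accepted particles, then
claims its footprint. This is the "fill in predicted densities in a
simulated tomogram, exclude overlapping lower-scoring particles" rule
expressed as an occupancy volume.

On the default phantom (50 particles, σ = 0.3·peak, ±60° wedge, 20° grid)
the full chain recovers 94–98% of truth positions within 2 voxels with
2–6% false discoveries across seeds.

## Structural repeats

A chain of tandem fold copies is segmented by superposition, since the
repeats share structure but not sequence (so sequence methods cannot find
them). Kabsch superposition (SVD with determinant correction; mirror inputs
still yield proper rotations) is the primitive throughout. The segmentation
algorithm — the published work states the repeat count, not a method — is:

1. Seed: the user's hint, or the window of length `(min_len + max_len)/2`
   whose trimmed superposition matches the most other windows.
2. Profile: trimmed superposition RMSD (iteratively discarding outlier
   residues, at least 70% coverage required, cutoff 3.5 Å) of the seed
   against every window start; qualifying starts are selected greedily in
   ascending RMSD with a small (12%) tolerated overlap.
3. Core trimming: window columns whose cross-repeat deviation exceeds 3× the
   median are linker contamination and are trimmed from both ends.
4. Re-scan with the trimmed core seed (pass 2). This matters because a
   nominal window longer than the true repeat period would overrun the
   chain's last repeat and miss it; the core seed fits every instance.
   Residual overlaps are clipped.

The structure-guided MSA superposes each segment onto a reference segment
(sequential-correspondence bootstrap, then nearest-Cα re-pairing < 5 Å,
iterated), and assigns segment residues to reference columns; columns are
1-based on the reference, so a residue conserved at template position 60
appears in column 60. The pairwise RMSD matrix uses the MSA correspondence
per pair. Sequence identity is reported as identical columns / alignment
length with gaps in the denominator (the convention is stated in output
metadata because published "pairwise identity" values rarely state theirs);
global alignment uses Needleman–Wunsch with BLOSUM62 (Biopython), gap open
10, extend 0.5. Disulfides are all Cys–Cys pairs with Sγ–Sγ ≤ 2.5 Å,
greedily assigned closest-first, one bond per cysteine.

The synthetic repeat chain places k noisy rigid copies of a deterministic
~100-residue compact fold along a jittered path, joined by extended
8-residue linkers. The template fold is a spherical spiral with a fixed
aperiodic radial modulation; the modulation is essential, because a bare
spiral is translationally self-similar (like a helix) and registration
shifted by one residue would superpose almost as well as the truth, which
no real Ig-like domain allows. Sequences are mutated from a common template
sequence so that the *mean pairwise identity between repeats* hits the
requested target (default 22%): the per-repeat fraction of kept positions p
solves `p² + (1−p)²/18 = y` for the non-invariant positions, with an exact
kept-count draw to reduce variance. Cysteine appears only at the planted
invariant positions (default 60 and 91), each repeat receiving one
2.05 Å Sγ–Sγ disulfide between them; targets below the random-match floor
(~6%) raise an error. Note the generator parameter is the pairwise quantity,
not identity-to-template — the former is what repeat families are described
by, and a 22% identity-to-template would realize only ~8% pairwise.

## Motility and detachment

Kymographs are built by sampling each frame along a line ROI at unit
spacing (linear interpolation) and max-projecting across the ROI width.
Tracks are traced by per-row peak detection (parabolic sub-pixel
refinement), nearest-neighbor linking with a short gap tolerance, and a
least-squares line fit per track; velocity is |slope| scaled by pixel size
and frame interval, and the reported distance is velocity × duration, so
the two are consistent by construction. Events whose fitted displacement is
under ~2 pixels over the whole track are reported with velocity 0 and
flagged excluded — the numerical reading of the "all gliding events
(velocity > 0 µm/s)" inclusion rule, since a noisy fit is never exactly
zero. At 10 fps and 0.1 µm pixels, velocities of 0.2–2 µm/s are recovered
within 5%.

Detachment movies are binarized per frame with Otsu's threshold (the
binarization method is unstated in the source; Otsu is the standard
parameter-free choice and is logged in output metadata), and "normalized
intensity" is read as foreground-area fraction normalized to frame 0 —
consistent with counting adherent cells; a raw-intensity alternative exists
behind a flag. Curves are annotated with the active step of the flow
schedule (default: the published pump program, 3.77→51.94 mL/min stepping
every ~30 s, final step unbounded) and replicate groups are compared with
equal-variance Student t tests at 50/100/150/200 s (Welch reported
alongside), as mean ± SD.

Mann–Whitney U (gliding statistics) uses midranks for ties; for n₁·n₂ ≤ 64
the two-sided p comes from full enumeration of all group assignments (the
permutation null, valid under ties — the reason this test is implemented
in-package rather than delegated), otherwise from the normal approximation
with tie and continuity corrections. The two agree to |Δp| < 0.01 by
n₁ = n₂ = 15.

## Numerical choices and degenerate inputs

- Greedy stages (peaks, overlap filter) break ties by score desc, then
  (z, y, x), then orientation index: bit-reproducible outputs.
- Local-normalization denominators below 1e-8 give score 0 (flat regions).
- Kabsch rejects < 3 pairs and near-collinear inputs (rank test at 1e-9).
- Contour fitting rejects < 4 or collinear points and self-intersecting
  fits; single-slice tubes are rejected with guidance to per-slice use.
- Empty particle sets yield zeroed summaries, not exceptions; constant
  movie frames binarize to background with a warning; empty first frames
  make normalization an error.
- Every generator is a pure function of its spec (seed included); the same
  config and seed reproduce outputs bit-identically.

## Problem sizes

Validation runs use a 128³ phantom with 50 particles and a 20° grid for
coat mapping (minutes on one CPU), chains of k ∈ {3, 5, 8} repeats for
segmentation, and 25 s movies at 10 fps for motility — sizes at which every
stage's truth can be checked exhaustively while the whole suite stays
interactive.

## What passing tests do and do not show

The generators emulate the geometry and the noise character of the real
assays, not their physics: no CTF or dose weighting, no reconstruction
artifacts beyond the binary wedge, no membrane undulation beyond a smooth
bow, spots instead of extended cells in kymographs, disks instead of cell
images in detachment movies, and an artificial (though deliberately
non-self-similar) repeat fold. Passing therefore establishes that the
implementations are correct and well-calibrated on data satisfying their
stated models — it does not establish detection performance on real
tomograms, where membrane proximity, crowding and reconstruction artifacts
are harsher than the phantom, nor event-splitting behavior on gliding data
with pausing and direction reversals, which the constant-velocity tracer
does not model.

## Known limitations

- The matcher is exhaustive over the rotation grid; no local orientation
  refinement. Orientation error is bounded by the grid step.
- Repeat segmentation assumes at least two instances of the repeat and a
  dominant repeat length inside `[min_len, max_len]`.
- The structure-guided MSA has reference-frame columns only; insertions
  relative to the reference are dropped rather than opening columns.
- The detachment analysis quantifies occupancy, not per-cell tracking; it
  cannot distinguish detachment from large migration.
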