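# Methods

`petdti` implements a PET-guided diffusion tractography pipeline for
suspected focal epilepsy: FDG-PET asymmetry-index (AI) mapping localizes a
hypometabolic gray-matter focus, white-matter (WM) regions at graded
distances around that focus seed deterministic tensor tractography, and
ipsilateral fiber metrics are normalized to their contralateral homologues
to quantify tract asymmetry. This note documents the models, the defaults
and why they were chosen, what the digital phantom does and does not
emulate, and the numerical choices that matter.

## Asymmetry-index mapping

The PET stage operates on a spatially normalized activity volume in a
single shared template space (RAS, mm). Stages, in order:

1. **SUV**: `SUV = C_PET * BW / Dose` with activity in Bq/mL, body weight
   in g and injected dose in Bq (the g/mL ≡ 1 convention makes SUV
   unitless).
2. **Smoothing**: Gaussian, FWHM 2 mm (per-axis sigma
   `FWHM / (2 sqrt(2 ln 2)) / spacing`; boundary mode *reflect* so compact
   signals keep their sum). Smoothing precedes GM masking by default; the
   other order is available via `smooth_before_mask: false`.
3. **GM restriction**: voxels with GM probability ≥ 0.30 (inclusive).
4. **Cerebellar normalization**: SUVr = SUV / mean GM SUV in the supplied
   cerebellum mask. No atlas lookup is implemented; the mask is an input.
5. **AI**: `AI = (I − fI) / (2 (I + fI)) × 100` where `fI` is the SUVr
   image reflected about the sagittal plane `x = midline` (default: the
   grid's central sagittal plane). AI is antisymmetric and bounded in
   (−50, 50) for positive images; voxels with `I + fI = 0` are undefined
   (NaN) and excluded from statistics.
6. **Standardization**: `Z_AI = (X − μ)/σ` with μ, σ the mean and
   *population* (ddof = 0) standard deviation of AI over GM voxels with
   defined AI — the GM voxels are treated as the distribution itself, not
   a sample from it.
7. **Threshold**: the normal criterion is replaced by the lower-tail
   Student-t critical value at α = 0.05 with df = n_subjects − 1, a
   small-sample correction of the Crawford–Garthwaite type. With a
   14-subject cohort (df = 13) the criterion is Z_AI < −1.77.
8. **ROI extraction**: suprathreshold GM voxels are decomposed into
   connected components (26-connectivity by default) and the largest
   component is the hypometabolic ROI, **provided** it reaches a minimum
   volume (default 150 mm³). The focality criterion is needed for type-I
   control: after per-image standardization a fixed fraction of GM voxels
   always falls below the threshold, so an any-voxel rule would detect
   "foci" in pure noise. The default is a null-calibrated cluster-extent
   threshold, the standard construction for this problem: on 100 null
   (symmetric, noisy) phantoms the largest suprathreshold cluster had a
   95th/99th percentile of 120/145 mm³, so 150 mm³ holds the
   false-detection rate near 1% while staying an order of magnitude below
   the lesions of interest (a radius-8 mm focus spans ~1 500 mm³ of GM).
   Runs without a sufficiently large cluster end with the clean status
   *no significant hypometabolism*.

Interpolation is trilinear for scalar volumes and nearest-neighbour for
masks (masks must stay binary). Sagittal flipping on a grid-aligned
midline is exact (voxel centers map to voxel centers).

## Seeding around the focus

A `3×3×3 mm³` VOI is placed at the ROI voxel nearest to WM (Euclidean
distance transform in world mm; ties broken by distance to the ROI
centroid, then smallest linear index). The VOI is dilated into WM at
cumulative distances of 3, 9 and 15 mm — the region at 9 mm contains the
region at 3 mm, matching the concentric coverage the method uses; disjoint
shells are available via `mode: shell`. Distances are voxel-center to
voxel-center EDT values. The contralateral VOI is the midline reflection
of the ipsilateral one — an automated, reproducible stand-in for manual
homologue placement — and is dilated identically. The WM mask defaults to
WM probability ≥ 0.5.

Seed regions are built on a 1 mm grid by default (`seed_grid_mm`),
regardless of the tensor grid: at 3 mm dilation a native 2 mm grid
contains only a handful of seed voxels in a single depth layer, which
makes the smallest region's fiber statistics dominated by discretization
noise. Tracking itself runs on the native tensor field; only the seed
coordinates come from the finer grid, and seed *density* per native-voxel
volume is held constant (`seeds_per_voxel` = 4 per native voxel by
default).

## Tensor fitting and tracking

The single-tensor model `S_i = S0 exp(−b_i g_iᵀ D g_i)` is fitted per
voxel: `linear_ls` solves the log-linearized system (exact on noise-free
data; non-positive signals are excluded per voxel), `nonlinear_ls`
(default) refines the linear solution by damped Gauss–Newton on the
exponential model, which has lower eigenvalue error under Rician noise.
Both are vectorized over voxels; Gauss–Newton runs in chunks of 20 000
voxels with per-voxel Levenberg damping (30 iterations max, monotone-cost
safeguard). Negative eigenvalues are clamped to zero for scalar maps and
counted. FA follows the standard eigenvalue formula, with FA = 0 where
all eigenvalues vanish.

Tractography is deterministic principal-eigenvector streamline
integration: Euler (default; RK4 behind `integrator: rk4`), fixed 0.5 mm
step, bidirectional from each seed with sign-coherent direction sampling.
Termination: FA < 0.10, turning angle > 45° per step, or leaving the
grid; retained length window 10–250 mm. These are standard
deterministic-tractography settings, exposed in config. The direction and
FA fields are sampled by **sign-coherent trilinear interpolation** by
default: nearest-neighbour sampling on a 2 mm grid truncates streamlines
that run along a bundle's edge, because sub-voxel excursions land on
off-bundle voxels and trip the FA stop; trilinear sampling removes the
artifact. Nearest-neighbour remains available (`interp: nearest`) and is
what the analytic geometry tests use, since it keeps slab edges sharp.
A constrained-spherical-deconvolution tracker can be substituted behind
the same interface; everything downstream consumes only streamlines.

## Fiber metrics and statistics

Per bundle: fiber count; mean length; mean FA as the length-weighted
average over all segments, FA sampled trilinearly at segment midpoints
(the natural weighting when only "weighted along the tracts" is
specified); mean cross-section as swept volume (unique voxels touched ×
voxel volume) divided by mean length — a dimensional surrogate (mm²)
isolated in one function so an alternative definition can be swapped in.
Empty bundles yield flagged-undefined metrics, never exceptions.

Ipsilateral metrics are divided by contralateral ones; 1 means symmetry,
< 1 an ipsilateral deficit. Across-distance comparisons use the Wilcoxon
signed-rank test, two-sided: zero differences dropped, ties mid-ranked,
exact null distribution (all 2ⁿ sign assignments, computed by dynamic
programming over doubled ranks — identical to literal enumeration) for
n ≤ 25, normal approximation with tie correction and no continuity
correction beyond that. Without continuity correction the approximation
sits within ~0.03 of the exact p at n = 15; the exact mode is what the
pipeline uses at cohort sizes of interest.

## The digital phantom

The phantom generates the inputs the pipeline assumes, with ground truth:

- **Geometry**: 64×64×48 grid, 2 mm isotropic, mirror-symmetric about
  x = 0 (even dimension ⇒ the midline is grid-aligned and flipping is
  exact). Layered ellipsoid: CSF shell, GM ribbon, WM core, plus an
  inferior GM cap labelled cerebellum (the normalization reference).
  Tissue probability maps are softened binaries (σ = 0.5 voxel).
- **PET**: activity = 20 000/7 000/1 000 Bq/mL weighted by GM/WM/CSF
  probability (GM-dominant uptake); one spherical GM lesion
  (default radius 8 mm, center (−45, 0, 0) mm) multiplies activity by
  (1 − hypometabolism fraction), default 15%; additive Gaussian noise at
  5% of mean GM activity (post-reconstruction PET noise model), clipped
  at zero inside the brain.
- **Bundles**: prolate tensors λ = (1.7, 0.3, 0.3)×10⁻³ mm²/s
  (FA = 0.799, textbook WM values) along two mirror-image long
  association-style arcs — annuli of constant in-plane ellipsoid fraction
  hugging the WM/GM interface of each hemisphere. The tangential field
  preserves each fiber's depth layer over the full arc, so fibers seeded
  next to the lesion can run far, as real cortex-adjacent tracts do; a
  straight tube (`bundle_geometry: straight`) is kept for tests but is
  clipped too quickly by the curving WM boundary to be the default.
  Background WM/GM/CSF are isotropic (0.7/0.8/3.0 ×10⁻³ mm²/s).
- **Damage model** (ipsilateral only): local severity
  `f = fa_deficit_fraction × exp(−d²/2σ_d²)` with d the distance to the
  lesion center and σ_d = 10 mm. The eigenvalues are shrunk toward their
  mean by `(1 − f) × S(σ_disp)` where `S = exp(−2 σ_disp²)` is the
  orientational order parameter of sub-voxel fiber dispersion with
  `σ_disp = 400° × f`: next to the lesion the voxel tensor approaches
  isotropy (tracking cannot propagate — the mechanism behind the reduced
  fiber counts close to the focus), while the Gaussian tail leaves only
  the mild scalar FA deficit (default 20% at the center). A small random
  rotation (0.3 σ_disp) adds macroscopic meander. Ground-truth FA is the
  closed-form FA of the shrunk eigenvalue triple.
- **Partial volume**: the generative tensor field is smoothed by
  σ = 0.6 voxel before signal synthesis, as a stand-in for acquisition
  partial-volume averaging; without it tissue interfaces are razor-sharp
  in a way 2 mm DWI never is. `truth.fa` stays the analytic pre-PVE FA.
- **DWI**: S0 = 1000 inside the brain; b = 0 plus 64 directions at
  b = 1000 s/mm² (hemisphere-folded Fibonacci axes); Rician magnitude
  noise at SNR 30.
- **Cohort**: 14 subjects by default, with lesion position (±4 mm
  tangentially), radius (±1 mm) and hypometabolism (±0.03) jittered, and
  per-subject RNG seeds derived from one cohort seed.

What the phantom does **not** emulate: scanner physics (attenuation,
scatter, PSF anisotropy), cortical folding, crossing fibers, registration
error, motion/eddy artifacts, and physiological asymmetries of a healthy
brain. Passing tests therefore demonstrate the correctness and internal
consistency of the computational pipeline under its stated model — not
clinical performance on patient data.

## Validation experiments

`petdti.evaluation` (used by the test suite and `scripts/acceptance.py`)
recomputes, from freshly generated data: the t critical value; type-I
control (fraction of 50 symmetric noisy phantoms with no detected ROI;
the focality criterion is what makes this controlled); lesion recovery
(ROI/lesion Dice at 10–20% injected asymmetry over 50 seeds); noise-free
tensor-fit error (machine precision); FA closed-form agreement (1e−12);
straight/arc streamline length errors versus analytic geometry (< 5%);
exactness of the signed-rank p against literal 2ⁿ enumeration; and the
cohort-level asymmetry directions (mean FA ratio < 1 at 3 mm in ≥ 13/14
subjects; count/length/FA ratios no higher at 3 mm than at 15 mm in the
majority; pooled Wilcoxon p for FA across distances). Problem sizes
(50 seeds for the ROI experiments, 14 subjects with full DWI synthesis,
fit and tracking for the cohort) keep the whole battery at roughly six
to eight minutes on one CPU while leaving the Monte-Carlo rates stable.

## Known limitations

- The tensor tracker is a substitute for the CSD-based tracking the
  clinical workflow used; tracking parameters (step, angle, FA stop,
  seed counts) are therefore package defaults, not values matched to any
  external tool.
- The mean cross-section definition is a surrogate; its absolute values
  should not be compared against other software.
- The contralateral VOI is a strict midline mirror; anatomical homologue
  placement on real, imperfectly symmetric brains needs registration
  machinery that is out of scope (an affine hook is provided).
- Nonlinear spatial normalization, DWI preprocessing (denoising, motion,
  eddy, distortion) and MR attenuation correction are assumed done
  upstream; the pipeline operates in one shared space.
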