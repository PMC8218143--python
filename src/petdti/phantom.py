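"""Digital head phantom: ground-truth-annotated PET + tissue + DWI data.

The phantom emulates the statistical structure the pipeline assumes, on a
2 mm isotropic grid (64 x 64 x 48 by default), mirror-symmetric about the
sagittal midline x = 0 before degradation:

- a head-like layered ellipsoid (CSF shell, GM ribbon, WM core) plus an
  inferior cerebellar GM cap used as the normalization reference;
- a PET activity map weighted by tissue (GM-dominant uptake) with one focal
  GM hypometabolic lesion — activity multiplied by (1 - hypometabolism
  fraction) inside a sphere — and additive Gaussian noise (post-
  reconstruction PET noise model);
- two mirror-image prolate-tensor fiber bundles in WM
  (lambda = (1.7, 0.3, 0.3) x 10^-3 mm^2/s, FA = 0.799): by default long
  association-style arcs hugging the WM/GM interface of each hemisphere
  (straight tubes behind a flag), the ipsilateral one degraded in FA
  (principal eigenvalue shrunk toward the mean) and in orientation
  coherence (random dispersion of the principal direction), both graded by
  a Gaussian falloff from the lesion center so damage is strongest next to
  the lesion;
- DWI signals S = S0 exp(-b g^T D g) at b = 0 and 1000 s/mm^2 over 64
  directions with Rician magnitude noise.

All randomness flows from a single integer seed; the same seed reproduces
the phantom bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .dti import DWIDataset, GradientTable, fa_from_evals
from .volume import BinaryMask, Volume3D

__all__ = ["PhantomSpec", "PhantomTruth", "Phantom", "generate_phantom",
           "generate_cohort"]

WATER_DIFFUSIVITY = 3.0e-3  # mm^2/s, CSF at body temperature


@dataclass
class PhantomSpec:
    """All knobs of the digital phantom (lengths in mm, world RAS space).

    The defaults reproduce the acquisition geometry the pipeline targets:
    2 mm isotropic voxels, b = 0 + 1000 s/mm^2, 64 diffusion directions,
    a 15% focal SUV reduction and a 20% ipsilateral FA deficit.
    """

    grid_shape: Tuple[int, int, int] = (64, 64, 48)
    spacing: float = 2.0
    brain_radii: Tuple[float, float, float] = (55.0, 60.0, 40.0)
    csf_inner_frac: float = 0.92      # GM/CSF boundary as ellipsoid fraction
    gm_inner_frac: float = 0.75       # WM/GM boundary
    cerebellum_z_frac: float = -0.75  # GM below this z-fraction = cerebellum

    lesion_center: Tuple[float, float, float] = (-45.0, 0.0, 0.0)
    lesion_radius: float = 8.0
    hypometabolism_fraction: float = 0.15
    pet_noise_sd: float = 0.05        # fraction of mean GM activity
    activity_gm: float = 20000.0      # Bq/mL
    activity_wm: float = 7000.0
    activity_csf: float = 1000.0

    bundle_geometry: str = "arc"       # "arc" | "straight"
    bundle_offset_x: float = 35.0      # straight mode: tube axis |x|
    bundle_z: float = 0.0
    bundle_radius: float = 7.0         # tube radius (arc: z half-thickness)
    bundle_half_length: float = 35.0   # straight mode: |y| extent
    arc_s_inner: float = 0.45          # arc mode: annulus inner fraction
    arc_s_outer: float = 0.76          # arc mode: annulus outer fraction
    arc_x_margin: float = 8.0          # arc mode: keep annulus |x| >= margin
    wm_lambdas: Tuple[float, float, float] = (1.7e-3, 0.3e-3, 0.3e-3)
    gm_diffusivity: float = 0.8e-3
    wm_background_diffusivity: float = 0.7e-3
    fa_deficit_fraction: float = 0.20
    deficit_sigma_mm: float = 10.0     # Gaussian falloff of damage from lesion
    dispersion_scale_deg: float = 400.0  # sub-voxel dispersion sigma (deg)
                                         # at full local damage f_local;
                                         # 400 deg * 0.2 = 80 deg: near-total
                                         # decoherence at the lesion face

    s0: float = 1000.0
    dwi_snr: float = 30.0              # Rician; 0 disables noise
    pve_sigma_vox: float = 0.6         # partial-volume smoothing of the
                                       # generative tensor field (voxels);
                                       # 0 = sharp tissue boundaries
    bvalue: float = 1000.0
    n_directions: int = 64
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.hypometabolism_fraction < 1.0:
            raise ValueError("hypometabolism fraction must be in [0, 1)")
        if not 0.0 <= self.fa_deficit_fraction < 1.0:
            raise ValueError("FA deficit fraction must be in [0, 1)")
        if abs(self.lesion_center[0]) <= self.lesion_radius:
            raise ValueError("lesion crosses the midline; it must lie strictly "
                             "within one hemisphere")
        if self.bundle_geometry not in ("straight", "arc"):
            raise ValueError(f"unknown bundle geometry {self.bundle_geometry!r}")
        if self.n_directions < 6:
            raise ValueError("need >= 6 diffusion directions")

    @property
    def affine(self) -> np.ndarray:
        """RAS affine centring the grid on the world origin; on the default
        even-size grid the midline x = 0 falls exactly between the two
        central sagittal slices, so sagittal flipping is exact."""
        a = np.eye(4)
        a[:3, :3] *= self.spacing
        a[:3, 3] = -(np.asarray(self.grid_shape) - 1) / 2.0 * self.spacing
        return a

    @classmethod
    def fixture(cls, **overrides) -> "PhantomSpec":
        """Miniature 16^3 phantom for fast unit tests."""
        base = dict(
            grid_shape=(16, 16, 16), spacing=4.0,
            brain_radii=(26.0, 28.0, 24.0),
            cerebellum_z_frac=-0.70,   # coarse grid: keep the cap populated
            lesion_center=(-22.0, 0.0, 0.0), lesion_radius=7.0,
            bundle_offset_x=14.0, bundle_radius=5.0, bundle_half_length=12.0,
            n_directions=12,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class PhantomTruth:
    """Ground truth the pipeline is graded against."""

    lesion_mask: BinaryMask
    bundle_masks: Dict[str, BinaryMask]     # "left", "right"
    d6: np.ndarray                          # true tensor field, (X,Y,Z,6)
    fa: Volume3D                            # analytic FA of the true tensors
    ai: Volume3D                            # noise-free AI map, percent
    ipsilateral: str                        # hemisphere holding the lesion


@dataclass
class Phantom:
    spec: PhantomSpec
    pet_activity: Volume3D
    gm_prob: Volume3D
    wm_prob: Volume3D
    csf_prob: Volume3D
    cerebellum_mask: BinaryMask
    brain_mask: BinaryMask
    truth: PhantomTruth
    dwi: Optional[DWIDataset] = None

    def write(self, outdir) -> None:
        """Write the full NIfTI + bval/bvec + mask bundle to a directory."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.pet_activity.save(out / "pet_activity.nii.gz")
        self.gm_prob.save(out / "gm_prob.nii.gz")
        self.wm_prob.save(out / "wm_prob.nii.gz")
        self.csf_prob.save(out / "csf_prob.nii.gz")
        self.cerebellum_mask.save(out / "cerebellum_mask.nii.gz")
        self.brain_mask.save(out / "brain_mask.nii.gz")
        self.truth.lesion_mask.save(out / "truth_lesion_mask.nii.gz")
        self.truth.fa.save(out / "truth_fa.nii.gz")
        self.truth.ai.save(out / "truth_ai.nii.gz")
        for side, m in self.truth.bundle_masks.items():
            m.save(out / f"truth_bundle_{side}.nii.gz")
        if self.dwi is not None:
            import nibabel as nib
            nib.save(nib.Nifti1Image(self.dwi.data.astype(np.float32),
                                     self.dwi.affine), str(out / "dwi.nii.gz"))
            np.savetxt(out / "dwi.bval", self.dwi.gtab.bvals[None], fmt="%g")
            np.savetxt(out / "dwi.bvec", self.dwi.gtab.bvecs.T, fmt="%.8f")


# ---------------------------------------------------------------------------
# geometry helpers


def _world_grid(spec: PhantomSpec):
    aff = spec.affine
    idx = np.indices(spec.grid_shape, dtype=float)
    x = aff[0, 0] * idx[0] + aff[0, 3]
    y = aff[1, 1] * idx[1] + aff[1, 3]
    z = aff[2, 2] * idx[2] + aff[2, 3]
    return x, y, z


def fibonacci_directions(n: int) -> np.ndarray:
    """n roughly uniform gradient axes (deterministic).

    Spiral points on the sphere, folded onto the z >= 0 hemisphere: DWI
    directions are axes (g and -g are equivalent), so hemisphere folding
    avoids near-antipodal duplicates in the scheme.
    """
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - i / n)          # upper hemisphere only
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def _perpendicular_basis(u: np.ndarray):
    """Two unit vectors orthogonal to each row of u."""
    ref = np.where(np.abs(u[:, [0]]) < 0.9,
                   np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]))
    p = np.cross(u, ref)
    p /= np.linalg.norm(p, axis=1, keepdims=True)
    q = np.cross(u, p)
    return p, q


# ---------------------------------------------------------------------------


def generate_phantom(spec: PhantomSpec, modalities: Tuple[str, ...] = ("pet", "dwi")) -> Phantom:
    """Build the phantom.  ``modalities`` can drop "dwi" to skip the (larger)
    diffusion synthesis when only the PET stages are exercised."""
    rng = np.random.default_rng(spec.rng_seed)
    aff = spec.affine
    x, y, z = _world_grid(spec)
    rx, ry, rz = spec.brain_radii
    rho = np.sqrt((x / rx) ** 2 + (y / ry) ** 2 + (z / rz) ** 2)

    brain = rho <= 1.0
    csf = (rho > spec.csf_inner_frac) & brain
    gm = (rho > spec.gm_inner_frac) & (rho <= spec.csf_inner_frac)
    wm = rho <= spec.gm_inner_frac
    cereb = gm & (z < spec.cerebellum_z_frac * rz)

    def prob(mask):
        from scipy import ndimage
        return Volume3D(ndimage.gaussian_filter(mask.astype(float), sigma=0.5,
                                                mode="constant"), aff)

    gm_prob, wm_prob, csf_prob = prob(gm), prob(wm), prob(csf)

    # --- lesion & PET -------------------------------------------------------
    lc = np.asarray(spec.lesion_center)
    lesion_sphere = ((x - lc[0]) ** 2 + (y - lc[1]) ** 2 + (z - lc[2]) ** 2
                     <= spec.lesion_radius ** 2)
    lesion = lesion_sphere & gm
    if not lesion.any():
        raise ValueError("lesion sphere does not intersect gray matter")

    activity0 = (spec.activity_gm * gm_prob.data
                 + spec.activity_wm * wm_prob.data
                 + spec.activity_csf * csf_prob.data)
    activity = activity0.copy()
    activity[lesion] *= (1.0 - spec.hypometabolism_fraction)

    # noise-free asymmetry ground truth (mirror of a symmetric baseline is
    # the baseline itself, so the AI formula reduces to the lesion contrast)
    mirrored = activity[::-1, :, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = 2.0 * (activity + mirrored)
        ai_truth = np.where(denom != 0, (activity - mirrored) / denom * 100.0, np.nan)

    if spec.pet_noise_sd > 0:
        sd = spec.pet_noise_sd * float(activity0[gm].mean())
        noisy = activity + rng.normal(0.0, sd, size=activity.shape)
        activity = np.where(brain, np.maximum(noisy, 0.0), activity)

    # --- tensor field -------------------------------------------------------
    d6 = np.zeros(spec.grid_shape + (6,))
    for mask, adc in ((csf, WATER_DIFFUSIVITY), (gm, spec.gm_diffusivity),
                      (wm, spec.wm_background_diffusivity)):
        d6[mask, 0] = d6[mask, 1] = d6[mask, 2] = adc

    bundles: Dict[str, np.ndarray] = {}
    evals_truth = np.zeros(spec.grid_shape + (3,))
    for mask, adc in ((csf, WATER_DIFFUSIVITY), (gm, spec.gm_diffusivity),
                      (wm, spec.wm_background_diffusivity)):
        evals_truth[mask] = adc

    lam1, lam2, lam3 = spec.wm_lambdas
    lam23 = (lam2 + lam3) / 2.0
    ipsi_side = "left" if spec.lesion_center[0] < 0 else "right"

    for side, sgn in (("left", -1.0), ("right", 1.0)):
        if spec.bundle_geometry == "straight":
            # y-aligned tube at |x| = bundle_offset_x
            bx = sgn * abs(spec.bundle_offset_x)
            in_tube = (((x - bx) ** 2 + (z - spec.bundle_z) ** 2
                        <= spec.bundle_radius ** 2)
                       & (np.abs(y) <= spec.bundle_half_length))
            mask = in_tube & wm
            pts = np.argwhere(mask)
            u = np.tile(np.array([0.0, 1.0, 0.0]), (len(pts), 1))
        else:
            # long association bundle hugging the WM/GM interface: an annulus
            # of in-plane ellipsoid fraction s in [inner, outer], running
            # tangentially around one hemisphere with limited z thickness.
            # The tangent field preserves s, so each fiber stays in its own
            # depth layer for the full arc; layers closer to the cortex (and
            # hence to the lesion) carry more of the graded damage.
            s2d = np.sqrt((x / rx) ** 2 + (y / ry) ** 2)
            in_band = ((s2d >= spec.arc_s_inner) & (s2d <= spec.arc_s_outer)
                       & (np.abs(z - spec.bundle_z) <= spec.bundle_radius)
                       & (sgn * x >= spec.arc_x_margin))
            mask = in_band & wm
            pts = np.argwhere(mask)
            xx = x[tuple(pts.T)]
            yy = y[tuple(pts.T)]
            # tangent of the ellipse (x/rx)^2 + (y/ry)^2 = s^2 at each voxel
            u = np.column_stack([-(rx / ry) * yy, (ry / rx) * xx,
                                 np.zeros(len(pts))])
            n = np.linalg.norm(u, axis=1, keepdims=True)
            u = np.where(n > 1e-12, u / np.where(n > 0, n, 1.0),
                         np.array([0.0, 1.0, 0.0]))
        bundles[side] = mask

        # graded degradation on the lesion's side: a scalar eigenvalue
        # shrink (the injected FA deficit) plus sub-voxel orientation
        # dispersion.  Dispersion of the underlying fibers reduces the
        # voxel-level anisotropy by the orientational order parameter
        # S ~ exp(-2 sigma^2) (1 = perfectly coherent, 0 = isotropic), so
        # next to the lesion — where sigma is largest — the voxel tensor
        # approaches isotropy and tracking cannot propagate, while the far
        # tail of the Gaussian falloff leaves only the mild scalar deficit.
        if side == ipsi_side and spec.fa_deficit_fraction > 0 and len(pts):
            pw = np.column_stack([x[tuple(pts.T)], y[tuple(pts.T)], z[tuple(pts.T)]])
            dist = np.linalg.norm(pw - lc, axis=1)
            w = np.exp(-dist ** 2 / (2.0 * spec.deficit_sigma_mm ** 2))
            f_local = spec.fa_deficit_fraction * w
        else:
            f_local = np.zeros(len(pts))

        sigma_disp = np.deg2rad(spec.dispersion_scale_deg) * f_local
        order_param = np.exp(-2.0 * sigma_disp ** 2)
        shrink = (1.0 - f_local) * order_param
        lbar = (lam1 + lam2 + lam3) / 3.0
        l1 = lbar + shrink * (lam1 - lbar)
        l23 = (lam1 + lam2 + lam3 - l1) / 2.0      # trace preserved

        # residual macroscopic meander of the local fiber axis
        theta = np.abs(rng.normal(0.0, 0.3 * sigma_disp))
        if len(pts):
            p, q = _perpendicular_basis(u)
            az = rng.uniform(0, 2 * np.pi, size=len(pts))
            perp = p * np.cos(az)[:, None] + q * np.sin(az)[:, None]
            u = u * np.cos(theta)[:, None] + perp * np.sin(theta)[:, None]

        sel = tuple(pts.T)
        outer = u[:, :, None] * u[:, None, :]
        dtensor = (l23[:, None, None] * np.eye(3)
                   + (l1 - l23)[:, None, None] * outer)
        d6[sel[0], sel[1], sel[2], 0] = dtensor[:, 0, 0]
        d6[sel[0], sel[1], sel[2], 1] = dtensor[:, 1, 1]
        d6[sel[0], sel[1], sel[2], 2] = dtensor[:, 2, 2]
        d6[sel[0], sel[1], sel[2], 3] = dtensor[:, 0, 1]
        d6[sel[0], sel[1], sel[2], 4] = dtensor[:, 0, 2]
        d6[sel[0], sel[1], sel[2], 5] = dtensor[:, 1, 2]
        evals_truth[sel[0], sel[1], sel[2]] = np.column_stack([l1, l23, l23])

    fa_truth = fa_from_evals(evals_truth)
    fa_truth[~brain] = 0.0

    # partial-volume effect of the acquisition: the generative tensor field
    # is smoothed so tissue interfaces transition over ~1 voxel, as in real
    # 2 mm DWI.  truth.fa stays the analytic FA of the assigned eigenvalue
    # triples (pre-PVE); truth.d6 is the generative (post-PVE) field.
    if spec.pve_sigma_vox > 0:
        from scipy import ndimage as _ndi
        for c in range(6):
            d6[..., c] = _ndi.gaussian_filter(d6[..., c],
                                              sigma=spec.pve_sigma_vox,
                                              mode="constant")
        d6[~brain] = 0.0

    # --- DWI synthesis ------------------------------------------------------
    dwi = None
    if "dwi" in modalities:
        dirs = fibonacci_directions(spec.n_directions)
        bvals = np.concatenate([[0.0], np.full(spec.n_directions, spec.bvalue)])
        bvecs = np.vstack([np.zeros(3), dirs])
        gtab = GradientTable(bvals, bvecs)
        quad = np.column_stack([
            bvecs[:, 0] ** 2, bvecs[:, 1] ** 2, bvecs[:, 2] ** 2,
            2 * bvecs[:, 0] * bvecs[:, 1], 2 * bvecs[:, 0] * bvecs[:, 2],
            2 * bvecs[:, 1] * bvecs[:, 2]])
        signal = np.zeros(spec.grid_shape + (len(bvals),), dtype=np.float32)
        bm = brain
        expo = d6[bm] @ (quad * bvals[:, None]).T   # (M, N): b g^T D g
        signal[bm] = (spec.s0 * np.exp(-expo)).astype(np.float32)
        if spec.dwi_snr > 0:
            sigma = spec.s0 / spec.dwi_snr
            n1 = rng.normal(0.0, sigma, size=signal[bm].shape)
            n2 = rng.normal(0.0, sigma, size=signal[bm].shape)
            signal[bm] = np.sqrt((signal[bm] + n1) ** 2 + n2 ** 2).astype(np.float32)
        dwi = DWIDataset(signal, aff, gtab)

    truth = PhantomTruth(
        lesion_mask=BinaryMask(lesion, aff),
        bundle_masks={s: BinaryMask(m, aff) for s, m in bundles.items()},
        d6=d6,
        fa=Volume3D(fa_truth, aff),
        ai=Volume3D(ai_truth, aff),
        ipsilateral=ipsi_side,
    )
    return Phantom(
        spec=spec,
        pet_activity=Volume3D(activity, aff),
        gm_prob=gm_prob, wm_prob=wm_prob, csf_prob=csf_prob,
        cerebellum_mask=BinaryMask(cereb, aff),
        brain_mask=BinaryMask(brain, aff),
        truth=truth,
        dwi=dwi,
    )


# ---------------------------------------------------------------------------
# cohort


def generate_cohort(n_subjects: int, template: Optional[PhantomSpec] = None,
                    lesion_jitter_mm: float = 4.0,
                    hypometabolism_jitter: float = 0.03,
                    radius_jitter_mm: float = 1.0,
                    rng_seed: int = 0):
    """Per-subject phantom specifications emulating a patient cohort.

    Lesion position (tangentially, within the hemisphere), magnitude and
    radius are jittered around the template; each subject gets its own
    derived RNG seed, so the cohort is reproducible from ``rng_seed``.
    Returns (list of PhantomSpec, manifest DataFrame); phantoms themselves
    are generated one at a time with :func:`generate_phantom` to keep
    memory bounded.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    template = template or PhantomSpec()
    rng = np.random.default_rng(rng_seed)
    specs: List[PhantomSpec] = []
    rows = []
    for i in range(n_subjects):
        dy, dz = rng.uniform(-lesion_jitter_mm, lesion_jitter_mm, size=2)
        dh = rng.uniform(-hypometabolism_jitter, hypometabolism_jitter)
        dr = rng.uniform(-radius_jitter_mm, radius_jitter_mm)
        seed = int(rng.integers(2 ** 31))
        lc = (template.lesion_center[0],
              template.lesion_center[1] + dy,
              template.lesion_center[2] + dz)
        s = replace(template,
                    lesion_center=lc,
                    lesion_radius=template.lesion_radius + dr,
                    hypometabolism_fraction=float(np.clip(
                        template.hypometabolism_fraction + dh, 0.0, 0.99)),
                    rng_seed=seed)
        specs.append(s)
        rows.append({"subject": i, "rng_seed": seed,
                     "lesion_x": lc[0], "lesion_y": lc[1], "lesion_z": lc[2],
                     "lesion_radius": s.lesion_radius,
                     "hypometabolism_fraction": s.hypometabolism_fraction,
                     "fa_deficit_fraction": s.fa_deficit_fraction})
    return specs, pd.DataFrame(rows)
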