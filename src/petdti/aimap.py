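"""FDG-PET asymmetry-index (AI) mapping and hypometabolic ROI extraction.

Pipeline implemented here, in order:

1. SUV map:  ``SUV = C_PET * BW / Dose``  (activity in Bq/mL, body weight in
   g, injected dose in Bq; the g/mL == 1 convention makes SUV unitless).
2. Gaussian smoothing (default FWHM 2 mm).
3. Gray-matter restriction: only voxels with GM probability >= 0.30 enter
   the analysis (the suspected focus is a focal GM abnormality).
4. Cerebellar normalization: SUVr = SUV / mean GM SUV in the cerebellum.
5. Asymmetry index:  ``AI = (I - fI) / (2 (I + fI)) * 100`` where I and fI
   are the SUVr image and its sagittal mirror.  AI is antisymmetric about
   the midline and bounded in (-50, 50) for positive images.
6. Standardization:  ``Z_AI = (X - mu) / sigma`` with mu, sigma the mean and
   standard deviation of AI over GM voxels.
7. Thresholding at the lower-tail Student-t critical value for the cohort's
   degrees of freedom (df = n - 1; df = 13 at alpha = 0.05 gives -1.77) and
   extraction of the largest focal suprathreshold GM cluster as the
   hypometabolic ROI (the suspected epileptic focus).

Negative AI means lower uptake than the homologous contralateral region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .volume import BinaryMask, Volume3D, connected_components, flip_sagittal

__all__ = [
    "SUVParams",
    "AIThreshold",
    "PETROI",
    "compute_suv",
    "apply_gm_mask",
    "normalize_cerebellum",
    "compute_ai",
    "compute_zai",
    "critical_value",
    "extract_roi",
]

#: Minimum cluster volume (mm^3) for a suprathreshold cluster to count as a
#: focal detection.  Clusters on the scale of a single PET resolution
#: element are indistinguishable from noise; the default is the (rounded)
#: 99th percentile of the largest-cluster volume measured on null
#: (symmetric, noisy) phantoms — the usual null-calibrated cluster-extent
#: criterion.  Configurable per run.
DEFAULT_MIN_CLUSTER_MM3 = 150.0


@dataclass
class SUVParams:
    """Subject-level quantities entering the SUV computation.

    body_weight_g : patient body weight in grams.
    injected_dose_bq : net injected FDG dose in Bq.
    gm_fraction_threshold : minimum GM probability for a voxel to enter the
        asymmetry analysis (default 0.30, inclusive).
    smoothing_fwhm_mm : FWHM of the Gaussian applied to the SUV map.
    """

    body_weight_g: float
    injected_dose_bq: float
    gm_fraction_threshold: float = 0.30
    smoothing_fwhm_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.body_weight_g <= 0:
            raise ValueError("body weight must be > 0")
        if self.injected_dose_bq <= 0:
            raise ValueError("injected dose must be > 0")
        if not 0.0 <= self.gm_fraction_threshold <= 1.0:
            raise ValueError("GM fraction threshold must be in [0, 1]")
        if self.smoothing_fwhm_mm < 0:
            raise ValueError("smoothing FWHM must be >= 0")


@dataclass
class AIThreshold:
    """Significance criterion for the standardized asymmetry map.

    Because the AI distribution over a small cohort is unknown, the normal
    z criterion is replaced by the Student-t lower-tail critical value at
    ``alpha`` with ``df = n_subjects - 1`` (Crawford-Garthwaite style small-
    sample correction).  With 14 subjects (df = 13) and alpha = 0.05 the
    criterion is Z_AI < -1.77.
    """

    n_subjects: int = 14
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError("need n_subjects >= 2 (df >= 1)")
        if not 0.0 < self.alpha < 0.5:
            raise ValueError("alpha must be in (0, 0.5)")

    @property
    def df(self) -> int:
        return self.n_subjects - 1

    @property
    def critical_z(self) -> float:
        return critical_value(self)


def critical_value(threshold: AIThreshold) -> float:
    """Lower-tail Student-t critical value at ``alpha`` with ``df`` degrees
    of freedom (a negative number; report rounded to 2 d.p.)."""
    return float(stats.t.ppf(threshold.alpha, threshold.df))


@dataclass
class PETROI:
    """The hypometabolic PET ROI — the suspected epileptic focus.

    ``mask`` is a single connected component of GM voxels with
    Z_AI < critical_z.  ``empty`` flags a run in which no sufficiently
    large focal cluster was found ("no significant hypometabolism").
    """

    mask: BinaryMask
    voxel_count: int
    mean_zai: float
    min_zai: float
    hemisphere: str  # "left" | "right"
    centroid_world: np.ndarray
    empty: bool = False
    secondary_cluster_sizes: list = field(default_factory=list)

    @classmethod
    def none_found(cls, geometry: BinaryMask) -> "PETROI":
        return cls(mask=geometry.like(np.zeros(geometry.shape, dtype=bool)),
                   voxel_count=0, mean_zai=float("nan"), min_zai=float("nan"),
                   hemisphere="none", centroid_world=np.full(3, np.nan),
                   empty=True)

    def summary(self) -> dict:
        return {
            "status": "no significant hypometabolism" if self.empty else "roi found",
            "voxel_count": self.voxel_count,
            "mean_zai": self.mean_zai,
            "min_zai": self.min_zai,
            "hemisphere": self.hemisphere,
            "centroid_world_mm": [float(v) for v in np.atleast_1d(self.centroid_world)],
            "secondary_cluster_sizes": list(self.secondary_cluster_sizes),
        }


# ---------------------------------------------------------------------------


def compute_suv(activity: Volume3D, params: SUVParams) -> Volume3D:
    """Voxel-wise standardized uptake value from an activity map (Bq/mL)."""
    suv = np.asarray(activity.data, dtype=float) * params.body_weight_g / params.injected_dose_bq
    return activity.like(suv)


def apply_gm_mask(gm_prob: Volume3D, threshold: float = 0.30,
                  connectivity: int = 26) -> BinaryMask:
    """Voxels with at least ``threshold`` gray-matter probability (inclusive)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("GM threshold must be in [0, 1]")
    return BinaryMask(np.asarray(gm_prob.data) >= threshold, gm_prob.affine,
                      connectivity)


def normalize_cerebellum(suv: Volume3D, gm_mask: BinaryMask,
                         cerebellum_mask: BinaryMask) -> Volume3D:
    """Scale a SUV map by the mean GM SUV in the cerebellum (global-metabolism
    normalization).  The mean SUVr over the reference region is 1 by
    construction."""
    ref = gm_mask.data & cerebellum_mask.data
    if not ref.any():
        raise ValueError("cerebellar reference region (cerebellum ∩ GM) is empty")
    ref_mean = float(np.nanmean(np.asarray(suv.data, dtype=float)[ref]))
    if not np.isfinite(ref_mean) or ref_mean == 0.0:
        raise ValueError(f"cerebellar reference mean is degenerate ({ref_mean})")
    return suv.like(np.asarray(suv.data, dtype=float) / ref_mean)


def compute_ai(suvr: Volume3D, midline_world_x: float) -> Volume3D:
    """Asymmetry-index map in percent: AI = (I - fI) / (2 (I + fI)) * 100.

    Voxels where I + fI == 0 are undefined (NaN) and excluded from all
    downstream statistics.
    """
    i_img = np.asarray(suvr.data, dtype=float)
    f_img = flip_sagittal(suvr, midline_world_x).data
    denom = 2.0 * (i_img + f_img)
    with np.errstate(divide="ignore", invalid="ignore"):
        ai = np.where(denom != 0.0, (i_img - f_img) / denom * 100.0, np.nan)
    return suvr.like(ai)


def compute_zai(ai: Volume3D, gm_mask: BinaryMask, ddof: int = 0) -> Volume3D:
    """Standardize an AI map by the mean/sd of AI over GM voxels.

    Only GM voxels with a defined (finite) AI enter mu and sigma.  The sd
    convention is population (ddof=0) by default: the GM voxels are treated
    as the distribution itself, not a sample from it.
    """
    ai_data = np.asarray(ai.data, dtype=float)
    sel = gm_mask.data & np.isfinite(ai_data)
    if sel.sum() < 2:
        raise ValueError("need at least 2 GM voxels with defined AI")
    mu = float(ai_data[sel].mean())
    sigma = float(ai_data[sel].std(ddof=ddof))
    if sigma == 0.0:
        raise ValueError("AI standard deviation over GM is zero; Z_AI undefined "
                         "(image is exactly symmetric)")
    return ai.like((ai_data - mu) / sigma)


def extract_roi(zai: Volume3D, gm_mask: BinaryMask, critical_z: float,
                midline_world_x: float = 0.0,
                min_cluster_mm3: float = DEFAULT_MIN_CLUSTER_MM3) -> PETROI:
    """Largest focal GM cluster of voxels with Z_AI below the critical value.

    The suprathreshold GM voxels are decomposed into connected components
    under the GM mask's connectivity; the largest component is the ROI,
    provided it reaches ``min_cluster_mm3`` (focality criterion — clusters
    below one PET resolution element are reported as "no significant
    hypometabolism").  Hemisphere is assigned by the ROI centroid's world-x
    relative to the midline (x < midline = left, RAS convention).
    """
    if critical_z >= 0:
        raise ValueError("critical_z must be negative (lower-tail criterion)")
    zai_data = np.asarray(zai.data, dtype=float)
    with np.errstate(invalid="ignore"):
        supra = gm_mask.data & np.isfinite(zai_data) & (zai_data < critical_z)
    thresh_mask = gm_mask.like(supra)
    comps = connected_components(thresh_mask)
    min_voxels = max(1, int(np.ceil(min_cluster_mm3 / gm_mask.voxel_volume)))
    if not comps or comps[0].size < min_voxels:
        return PETROI.none_found(gm_mask)

    best = comps[0]
    roi = np.zeros(gm_mask.shape, dtype=bool)
    roi[tuple(best.indices.T)] = True
    centroid = gm_mask.index_to_world(best.indices.mean(axis=0))[0]
    zvals = zai_data[roi]
    return PETROI(
        mask=gm_mask.like(roi),
        voxel_count=best.size,
        mean_zai=float(zvals.mean()),
        min_zai=float(zvals.min()),
        hemisphere="left" if centroid[0] < midline_world_x else "right",
        centroid_world=centroid,
        secondary_cluster_sizes=[c.size for c in comps[1:6]],
    )
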