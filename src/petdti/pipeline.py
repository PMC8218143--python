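"""End-to-end orchestration: config validation, the full PET -> tractography
run, and cohort-level analysis.

A run executes, in order: SUV -> smoothing -> GM mask -> cerebellar
normalization -> AI -> Z_AI -> ROI extraction -> VOI placement and
distance-graded seeding (both sides) -> tensor fit -> FA -> tracking ->
bundle metrics -> asymmetry report.  Every stage output is written to the
output directory with a content hash recorded in the run manifest, so an
identical config + seed reproduces identical hashes.  "No significant
hypometabolism" is a clean terminal status, not an error.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from . import aimap, quantify, seeds as seeds_mod, tracking
from .aimap import AIThreshold, PETROI, SUVParams
from .dti import DWIDataset, compute_fa, compute_md, fit_tensor, parse_gradients
from .phantom import Phantom, PhantomSpec, generate_phantom
from .quantify import AsymmetryReport, BundleMetrics, build_report, bundle_metrics
from .seeds import SeedSpec
from .tracking import TrackingParams
from .volume import BinaryMask, Volume3D, default_midline, gaussian_smooth

__all__ = ["PipelineConfig", "InputPaths", "RunResult", "validate_config",
           "run_pipeline", "analyze_subject", "analyze_cohort"]

STATUS_OK = "completed"
STATUS_NO_HYPOMETABOLISM = "no significant hypometabolism"


@dataclass
class InputPaths:
    """Template-space NIfTI inputs for a real-data run."""
    pet_activity: str
    gm_prob: str
    wm_prob: str
    csf_prob: str
    cerebellum_mask: str
    dwi: str
    bval: str
    bvec: str


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "petdti_out"
    phantom: Optional[PhantomSpec] = None
    inputs: Optional[InputPaths] = None
    suv: SUVParams = field(default_factory=lambda: SUVParams(
        body_weight_g=70_000.0, injected_dose_bq=1.9e8))
    threshold: AIThreshold = field(default_factory=AIThreshold)
    seeding: SeedSpec = field(default_factory=SeedSpec)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    tensor_method: str = "nonlinear_ls"
    wm_prob_threshold: float = 0.5
    seed_grid_mm: Optional[float] = 1.0  # build seed regions on this grid
                                         # (None: native voxel grid)
    connectivity: int = 26
    min_cluster_mm3: float = aimap.DEFAULT_MIN_CLUSTER_MM3
    smooth_before_mask: bool = True
    midline_world_x: Optional[float] = None   # None: grid central plane
    upsample_dwi_mm: Optional[float] = None   # e.g. 1.0; None: native grid
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.phantom is None and self.inputs is None:
            self.phantom = PhantomSpec()
        if self.phantom is not None and self.inputs is not None:
            raise ValueError("config must set either 'phantom' or 'inputs', not both")


_SECTION_TYPES = {
    "phantom": PhantomSpec,
    "inputs": InputPaths,
    "suv": SUVParams,
    "threshold": AIThreshold,
    "seeding": SeedSpec,
    "tracking": TrackingParams,
}


def _build_section(cls, payload: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - names
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} under '{path}'")
    kwargs = dict(payload)
    for key in ("distances", "grid_shape", "brain_radii", "lesion_center",
                "wm_lambdas"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    if cls is SeedSpec and "distances" in kwargs:
        kwargs["distances"] = tuple(sorted(kwargs["distances"]))
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config under '{path}': {exc}") from exc


def validate_config(source) -> PipelineConfig:
    """Normalize a YAML file / YAML string / dict into a PipelineConfig.

    Unknown keys and unit violations are rejected with the offending key
    path; defaults (2 mm FWHM, GM threshold 0.30, distances 3/9/15 mm,
    alpha 0.05, ...) are filled; distances are sorted ascending.
    """
    is_file = False
    if isinstance(source, (str, Path)):
        try:
            is_file = Path(str(source)).exists()
        except OSError:  # e.g. a long YAML string, not a path
            is_file = False
    if is_file:
        payload = yaml.safe_load(Path(source).read_text())
    elif isinstance(source, str):
        payload = yaml.safe_load(source)
    else:
        payload = dict(source)
    if payload is None:
        payload = {}
    if not isinstance(payload, dict):
        raise ValueError("config must be a mapping")

    top_names = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(payload) - top_names
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    kwargs = {}
    for key, val in payload.items():
        if key in _SECTION_TYPES:
            if not isinstance(val, dict):
                raise ValueError(f"'{key}' must be a mapping")
            kwargs[key] = _build_section(_SECTION_TYPES[key], val, key)
        else:
            kwargs[key] = val
    try:
        return PipelineConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config: {exc}") from exc


def config_to_yaml(config: PipelineConfig) -> str:
    """Lossless round-trip serialization of a normalized config."""
    d = dataclasses.asdict(config)
    if d.get("phantom") is None:
        d.pop("phantom", None)
    if d.get("inputs") is None:
        d.pop("inputs", None)
    return yaml.safe_dump(d, sort_keys=True)


# ---------------------------------------------------------------------------


def _hash(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


@dataclass
class RunResult:
    status: str
    manifest: Dict[str, str]
    roi: Optional[PETROI] = None
    report: Optional[AsymmetryReport] = None
    ai: Optional[Volume3D] = None
    zai: Optional[Volume3D] = None
    metrics: Optional[Dict[Tuple[str, float], BundleMetrics]] = None


def _load_inputs(paths: InputPaths):
    pet = Volume3D.load(paths.pet_activity)
    gm = Volume3D.load(paths.gm_prob)
    wm = Volume3D.load(paths.wm_prob)
    csf = Volume3D.load(paths.csf_prob)
    cereb = BinaryMask.load(paths.cerebellum_mask)
    import nibabel as nib
    img = nib.load(paths.dwi)
    gtab = parse_gradients(Path(paths.bval).read_text(),
                           Path(paths.bvec).read_text())
    dwi = DWIDataset(np.asarray(img.get_fdata()), img.affine, gtab)
    return pet, gm, wm, csf, cereb, dwi


@dataclass
class AIStageResult:
    suv: Volume3D
    suvr: Volume3D
    ai: Volume3D
    zai: Optional[Volume3D]  # None for an exactly symmetric image
    gm_mask: BinaryMask
    midline: float

    def __iter__(self):  # (ai, zai, gm_mask, midline) unpacking
        return iter((self.ai, self.zai, self.gm_mask, self.midline))


def compute_ai_stage(pet_activity: Volume3D, gm_prob: Volume3D,
                     cerebellum_mask: BinaryMask,
                     config: PipelineConfig) -> AIStageResult:
    """SUV -> smoothing -> GM mask -> cerebellar normalization -> AI -> Z_AI.

    ``zai`` is None for an exactly symmetric image (zero AI variance), which
    downstream treats as "no significant hypometabolism".
    """
    midline = (config.midline_world_x if config.midline_world_x is not None
               else default_midline(pet_activity))
    suv = aimap.compute_suv(pet_activity, config.suv)
    gm_mask = aimap.apply_gm_mask(gm_prob, config.suv.gm_fraction_threshold,
                                  config.connectivity)
    if config.smooth_before_mask:
        suv = gaussian_smooth(suv, config.suv.smoothing_fwhm_mm)
    else:
        masked = np.where(gm_mask.data, suv.data, 0.0)
        suv = gaussian_smooth(suv.like(masked), config.suv.smoothing_fwhm_mm)
    suvr = aimap.normalize_cerebellum(suv, gm_mask, cerebellum_mask)
    ai = aimap.compute_ai(suvr, midline)
    try:
        zai = aimap.compute_zai(ai, gm_mask)
    except ValueError:
        zai = None
    return AIStageResult(suv=suv, suvr=suvr, ai=ai, zai=zai, gm_mask=gm_mask,
                         midline=midline)


@dataclass
class SubjectResult:
    status: str
    ai: Volume3D
    zai: Optional[Volume3D] = None
    roi: Optional[PETROI] = None
    regions: Optional[list] = None
    metrics: Optional[Dict[Tuple[str, float], BundleMetrics]] = None
    fa: Optional[Volume3D] = None
    md: Optional[Volume3D] = None
    bundles: Optional[dict] = None  # (side, distance) -> FiberBundle
    ai_stage: Optional["AIStageResult"] = None


def analyze_subject(pet_activity: Volume3D, gm_prob: Volume3D,
                    wm_prob: Volume3D, cerebellum_mask: BinaryMask,
                    dwi: Optional[DWIDataset], config: PipelineConfig,
                    fit_mask: Optional[np.ndarray] = None,
                    keep_bundles: bool = False) -> SubjectResult:
    """Full single-subject analysis on in-memory volumes."""
    stage = compute_ai_stage(pet_activity, gm_prob, cerebellum_mask, config)
    ai, zai, gm_mask, midline = stage
    if zai is None:
        return SubjectResult(status=STATUS_NO_HYPOMETABOLISM, ai=ai,
                             ai_stage=stage)
    roi = aimap.extract_roi(zai, gm_mask, config.threshold.critical_z,
                            midline, config.min_cluster_mm3)
    if roi.empty:
        return SubjectResult(status=STATUS_NO_HYPOMETABOLISM, ai=ai, zai=zai,
                             roi=roi, ai_stage=stage)

    # seed regions are built on a finer grid (default 1 mm) so the smallest
    # dilation distances contain enough seed voxels; tracking itself stays on
    # the native tensor grid (seed coordinates are world-space)
    if (config.seed_grid_mm is not None
            and config.seed_grid_mm < float(np.min(wm_prob.spacing))):
        from .volume import resample
        wm_fine = resample(wm_prob, config.seed_grid_mm)
        wm_mask = BinaryMask(np.asarray(wm_fine.data) >= config.wm_prob_threshold,
                             wm_fine.affine, config.connectivity)
        roi_fine = resample(Volume3D(roi.mask.data.astype(float), roi.mask.affine),
                            config.seed_grid_mm, order=0)
        roi_for_seeding = dataclasses.replace(
            roi, mask=BinaryMask(roi_fine.data > 0.5, roi_fine.affine,
                                 config.connectivity))
    else:
        wm_mask = BinaryMask(np.asarray(wm_prob.data) >= config.wm_prob_threshold,
                             wm_prob.affine, config.connectivity)
        roi_for_seeding = roi
    spec = dataclasses.replace(config.seeding, midline_world_x=midline)
    regions = seeds_mod.build_seed_regions(roi_for_seeding, wm_mask, spec)

    metrics: Dict[Tuple[str, float], BundleMetrics] = {}
    fa = md = None
    bundles = {} if keep_bundles else None
    if dwi is not None:
        if config.upsample_dwi_mm is not None:
            from .volume import resample
            vols = [resample(Volume3D(dwi.data[..., i], dwi.affine),
                             config.upsample_dwi_mm).data
                    for i in range(dwi.data.shape[3])]
            new_aff = resample(Volume3D(dwi.data[..., 0], dwi.affine),
                               config.upsample_dwi_mm).affine
            dwi = DWIDataset(np.stack(vols, axis=-1), new_aff, dwi.gtab)
        tf = fit_tensor(dwi, mask=fit_mask, method=config.tensor_method)
        fa = compute_fa(tf)
        md = compute_md(tf)
        for ri, region in enumerate(regions):
            key = (region.side, region.distance)
            if region.empty:
                metrics[key] = BundleMetrics.undefined()
                continue
            # one jitter stream per distance, shared by the two sides, so a
            # mirror-symmetric subject gets mirrored seed patterns; seed
            # density (seeds per native-voxel volume) is kept constant when
            # the seed grid is finer than the tensor grid
            density = region.mask.voxel_volume / fa.voxel_volume
            spv = max(1, int(round(config.tracking.seeds_per_voxel * density)))
            tp = dataclasses.replace(
                config.tracking, seeds_per_voxel=spv,
                rng_seed=(config.tracking.rng_seed + ri // 2) % (2 ** 31))
            bundle = tracking.track_bundle(tf, fa, region.mask, tp)
            metrics[key] = bundle_metrics(bundle, fa)
            if keep_bundles:
                bundles[key] = bundle
    return SubjectResult(status=STATUS_OK, ai=ai, zai=zai, roi=roi,
                         regions=regions, metrics=metrics, fa=fa, md=md,
                         bundles=bundles, ai_stage=stage)


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Execute the full pipeline and write all stage outputs + manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, str] = {"seed": str(config.seed)}

    if config.phantom is not None:
        spec = dataclasses.replace(config.phantom, rng_seed=config.seed)
        ph = generate_phantom(spec)
        pet, gm, wm, cereb, dwi = (ph.pet_activity, ph.gm_prob, ph.wm_prob,
                                   ph.cerebellum_mask, ph.dwi)
        ph.write(out / "phantom")
        manifest["phantom"] = _hash(pet.data)
    else:
        pet, gm, wm, _csf, cereb, dwi = _load_inputs(config.inputs)

    sub = analyze_subject(pet, gm, wm, cereb, dwi, config, keep_bundles=True)

    sub.ai.save(out / "ai.nii.gz")
    manifest["ai"] = _hash(sub.ai.data)
    if sub.ai_stage is not None:
        sub.ai_stage.suv.save(out / "suv.nii.gz")
        sub.ai_stage.suvr.save(out / "suvr.nii.gz")
        manifest["suv"] = _hash(sub.ai_stage.suv.data)
    if sub.zai is not None:
        sub.zai.save(out / "zai.nii.gz")
        manifest["zai"] = _hash(sub.zai.data)
    if sub.roi is not None:
        sub.roi.mask.save(out / "roi_mask.nii.gz")
        (out / "roi_summary.json").write_text(
            json.dumps(sub.roi.summary(), indent=2))
        manifest["roi"] = _hash(sub.roi.mask.data.astype(np.uint8))

    report = None
    if sub.status == STATUS_OK and sub.metrics:
        sub.fa.save(out / "fa.nii.gz")
        manifest["fa"] = _hash(sub.fa.data)
        sub.md.save(out / "md.nii.gz")
        from .tracking import save_bundle_jsonl, save_bundle_tck
        seed_manifest = []
        for region in sub.regions:
            name = f"seed_{region.side}_{region.distance:g}mm"
            region.mask.save(out / f"{name}.nii.gz")
            manifest[name] = _hash(region.mask.data.astype(np.uint8))
            seed_manifest.append({
                "side": region.side, "distance_mm": region.distance,
                "voxel_count": int(region.mask.count),
                "voi_center_world_mm": [float(v)
                                        for v in region.source_voi_center]})
        (out / "seed_regions.json").write_text(
            json.dumps(seed_manifest, indent=2))
        for (side, dist), bundle in (sub.bundles or {}).items():
            if bundle.fiber_count:
                stem = f"tracts_{side}_{dist:g}mm"
                save_bundle_tck(bundle, out / f"{stem}.tck")
                save_bundle_jsonl(bundle, out / f"{stem}.jsonl")
        rows = [dict(side=s, distance=d, **m.as_dict())
                for (s, d), m in sub.metrics.items()]
        import pandas as pd
        pd.DataFrame(rows).to_csv(out / "bundle_metrics.csv", index=False)
        report = build_report(sub.metrics)
        (out / "asymmetry_report.json").write_text(report.to_json())
        manifest["metrics"] = hashlib.sha256(
            json.dumps(rows, sort_keys=True, default=float).encode()
        ).hexdigest()[:16]

    manifest["status"] = sub.status
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return RunResult(status=sub.status, manifest=manifest, roi=sub.roi,
                     report=report, ai=sub.ai, zai=sub.zai, metrics=sub.metrics)


# ---------------------------------------------------------------------------
# cohort


def analyze_cohort(specs: List[PhantomSpec], config: Optional[PipelineConfig] = None,
                   fit_wm_only: bool = True) -> AsymmetryReport:
    """Run the full per-subject analysis over a cohort of phantom specs and
    pool the per-subject ipsi/contra ratios into one report (paired Wilcoxon
    across distances, subjects as pairs).

    ``fit_wm_only`` restricts the tensor fit to the white-matter mask, where
    all seeding and tracking happens.
    """
    config = config or PipelineConfig()
    per_side_dist: Dict[Tuple[str, float], List[BundleMetrics]] = {}
    skipped = []
    for i, spec in enumerate(specs):
        ph = generate_phantom(spec)
        cfg = dataclasses.replace(config, phantom=None, inputs=None, seed=spec.rng_seed)
        cfg.phantom = None
        fit_mask = (np.asarray(ph.wm_prob.data) >= config.wm_prob_threshold
                    if fit_wm_only else None)
        sub = analyze_subject(
            ph.pet_activity, ph.gm_prob, ph.wm_prob, ph.cerebellum_mask,
            ph.dwi, cfg, fit_mask=fit_mask)
        if sub.status != STATUS_OK or not sub.metrics:
            skipped.append(i)
            continue
        for key, m in sub.metrics.items():
            per_side_dist.setdefault(key, []).append(m)
    if not per_side_dist:
        raise ValueError("no subject produced a detectable ROI")
    report = build_report(per_side_dist)
    if skipped:
        report.notes.append(f"subjects without detected ROI skipped: {skipped}")
    return report
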