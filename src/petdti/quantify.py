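"""Fiber-bundle metrics, ipsilateral/contralateral ratios, and the exact
Wilcoxon signed-rank test used to compare metrics across seeding distances.

Bundle metrics follow the conventions of interactive tractography tools:

- fiber count: number of retained streamlines;
- mean fiber length (mm): mean of streamline lengths;
- mean FA: length-weighted average of FA along all tracts — each segment
  contributes its length times the FA sampled (trilinear) at its midpoint;
- mean cross-section (mm^2): bundle swept volume (unique voxels touched by
  any streamline times voxel volume) divided by mean fiber length.  This is
  a dimensional surrogate for the average cross-sectional area and is
  isolated here so an alternative definition can be swapped in.

Ipsilateral metrics are normalized to the contralateral homologue; a ratio
of 1 indicates symmetry and < 1 an ipsilateral deficit.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .tracking import FiberBundle
from .volume import Volume3D

__all__ = ["BundleMetrics", "WilcoxonResult", "AsymmetryReport",
           "bundle_metrics", "normalize_ipsi_contra", "wilcoxon_signed_rank",
           "build_report"]

METRIC_NAMES = ("fiber_count", "mean_length", "mean_fa", "mean_cs")

#: largest n for which the exact signed-rank distribution is computed
EXACT_WILCOXON_LIMIT = 25


@dataclass
class BundleMetrics:
    fiber_count: int
    mean_length: float  # mm
    mean_fa: float
    mean_cs: float      # mm^2

    @property
    def defined(self) -> bool:
        return self.fiber_count > 0

    @classmethod
    def undefined(cls) -> "BundleMetrics":
        return cls(0, float("nan"), float("nan"), float("nan"))

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in METRIC_NAMES}


def bundle_metrics(bundle: FiberBundle, fa: Volume3D,
                   voxel_volume: Optional[float] = None) -> BundleMetrics:
    """Quantify a fiber bundle against an FA map.

    ``voxel_volume`` defaults to the FA grid's voxel volume; it is exposed
    because the swept volume should be counted on the grid the streamlines
    were tracked on.
    """
    if bundle.fiber_count == 0:
        return BundleMetrics.undefined()
    if voxel_volume is None:
        voxel_volume = fa.voxel_volume

    lengths = bundle.lengths
    mean_length = float(lengths.mean())

    all_pts = np.vstack([s.points for s in bundle.streamlines])
    fa_data = np.asarray(fa.data, dtype=float)

    # length-weighted FA over all segments, FA at segment midpoints
    mids, wts = [], []
    for s in bundle.streamlines:
        if len(s.points) < 2:
            continue
        seg = np.diff(s.points, axis=0)
        mids.append((s.points[:-1] + s.points[1:]) / 2.0)
        wts.append(np.linalg.norm(seg, axis=1))
    if mids:
        mids = np.vstack(mids)
        wts = np.concatenate(wts)
        idx = fa.world_to_index(mids)
        vals = ndimage.map_coordinates(fa_data, idx.T, order=1, mode="nearest")
        mean_fa = float((vals * wts).sum() / wts.sum())
    else:
        mean_fa = float("nan")

    # swept volume: unique voxels visited by any streamline point
    vox = np.rint(fa.world_to_index(all_pts)).astype(int)
    shape = np.asarray(fa.shape)
    vox = np.clip(vox, 0, shape - 1)
    n_unique = np.unique(np.ravel_multi_index(tuple(vox.T), fa.shape)).size
    mean_cs = float(n_unique * voxel_volume / mean_length) if mean_length > 0 else float("nan")

    return BundleMetrics(fiber_count=bundle.fiber_count,
                         mean_length=mean_length,
                         mean_fa=mean_fa,
                         mean_cs=mean_cs)


def normalize_ipsi_contra(ipsi: BundleMetrics, contra: BundleMetrics) -> Dict[str, float]:
    """Ipsilateral / contralateral ratio for each metric; NaN where the
    contralateral value is zero or undefined."""
    out = {}
    for name in METRIC_NAMES:
        c = getattr(contra, name)
        i = getattr(ipsi, name)
        if not contra.defined or not np.isfinite(c) or c == 0:
            out[name] = float("nan")
        else:
            out[name] = float(i) / float(c)
    return out


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


@dataclass
class WilcoxonResult:
    statistic: float        # W+ = sum of ranks of positive differences
    pvalue: float           # two-sided
    n_used: int             # pairs after dropping zero differences
    n_zeros_dropped: int
    mode: str

    @property
    def defined(self) -> bool:
        return np.isfinite(self.pvalue)


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p for the signed-rank statistic, conditional on the
    observed (mid-)ranks.  The null distribution of W+ = sum over i of
    rank_i * B_i (B_i iid fair signs) is built by dynamic programming over
    doubled ranks (mid-ranks are half-integers)."""
    r2 = np.rint(2 * np.asarray(ranks, dtype=float)).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[:total + 1 - r]
        dist = dist + shifted
    dist /= 2.0 ** len(r2)
    w2 = int(np.rint(2 * w_plus))
    p_le = dist[:w2 + 1].sum()
    p_ge = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(paired_a, paired_b, mode: str = "auto") -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired samples, two-sided.

    Zero differences are dropped; tied magnitudes are mid-ranked.  The exact
    null distribution (all 2^n sign assignments, conditional on observed
    ranks) is used for n <= 25 in 'auto'/'exact' modes; otherwise the normal
    approximation with tie correction and no continuity correction.  With
    every difference zero the p-value is undefined (NaN), flagged rather
    than raised.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired samples must have equal length >= 2")
    if mode not in ("auto", "exact", "normal_approx"):
        raise ValueError(f"unknown mode {mode!r}")
    d = a - b
    nz = d != 0
    n_zeros = int((~nz).sum())
    d = d[nz]
    n = d.size
    if n == 0:
        return WilcoxonResult(float("nan"), float("nan"), 0, n_zeros, mode)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    use_exact = mode == "exact" or (mode == "auto" and n <= EXACT_WILCOXON_LIMIT)
    if mode == "exact" and n > EXACT_WILCOXON_LIMIT:
        raise ValueError(f"exact mode supports n <= {EXACT_WILCOXON_LIMIT}, got {n}")
    if use_exact:
        p = _exact_signed_rank_p(ranks, w_plus)
        used = "exact"
    else:
        mean = n * (n + 1) / 4.0
        # tie correction on the variance
        _, counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (counts ** 3 - counts).sum() / 48.0
        if var <= 0:
            return WilcoxonResult(w_plus, float("nan"), n, n_zeros, "normal_approx")
        z = (w_plus - mean) / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
        used = "normal_approx"
    return WilcoxonResult(w_plus, min(p, 1.0), n, n_zeros, used)


# ---------------------------------------------------------------------------
# report assembly


@dataclass
class AsymmetryReport:
    """Per-distance ipsi/contra ratios and across-distance signed-rank tests.

    ``ratios`` has one row per (subject, distance) with the four metric
    ratios; ``tests`` maps metric -> {(d1, d2): WilcoxonResult} over all
    distance pairs, pairing subjects.  ``notes`` records skipped analyses.
    """

    ratios: pd.DataFrame
    tests: Dict[str, Dict[Tuple[float, float], WilcoxonResult]]
    alpha: float = 0.05
    notes: List[str] = field(default_factory=list)

    def deficit_flags(self) -> pd.DataFrame:
        """Boolean table: ratio < 1 (the hypometabolism-side deficit
        direction) per subject, distance and metric."""
        return self.ratios.set_index(["subject", "distance"])[list(METRIC_NAMES)] < 1.0

    def to_json(self) -> str:
        tests = {
            m: {f"{d1}_vs_{d2}": {"W": r.statistic, "p": r.pvalue,
                                  "n": r.n_used, "mode": r.mode}
                for (d1, d2), r in per.items()}
            for m, per in self.tests.items()
        }
        return json.dumps({"alpha": self.alpha,
                           "ratios": self.ratios.to_dict(orient="records"),
                           "tests": tests, "notes": self.notes}, indent=2,
                          default=float)

    def plot(self, ax=None):
        """Box + strip plot of normalized metrics by distance (one panel per
        metric), mirroring the usual presentation of tract asymmetry."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        metrics = list(METRIC_NAMES)
        fig, axes = plt.subplots(1, len(metrics), figsize=(4 * len(metrics), 4))
        axes = np.atleast_1d(axes)
        for axi, m in zip(axes, metrics):
            groups, dists = [], sorted(self.ratios["distance"].unique())
            for dist in dists:
                groups.append(self.ratios.loc[self.ratios["distance"] == dist, m]
                              .dropna().values)
            axi.boxplot(groups, tick_labels=[f"{d:g} mm" for d in dists])
            for gi, g in enumerate(groups):
                axi.plot(np.full(len(g), gi + 1) +
                         np.linspace(-0.08, 0.08, max(len(g), 1)), g, "k.", ms=4)
            axi.axhline(1.0, color="gray", ls="--", lw=0.8)
            axi.set_title(m)
            axi.set_ylabel("ipsi / contra")
        fig.tight_layout()
        return fig


def build_report(metrics: Dict[Tuple[str, float], "BundleMetrics | list"],
                 alpha: float = 0.05, mode: str = "auto") -> AsymmetryReport:
    """Assemble the asymmetry report from per-side, per-distance metrics.

    ``metrics`` maps (side, distance) -> BundleMetrics (single subject) or a
    list of BundleMetrics (one per subject, pooled mode).  Sides must be
    'ipsilateral' and 'contralateral' and each distance must be present for
    both sides.  Wilcoxon comparisons across distances are run per metric on
    the paired per-subject ratios; with a single distance or a single
    subject the tests are skipped with a notice.
    """
    sides = {s for s, _ in metrics}
    if sides != {"ipsilateral", "contralateral"}:
        raise ValueError(f"need both sides, got {sorted(sides)}")
    distances = sorted({d for _, d in metrics})
    rows = []
    for d in distances:
        ipsi = metrics[("ipsilateral", d)]
        contra = metrics[("contralateral", d)]
        ipsi_list = ipsi if isinstance(ipsi, (list, tuple)) else [ipsi]
        contra_list = contra if isinstance(contra, (list, tuple)) else [contra]
        if len(ipsi_list) != len(contra_list):
            raise ValueError("ipsilateral and contralateral subject counts differ")
        for subj, (im, cm) in enumerate(zip(ipsi_list, contra_list)):
            row = {"subject": subj, "distance": float(d)}
            row.update(normalize_ipsi_contra(im, cm))
            rows.append(row)
    ratios = pd.DataFrame(rows)

    tests: Dict[str, Dict[Tuple[float, float], WilcoxonResult]] = {}
    notes: List[str] = []
    n_subjects = ratios["subject"].nunique()
    if len(distances) < 2:
        notes.append("single distance: across-distance tests skipped")
    elif n_subjects < 2:
        notes.append("fewer than 2 paired observations: tests skipped")
    else:
        wide = ratios.pivot(index="subject", columns="distance")
        for m in METRIC_NAMES:
            tests[m] = {}
            for d1, d2 in itertools.combinations(distances, 2):
                a = wide[(m, d1)].values
                b = wide[(m, d2)].values
                ok = np.isfinite(a) & np.isfinite(b)
                if ok.sum() < 2:
                    notes.append(f"{m} {d1} vs {d2}: <2 defined pairs, skipped")
                    continue
                tests[m][(d1, d2)] = wilcoxon_signed_rank(a[ok], b[ok], mode)
    return AsymmetryReport(ratios=ratios, tests=tests, alpha=alpha, notes=notes)
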