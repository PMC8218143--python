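"""Diffusion-tensor fitting: gradient tables, tensor estimation, FA.

The single-tensor model per voxel is

    S_i = S0 * exp(-b_i * g_i^T D g_i)

with D a symmetric positive 3x3 tensor (mm^2/s).  Two estimators are
provided: ``linear_ls`` solves the log-linearized system (exact on
noise-free data), and ``nonlinear_ls`` refines the linear solution by
damped Gauss-Newton least squares on the exponential model, which is the
better-behaved estimator under Rician noise.  Both are fully vectorized
over voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .volume import Volume3D

__all__ = [
    "GradientTable",
    "DWIDataset",
    "TensorField",
    "parse_gradients",
    "fit_tensor",
    "compute_fa",
    "compute_md",
]

_BVEC_NORM_TOL = 1e-3


@dataclass
class GradientTable:
    """b-values (s/mm^2) and unit gradient directions, FSL convention.

    The zero vector is allowed (and expected) for b=0 entries.  Tensor
    fitting requires at least one b=0 measurement and at least 6 unique
    non-collinear nonzero directions (directions equal up to sign count
    once).
    """

    bvals: np.ndarray
    bvecs: np.ndarray  # (N, 3)

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape != (self.bvals.size, 3):
            raise ValueError(
                f"bvecs shape {self.bvecs.shape} does not match "
                f"{self.bvals.size} b-values")
        nz = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[nz], axis=1)
        bad = np.abs(norms - 1.0) > _BVEC_NORM_TOL
        if bad.any():
            rows = np.flatnonzero(nz)[bad]
            raise ValueError(
                f"gradient direction(s) at column(s) {rows.tolist()} have "
                f"norm(s) {norms[bad].round(4).tolist()}, outside the "
                f"renormalization tolerance {_BVEC_NORM_TOL}")
        # renormalize small deviations
        self.bvecs = self.bvecs.copy()
        self.bvecs[nz] /= norms[:, None]
        if not (~nz).any():
            raise ValueError("gradient table has no b=0 entry")
        if self.n_unique_directions < 6:
            raise ValueError(
                f"only {self.n_unique_directions} unique nonzero directions; "
                "tensor fitting needs >= 6")

    @property
    def n_unique_directions(self) -> int:
        nz = self.bvecs[self.bvals > 0]
        # canonicalize sign so antipodal pairs count once
        canon = nz * np.sign(nz[:, [0]] + 1e-12 * (nz[:, [1]] + 1e-12 * nz[:, [2]]))
        return np.unique(np.round(canon, 6), axis=0).shape[0]

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    def design_matrix(self) -> np.ndarray:
        """(N, 7) design: columns [1, -b gx^2, -b gy^2, -b gz^2,
        -2b gxgy, -2b gxgz, -2b gygz] acting on [ln S0, Dxx, Dyy, Dzz,
        Dxy, Dxz, Dyz]."""
        g = self.bvecs
        b = self.bvals
        quad = np.column_stack([
            g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2],
        ])
        return np.column_stack([np.ones_like(b), -b[:, None] * quad])


def parse_gradients(bval_text: str, bvec_text: str) -> GradientTable:
    """Parse FSL-layout gradient files (bvals: one row; bvecs: 3 rows x N)."""
    try:
        bvals = np.array([float(tok) for tok in bval_text.split()])
    except ValueError as exc:
        raise ValueError(f"non-numeric token in bvals: {exc}") from exc
    rows = [ln for ln in bvec_text.splitlines() if ln.strip()]
    if len(rows) != 3:
        raise ValueError(f"bvecs must have 3 rows (FSL layout), got {len(rows)}")
    try:
        mat = np.array([[float(tok) for tok in ln.split()] for ln in rows])
    except ValueError as exc:
        raise ValueError(f"non-numeric token in bvecs: {exc}") from exc
    if mat.shape[1] != bvals.size:
        raise ValueError(
            f"bvals has {bvals.size} entries but bvecs has {mat.shape[1]} columns")
    return GradientTable(bvals, mat.T)


@dataclass
class DWIDataset:
    """4-D diffusion-weighted signal volume plus its gradient table."""

    data: np.ndarray  # (X, Y, Z, N)
    affine: np.ndarray
    gtab: GradientTable

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DWI data must be 4-D")
        if self.data.shape[3] != self.gtab.bvals.size:
            raise ValueError(
                f"4th dimension ({self.data.shape[3]}) does not match gradient "
                f"table length ({self.gtab.bvals.size})")

    @property
    def spacing(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensor with its eigen-system.

    ``d6`` stores the unique components in the order
    (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz), mm^2/s.  Eigenvalues are sorted
    descending; negative eigenvalues are clamped to 0 for scalar maps and
    the number of clamped voxels is recorded in ``n_clamped``.
    """

    d6: np.ndarray          # (X, Y, Z, 6)
    affine: np.ndarray
    mask: np.ndarray        # (X, Y, Z) bool: voxels actually fitted
    evals: np.ndarray = field(default=None, repr=False)  # (X, Y, Z, 3) desc
    e1: np.ndarray = field(default=None, repr=False)     # (X, Y, Z, 3) unit
    s0: np.ndarray = field(default=None, repr=False)
    n_clamped: int = 0

    def __post_init__(self) -> None:
        if self.evals is None:
            self._eigendecompose()

    def _tensor33(self) -> np.ndarray:
        d = self.d6
        t = np.zeros(d.shape[:-1] + (3, 3))
        t[..., 0, 0] = d[..., 0]
        t[..., 1, 1] = d[..., 1]
        t[..., 2, 2] = d[..., 2]
        t[..., 0, 1] = t[..., 1, 0] = d[..., 3]
        t[..., 0, 2] = t[..., 2, 0] = d[..., 4]
        t[..., 1, 2] = t[..., 2, 1] = d[..., 5]
        return t

    def _eigendecompose(self) -> None:
        shape = self.d6.shape[:-1]
        self.evals = np.zeros(shape + (3,))
        self.e1 = np.zeros(shape + (3,))
        m = self.mask
        if m.any():
            t = self._tensor33()[m]
            w, v = np.linalg.eigh(t)          # ascending
            w = w[:, ::-1]
            v = v[:, :, ::-1]
            neg = (w < 0).any(axis=1)
            self.n_clamped = int(neg.sum())
            self.evals[m] = np.maximum(w, 0.0)
            self.e1[m] = v[:, :, 0]

    @property
    def shape(self) -> tuple:
        return self.d6.shape[:-1]


def _masked_wls(design: np.ndarray, log_s: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Per-voxel least squares of ``design @ gamma = log_s`` using only the
    measurements flagged valid in each voxel.  Shapes: design (N, 7),
    log_s (M, N), valid (M, N) -> gamma (M, 7)."""
    w = valid.astype(float)
    n, k = design.shape
    # normal equations per voxel: (X^T W X) gamma = X^T W y, computed as a
    # matrix product against the precomputed per-measurement outer products
    outer = (design[:, :, None] * design[:, None, :]).reshape(n, k * k)
    xtwx = (w @ outer).reshape(-1, k, k)
    xtwy = np.where(valid, w * log_s, 0.0) @ design
    try:
        return np.linalg.solve(xtwx, xtwy[..., None])[..., 0]
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular design matrix in tensor fit") from exc


def _gauss_newton(design: np.ndarray, signals: np.ndarray, gamma0: np.ndarray,
                  n_iter: int = 30, lam0: float = 1e-6,
                  tol: float = 1e-12) -> np.ndarray:
    """Damped Gauss-Newton on S = exp(X gamma), vectorized over voxels.

    Levenberg-style diagonal damping is increased per-voxel whenever a step
    fails to reduce the residual sum of squares.
    """
    gamma = gamma0.copy()
    m = gamma.shape[0]
    n, k = design.shape
    lam = np.full(m, lam0)
    pred = np.exp(np.clip(gamma @ design.T, -700, 700))
    cost = ((signals - pred) ** 2).sum(axis=1)
    eye = np.eye(k)
    outer = (design[:, :, None] * design[:, None, :]).reshape(n, k * k)
    for _ in range(n_iter):
        r = signals - pred                       # (M, N)
        jtj = (pred ** 2 @ outer).reshape(m, k, k)
        jtr = (pred * r) @ design
        step = np.linalg.solve(jtj + lam[:, None, None] * eye, jtr[..., None])[..., 0]
        cand = gamma + step
        cand_pred = np.exp(np.clip(cand @ design.T, -700, 700))
        cand_cost = ((signals - cand_pred) ** 2).sum(axis=1)
        better = cand_cost <= cost
        gamma[better] = cand[better]
        pred[better] = cand_pred[better]
        improvement = cost[better] - cand_cost[better]
        cost = np.where(better, cand_cost, cost)
        lam = np.where(better, np.maximum(lam * 0.3, 1e-12), lam * 10.0)
        if better.all() and (improvement <= tol * (cost[better] + 1e-300)).all():
            break
    return gamma


def fit_tensor(dwi: DWIDataset, mask: Optional[np.ndarray] = None,
               method: str = "nonlinear_ls", chunk: int = 20000) -> TensorField:
    """Fit the single-tensor model per voxel.

    method='linear_ls' solves the log-linear system (exact inverse on
    noise-free data); method='nonlinear_ls' refines from the linear solution
    by Gauss-Newton on the exponential model.  Non-positive signals are
    excluded per voxel from the log-linear stage; voxels with no positive
    b=0 signal are excluded from the fit entirely.
    """
    if method not in ("linear_ls", "nonlinear_ls"):
        raise ValueError(f"unknown method {method!r}")
    data = dwi.data
    shape = data.shape[:3]
    if mask is None:
        mask = data[..., dwi.gtab.b0_mask].mean(axis=-1) > 0
    mask = np.asarray(mask, dtype=bool)
    s0_ok = (data[..., dwi.gtab.b0_mask] > 0).any(axis=-1)
    fit_mask = mask & s0_ok

    design = dwi.gtab.design_matrix()
    d6 = np.zeros(shape + (6,))
    s0 = np.zeros(shape)
    flat_idx = np.flatnonzero(fit_mask.ravel())
    sig_all = data.reshape(-1, data.shape[3])

    gammas = np.zeros((flat_idx.size, 7))
    for start in range(0, flat_idx.size, chunk):
        sel = flat_idx[start:start + chunk]
        sig = sig_all[sel]
        valid = sig > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            log_s = np.where(valid, np.log(np.where(valid, sig, 1.0)), 0.0)
        gamma = _masked_wls(design, log_s, valid)
        if method == "nonlinear_ls":
            gamma = _gauss_newton(design, sig, gamma)
        gammas[start:start + chunk] = gamma

    d6.reshape(-1, 6)[flat_idx] = gammas[:, 1:]
    s0.reshape(-1)[flat_idx] = np.exp(gammas[:, 0])
    return TensorField(d6=d6, affine=np.asarray(dwi.affine, dtype=float),
                       mask=fit_mask, s0=s0)


def fa_from_evals(evals: np.ndarray) -> np.ndarray:
    """Fractional anisotropy from eigenvalue triples (last axis length 3).

    FA = sqrt(3/2) * ||lambda - mean||  / ||lambda||, in [0, 1];
    FA = 0 where all eigenvalues are 0.
    """
    evals = np.asarray(evals, dtype=float)
    mean = evals.mean(axis=-1, keepdims=True)
    num = np.sqrt((3.0 / 2.0) * ((evals - mean) ** 2).sum(axis=-1))
    den = np.sqrt((evals ** 2).sum(axis=-1))
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.where(den > 0, num / den, 0.0)
    return np.clip(fa, 0.0, 1.0)


def compute_fa(tf: TensorField) -> Volume3D:
    """Fractional anisotropy map of a tensor field (0 outside the fit mask)."""
    fa = fa_from_evals(tf.evals)
    fa[~tf.mask] = 0.0
    return Volume3D(fa, tf.affine)


def compute_md(tf: TensorField) -> Volume3D:
    """Mean diffusivity map (mm^2/s)."""
    md = tf.evals.mean(axis=-1)
    md[~tf.mask] = 0.0
    return Volume3D(md, tf.affine)
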