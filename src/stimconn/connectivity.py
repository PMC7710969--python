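"""First-level functional-connectivity metrics.

Five analyses, all computed on denoised, standardized, run-concatenated
BOLD residuals:

* ``fisher_z`` / ``interhemispheric_fc`` — Fisher-transformed Pearson
  correlation between the mean series of two seed spheres (the left/right
  M1 interhemispheric connection).
* ``intrinsic_connectivity`` — IC(x) = sqrt(sum_y r(x,y)^2 / N), the root
  mean square of a voxel's correlations with every in-mask voxel, a
  voxel-wise network-centrality measure.  Computed through a truncated
  SVD of the standardized voxel x time matrix (default 64 components),
  which reproduces the brute-force definition exactly when the truncation
  order reaches the matrix rank.
* ``local_correlation`` — LCOR(x), the Gaussian-weighted average of
  correlations between x and its spatial neighbours (default FWHM 8 mm,
  offsets measured in mm so anisotropic voxels are handled correctly).
* ``seed_to_voxel`` — Fisher-z map of correlation with a seed-mean series.
* ``roi_mean`` — average of any map over a seed sphere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .images import BoldImage, RoiSphere

DEFAULT_IC_COMPONENTS = 64
DEFAULT_LCOR_FWHM_MM = 8.0
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class AnalysisMask:
    """The set M of in-analysis voxels."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, bool)
        if self.data.ndim != 3:
            raise ValueError("analysis mask must be 3D")
        if self.n_voxels < 2:
            raise ValueError("analysis mask needs at least 2 voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class KernelSpec:
    """Isotropic Gaussian weighting kernel, parameterised by FWHM in mm."""

    fwhm_mm: float = DEFAULT_LCOR_FWHM_MM
    truncate_sigmas: float = 3.0

    def __post_init__(self) -> None:
        if self.fwhm_mm <= 0:
            raise ValueError("FWHM must be positive")

    @property
    def sigma_mm(self) -> float:
        return self.fwhm_mm * FWHM_TO_SIGMA

    def weight(self, offset_mm: np.ndarray) -> np.ndarray:
        d2 = np.sum(np.atleast_2d(offset_mm) ** 2, axis=-1)
        return np.exp(-d2 / (2.0 * self.sigma_mm**2))


@dataclass
class ConnectivityMap:
    """3D per-voxel statistic map tied to an analysis mask."""

    data: np.ndarray
    metric: str
    mask: np.ndarray
    normalized: bool = False
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        self.mask = np.asarray(self.mask, bool)
        if self.data.shape != self.mask.shape:
            raise ValueError("map and mask shapes differ")
        if not np.all(np.isfinite(self.data[self.mask])):
            raise ValueError("non-finite values inside the analysis mask")

    def normalize(self) -> "ConnectivityMap":
        """Z-score across in-mask voxels (session-level scale removal)."""
        vals = self.data[self.mask]
        sd = vals.std(ddof=1)
        if sd == 0:
            raise ValueError("cannot normalize a constant map")
        out = np.zeros_like(self.data)
        out[self.mask] = (vals - vals.mean()) / sd
        return ConnectivityMap(out, self.metric, self.mask, normalized=True,
                               affine=self.affine)


def fisher_z(r):
    """Variance-stabilizing atanh transform of a Pearson correlation."""
    r = np.asarray(r, float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("|r| must be < 1 for the Fisher transform")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    """Demean each row and scale to unit norm, so X Xᵀ is the correlation
    matrix.  Zero-variance rows raise."""
    X = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-variance series in the analysis set")
    return X / norms


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-variance series")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def interhemispheric_fc(
    bold: BoldImage, left: RoiSphere, right: RoiSphere
) -> float:
    """Fisher-z of the correlation between the two seed-mean series."""
    r = _pearson(left.mean_series(bold), right.mean_series(bold))
    if abs(r) >= 1.0 - 1e-12:
        raise ValueError(f"degenerate seed correlation r={r:+.3f} (|r| >= 1)")
    return fisher_z(r)


def _masked_standardized(bold: BoldImage, mask: AnalysisMask):
    """Drop zero-variance voxels from M (with a warning), return the
    surviving mask and the row-standardized voxel x time matrix."""
    m = mask.data.copy()
    X = bold.data[m]
    sd = X.std(axis=1)
    dead = sd == 0
    if dead.any():
        warnings.warn(f"dropping {int(dead.sum())} zero-variance voxel(s) from "
                      "the analysis mask", stacklevel=3)
        coords = np.argwhere(m)[dead]
        m[tuple(coords.T)] = False
        X = X[~dead]
    if X.shape[0] < 2:
        raise ValueError("fewer than 2 usable voxels in the analysis mask")
    return m, _standardize_rows(X)


@dataclass
class ICParams:
    n_components: int = DEFAULT_IC_COMPONENTS
    normalize: bool = False

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")


def intrinsic_connectivity(
    bold: BoldImage,
    mask: AnalysisMask,
    params: ICParams | None = None,
) -> ConnectivityMap:
    """IC(x) = sqrt(sum over y in M of r(x,y)^2 / N), including the self
    term y = x, via rank-K truncated SVD of the standardized matrix.

    With standardized rows X, the correlation matrix is C = X Xᵀ =
    U S² Uᵀ, so row norms of the rank-K reconstruction are the row norms
    of U_K S_K²; no N x N matrix is ever formed.
    """
    params = params or ICParams()
    m, X = _masked_standardized(bold, mask)
    N = X.shape[0]
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12))
    K = min(params.n_components, rank)
    ic = np.sqrt(np.sum((U[:, :K] * s[:K] ** 2) ** 2, axis=1) / N)
    out = np.zeros(m.shape)
    out[m] = ic
    cmap = ConnectivityMap(out, "IC", m, affine=bold.affine)
    return cmap.normalize() if params.normalize else cmap


def intrinsic_connectivity_bruteforce(
    bold: BoldImage, mask: AnalysisMask
) -> ConnectivityMap:
    """Direct N x N correlation-matrix evaluation of IC (reference path
    for small instances)."""
    m, X = _masked_standardized(bold, mask)
    C = X @ X.T
    ic = np.sqrt((C**2).sum(axis=1) / C.shape[0])
    out = np.zeros(m.shape)
    out[m] = ic
    return ConnectivityMap(out, "IC", m, affine=bold.affine)


def local_correlation(
    bold: BoldImage,
    mask: AnalysisMask,
    kernel: KernelSpec | None = None,
) -> ConnectivityMap:
    """LCOR(x) = sum_y w(x-y) r(x,y) / sum_y w(x-y), with Gaussian weights
    on mm offsets, truncated beyond ``kernel.truncate_sigmas`` sigma.

    The self term (offset 0, r = 1) is part of the neighbourhood, as in
    the defining sum over all in-mask voxels.
    """
    kernel = kernel or KernelSpec()
    m, X = _masked_standardized(bold, mask)
    shape = m.shape
    Z = np.zeros((*shape, X.shape[1]))
    Z[m] = X
    voxel_mm = np.abs(np.diag(bold.affine[:3, :3]))
    r_mm = kernel.truncate_sigmas * kernel.sigma_mm
    max_off = np.floor(r_mm / voxel_mm).astype(int)
    if np.all(max_off == 0):
        raise ValueError("kernel truncation radius below one voxel")
    num = np.zeros(shape)
    den = np.zeros(shape)
    inmask = m.astype(float)
    for dx in range(-max_off[0], max_off[0] + 1):
        for dy in range(-max_off[1], max_off[1] + 1):
            for dz in range(-max_off[2], max_off[2] + 1):
                off_mm = np.array([dx, dy, dz]) * voxel_mm
                if np.linalg.norm(off_mm) > r_mm:
                    continue
                w = float(kernel.weight(off_mm)[0])
                shifted = np.roll(Z, (dx, dy, dz), axis=(0, 1, 2))
                shifted_mask = np.roll(inmask, (dx, dy, dz), axis=(0, 1, 2))
                # zero out wrap-around
                valid = np.ones(shape, dtype=bool)
                for ax, d in enumerate((dx, dy, dz)):
                    if d > 0:
                        valid &= np.arange(shape[ax]).reshape(
                            [-1 if a == ax else 1 for a in range(3)]) >= d
                    elif d < 0:
                        valid &= np.arange(shape[ax]).reshape(
                            [-1 if a == ax else 1 for a in range(3)]) < shape[ax] + d
                ok = valid & (shifted_mask > 0)
                r_off = np.einsum("...t,...t->...", Z, shifted)
                num += np.where(ok, w * r_off, 0.0)
                den += np.where(ok, w, 0.0)
    if np.any((den == 0) & m):
        raise ValueError("empty neighbourhood for some mask voxel")
    out = np.zeros(shape)
    out[m] = num[m] / den[m]
    return ConnectivityMap(out, "LCOR", m, affine=bold.affine)


def seed_to_voxel(
    bold: BoldImage, seed: RoiSphere, mask: AnalysisMask
) -> ConnectivityMap:
    """Fisher-z map of each voxel's correlation with the seed-mean series.

    Correlations within 1e-12 of |r| = 1 (e.g. the seed's own voxel for a
    single-voxel seed) are clipped to that guard value before the
    transform rather than mapped to infinity.
    """
    s = seed.mean_series(bold)
    s = s - s.mean()
    ns = np.linalg.norm(s)
    if ns == 0:
        raise ValueError("zero-variance seed series")
    m, X = _masked_standardized(bold, mask)
    r = X @ (s / ns)
    guard = 1.0 - 1e-12
    z = np.arctanh(np.clip(r, -guard, guard))
    out = np.zeros(m.shape)
    out[m] = z
    return ConnectivityMap(out, "seed_z", m, affine=bold.affine)


def roi_mean(cmap: ConnectivityMap, roi: RoiSphere) -> float:
    """Arithmetic mean of the map over the ROI voxels inside the mask."""
    roi_mask = roi.mask(cmap.data.shape)
    sel = roi_mask & cmap.mask
    if not sel.any():
        raise ValueError("ROI does not intersect the analysis mask")
    return float(cmap.data[sel].mean())
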