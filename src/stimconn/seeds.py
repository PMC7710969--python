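"""Subject-specific motor seeds from task fMRI.

A block general linear model (boxcar convolved with the canonical HRF,
plus a high-pass cosine basis and an intercept) yields a task-versus-rest
t-map; the peak voxel inside an anatomically allowed mask becomes the
centre of a 6-mm spherical region of interest.  Peaks outside the allowed
mask are skipped in rank order — the fallback used when a task peak lands
implausibly far from motor cortex (e.g. in the cerebellum).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .images import BoldImage, RoiSphere
from .preprocess import build_highpass_basis
from .synthetic import FWHM_TO_SIGMA, BlockDesign, expected_response


@dataclass
class TMap:
    """Per-voxel t statistic with its degrees of freedom."""

    data: np.ndarray
    df: int
    contrast: str = "task>rest"
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 3:
            raise ValueError("t-map must be 3D")


def run_block_glm(
    task_bold: BoldImage,
    design: BlockDesign,
    smooth_fwhm_mm: float = 6.0,
    highpass_hz: float = 0.009,
) -> TMap:
    """Voxel-wise OLS of [HRF-convolved boxcar, cosine basis, intercept];
    t = contrast estimate / its standard error.

    Spatial smoothing (Gaussian, default FWHM 6 mm) is applied before the
    fit, matching standard volumetric task preprocessing; pass 0 to skip.
    """
    if design.n_volumes != task_bold.n_volumes:
        raise ValueError("design must cover all volumes")
    data = task_bold.data
    if smooth_fwhm_mm > 0:
        voxel_mm = np.abs(np.diag(task_bold.affine[:3, :3]))
        sigma = smooth_fwhm_mm * FWHM_TO_SIGMA / voxel_mm
        data = ndimage.gaussian_filter(data, sigma=(*sigma, 0.0))
    resp = expected_response(design)
    hp = build_highpass_basis(design.n_volumes, design.tr, highpass_hz).matrix
    X = np.column_stack([resp, hp, np.ones(design.n_volumes)])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient task design")
    T = design.n_volumes
    df = T - rank
    pinv = np.linalg.pinv(X)
    Y = data.reshape(-1, T).T  # (T, voxels)
    beta = pinv @ Y
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    c = np.zeros(X.shape[1])
    c[0] = 1.0
    var_c = c @ np.linalg.inv(X.T @ X) @ c
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (c @ beta) / np.sqrt(sigma2 * var_c)
    t = np.where(np.isfinite(t), t, 0.0)
    return TMap(t.reshape(task_bold.grid_shape), df=df, affine=task_bold.affine)


def resolve_sphere(
    center_mm: np.ndarray,
    radius_mm: float,
    affine: np.ndarray,
    grid_shape: tuple[int, int, int],
) -> np.ndarray:
    """All voxel indices whose centres lie within ``radius_mm`` of
    ``center_mm`` (clipped at the grid boundary)."""
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    center_mm = np.asarray(center_mm, float).reshape(3)
    inv = np.linalg.inv(affine)
    c_vox = inv[:3, :3] @ center_mm + inv[:3, 3]
    # candidate bounding box in voxel space
    scale = np.abs(np.diag(affine[:3, :3]))
    lo = np.maximum(np.floor(c_vox - radius_mm / scale - 1), 0).astype(int)
    hi = np.minimum(np.ceil(c_vox + radius_mm / scale + 1) + 1,
                    np.asarray(grid_shape)).astype(int)
    if np.any(lo >= hi):
        raise ValueError("sphere lies entirely outside the grid")
    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    idx = np.stack([g.ravel() for g in grids], axis=1)
    mm = idx @ affine[:3, :3].T + affine[:3, 3]
    keep = np.linalg.norm(mm - center_mm, axis=1) <= radius_mm
    out = idx[keep]
    if out.shape[0] == 0:
        raise ValueError("sphere resolves to no voxel centres inside the grid")
    return out


def pick_peak_seed(
    tmap: TMap,
    allowed_mask: np.ndarray,
    radius_mm: float = 6.0,
    affine: np.ndarray | None = None,
    side: str = "left",
) -> RoiSphere:
    """Sphere centred on the highest-t voxel inside ``allowed_mask``.

    Voxels outside the mask are skipped in descending-t order (the
    anatomical fallback: if the global peak is implausible, the next
    highest admissible voxel is used).  Ties break on the lowest linear
    voxel index, so selection is deterministic.
    """
    allowed_mask = np.asarray(allowed_mask, bool)
    if allowed_mask.shape != tmap.data.shape:
        raise ValueError("mask shape must match the t-map")
    if not allowed_mask.any():
        raise ValueError("allowed mask is empty")
    affine = affine if affine is not None else tmap.affine
    if affine is None:
        raise ValueError("an affine is required to place the sphere in mm")
    t = tmap.data.ravel()
    ok = allowed_mask.ravel() & np.isfinite(t)
    if not ok.any():
        raise ValueError("no voxel in the mask has a finite t value")
    # stable argsort descending; ties resolved toward the lower linear index
    order = np.argsort(-t, kind="stable")
    best = order[ok[order]][0]
    center_vox = np.array(np.unravel_index(best, tmap.data.shape))
    center_mm = affine[:3, :3] @ center_vox + affine[:3, 3]
    voxels = resolve_sphere(center_mm, radius_mm, affine, tmap.data.shape)
    return RoiSphere(center_mm=center_mm, radius_mm=radius_mm, voxel_set=voxels,
                     side=side)


def box_mask(
    grid_shape: tuple[int, int, int],
    affine: np.ndarray,
    mm_min: np.ndarray,
    mm_max: np.ndarray,
) -> np.ndarray:
    """Axis-aligned mm box as a voxel mask (anatomical 'expected region')."""
    idx = np.indices(grid_shape).reshape(3, -1).T
    mm = idx @ affine[:3, :3].T + affine[:3, 3]
    keep = np.all((mm >= np.asarray(mm_min)) & (mm <= np.asarray(mm_max)), axis=1)
    return keep.reshape(grid_shape)
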