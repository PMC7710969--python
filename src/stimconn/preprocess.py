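"""Resting-state denoising: outlier scrubbing regressors, aCompCor,
DCT high-pass basis, and simultaneous nuisance regression.

The denoising recipe mirrors the common toolbox practice for seed-based
resting-state analysis: flag volumes that are outliers in global signal
or framewise displacement, build a confound matrix (6 motion parameters,
their first temporal derivatives, k principal components of the noise-ROI
signal, one indicator column per outlier volume, and a discrete-cosine
high-pass basis below 0.009 Hz), and regress everything out of every
voxel in a single OLS.  Filtering and nuisance removal therefore commute
by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .images import BoldImage, MotionTrace

DEFAULT_Z_THRESH = 5.0
DEFAULT_FD_THRESH = 0.9  # mm
DEFAULT_HIGHPASS_HZ = 0.009


@dataclass
class OutlierMask:
    flags: np.ndarray  # (n_volumes,) bool
    z_thresh: float
    fd_thresh: float

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool).ravel()

    @property
    def n_outliers(self) -> int:
        return int(self.flags.sum())

    def indicator_columns(self) -> np.ndarray:
        """One 0/1 column per flagged volume (scrubbing regressors)."""
        idx = np.flatnonzero(self.flags)
        cols = np.zeros((self.flags.size, idx.size))
        cols[idx, np.arange(idx.size)] = 1.0
        return cols


@dataclass
class ConfoundSet:
    """Per-volume nuisance regressor matrix with column labels."""

    matrix: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, float))
        if self.matrix.ndim != 2:
            raise ValueError("confound matrix must be 2D (volumes x regressors)")
        if not self.labels:
            self.labels = [f"conf_{i}" for i in range(self.matrix.shape[1])]
        if len(self.labels) != self.matrix.shape[1]:
            raise ValueError("labels must match confound columns")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    @staticmethod
    def concat(parts: list["ConfoundSet"]) -> "ConfoundSet":
        parts = [p for p in parts if p.matrix.shape[1] > 0]
        if not parts:
            raise ValueError("nothing to concatenate")
        return ConfoundSet(
            np.hstack([p.matrix for p in parts]),
            labels=[l for p in parts for l in p.labels],
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, columns=self.labels).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ConfoundSet":
        df = pd.read_csv(path, sep="\t")
        return cls(df.to_numpy(float), labels=list(df.columns))


def global_signal(bold: BoldImage, mask: np.ndarray | None = None) -> np.ndarray:
    data = bold.data if mask is None else bold.data[mask]
    return data.reshape(-1, bold.n_volumes).mean(axis=0)


def detect_outliers(
    bold: BoldImage,
    motion: MotionTrace,
    z_thresh: float = DEFAULT_Z_THRESH,
    fd_thresh: float = DEFAULT_FD_THRESH,
    mask: np.ndarray | None = None,
) -> OutlierMask:
    """Flag volumes whose global-signal z-score or framewise displacement
    exceeds its threshold (art-style quality assurance)."""
    if z_thresh <= 0 or fd_thresh <= 0:
        raise ValueError("thresholds must be positive")
    if bold.n_volumes < 3:
        raise ValueError("need at least 3 volumes for outlier detection")
    if motion.n_volumes != bold.n_volumes:
        raise ValueError("motion trace length must match volume count")
    g = global_signal(bold, mask)
    sd = g.std(ddof=1)
    z = np.zeros_like(g) if sd == 0 else (g - g.mean()) / sd
    fd = motion.framewise_displacement()
    flags = (np.abs(z) > z_thresh) | (fd > fd_thresh)
    return OutlierMask(flags=flags, z_thresh=z_thresh, fd_thresh=fd_thresh)


def motion_confounds(motion: MotionTrace) -> ConfoundSet:
    """6 rigid-body parameters and their first temporal derivatives
    (backward differences, zero-padded at the first volume)."""
    p = motion.params
    d = np.vstack([np.zeros((1, 6)), np.diff(p, axis=0)])
    labels = [f"motion_{i}" for i in range(6)] + [f"motion_deriv_{i}" for i in range(6)]
    return ConfoundSet(np.hstack([p, d]), labels=labels)


def compute_acompcor(
    bold: BoldImage, noise_mask: np.ndarray, k: int = 5
) -> ConfoundSet:
    """First ``k`` principal-component time courses of the demeaned
    noise-ROI voxel x time matrix, variance ordered (aCompCor).

    If ``k`` exceeds the matrix rank the available components are returned
    with a warning.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    noise_mask = np.asarray(noise_mask, bool)
    if not noise_mask.any():
        raise ValueError("noise mask is empty")
    if k == 0:
        return ConfoundSet(np.empty((bold.n_volumes, 0)), labels=[])
    X = bold.data[noise_mask]  # (voxels, T)
    X = X - X.mean(axis=1, keepdims=True)
    # PCA over time: right singular vectors of the voxel x time matrix
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    if k > rank:
        warnings.warn(
            f"requested {k} aCompCor components but noise matrix rank is {rank}",
            stacklevel=2,
        )
        k = rank
    comps = vt[:k].T  # (T, k), orthonormal
    return ConfoundSet(comps, labels=[f"acompcor_{i}" for i in range(k)])


def build_highpass_basis(
    n_volumes: int, tr: float, cutoff_hz: float = DEFAULT_HIGHPASS_HZ
) -> ConfoundSet:
    """Discrete-cosine columns spanning frequencies below ``cutoff_hz``.

    The DCT-II term j has frequency j / (2 N tr); the number of columns is
    floor(2 N tr cutoff), the SPM convention for regression-based
    high-pass filtering.
    """
    if cutoff_hz < 0:
        raise ValueError("cutoff must be non-negative")
    nyquist = 1.0 / (2.0 * tr)
    if cutoff_hz > nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz above Nyquist {nyquist} Hz")
    n_cols = int(np.floor(2 * n_volumes * tr * cutoff_hz))
    t = np.arange(n_volumes)
    cols = [
        np.cos(np.pi * (t + 0.5) * j / n_volumes) for j in range(1, n_cols + 1)
    ]
    mat = np.column_stack(cols) if cols else np.empty((n_volumes, 0))
    return ConfoundSet(mat, labels=[f"cosine_{j}" for j in range(1, n_cols + 1)])


def regress_confounds(
    bold: BoldImage, confounds: ConfoundSet | None
) -> BoldImage:
    """OLS residuals of every voxel series on the confound matrix plus an
    intercept; collinear columns are dropped with a warning."""
    T = bold.n_volumes
    if confounds is None:
        X = np.ones((T, 1))
    else:
        if confounds.n_volumes != T:
            raise ValueError("confound rows must match volume count")
        X = np.hstack([np.ones((T, 1)), confounds.matrix])
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    keep = diag > diag.max() * 1e-10
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} collinear confound column(s)",
            stacklevel=2,
        )
        X = X[:, keep]
        q, _ = np.linalg.qr(X)
    Y = bold.data.reshape(-1, T)  # (voxels, T)
    resid = Y - (Y @ q) @ q.T
    return BoldImage(
        data=resid.reshape(bold.data.shape),
        tr_seconds=bold.tr_seconds,
        affine=bold.affine,
        run_id=bold.run_id,
    )


def denoise_run(
    bold: BoldImage,
    motion: MotionTrace,
    noise_mask: np.ndarray | None = None,
    n_compcor: int = 5,
    z_thresh: float = DEFAULT_Z_THRESH,
    fd_thresh: float = DEFAULT_FD_THRESH,
    highpass_hz: float = DEFAULT_HIGHPASS_HZ,
) -> tuple[BoldImage, ConfoundSet, OutlierMask]:
    """Full single-run recipe: outlier flags -> confound matrix -> one OLS."""
    outliers = detect_outliers(bold, motion, z_thresh, fd_thresh)
    parts = [motion_confounds(motion)]
    if noise_mask is not None and n_compcor > 0:
        parts.append(compute_acompcor(bold, noise_mask, n_compcor))
    if outliers.n_outliers:
        parts.append(
            ConfoundSet(
                outliers.indicator_columns(),
                labels=[f"outlier_{i}" for i in range(outliers.n_outliers)],
            )
        )
    parts.append(build_highpass_basis(bold.n_volumes, bold.tr_seconds, highpass_hz))
    confounds = ConfoundSet.concat(parts)
    residual = regress_confounds(bold, confounds)
    return residual, confounds, outliers


def standardize(bold: BoldImage) -> BoldImage:
    """Z-score every voxel series over time (zero-variance voxels -> 0)."""
    Y = bold.data.reshape(-1, bold.n_volumes)
    mu = Y.mean(axis=1, keepdims=True)
    sd = Y.std(axis=1, keepdims=True)
    out = np.where(sd > 0, (Y - mu) / np.where(sd == 0, 1, sd), 0.0)
    return BoldImage(out.reshape(bold.data.shape), bold.tr_seconds, bold.affine,
                     bold.run_id)


def concat_runs(runs: list[BoldImage]) -> BoldImage:
    """Concatenate denoised, standardized runs along time for connectivity."""
    if not runs:
        raise ValueError("no runs")
    first = runs[0]
    for r in runs[1:]:
        if r.grid_shape != first.grid_shape:
            raise ValueError("runs must share the voxel grid")
    data = np.concatenate([r.data for r in runs], axis=3)
    return BoldImage(data, first.tr_seconds, first.affine, run_id="concat")
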