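"""Synthetic study inputs with known ground truth.

The real study acquired paired pre/post resting fMRI, a hand-clench task
run, and anatomical scans per patient; none of that data is public.  This
module generates desk-scale stand-ins with a full ground-truth record:

* resting BOLD with a *planted* correlation structure between spherical
  "M1-like" regions (shared latent Gaussian sources mixed to the target
  correlation matrix, plus spatially smoothed voxel noise so that local
  coherence exists),
* task BOLD with a boxcar-times-HRF response of known amplitude at a known
  activation locus,
* rigid-body motion traces (Gaussian jitter plus optional step spikes),
* multi-layer spherical head phantoms with nested tumor compartments
  (edema > non-enhancing > enhancing > necrosis).

Every generator is a pure function of its parameters and an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .images import BoldImage, LabelVolume, MotionTrace, default_affine

DEFAULT_SEED = 20201119

#: canonical label coding for phantom volumes
PHANTOM_LABELS = {
    1: "skin",
    2: "bone",
    3: "CSF",
    4: "GM",
    5: "WM",
    9: "tumor_enhancing",
    10: "tumor_nonenhancing",
    11: "necrosis",
    12: "edema",
}

#: outer radius of each concentric layer, mm (skin -> WM), loosely modelled
#: on adult head dimensions
DEFAULT_LAYER_RADII = (92.0, 85.0, 78.0, 75.0, 67.0)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class GroundTruth:
    """Planted generative parameters for one synthetic subject.

    ``pairwise_r`` is the pre-session correlation matrix of the latent
    region sources; ``delta_r`` is added to it for the post session
    (modelling the intervention effect).
    """

    region_centers: np.ndarray  # (n_regions, 3) mm
    pairwise_r: np.ndarray  # (n_regions, n_regions) pre-session correlations
    delta_r: np.ndarray  # same shape; pre -> post change
    activation_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    activation_amplitude: float = 2.0  # percent signal change at the peak
    noise_sd: float = 0.2  # voxel noise SD relative to unit-variance sources
    region_radius_mm: float = 6.0
    smooth_fwhm_mm: float = 6.0
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        self.region_centers = np.atleast_2d(np.asarray(self.region_centers, float))
        n = self.region_centers.shape[0]
        self.pairwise_r = np.asarray(self.pairwise_r, float).reshape(n, n)
        self.delta_r = np.broadcast_to(
            np.asarray(self.delta_r, float), (n, n)
        ).copy() if np.ndim(self.delta_r) else self._pair_delta(float(self.delta_r), n)
        for name, mat in (("pre", self.pairwise_r), ("post", self.post_r)):
            off = mat[~np.eye(n, dtype=bool)]
            if off.size and np.max(np.abs(off)) >= 1.0:
                raise ValueError(f"planted {name} correlations must lie in (-1, 1)")
        self.activation_center = np.asarray(self.activation_center, float).reshape(3)

    @staticmethod
    def _pair_delta(d: float, n: int) -> np.ndarray:
        out = np.zeros((n, n))
        if n >= 2:
            out[0, 1] = out[1, 0] = d
        return out

    @property
    def post_r(self) -> np.ndarray:
        return self.pairwise_r + self.delta_r


def default_truth(
    delta_r: float = 0.15,
    base_r: float = 0.5,
    seed: int = DEFAULT_SEED,
    grid_shape: tuple[int, int, int] = (24, 24, 18),
    voxel_size_mm: float = 4.0,
    **kwargs,
) -> GroundTruth:
    """Two homotopic 'M1' regions, left and right of the midline."""
    aff = default_affine(voxel_size_mm, grid_shape)
    half = np.array(grid_shape) * voxel_size_mm / 2.0
    centers = np.array(
        [[-half[0] * 0.45, 0.0, half[2] * 0.3], [half[0] * 0.45, 0.0, half[2] * 0.3]]
    )
    r = np.array([[1.0, base_r], [base_r, 1.0]])
    return GroundTruth(
        region_centers=centers,
        pairwise_r=r,
        delta_r=delta_r,
        activation_center=centers[0],
        seed=seed,
        **kwargs,
    )


def _region_masks(
    centers: np.ndarray, radius_mm: float, grid_shape, affine
) -> list[np.ndarray]:
    idx = np.indices(grid_shape).reshape(3, -1).T
    mm = idx @ affine[:3, :3].T + affine[:3, 3]
    masks = []
    for c in centers:
        d = np.linalg.norm(mm - c, axis=1)
        m = (d <= radius_mm).reshape(grid_shape)
        if not m.any():
            raise ValueError(f"region centre {c} resolves to no voxels inside the grid")
        masks.append(m)
    return masks


def _smooth_noise(
    rng: np.random.Generator, shape4d, sd: float, fwhm_mm: float, voxel_mm: np.ndarray
) -> np.ndarray:
    """Spatially smoothed Gaussian noise, rescaled back to SD ``sd``."""
    noise = rng.standard_normal(shape4d)
    if fwhm_mm > 0:
        sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_mm
        noise = ndimage.gaussian_filter(noise, sigma=(*sigma_vox, 0.0))
        noise /= noise.std()
    return sd * noise


def _correlated_sources(
    rng: np.random.Generator, corr: np.ndarray, n_volumes: int
) -> np.ndarray:
    """(n_regions, T) unit-variance Gaussian sources with given correlation."""
    L = np.linalg.cholesky(corr + 1e-12 * np.eye(corr.shape[0]))
    return L @ rng.standard_normal((corr.shape[0], n_volumes))


def _rest_session(
    rng: np.random.Generator,
    truth: GroundTruth,
    corr: np.ndarray,
    grid_shape,
    n_volumes: int,
    tr: float,
    affine: np.ndarray,
    run_id: str,
    drift_amplitude: float,
) -> BoldImage:
    masks = _region_masks(truth.region_centers, truth.region_radius_mm, grid_shape, affine)
    voxel_mm = np.abs(np.diag(affine[:3, :3]))
    data = _smooth_noise(rng, (*grid_shape, n_volumes), truth.noise_sd,
                         truth.smooth_fwhm_mm, voxel_mm)
    sources = _correlated_sources(rng, corr, n_volumes)
    for m, s in zip(masks, sources):
        data[m] += s
    if drift_amplitude:
        t = np.linspace(-1, 1, n_volumes)
        data += drift_amplitude * t  # common-mode linear drift
    data += 100.0
    return BoldImage(data=data, tr_seconds=tr, affine=affine, run_id=run_id)


def make_rest_bold(
    truth: GroundTruth,
    grid_shape: tuple[int, int, int] = (24, 24, 18),
    n_volumes: int = 150,
    tr: float = 2.0,
    voxel_size_mm: float = 4.0,
    drift_amplitude: float = 0.0,
    session: str | None = None,
) -> tuple[BoldImage, BoldImage] | BoldImage:
    """Paired pre/post resting runs with the planted correlation change.

    Returns ``(pre, post)``; pass ``session='pre'`` or ``'post'`` for one.
    Deterministic given ``truth.seed``: each session has its own child
    stream, so ``delta_r = 0`` means pre and post are independent draws
    from the identical model.
    """
    if n_volumes < 20:
        raise ValueError("need at least 20 volumes")
    affine = default_affine(voxel_size_mm, grid_shape)
    ss = np.random.SeedSequence(truth.seed)
    rng_pre, rng_post = (np.random.default_rng(s) for s in ss.spawn(2))
    out = {}
    if session in (None, "pre"):
        out["pre"] = _rest_session(rng_pre, truth, truth.pairwise_r, grid_shape,
                                   n_volumes, tr, affine, "ses-pre", drift_amplitude)
    if session in (None, "post"):
        out["post"] = _rest_session(rng_post, truth, truth.post_r, grid_shape,
                                    n_volumes, tr, affine, "ses-post", drift_amplitude)
    if session is None:
        return out["pre"], out["post"]
    return out[session]


@dataclass
class BlockDesign:
    """Alternating task/rest boxcar, starting with rest."""

    n_volumes: int
    tr: float = 2.0
    block_seconds: float = 20.0

    def __post_init__(self) -> None:
        if self.n_volumes < 2:
            raise ValueError("empty design")
        if self.block_seconds <= 0:
            raise ValueError("block length must be positive")

    def boxcar(self) -> np.ndarray:
        t = np.arange(self.n_volumes) * self.tr
        return ((t // self.block_seconds) % 2 == 1).astype(float)


def double_gamma_hrf(
    t: np.ndarray,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    ratio: float = 6.0,
    dispersion: float = 1.0,
) -> np.ndarray:
    """Canonical double-gamma haemodynamic response, peak-normalised to 1."""
    t = np.asarray(t, float)
    h = stats.gamma.pdf(t, peak_delay / dispersion, scale=dispersion) - (
        stats.gamma.pdf(t, undershoot_delay / dispersion, scale=dispersion) / ratio
    )
    h[t < 0] = 0.0
    return h / h.max()


def expected_response(design: BlockDesign, oversample: int = 10) -> np.ndarray:
    """Boxcar convolved with the canonical HRF, sampled at the TR grid,
    peak-normalised to 1 (so amplitude parameters are in peak % signal)."""
    dt = design.tr / oversample
    t_hi = np.arange(design.n_volumes * oversample) * dt
    box_hi = ((t_hi // design.block_seconds) % 2 == 1).astype(float)
    hrf = double_gamma_hrf(np.arange(0, 32, dt))
    resp = np.convolve(box_hi, hrf)[: box_hi.size] * dt
    resp = resp[::oversample]
    peak = np.abs(resp).max()
    return resp / peak if peak > 0 else resp


def make_task_bold(
    truth: GroundTruth,
    block_design: BlockDesign,
    grid_shape: tuple[int, int, int] = (24, 24, 18),
    voxel_size_mm: float = 4.0,
) -> BoldImage:
    """Task run: boxcar (x) HRF signal at the planted activation locus.

    The spatial activation profile is a Gaussian of FWHM equal to the
    truth's region radius, scaled so the peak voxel carries
    ``activation_amplitude`` percent signal change over the 100 baseline.
    """
    if truth.activation_amplitude < 0:
        raise ValueError("activation amplitude must be non-negative")
    affine = default_affine(voxel_size_mm, grid_shape)
    rng = np.random.default_rng(np.random.SeedSequence(truth.seed).spawn(3)[2])
    voxel_mm = np.abs(np.diag(affine[:3, :3]))
    data = _smooth_noise(
        rng, (*grid_shape, block_design.n_volumes), truth.noise_sd,
        truth.smooth_fwhm_mm, voxel_mm,
    )
    idx = np.indices(grid_shape).reshape(3, -1).T
    mm = idx @ affine[:3, :3].T + affine[:3, 3]
    d2 = np.sum((mm - truth.activation_center) ** 2, axis=1)
    sig_sp = truth.region_radius_mm * FWHM_TO_SIGMA
    profile = np.exp(-d2 / (2 * sig_sp**2)).reshape(grid_shape)
    resp = expected_response(block_design)
    data += truth.activation_amplitude * profile[..., None] * resp[None, None, None, :]
    data += 100.0
    return BoldImage(data=data, tr_seconds=block_design.tr, affine=affine,
                     run_id="task")


@dataclass
class TumorSpec:
    """Nested spherical tumor compartments centred at ``center_mm``.

    ``radii_mm`` maps compartment name to outer radius; compartments must
    nest edema > tumor_nonenhancing > tumor_enhancing > necrosis (any
    subset allowed).
    """

    center_mm: np.ndarray
    radii_mm: dict[str, float]

    ORDER = ("edema", "tumor_nonenhancing", "tumor_enhancing", "necrosis")

    def __post_init__(self) -> None:
        self.center_mm = np.asarray(self.center_mm, float).reshape(3)
        unknown = set(self.radii_mm) - set(self.ORDER)
        if unknown:
            raise ValueError(f"unknown tumor compartments {sorted(unknown)}")
        seq = [self.radii_mm[c] for c in self.ORDER if c in self.radii_mm]
        if any(a <= b for a, b in zip(seq, seq[1:])):
            raise ValueError("tumor compartment radii must strictly decrease "
                             "edema > non-enhancing > enhancing > necrosis")


def default_tumor() -> TumorSpec:
    return TumorSpec(
        center_mm=(-30.0, 5.0, 25.0),
        radii_mm={"edema": 18.0, "tumor_nonenhancing": 13.0,
                  "tumor_enhancing": 9.0, "necrosis": 5.0},
    )


def make_head_phantom(
    layer_radii_mm: tuple[float, ...] = DEFAULT_LAYER_RADII,
    tumor_spec: TumorSpec | None = None,
    voxel_size: float = 4.0,
    margin_mm: float = 4.0,
) -> LabelVolume:
    """Concentric-sphere head phantom (skin/bone/CSF/GM/WM) with optional
    nested tumor compartments replacing brain tissue.

    The grid has even dimensions so that the mm origin falls on a voxel
    corner; the meshing stage relies on that for symmetric meshes.
    """
    radii = tuple(float(r) for r in layer_radii_mm)
    if len(radii) != 5 or any(inner >= outer for outer, inner in zip(radii, radii[1:])):
        raise ValueError("need 5 strictly decreasing radii (skin, bone, CSF, GM, WM)")
    n = int(np.ceil(2 * (radii[0] + margin_mm) / voxel_size))
    n += n % 2  # even dims -> origin on a voxel corner
    shape = (n, n, n)
    affine = default_affine(voxel_size, shape)
    idx = np.indices(shape).reshape(3, -1).T
    mm = idx @ affine[:3, :3].T + affine[:3, 3]
    r = np.linalg.norm(mm, axis=1).reshape(shape)
    labels = np.zeros(shape, dtype=np.int64)
    # outermost to innermost: later assignments overwrite
    for code, radius in zip((1, 2, 3, 4, 5), radii):
        labels[r <= radius] = code
    if tumor_spec is not None:
        r_gm = radii[3]
        dist_c = np.linalg.norm(tumor_spec.center_mm)
        outer = max(tumor_spec.radii_mm.values())
        if dist_c + outer > r_gm:
            raise ValueError("tumor extends outside the brain (GM radius)")
        dt = np.linalg.norm(mm - tumor_spec.center_mm, axis=1).reshape(shape)
        code_of = {v: k for k, v in PHANTOM_LABELS.items()}
        for comp in TumorSpec.ORDER:  # outer -> inner, inner overwrites
            if comp in tumor_spec.radii_mm:
                labels[dt <= tumor_spec.radii_mm[comp]] = code_of[comp]
    present = set(np.unique(labels)) - {0}
    label_map = {k: v for k, v in PHANTOM_LABELS.items() if k in present}
    return LabelVolume(data=labels, label_map=label_map, voxel_size_mm=voxel_size,
                       affine=affine)


def make_motion_trace(
    n_volumes: int,
    spike_times: tuple[int, ...] = (),
    spike_mm: float = 0.0,
    jitter_mm: float = 0.05,
    jitter_rad: float = 5e-4,
    seed: int = DEFAULT_SEED,
) -> MotionTrace:
    """Gaussian jitter around zero plus step displacements in x at
    ``spike_times`` (so framewise displacement peaks exactly there)."""
    if any(t < 0 or t >= n_volumes for t in spike_times):
        raise ValueError("spike_times must be valid volume indices")
    rng = np.random.default_rng(seed)
    p = np.zeros((n_volumes, 6))
    if jitter_mm or jitter_rad:
        p[:, :3] = rng.normal(0, jitter_mm, (n_volumes, 3))
        p[:, 3:] = rng.normal(0, jitter_rad, (n_volumes, 3))
    for t in spike_times:
        p[t:, 0] += spike_mm
    return MotionTrace(p)
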