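"""Second-level inference.

Normality screening (Shapiro-Wilk), one-tailed paired t-tests on ROI
connectivity summaries, simple linear regression of connectivity change
on electric-field magnitude, voxel-wise paired contrasts, and cluster
inference by sign-flip permutation of the subject difference maps with
Benjamini-Hochberg FDR across clusters.

The permutation route replaces parametric cluster machinery: for a paired
design under an exchangeable symmetric null, flipping the sign of whole
subject difference maps is exact, and the max-cluster-size null gives
valid cluster p-values without distributional assumptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

DEFAULT_PERM_SEED = 20201119


@dataclass
class TestResult:
    t: float
    df: int
    p: float
    mean_diff: float
    sd_diff: float
    n: int
    tail: str = "one-tailed"

    def as_dict(self) -> dict:
        return {
            "t": self.t, "df": self.df, "p": self.p, "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff, "n": self.n, "tail": self.tail,
        }


def t_from_summary(mean_diff: float, sd_diff: float, n: int) -> TestResult:
    """Paired t from the summary statistics (mean and SD of differences)."""
    if n < 2:
        raise ValueError("need n >= 2")
    if sd_diff <= 0:
        raise ValueError("degenerate input: zero SD of differences")
    t = mean_diff / (sd_diff / np.sqrt(n))
    df = n - 1
    p = float(sps.t.sf(t, df))
    return TestResult(t=float(t), df=df, p=p, mean_diff=float(mean_diff),
                      sd_diff=float(sd_diff), n=n)


def paired_t_one_tailed(pre: np.ndarray, post: np.ndarray) -> TestResult:
    """Upper-tail paired t-test of post > pre (the directional hypothesis
    of increased connectivity after the intervention)."""
    pre = np.asarray(pre, float).ravel()
    post = np.asarray(post, float).ravel()
    if pre.size != post.size:
        raise ValueError("pre and post must have equal length")
    d = post - pre
    if d.size < 2:
        raise ValueError("need n >= 2 pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate input: all differences equal")
    return t_from_summary(d.mean(), sd, d.size)


def shapiro_wilk_screen(values: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W and p for a normality screen (3 <= n <= 5000)."""
    values = np.asarray(values, float).ravel()
    if not 3 <= values.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(values) == 0:
        raise ValueError("degenerate input: identical values")
    w, p = sps.shapiro(values)
    return float(w), float(p)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    t: float
    df: int
    p: float  # two-tailed

    def as_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept, "r2": self.r2,
                "t": self.t, "df": self.df, "p": self.p}


def regression_p_from_r2(r2: float, n: int) -> float:
    """Two-tailed p of the slope implied by r² and the sample size, via
    t = r sqrt((n-2) / (1-r²))."""
    if not 0 <= r2 <= 1:
        raise ValueError("r2 must lie in [0, 1]")
    if n < 3:
        raise ValueError("need n >= 3")
    if r2 >= 1.0:
        return 0.0
    t = np.sqrt(r2 * (n - 2) / (1.0 - r2))
    return float(2.0 * sps.t.sf(t, n - 2))


def simple_regression(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """OLS of y on x; r² is the squared Pearson correlation; the slope p
    comes from t = r sqrt((n-2)/(1-r²)), two-tailed."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("need n >= 3 paired observations")
    if x.std() == 0:
        raise ValueError("constant predictor")
    n = x.size
    xm, ym = x - x.mean(), y - y.mean()
    slope = float(xm @ ym / (xm @ xm))
    intercept = float(y.mean() - slope * x.mean())
    denom = np.linalg.norm(xm) * np.linalg.norm(ym)
    r = float(xm @ ym / denom) if denom > 0 else 0.0
    r2 = r * r
    if r2 >= 1.0 - 1e-15:
        return RegressionResult(slope, intercept, 1.0, np.inf, n - 2, 0.0)
    t = r * np.sqrt((n - 2) / (1.0 - r2))
    p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return RegressionResult(slope, intercept, r2, float(t), n - 2, p)


def voxelwise_paired_contrast(
    maps_pre: np.ndarray, maps_post: np.ndarray
) -> tuple[np.ndarray, int]:
    """Per-voxel paired t across subjects; returns (t_map, df).

    Input stacks are (n_subjects, x, y, z).  Voxels with zero difference
    variance get t = 0.
    """
    maps_pre = np.asarray(maps_pre, float)
    maps_post = np.asarray(maps_post, float)
    if maps_pre.shape != maps_post.shape:
        raise ValueError("pre/post stacks must have identical shape")
    n = maps_pre.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    return _t_of_diffs(maps_post - maps_pre), n - 1


def _t_of_diffs(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(sd > 0, t, 0.0)


@dataclass
class ClusterResult:
    """Suprathreshold clusters with permutation p and FDR q values."""

    labels: np.ndarray  # 3D int, 0 = background
    sizes: np.ndarray
    peaks: np.ndarray  # (k, 3) voxel coordinate of |t| peak per cluster
    p_values: np.ndarray
    q_values: np.ndarray
    voxel_p_thresh: float
    n_perm: int
    cluster_masks: list[np.ndarray] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return int(self.sizes.size)

    def surviving(self, q_thresh: float = 0.05) -> np.ndarray:
        """Indices of clusters with FDR-adjusted q below threshold."""
        if self.n_clusters == 0:
            return np.array([], dtype=int)
        return np.flatnonzero(self.q_values < q_thresh)


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _cluster_sizes(supra: np.ndarray) -> tuple[np.ndarray, int, np.ndarray]:
    labels, k = ndimage.label(supra, structure=_STRUCT_26)
    if k == 0:
        return labels, 0, np.array([], dtype=int)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, k + 1))
    return labels, k, sizes.astype(int)


def cluster_inference(
    diff_maps: np.ndarray,
    mask: np.ndarray | None = None,
    voxel_p_thresh: float = 0.005,
    n_perm: int = 1000,
    seed: int = DEFAULT_PERM_SEED,
    two_tailed: bool = True,
) -> ClusterResult:
    """Cluster-level inference on a paired contrast by sign-flip permutation.

    ``diff_maps`` is the (n_subjects, x, y, z) stack of post-minus-pre
    maps.  Suprathreshold voxels (voxel-level p below ``voxel_p_thresh``,
    two-tailed by default) are grouped by 26-connectivity; the null of the
    maximum cluster size is built by randomly flipping the sign of whole
    subject difference maps; each observed cluster's p is the proportion
    of permutations whose largest cluster is at least as big, and
    Benjamini-Hochberg FDR is applied across clusters.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    diff_maps = np.asarray(diff_maps, float)
    n = diff_maps.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if mask is None:
        mask = np.ones(diff_maps.shape[1:], dtype=bool)
    df = n - 1
    if two_tailed:
        t_crit = sps.t.isf(voxel_p_thresh / 2.0, df)
        supra_of = lambda t: np.abs(t) > t_crit  # noqa: E731
    else:
        t_crit = sps.t.isf(voxel_p_thresh, df)
        supra_of = lambda t: t > t_crit  # noqa: E731

    t_obs = _t_of_diffs(diff_maps)
    labels, k, sizes = _cluster_sizes(supra_of(t_obs) & mask)
    if k == 0:
        return ClusterResult(labels, sizes, np.empty((0, 3), int),
                             np.array([]), np.array([]), voxel_p_thresh, n_perm)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    flat = diff_maps.reshape(n, -1)
    for i in range(n_perm):
        signs = rng.choice((-1.0, 1.0), size=n)
        t_perm = _t_of_diffs((flat * signs[:, None]).reshape(diff_maps.shape))
        _, kp, sp = _cluster_sizes(supra_of(t_perm) & mask)
        null_max[i] = sp.max() if kp else 0

    p_values = np.array([(1 + np.sum(null_max >= s)) / (1 + n_perm) for s in sizes])
    _, q_values, _, _ = multipletests(p_values, method="fdr_bh")
    peaks = np.zeros((k, 3), dtype=int)
    masks = []
    for j in range(1, k + 1):
        cm = labels == j
        masks.append(cm)
        inside = np.argwhere(cm)
        peaks[j - 1] = inside[np.argmax(np.abs(t_obs[cm]))]
    return ClusterResult(labels, sizes, peaks, p_values, q_values,
                         voxel_p_thresh, n_perm, cluster_masks=masks)
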