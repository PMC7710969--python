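"""Connectivity metrics: Fisher-z, IC, LCOR, seed maps, ROI averaging."""

import numpy as np
import pytest

from stimconn.connectivity import (
    AnalysisMask,
    ICParams,
    KernelSpec,
    fisher_z,
    interhemispheric_fc,
    intrinsic_connectivity,
    intrinsic_connectivity_bruteforce,
    local_correlation,
    roi_mean,
    seed_to_voxel,
)
from stimconn.images import RoiSphere

from conftest import make_bold


def full_mask(shape):
    return AnalysisMask(np.ones(shape, dtype=bool))


class TestFisherZ:
    def test_reference_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.549306, abs=1e-6)

    def test_odd_symmetry(self, rng):
        r = rng.uniform(-0.99, 0.99, size=50)
        assert np.allclose(fisher_z(-r), -fisher_z(r), atol=1e-14)

    def test_invalid_correlation_rejected(self):
        for bad in (1.0, -1.0, 1.3):
            with pytest.raises(ValueError):
                fisher_z(bad)


class TestInterhemispheric:
    def _rois(self):
        left = RoiSphere([-4, 0, 0], 2.0, [[0, 0, 0]], side="left")
        right = RoiSphere([4, 0, 0], 2.0, [[1, 0, 0]], side="right")
        return left, right

    def test_identical_series_is_degenerate(self):
        data = np.zeros((2, 1, 1, 10))
        data[0, 0, 0] = data[1, 0, 0] = np.sin(np.arange(10))
        with pytest.raises(ValueError):
            interhemispheric_fc(make_bold(data), *self._rois())

    def test_orthogonal_series_give_zero(self):
        t = np.arange(40)
        data = np.zeros((2, 1, 1, 40))
        data[0, 0, 0] = np.sin(2 * np.pi * t / 8)
        data[1, 0, 0] = np.cos(2 * np.pi * t / 8)
        z = interhemispheric_fc(make_bold(data), *self._rois())
        assert abs(z) < 1e-12


class TestIntrinsicConnectivity:
    def test_shared_series_gives_unit_ic(self):
        series = np.sin(np.arange(20.0))
        data = np.tile(series, (3, 2, 2, 1))
        ic = intrinsic_connectivity(make_bold(data), full_mask((3, 2, 2)))
        assert np.allclose(ic.data, 1.0, atol=1e-10)

    def test_two_voxel_anticorrelated(self):
        data = np.zeros((2, 1, 1, 4))
        data[0, 0, 0] = [1, 2, 3, 4]
        data[1, 0, 0] = [4, 3, 2, 1]
        ic = intrinsic_connectivity(make_bold(data), full_mask((2, 1, 1)))
        # r = -1 -> IC = sqrt((1 + 1)/2) = 1 at both voxels
        assert np.allclose(ic.data.ravel(), 1.0, atol=1e-12)

    def test_truncated_svd_matches_bruteforce(self, rng):
        """With K >= rank, the SVD route equals the N x N correlation
        definition on a 200-voxel instance."""
        shape = (10, 5, 4)
        bold = make_bold(rng.standard_normal((*shape, 30)))
        fast = intrinsic_connectivity(bold, full_mask(shape), ICParams(64))
        ref = intrinsic_connectivity_bruteforce(bold, full_mask(shape))
        assert np.max(np.abs(fast.data - ref.data)) <= 1e-10

    def test_invariant_to_voxel_rescaling(self, rng):
        shape = (4, 4, 3)
        data = rng.standard_normal((*shape, 25))
        scales = rng.uniform(0.5, 5.0, size=shape)[..., None]
        offsets = rng.normal(0, 10, size=shape)[..., None]
        a = intrinsic_connectivity(make_bold(data), full_mask(shape))
        b = intrinsic_connectivity(make_bold(data * scales + offsets),
                                   full_mask(shape))
        assert np.allclose(a.data, b.data, atol=1e-10)

    def test_equivariant_under_time_permutation(self, rng):
        shape = (4, 3, 3)
        data = rng.standard_normal((*shape, 20))
        perm = rng.permutation(20)
        a = intrinsic_connectivity(make_bold(data), full_mask(shape))
        b = intrinsic_connectivity(make_bold(data[..., perm]), full_mask(shape))
        assert np.allclose(a.data, b.data, atol=1e-10)

    def test_noise_ic_falls_toward_floor_with_time(self):
        """For independent voxels IC converges to the sqrt(1/N) floor as
        the series lengthens: median IC decreases over T = 50, 200, 800."""
        shape = (10, 5, 4)
        medians = []
        rng = np.random.default_rng(11)
        for T in (50, 200, 800):
            ic = intrinsic_connectivity(
                make_bold(rng.standard_normal((*shape, T))), full_mask(shape))
            medians.append(np.median(ic.data))
        assert medians[0] > medians[1] > medians[2]

    def test_normalize_zscores_in_mask(self, rng):
        shape = (5, 4, 3)
        ic = intrinsic_connectivity(
            make_bold(rng.standard_normal((*shape, 30))), full_mask(shape))
        z = ic.normalize()
        assert z.data.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.data.std(ddof=1) == pytest.approx(1.0, abs=1e-12)


class TestLocalCorrelation:
    def test_shared_series_gives_unit_lcor(self):
        series = np.cos(np.arange(15.0))
        data = np.tile(series, (3, 3, 2, 1))
        lc = local_correlation(make_bold(data), full_mask((3, 3, 2)))
        assert np.allclose(lc.data, 1.0, atol=1e-12)

    def test_two_voxel_closed_form(self):
        """Anti-correlated two-voxel grid: LCOR equals the two-term
        Gaussian-weighted sum (1 - e^{-d²/2σ²}) / (1 + e^{-d²/2σ²})."""
        d = 4.0
        data = np.zeros((2, 1, 1, 4))
        data[0, 0, 0] = [1, 2, 3, 4]
        data[1, 0, 0] = [4, 3, 2, 1]
        kernel = KernelSpec(8.0)
        lc = local_correlation(make_bold(data, voxel_mm=d),
                               full_mask((2, 1, 1)), kernel)
        w = np.exp(-(d**2) / (2 * kernel.sigma_mm**2))
        expected = (1 - w) / (1 + w)
        assert lc.data[0, 0, 0] == pytest.approx(expected, abs=1e-12)
        assert lc.data[1, 0, 0] == pytest.approx(expected, abs=1e-12)

    def test_bounded_by_one(self, rng):
        shape = (5, 4, 3)
        lc = local_correlation(make_bold(rng.standard_normal((*shape, 20))),
                               full_mask(shape))
        assert np.all(lc.data <= 1.0 + 1e-12)

    def test_tight_kernel_approaches_self_correlation(self, rng):
        shape = (4, 4, 3)
        bold = make_bold(rng.standard_normal((*shape, 20)))
        lc = local_correlation(bold, full_mask(shape),
                               KernelSpec(fwhm_mm=0.5, truncate_sigmas=20.0))
        # self weight dominates every neighbour by many orders of magnitude
        assert np.allclose(lc.data, 1.0, atol=1e-6)


class TestSeedToVoxel:
    def test_matches_naive_loop(self, rng):
        shape = (4, 3, 3)
        bold = make_bold(rng.standard_normal((*shape, 25)))
        seed = RoiSphere([0, 0, 0], 5.0, [[1, 1, 1], [2, 1, 1]])
        cmap = seed_to_voxel(bold, seed, full_mask(shape))
        s = bold.data[1, 1, 1] + bold.data[2, 1, 1]
        for idx in np.ndindex(shape):
            r = np.corrcoef(s, bold.data[idx])[0, 1]
            assert cmap.data[idx] == pytest.approx(np.arctanh(r), abs=1e-8)

    def test_single_voxel_seed_guard(self, rng):
        shape = (3, 3, 3)
        bold = make_bold(rng.standard_normal((*shape, 20)))
        seed = RoiSphere([0, 0, 0], 2.0, [[1, 1, 1]])
        cmap = seed_to_voxel(bold, seed, full_mask(shape))
        assert np.isfinite(cmap.data[1, 1, 1])  # |r| = 1 clipped, not inf

    def test_peaks_in_correlated_region(self, rng):
        shape = (6, 4, 4)
        data = rng.standard_normal((*shape, 40)) * 0.1
        common = rng.standard_normal(40)
        data[0:2, 0:2, 0:2] += common
        bold = make_bold(data)
        seed = RoiSphere([0, 0, 0], 2.0, [[0, 0, 0]])
        cmap = seed_to_voxel(bold, seed, full_mask(shape))
        assert np.unravel_index(np.argmax(np.where(cmap.data < 5, cmap.data, -1)),
                                shape) < (2, 2, 2)


class TestRoiMean:
    def test_constant_and_single_voxel(self, rng):
        shape = (4, 4, 4)
        cmap = intrinsic_connectivity(
            make_bold(rng.standard_normal((*shape, 20))), full_mask(shape))
        roi1 = RoiSphere([0, 0, 0], 2.0, [[2, 2, 2]])
        assert roi_mean(cmap, roi1) == cmap.data[2, 2, 2]
        cmap.data[:] = 3.14
        roi = RoiSphere([0, 0, 0], 5.0, [[0, 0, 0], [1, 1, 1], [2, 2, 2]])
        assert roi_mean(cmap, roi) == pytest.approx(3.14)

    def test_equals_direct_enumeration(self, rng):
        shape = (5, 4, 3)
        cmap = intrinsic_connectivity(
            make_bold(rng.standard_normal((*shape, 20))), full_mask(shape))
        vox = np.array([[0, 0, 0], [1, 2, 1], [4, 3, 2]])
        roi = RoiSphere([0, 0, 0], 9.0, vox)
        manual = np.mean([cmap.data[tuple(v)] for v in vox])
        assert roi_mean(cmap, roi) == pytest.approx(manual, abs=1e-14)
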