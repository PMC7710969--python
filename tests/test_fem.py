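"""Finite-element field model: meshing, electrodes, Laplace solve, oracle."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from stimconn import fem
from stimconn.images import LabelVolume, RoiSphere, default_affine
from stimconn.seeds import resolve_sphere
from stimconn.synthetic import TumorSpec, make_head_phantom


def sphere_volume(radius=40.0, voxel=4.0, tissue="GM"):
    n = int(np.ceil(2 * (radius + 4) / voxel))
    n += n % 2
    shape = (n, n, n)
    aff = default_affine(voxel, shape)
    idx = np.indices(shape).reshape(3, -1).T
    mm = idx @ aff[:3, :3].T + aff[:3, 3]
    r = np.linalg.norm(mm, axis=1).reshape(shape)
    code = {"GM": 4}[tissue]
    return LabelVolume(np.where(r <= radius, code, 0).astype(np.int64),
                       {code: tissue}, voxel, affine=aff)


@pytest.fixture(scope="module")
def small_sphere_solution():
    """Homogeneous 40-mm sphere, antipodal small pads, both-Neumann mode."""
    vol = sphere_volume(40.0, 4.0)
    mesh = fem.voxels_to_tetmesh(vol)
    montage = fem.MontageSpec(anode=(0, 0, 1.0), cathode=(0, 0, -1.0),
                              pad_cm=(1.5, 1.5), current_A=1e-3)
    patches = fem.place_electrodes(mesh, montage, skin_tissue="GM")
    patches.cathode_faces = fem.reflect_patch(mesh, patches.anode_faces)
    sol = fem.solve_field(mesh, fem.ConductivityTable(), patches, 1e-3,
                          cathode_mode="neumann")
    return vol, mesh, patches, sol


class TestMeshing:
    def test_single_voxel_decomposition(self):
        vol = LabelVolume(np.full((1, 1, 1), 4, dtype=np.int64), {4: "GM"}, 2.0)
        mesh = fem.voxels_to_tetmesh(vol)
        assert mesh.n_tets == 5
        assert mesh.element_volumes_mm3().sum() == pytest.approx(8.0, rel=1e-12)

    def test_block_conforms(self):
        vol = LabelVolume(np.full((2, 2, 2), 5, dtype=np.int64), {5: "WM"}, 1.0)
        mesh = fem.voxels_to_tetmesh(vol)
        assert mesh.n_tets == 40
        faces, counts, _ = fem._face_census(mesh.tets)
        assert set(np.unique(counts)) <= {1, 2}  # every interior face shared by 2
        assert mesh.element_volumes_mm3().sum() == pytest.approx(8.0, rel=1e-12)

    def test_no_inverted_elements_on_random_shape(self, rng):
        data = (rng.random((6, 5, 7)) < 0.6).astype(np.int64) * 4
        data[3, 2, 3] = 4  # ensure nonempty
        vol = LabelVolume(data, {4: "GM"}, 3.0)
        mesh = fem.voxels_to_tetmesh(vol)
        assert np.all(mesh.element_volumes_mm3() > 0)
        expected = data.astype(bool).sum() * 27.0
        assert mesh.element_volumes_mm3().sum() == pytest.approx(expected, rel=1e-10)

    def test_empty_volume_rejected(self):
        vol = LabelVolume(np.zeros((3, 3, 3), dtype=np.int64), {}, 1.0)
        with pytest.raises(ValueError):
            fem.voxels_to_tetmesh(vol)


@pytest.fixture(scope="module")
def head_mesh():
    return fem.voxels_to_tetmesh(make_head_phantom())


class TestElectrodes:
    def test_pad_area_close_to_requested(self, head_mesh):
        patches = fem.place_electrodes(head_mesh, fem.MontageSpec())
        for area in (patches.anode_area_mm2, patches.cathode_area_mm2):
            assert abs(area - 3500.0) / 3500.0 <= 0.15

    def test_pads_disjoint(self, head_mesh):
        patches = fem.place_electrodes(head_mesh, fem.MontageSpec())
        a = {tuple(f) for f in patches.anode_faces}
        c = {tuple(f) for f in patches.cathode_faces}
        assert not (a & c)

    def test_antipodal_montage_centroids(self, head_mesh):
        montage = fem.MontageSpec(anode=(0, 0, 1.0), cathode=(0, 0, -1.0))
        patches = fem.place_electrodes(head_mesh, montage)
        ca = patches.centroid(head_mesh.nodes_mm, "anode")
        cc = patches.centroid(head_mesh.nodes_mm, "cathode")
        assert np.linalg.norm(ca + cc) <= 4.0  # within one voxel

    def test_overlapping_pads_rejected(self, head_mesh):
        montage = fem.MontageSpec(anode=(0, 0, 1.0), cathode=(0.05, 0, 1.0))
        with pytest.raises(ValueError, match="overlap"):
            fem.place_electrodes(head_mesh, montage)


class TestSolver:
    def test_linearity_in_current(self, small_sphere_solution):
        vol, mesh, patches, sol = small_sphere_solution
        sol2 = fem.solve_field(mesh, fem.ConductivityTable(), patches, 2e-3,
                               cathode_mode="neumann")
        assert np.allclose(sol2.potentials, 2 * sol.potentials,
                           atol=2e-8 * np.abs(sol.potentials).max())
        assert np.allclose(sol2.e_magnitude, 2 * sol.e_magnitude,
                           rtol=1e-6, atol=1e-10)

    def test_antipodal_antisymmetry(self, small_sphere_solution):
        """With exactly mirrored pads on a point-symmetric mesh the
        potential is antisymmetric: V(p) = -V(-p)."""
        vol, mesh, patches, sol = small_sphere_solution
        tree = cKDTree(mesh.nodes_mm)
        d, idx = tree.query(-mesh.nodes_mm)
        assert d.max() < 1e-9  # mesh is point symmetric
        v = sol.potentials
        assert np.max(np.abs(v + v[idx])) <= 1e-3 * np.max(np.abs(v))

    def test_missing_conductivity_rejected(self, small_sphere_solution):
        vol, mesh, patches, _ = small_sphere_solution
        with pytest.raises(ValueError, match="conductivity"):
            fem.solve_field(mesh, fem.ConductivityTable(values={"WM": 0.126}),
                            patches, 1e-3)

    def test_dirichlet_mode_grounds_cathode(self, small_sphere_solution):
        vol, mesh, patches, _ = small_sphere_solution
        sol = fem.solve_field(mesh, fem.ConductivityTable(), patches, 1e-3,
                              cathode_mode="dirichlet")
        cathode_nodes = np.unique(patches.cathode_faces)
        assert np.all(sol.potentials[cathode_nodes] == 0)
        assert sol.potentials.max() > 0


class TestAnalyticOracle:
    def test_midplane_probe_is_zero(self):
        v = fem.analytic_sphere_potential([10.0, 0.0, 0.0], (0, 0, 1),
                                          (0, 0, -1), 0.3, 40.0)
        assert abs(v) < 1e-15

    def test_ohmic_scaling(self):
        p = [5.0, 3.0, 20.0]
        v1 = fem.analytic_sphere_potential(p, (0, 0, 1), (0, 0, -1), 0.3, 40.0)
        v2 = fem.analytic_sphere_potential(p, (0, 0, 1), (0, 0, -1), 0.6, 40.0)
        assert v2 == pytest.approx(v1 / 2, rel=1e-12)

    def test_truncation_stability(self):
        p = [5.0, 3.0, 20.0]
        loose = fem.analytic_sphere_potential(p, (0, 0, 1), (0, 0, -1), 0.3,
                                              40.0, tol=1e-6)
        tight = fem.analytic_sphere_potential(p, (0, 0, 1), (0, 0, -1), 0.3,
                                              40.0, tol=1e-12)
        assert loose == pytest.approx(tight, rel=1e-6)

    def test_probe_outside_rejected(self):
        with pytest.raises(ValueError):
            fem.analytic_sphere_potential([50.0, 0, 0], (0, 0, 1), (0, 0, -1),
                                          0.3, 40.0)


class TestOracleAgreement:
    def _compare(self, radius, voxel, n_probes=20, seed=0):
        vol = sphere_volume(radius, voxel)
        mesh = fem.voxels_to_tetmesh(vol)
        montage = fem.MontageSpec(anode=(0, 0, 1.0), cathode=(0, 0, -1.0),
                                  pad_cm=(2.0, 2.0), current_A=2e-3)
        patches = fem.place_electrodes(mesh, montage, skin_tissue="GM")
        sol = fem.solve_field(mesh, fem.ConductivityTable(), patches, 2e-3,
                              cathode_mode="neumann")
        cents = mesh.nodes_mm[patches.anode_faces].mean(axis=1)
        u = cents / np.linalg.norm(cents, axis=1, keepdims=True)
        theta = np.arccos(np.clip(u @ np.array([0, 0, 1.0]), -1, 1)).max()
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n_probes, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts *= rng.uniform(8.0, 0.7 * radius, size=(n_probes, 1))
        v_fem = fem.interpolate_potential(sol, pts)
        v_an = fem.analytic_sphere_potential(pts, (0, 0, 1), (0, 0, -1),
                                             0.276, radius, current=2e-3,
                                             cap_theta_rad=theta)
        offset = (v_fem - v_an).mean()  # gauge alignment
        scale = np.max(np.abs(v_an - v_an.mean()))
        return np.abs(v_fem - v_an - offset) / scale, sol, vol

    def test_homogeneous_sphere_within_five_percent(self):
        """Potential at 20 interior probes agrees with the Legendre cap
        series within 5% of the potential scale."""
        err, _, _ = self._compare(90.0, 4.0)
        assert err.max() <= 0.05

    def test_error_decreases_with_refinement(self):
        coarse, _, _ = self._compare(40.0, 8.0)
        fine, _, _ = self._compare(40.0, 4.0)
        assert np.sqrt((fine**2).mean()) < np.sqrt((coarse**2).mean())

    def test_current_conservation_across_layers(self):
        """Every voxel layer between the electrodes carries the injected
        current within 1%."""
        _, sol, vol = self._compare(90.0, 4.0, n_probes=2)
        nz = vol.data.shape[2]
        for layer in (nz // 3, nz // 2, 2 * nz // 3):
            current = sol.current_through_layer(layer)
            assert abs(abs(current) - 2e-3) / 2e-3 <= 0.01


class TestFieldExtraction:
    def _uniform_solution(self):
        """Impose V = -E0 * x so every element carries the same field."""
        vol = sphere_volume(20.0, 4.0)
        mesh = fem.voxels_to_tetmesh(vol)
        e0 = 0.25  # V/m
        V = -e0 * mesh.nodes_mm[:, 0] * 1e-3
        K, G, _, sigma = fem._assemble(mesh, fem.ConductivityTable())
        E = -np.einsum("mi,mik->mk", V[mesh.tets], G)
        return vol, fem.FemSolution(mesh, V, E, np.linalg.norm(E, axis=1),
                                    1e-3, sigma, K, np.zeros(mesh.n_nodes)), e0

    def test_uniform_field_recovered_exactly(self):
        vol, sol, e0 = self._uniform_solution()
        ef = fem.efield_to_voxels(sol, vol)
        inside = np.isfinite(ef)
        assert np.allclose(ef[inside], e0, atol=1e-10)

    def test_voxel_value_bounded_by_elements(self, small_sphere_solution):
        vol, mesh, _, sol = small_sphere_solution
        ef = fem.efield_to_voxels(sol, vol)
        flat = ef.ravel()
        for lin in np.unique(mesh.voxel_of)[:200]:
            elems = sol.e_magnitude[mesh.voxel_of == lin]
            assert elems.min() - 1e-12 <= flat[lin] <= elems.max() + 1e-12

    def test_roi_mean_constant_and_single(self):
        vol, sol, e0 = self._uniform_solution()
        ef = fem.efield_to_voxels(sol, vol)
        c = np.array(vol.data.shape) // 2
        roi = RoiSphere([0, 0, 0], 5.0, [c])
        assert fem.roi_mean_ef(ef, roi) == pytest.approx(e0, abs=1e-10)
        roi2 = RoiSphere([0, 0, 0], 8.0,
                         resolve_sphere([0, 0, 0], 8.0, vol.affine,
                                        vol.data.shape))
        assert fem.roi_mean_ef(ef, roi2) == pytest.approx(e0, abs=1e-10)


class TestTumorShunting:
    def test_raising_compartment_conductivity_lowers_inner_field(self):
        """A more conductive tumor compartment shunts current around its
        interior: mean |E| inside drops as sigma rises."""
        tumor = TumorSpec(center_mm=(-20, 5, 15),
                          radii_mm={"edema": 14.0})
        ph = make_head_phantom(tumor_spec=tumor, voxel_size=6.0)
        mesh = fem.voxels_to_tetmesh(ph)
        patches = fem.place_electrodes(mesh, fem.MontageSpec())
        means = []
        for sig in (0.3, 1.185, 3.0):
            table = fem.ConductivityTable()
            table.values["edema"] = sig
            sol = fem.solve_field(mesh, table, patches, 2e-3)
            ef = fem.efield_to_voxels(sol, ph)
            means.append(np.nanmean(ef[ph.mask("edema")]))
        assert means[0] > means[1] > means[2]


class TestEfPlausibility:
    def test_default_montage_brain_field_in_band(self):
        """2 mA through 35-cm² C3/FP1 pads on the default 5-layer phantom:
        mean brain |E| lands in the 0.05-0.5 V/m range reported for
        conventional tDCS."""
        ph = make_head_phantom()
        mesh = fem.voxels_to_tetmesh(ph)
        patches = fem.place_electrodes(mesh, fem.MontageSpec())
        sol = fem.solve_field(mesh, fem.ConductivityTable(), patches, 2e-3)
        ef = fem.efield_to_voxels(sol, ph)
        mean_brain = np.nanmean(ef[ph.mask("GM", "WM")])
        assert 0.05 <= mean_brain <= 0.5


def test_vtk_export_roundtrip_text(tmp_path):
    vol = LabelVolume(np.full((2, 2, 1), 4, dtype=np.int64), {4: "GM"}, 2.0)
    mesh = fem.voxels_to_tetmesh(vol)
    path = tmp_path / "mesh.vtk"
    mesh.save_vtk(path)
    text = path.read_text()
    assert "UNSTRUCTURED_GRID" in text
    assert f"CELLS {mesh.n_tets}" in text
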