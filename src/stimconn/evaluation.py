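"""Worked-example and calibration harnesses.

These functions recompute, from scratch and at desk scale, the quantities
the study reports: paired t statistics from the published cohort
summaries, regression p-values from published r² values, the phantom
electric-field magnitudes, the agreement of the fast IC path and the FEM
solver with their independent oracles, and the operating characteristics
(power, false-positive rate, cluster family-wise rate) of the pipeline on
synthetic cohorts.  Both the test suite and the acceptance script drive
the package through this module.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from . import fem
from .connectivity import (
    AnalysisMask,
    ICParams,
    KernelSpec,
    intrinsic_connectivity,
    intrinsic_connectivity_bruteforce,
    local_correlation,
)
from .images import BoldImage, LabelVolume, RoiSphere, default_affine
from .pipeline import StudyConfig, run_study
from .seeds import resolve_sphere
from .stats import cluster_inference, t_from_summary
from .synthetic import make_head_phantom

#: published cohort summaries (mean change, SD of change, n = 8):
#: interhemispheric Fisher-z, seed-averaged IC and LCOR for each M1
PUBLISHED_SUMMARIES = {
    "interhemispheric": (0.095, 0.16),
    "left_m1_ic": (0.380, 0.56),
    "right_m1_ic": (0.290, 0.69),
    "left_m1_lcor": (0.377, 0.35),
    "right_m1_lcor": (0.257, 0.43),
}

#: published r² values of the EF-versus-connectivity-change regressions
PUBLISHED_R2 = {
    "ef_vs_right_m1_ic": 0.53,
    "ef_vs_left_m1_ic": 0.0257,
    "ef_vs_left_m1_lcor": 0.0006,
    "ef_vs_right_m1_lcor": 0.33,
}


def recomputed_summary_ts(n: int = 8) -> dict[str, float]:
    """Paired t for each published mean±SD cohort summary."""
    return {name: t_from_summary(m, s, n).t
            for name, (m, s) in PUBLISHED_SUMMARIES.items()}


def ic_oracle_max_error(n_voxels: int = 200, n_volumes: int = 30,
                        seed: int = 0) -> float:
    """Max |truncated-SVD IC - brute-force IC| on a random instance whose
    rank is below the 64-component truncation."""
    shape = (n_voxels // 20, 5, 4)
    rng = np.random.default_rng(seed)
    bold = BoldImage(rng.standard_normal((*shape, n_volumes)), 2.0,
                     default_affine(4.0, shape))
    mask = AnalysisMask(np.ones(shape, dtype=bool))
    fast = intrinsic_connectivity(bold, mask, ICParams(64))
    ref = intrinsic_connectivity_bruteforce(bold, mask)
    return float(np.max(np.abs(fast.data - ref.data)))


def lcor_closed_form_error(spacing_mm: float = 4.0,
                           fwhm_mm: float = 8.0) -> float:
    """|LCOR - closed form| for the two-voxel anti-correlated grid."""
    data = np.zeros((2, 1, 1, 4))
    data[0, 0, 0] = [1, 2, 3, 4]
    data[1, 0, 0] = [4, 3, 2, 1]
    bold = BoldImage(data, 2.0, default_affine(spacing_mm, (2, 1, 1)))
    kernel = KernelSpec(fwhm_mm)
    lc = local_correlation(bold, AnalysisMask(np.ones((2, 1, 1), bool)), kernel)
    w = np.exp(-(spacing_mm**2) / (2 * kernel.sigma_mm**2))
    expected = (1 - w) / (1 + w)
    return float(abs(lc.data[0, 0, 0] - expected))


def _sphere_volume(radius: float, voxel: float) -> LabelVolume:
    n = int(np.ceil(2 * (radius + 4) / voxel))
    n += n % 2
    shape = (n, n, n)
    aff = default_affine(voxel, shape)
    idx = np.indices(shape).reshape(3, -1).T
    mm = idx @ aff[:3, :3].T + aff[:3, 3]
    r = np.linalg.norm(mm, axis=1).reshape(shape)
    return LabelVolume(np.where(r <= radius, 4, 0).astype(np.int64),
                       {4: "GM"}, voxel, affine=aff)


def fem_sphere_oracle(radius: float = 90.0, voxel: float = 4.0,
                      n_probes: int = 20, seed: int = 0) -> dict[str, float]:
    """Homogeneous-sphere FEM versus the Legendre cap-series solution.

    Returns the max probe error relative to the potential scale, and the
    worst relative current-conservation error across three voxel layers
    between the electrodes.
    """
    vol = _sphere_volume(radius, voxel)
    mesh = fem.voxels_to_tetmesh(vol)
    montage = fem.MontageSpec(anode=(0, 0, 1.0), cathode=(0, 0, -1.0),
                              pad_cm=(2.0, 2.0), current_A=2e-3)
    patches = fem.place_electrodes(mesh, montage, skin_tissue="GM")
    sol = fem.solve_field(mesh, fem.ConductivityTable(), patches, 2e-3,
                          cathode_mode="neumann")
    cents = mesh.nodes_mm[patches.anode_faces].mean(axis=1)
    u = cents / np.linalg.norm(cents, axis=1, keepdims=True)
    theta = float(np.arccos(np.clip(u @ np.array([0, 0, 1.0]), -1, 1)).max())
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n_probes, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts *= rng.uniform(8.0, 0.7 * radius, size=(n_probes, 1))
    v_fem = fem.interpolate_potential(sol, pts)
    v_an = fem.analytic_sphere_potential(pts, (0, 0, 1), (0, 0, -1), 0.276,
                                         radius, current=2e-3,
                                         cap_theta_rad=theta)
    offset = (v_fem - v_an).mean()
    scale = np.max(np.abs(v_an - v_an.mean()))
    max_err = float(np.max(np.abs(v_fem - v_an - offset)) / scale)
    nz = vol.data.shape[2]
    cons = max(
        abs(abs(sol.current_through_layer(layer)) - 2e-3) / 2e-3
        for layer in (nz // 3, nz // 2, 2 * nz // 3)
    )
    # exact linearity: doubling the current must double the solution
    sol2 = fem.solve_field(mesh, fem.ConductivityTable(), patches, 4e-3,
                           cathode_mode="neumann")
    lin = float(np.max(np.abs(sol2.potentials - 2 * sol.potentials))
                / np.max(np.abs(sol.potentials)))
    return {"max_rel_error": max_err, "conservation_error": float(cons),
            "linearity_error": lin}


def default_phantom_efield() -> dict[str, float]:
    """2-mA C3/FP1 montage on the default 5-layer phantom: mean |E| over
    brain tissue and over a 6-mm left-M1 sphere."""
    ph = make_head_phantom()
    mesh = fem.voxels_to_tetmesh(ph)
    montage = fem.MontageSpec()
    patches = fem.place_electrodes(mesh, montage)
    sol = fem.solve_field(mesh, fem.ConductivityTable(), patches,
                          montage.current_A)
    ef = fem.efield_to_voxels(sol, ph)
    brain = ph.mask("GM", "WM")
    m1_center = montage.direction("anode") * (75.0 - 4.0)
    roi = RoiSphere(m1_center, 6.0,
                    resolve_sphere(m1_center, 6.0, ph.affine, ph.data.shape))
    return {
        "mean_brain_ef": float(np.nanmean(ef[brain])),
        "left_m1_ef": fem.roi_mean_ef(ef, roi, restrict_mask=brain),
    }


def _replicate_config(delta_r: float, master_seed: int) -> StudyConfig:
    """Lean study configuration for operating-characteristic replicates:
    12 subjects, reduced grids, interhemispheric readout only."""
    return StudyConfig(
        cohort_size=12, grid_shape=(16, 16, 12), n_volumes_per_run=60,
        delta_r=delta_r, with_maps=False, with_voxelwise=False,
        with_efield=False, master_seed=master_seed,
    )


def detection_rate(n_replicates: int = 50, delta_r: float = 0.15,
                   alpha: float = 0.05, seed: int = 0) -> float:
    """Fraction of replicate studies whose left-M1 one-tailed paired t is
    positive with p below alpha."""
    hits = 0
    for rep in range(n_replicates):
        report = run_study(_replicate_config(delta_r, seed * 100003 + rep))
        res = report["group_tests"]["interhemispheric_z"]
        hits += (res["t"] > 0) and (res["p"] < alpha)
    return hits / n_replicates


def cluster_null_familywise_rate(n_studies: int = 200, n_subjects: int = 12,
                                 grid=(10, 10, 8), n_perm: int = 200,
                                 q: float = 0.05, seed: int = 0) -> float:
    """Family-wise rate of any FDR-surviving cluster when subject
    difference maps are pure smooth noise (no effect anywhere)."""
    rng = np.random.default_rng(seed)
    false_alarms = 0
    for study in range(n_studies):
        diffs = ndimage.gaussian_filter(
            rng.standard_normal((n_subjects, *grid)), sigma=(0, 1, 1, 1))
        res = cluster_inference(diffs, voxel_p_thresh=0.005, n_perm=n_perm,
                                seed=int(rng.integers(2**31)))
        false_alarms += res.surviving(q).size > 0
    return false_alarms / n_studies
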