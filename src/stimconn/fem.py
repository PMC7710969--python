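"""Phantom-specific tDCS electric-field model.

A labelled head volume is turned into a conforming tetrahedral mesh (each
voxel split into 5 tetrahedra, mirrored on alternating voxel parity so
shared faces match), per-tissue conductivities are attached, and the
current-conservation equation div(sigma grad V) = 0 is solved with
piecewise-linear finite elements:

* anode pad: uniform inward normal current density I / area (natural
  boundary condition),
* cathode pad: either grounded (Dirichlet V = 0, the gauge used for
  montage runs) or an equal-and-opposite current density with the gauge
  fixed by pinning the node nearest the head centre (used when comparing
  against the analytic two-cap sphere solution, which injects current at
  both electrodes),
* everywhere else: insulated (zero flux).

E = -grad V is constant per element; per-voxel magnitudes are the
volume-weighted mean of the voxel's 5 elements.  An analytic
Legendre-series solution for a homogeneous conducting sphere with uniform
spherical-cap current source/sink serves as the validation oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import LinearOperator, cg, splu

from .images import LabelVolume, RoiSphere

MM = 1e-3  # mm -> m

#: tissue conductivities in S/m
DEFAULT_CONDUCTIVITIES = {
    "WM": 0.126,
    "GM": 0.276,
    "CSF": 1.65,
    "bone": 0.01,
    "skin": 0.465,
    "air": 2.5e-14,
    "gel": 0.3,
    "electrode": 5.9e7,
    "tumor_enhancing": 0.170,
    "tumor_nonenhancing": 0.332,
    "necrosis": 1.0,
    "edema": 1.185,
}

#: approximate 10-20 positions as unit directions on the phantom scalp
#: (x: left negative, y: anterior, z: superior)
ELECTRODE_DIRECTIONS = {
    "C3": np.array([-np.sin(np.pi / 4), 0.0, np.cos(np.pi / 4)]),
    "C4": np.array([np.sin(np.pi / 4), 0.0, np.cos(np.pi / 4)]),
    "FP1": np.array([-np.sin(np.radians(18)), np.cos(np.radians(18)), 0.0]),
    "FP2": np.array([np.sin(np.radians(18)), np.cos(np.radians(18)), 0.0]),
    "Cz": np.array([0.0, 0.0, 1.0]),
}


@dataclass
class ConductivityTable:
    values: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONDUCTIVITIES)
    )

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.values.items() if not v > 0}
        if bad:
            raise ValueError(f"conductivities must be positive: {bad}")

    def sigma_of_labels(self, label_map: dict[int, str]) -> dict[int, float]:
        missing = [t for t in label_map.values() if t not in self.values]
        if missing:
            raise ValueError(f"no conductivity for tissues {missing}")
        return {code: self.values[t] for code, t in label_map.items()}


@dataclass
class MontageSpec:
    """Electrode montage: pad centres as unit directions from the head
    centre, pad area, injected current."""

    anode: str | np.ndarray = "C3"
    cathode: str | np.ndarray = "FP1"
    pad_cm: tuple[float, float] = (5.0, 7.0)
    current_A: float = 2e-3

    def __post_init__(self) -> None:
        if not self.current_A > 0:
            raise ValueError("current must be positive")

    @property
    def pad_area_mm2(self) -> float:
        return self.pad_cm[0] * self.pad_cm[1] * 100.0

    def direction(self, which: str) -> np.ndarray:
        v = getattr(self, which)
        if isinstance(v, str):
            v = ELECTRODE_DIRECTIONS[v]
        v = np.asarray(v, float).reshape(3)
        return v / np.linalg.norm(v)


# 5-tet decomposition of the unit cube.  Corner tets sit on the even-sum
# corners, the central tet is the odd-sum regular tetrahedron; for odd
# voxel parity the whole pattern is mirrored in x so faces on shared cube
# sides carry matching diagonals.
_D0 = np.array(
    [
        [(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)],
        [(1, 1, 0), (0, 1, 0), (1, 0, 0), (1, 1, 1)],
        [(1, 0, 1), (0, 0, 1), (1, 1, 1), (1, 0, 0)],
        [(0, 1, 1), (1, 1, 1), (0, 0, 1), (0, 1, 0)],
        [(1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 1)],
    ],
    dtype=np.int64,
)
_D1 = _D0.copy()
_D1[..., 0] = 1 - _D1[..., 0]


@dataclass
class TetMesh:
    """Tet mesh in mm with per-element tissue label and source voxel."""

    nodes_mm: np.ndarray  # (n_nodes, 3)
    tets: np.ndarray  # (n_tets, 4) node indices, positively oriented
    labels: np.ndarray  # (n_tets,) tissue label codes
    label_map: dict[int, str]
    voxel_of: np.ndarray  # (n_tets,) linear index into the source grid
    grid_shape: tuple[int, int, int]
    affine: np.ndarray | None = None  # voxel->mm map of the source grid

    @property
    def n_nodes(self) -> int:
        return self.nodes_mm.shape[0]

    @property
    def n_tets(self) -> int:
        return self.tets.shape[0]

    def element_volumes_mm3(self) -> np.ndarray:
        x = self.nodes_mm[self.tets]
        d = x[:, 1:] - x[:, :1]
        return np.linalg.det(d) / 6.0

    def boundary_faces(self) -> np.ndarray:
        """Faces owned by exactly one tet, as (k, 3) node-index triples."""
        faces, counts, _ = _face_census(self.tets)
        return faces[counts == 1]

    def save_vtk(self, path: str | Path, cell_data: dict[str, np.ndarray] | None = None) -> None:
        write_vtk(path, self.nodes_mm, self.tets,
                  {"label": self.labels, **(cell_data or {})})


_FACE_LOCAL = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]])


def _face_census(tets: np.ndarray):
    faces = np.sort(tets[:, _FACE_LOCAL].reshape(-1, 3), axis=1)
    uniq, inverse, counts = np.unique(
        faces, axis=0, return_inverse=True, return_counts=True
    )
    return uniq, counts, inverse


def voxels_to_tetmesh(labels: LabelVolume) -> TetMesh:
    """Split every labelled voxel into 5 tetrahedra (parity-mirrored so
    the mesh conforms); element volumes sum exactly to the voxel volume."""
    grid = labels.data
    vox = np.argwhere(grid > 0)
    if vox.shape[0] == 0:
        raise ValueError("label volume has no labelled voxels")
    shape = grid.shape
    corner_shape = tuple(s + 1 for s in shape)

    parity = vox.sum(axis=1) % 2
    local = np.where(parity[:, None, None, None] == 0, _D0[None], _D1[None])
    corners = vox[:, None, None, :] + local  # (V, 5, 4, 3)
    corner_ids = np.ravel_multi_index(
        tuple(corners.reshape(-1, 3).T), corner_shape
    ).reshape(-1, 4)

    used, tets = np.unique(corner_ids, return_inverse=True)
    tets = tets.reshape(-1, 4)
    cijk = np.stack(np.unravel_index(used, corner_shape), axis=1).astype(float)
    # corner (i,j,k) sits at voxel coordinate (i-1/2, j-1/2, k-1/2)
    A, b = labels.affine[:3, :3], labels.affine[:3, 3]
    nodes_mm = (cijk - 0.5) @ A.T + b

    elem_labels = np.repeat(grid[tuple(vox.T)], 5)
    voxel_of = np.repeat(np.ravel_multi_index(tuple(vox.T), shape), 5)

    # enforce positive orientation
    x = nodes_mm[tets]
    vol6 = np.linalg.det(x[:, 1:] - x[:, :1])
    flip = vol6 < 0
    tets[flip, 2], tets[flip, 3] = tets[flip, 3].copy(), tets[flip, 2].copy()
    return TetMesh(nodes_mm, tets, elem_labels, dict(labels.label_map),
                   voxel_of, shape, affine=np.asarray(labels.affine))


@dataclass
class ElectrodePatches:
    """Boundary-face sets for the anode and cathode pads (areas in mm²)."""

    anode_faces: np.ndarray
    cathode_faces: np.ndarray
    anode_area_mm2: float
    cathode_area_mm2: float

    def centroid(self, nodes_mm: np.ndarray, which: str) -> np.ndarray:
        f = getattr(self, f"{which}_faces")
        return nodes_mm[f].mean(axis=(0, 1))


def _face_areas(nodes_mm: np.ndarray, faces: np.ndarray) -> np.ndarray:
    p = nodes_mm[faces]
    return 0.5 * np.linalg.norm(
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
    )


def _select_patch(
    nodes_mm: np.ndarray,
    faces: np.ndarray,
    direction: np.ndarray,
    target_area_mm2: float,
    center: np.ndarray,
) -> np.ndarray:
    cent = nodes_mm[faces].mean(axis=1) - center
    cent /= np.linalg.norm(cent, axis=1, keepdims=True)
    ang = np.arccos(np.clip(cent @ direction, -1, 1))
    areas = _face_areas(nodes_mm, faces)
    order = np.argsort(ang, kind="stable")
    cum = np.cumsum(areas[order])
    k = int(np.searchsorted(cum, target_area_mm2)) + 1
    k = min(k, faces.shape[0])
    return faces[order[:k]]


def place_electrodes(
    mesh: TetMesh,
    montage: MontageSpec,
    skin_tissue: str = "skin",
) -> ElectrodePatches:
    """Select scalp boundary faces around each montage direction, growing
    the patch by angular distance until the requested pad area is covered."""
    faces, counts, _ = _face_census(mesh.tets)
    bfaces = faces[counts == 1]
    skin_code = {v: k for k, v in mesh.label_map.items()}.get(skin_tissue)
    if skin_code is not None:
        skin_nodes = np.unique(mesh.tets[mesh.labels == skin_code])
        on_skin = np.isin(bfaces, skin_nodes).all(axis=1)
        surf = bfaces[on_skin]
    else:
        surf = bfaces
    if surf.shape[0] == 0:
        raise ValueError("no scalp surface faces found")
    center = mesh.nodes_mm.mean(axis=0)
    target = montage.pad_area_mm2
    anode = _select_patch(mesh.nodes_mm, surf, montage.direction("anode"),
                          target, center)
    cathode = _select_patch(mesh.nodes_mm, surf, montage.direction("cathode"),
                            target, center)
    a_set = {tuple(f) for f in anode}
    if any(tuple(f) in a_set for f in cathode):
        raise ValueError("electrode pads overlap on the scalp")
    a_area = float(_face_areas(mesh.nodes_mm, anode).sum())
    c_area = float(_face_areas(mesh.nodes_mm, cathode).sum())
    if a_area > _face_areas(mesh.nodes_mm, surf).sum() / 2:
        raise ValueError("pad larger than half the scalp surface")
    return ElectrodePatches(anode, cathode, a_area, c_area)


def reflect_patch(mesh: TetMesh, faces: np.ndarray, center_mm=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Point-reflect a boundary face set through ``center_mm`` (used to
    build exactly antipodal montages on symmetric phantoms)."""
    center_mm = np.asarray(center_mm, float)
    target = 2 * center_mm - mesh.nodes_mm[faces]  # (k, 3, 3)
    # match reflected node coordinates back to node indices
    from scipy.spatial import cKDTree

    tree = cKDTree(mesh.nodes_mm)
    d, idx = tree.query(target.reshape(-1, 3))
    if d.max() > 1e-6:
        raise ValueError("mesh is not point-symmetric about the given centre")
    return idx.reshape(-1, 3)


@dataclass
class FemSolution:
    mesh: TetMesh
    potentials: np.ndarray  # (n_nodes,) volts
    e_vectors: np.ndarray  # (n_tets, 3) V/m
    e_magnitude: np.ndarray  # (n_tets,) V/m
    current_A: float
    sigma: np.ndarray  # (n_tets,) S/m
    stiffness: sparse.csr_matrix  # full (unconstrained) system, SI units
    load: np.ndarray

    def current_through_layer(self, layer: int, axis: int = 2) -> float:
        """Current (A) crossing the voxel layer ``layer`` along ``axis``.

        Integrates the current density component sigma * E_axis over the
        slab of elements whose source voxel sits in that layer and divides
        by the slab thickness — the exact mean, over planes within the
        slab, of the discrete current through a cutting plane.  For a
        layer separating anode from cathode this must equal the injected
        current up to discretization leakage.
        """
        mesh = self.mesh
        vidx = np.array(np.unravel_index(mesh.voxel_of, mesh.grid_shape))
        sel = vidx[axis] == layer
        if not sel.any():
            raise ValueError(f"no elements in layer {layer} of axis {axis}")
        vols_m3 = mesh.element_volumes_mm3()[sel] * MM**3
        j = self.sigma[sel] * self.e_vectors[sel, axis]
        h_m = np.abs(mesh.affine[axis, axis]) * MM if mesh.affine is not None \
            else np.nan
        return float(np.sum(j * vols_m3) / h_m)


def _assemble(mesh: TetMesh, table: ConductivityTable):
    sigma_of = table.sigma_of_labels(mesh.label_map)
    sigma = np.vectorize(sigma_of.get)(mesh.labels).astype(float)
    x = mesh.nodes_mm[mesh.tets] * MM  # (M, 4, 3) metres
    D = x[:, 1:] - x[:, :1]  # (M, 3, 3)
    vol = np.linalg.det(D) / 6.0
    if np.any(vol <= 0):
        raise ValueError("inverted elements in mesh")
    Dinv = np.linalg.inv(D)  # rows of Dinv.T are grad lambda_{1..3}
    G = np.empty((mesh.n_tets, 4, 3))
    G[:, 1:, :] = np.transpose(Dinv, (0, 2, 1))
    G[:, 0, :] = -G[:, 1:, :].sum(axis=1)
    Ke = np.einsum("m,m,mik,mjk->mij", sigma, vol, G, G)
    rows = np.repeat(mesh.tets, 4, axis=1).ravel()
    cols = np.tile(mesh.tets, (1, 4)).ravel()
    K = sparse.coo_matrix(
        (Ke.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    ).tocsr()
    return K, G, vol, sigma


def _neumann_load(mesh: TetMesh, faces: np.ndarray, total_current_A: float) -> np.ndarray:
    """Consistent nodal loads for a uniform normal current density
    ``total_current_A / patch_area`` over the face set."""
    areas_m2 = _face_areas(mesh.nodes_mm, faces) * MM**2
    density = total_current_A / areas_m2.sum()
    f = np.zeros(mesh.n_nodes)
    contrib = density * areas_m2 / 3.0
    for j in range(3):
        np.add.at(f, faces[:, j], contrib)
    return f


def _solve_spd(K: sparse.csr_matrix, f: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """Jacobi-preconditioned conjugate gradients (the system is SPD once
    the gauge is fixed); direct sparse LU as fallback."""
    n = K.shape[0]
    d = K.diagonal()
    M = LinearOperator((n, n), lambda x: x / d)
    x, info = cg(K, f, M=M, rtol=rtol, maxiter=20000)
    if info != 0:  # pragma: no cover - heterogeneity beyond CG's reach
        return splu(K.tocsc()).solve(f)
    return x


def solve_field(
    mesh: TetMesh,
    table: ConductivityTable,
    patches: ElectrodePatches,
    current: float | None = None,
    cathode_mode: str = "dirichlet",
) -> FemSolution:
    """P1 finite-element solution of div(sigma grad V) = 0.

    ``cathode_mode='dirichlet'`` grounds the cathode pad (V = 0);
    ``'neumann'`` injects -I there and pins the node nearest the head
    centre as the gauge (the configuration matching the analytic two-cap
    sphere solution).
    """
    current = current if current is not None else 2e-3
    K, G, vol, sigma = _assemble(mesh, table)
    f = _neumann_load(mesh, patches.anode_faces, current)
    if cathode_mode == "neumann":
        f -= _neumann_load(mesh, patches.cathode_faces, current)
        center = mesh.nodes_mm.mean(axis=0)
        pin = int(np.argmin(np.linalg.norm(mesh.nodes_mm - center, axis=1)))
        fixed = np.array([pin])
    elif cathode_mode == "dirichlet":
        fixed = np.unique(patches.cathode_faces)
    else:
        raise ValueError("cathode_mode must be 'dirichlet' or 'neumann'")
    free = np.setdiff1d(np.arange(mesh.n_nodes), fixed)
    Kff = K[free][:, free].tocsr()
    Vf = _solve_spd(Kff, f[free])
    V = np.zeros(mesh.n_nodes)
    V[free] = Vf
    if cathode_mode == "neumann":
        V -= V.mean()
    E = -np.einsum("mi,mik->mk", V[mesh.tets], G)  # V/m
    return FemSolution(mesh, V, E, np.linalg.norm(E, axis=1), current, sigma,
                       K, f)


def analytic_sphere_potential(
    probe_mm,
    source_pos,
    sink_pos,
    sigma: float,
    radius: float,
    current: float = 1.0,
    cap_theta_rad: float = 0.0,
    tol: float = 1e-10,
    max_terms: int = 20000,
):
    """Legendre-series potential inside a homogeneous insulated sphere
    with surface current source and sink.

    ``cap_theta_rad = 0`` gives the classical point-electrode solution;
    a positive value spreads each electrode as a uniform current density
    over a spherical cap of that angular radius (matching pad patches).
    Distances in mm, sigma in S/m, current in A, result in volts.
    """
    probe = np.atleast_2d(np.asarray(probe_mm, float))
    src = np.asarray(source_pos, float) / np.linalg.norm(source_pos)
    snk = np.asarray(sink_pos, float) / np.linalg.norm(sink_pos)
    r = np.linalg.norm(probe, axis=1)
    if np.any(r >= radius):
        raise ValueError("probe must lie strictly inside the sphere")
    with np.errstate(invalid="ignore"):
        u = np.where(r[:, None] > 0, probe / np.maximum(r, 1e-300)[:, None], 0.0)
    cos_s = np.clip(u @ src, -1, 1)
    cos_k = np.clip(u @ snk, -1, 1)
    rho = r / radius
    R_m = radius * MM

    x0 = np.cos(cap_theta_rad)
    # Legendre recurrences for P_n at cos_s, cos_k and x0
    p_s = [np.ones_like(cos_s), cos_s]
    p_k = [np.ones_like(cos_k), cos_k]
    p_0 = [1.0, x0]

    V = np.zeros(probe.shape[0])
    ref = 0.0
    stall = 0
    for n in range(1, max_terms):
        if len(p_s) <= n + 1:
            for p, xv in ((p_s, cos_s), (p_k, cos_k), (p_0, x0)):
                m = len(p) - 1
                p.append(((2 * m + 1) * xv * p[m] - m * p[m - 1]) / (m + 1))
        if cap_theta_rad > 0:
            # uniform cap: coefficient of P_n in the surface current density
            j0 = current / (2 * np.pi * R_m**2 * (1 - x0))
            b_n = j0 * (p_0[n - 1] - p_0[n + 1]) / 2.0
        else:
            b_n = current * (2 * n + 1) / (4 * np.pi * R_m**2)
        coef = b_n * R_m / (sigma * n)
        term = coef * rho**n * (p_s[n] - p_k[n])
        V += term
        mag = np.max(np.abs(term))
        ref = max(ref, np.max(np.abs(V)), 1e-300)
        if mag < tol * ref:
            stall += 1
            if stall >= 5:
                break
        else:
            stall = 0
    else:
        raise RuntimeError("Legendre series did not converge "
                           "(probe too close to an electrode?)")
    return V if np.ndim(probe_mm) == 2 else float(V[0])


def interpolate_potential(solution: FemSolution, points_mm: np.ndarray) -> np.ndarray:
    """Barycentric (P1) interpolation of the potential at interior points.

    Each point is located in its containing voxel through the affine and
    tested against that voxel's 5 tetrahedra."""
    pts = np.atleast_2d(np.asarray(points_mm, float))
    mesh = solution.mesh
    if mesh.affine is None:
        raise ValueError("mesh carries no affine; cannot locate points")
    nodes = mesh.nodes_mm
    out = np.full(pts.shape[0], np.nan)
    order = np.argsort(mesh.voxel_of, kind="stable")
    vox_sorted = mesh.voxel_of[order]
    inv = np.linalg.inv(mesh.affine)
    for i, p in enumerate(pts):
        vi = np.round(inv[:3, :3] @ p + inv[:3, 3]).astype(int)
        vi = np.clip(vi, 0, np.array(mesh.grid_shape) - 1)
        best = None
        # the containing tet may sit in a face/edge-neighbouring voxel when
        # the point lies exactly on a voxel boundary
        for dv in _NEIGHBOUR_OFFSETS:
            vj = vi + dv
            if np.any(vj < 0) or np.any(vj >= mesh.grid_shape):
                continue
            lin = np.ravel_multi_index(tuple(vj), mesh.grid_shape)
            lo = np.searchsorted(vox_sorted, lin)
            hi = np.searchsorted(vox_sorted, lin, side="right")
            for e in order[lo:hi]:
                verts = nodes[mesh.tets[e]]
                T = (verts[1:] - verts[:1]).T
                lam = np.linalg.solve(T, p - verts[0])
                lams = np.concatenate([[1 - lam.sum()], lam])
                if np.all(lams >= -1e-9):
                    best = (e, lams)
                    break
            if best is not None:
                break
        if best is None:
            raise ValueError(f"point {p} not inside the meshed region")
        e, lams = best
        out[i] = lams @ solution.potentials[mesh.tets[e]]
    return out


_NEIGHBOUR_OFFSETS = np.vstack(
    [[0, 0, 0]]
    + [np.array(v) - 1 for v in np.ndindex(3, 3, 3) if v != (1, 1, 1)]
)


def efield_to_voxels(solution: FemSolution, labels: LabelVolume) -> np.ndarray:
    """Per-voxel |E| as the volume-weighted mean over the voxel's elements
    (NaN outside the labelled region)."""
    mesh = solution.mesh
    if mesh.grid_shape != labels.data.shape:
        raise ValueError("mesh does not derive from this label volume")
    nvox = int(np.prod(mesh.grid_shape))
    vols = mesh.element_volumes_mm3()
    wsum = np.bincount(mesh.voxel_of, weights=vols * solution.e_magnitude,
                       minlength=nvox)
    w = np.bincount(mesh.voxel_of, weights=vols, minlength=nvox)
    out = np.full(nvox, np.nan)
    ok = w > 0
    out[ok] = wsum[ok] / w[ok]
    return out.reshape(mesh.grid_shape)


def roi_mean_ef(
    ef_volume: np.ndarray, roi: RoiSphere, restrict_mask: np.ndarray | None = None
) -> float:
    """Mean |E| (V/m) over the ROI voxels that carry a field value.

    ``restrict_mask`` (e.g. the brain labels) drops sphere voxels that
    fall into other tissues — without it a cortical sphere on a coarse
    grid picks up high-field skull voxels."""
    sel = np.zeros(ef_volume.shape, dtype=bool)
    sel[roi.indices()] = True
    if restrict_mask is not None:
        sel &= np.asarray(restrict_mask, bool)
    vals = ef_volume[sel]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("ROI contains no field-carrying voxels")
    return float(vals.mean())


def write_vtk(path: str | Path, nodes_mm: np.ndarray, tets: np.ndarray,
              cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Minimal legacy-ASCII VTK unstructured-grid writer (tet cells)."""
    lines = [
        "# vtk DataFile Version 3.0", "stimconn tetrahedral mesh", "ASCII",
        "DATASET UNSTRUCTURED_GRID", f"POINTS {len(nodes_mm)} float",
    ]
    lines += [" ".join(f"{v:.6g}" for v in p) for p in nodes_mm]
    lines.append(f"CELLS {len(tets)} {len(tets) * 5}")
    lines += ["4 " + " ".join(str(i) for i in t) for t in tets]
    lines.append(f"CELL_TYPES {len(tets)}")
    lines += ["10"] * len(tets)
    if cell_data:
        lines.append(f"CELL_DATA {len(tets)}")
        for name, vals in cell_data.items():
            lines += [f"SCALARS {name} float 1", "LOOKUP_TABLE default"]
            lines += [f"{float(v):.6g}" for v in vals]
    Path(path).write_text("\n".join(lines) + "\n")
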