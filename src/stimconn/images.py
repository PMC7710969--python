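"""Core in-memory containers for the pipeline.

Everything downstream operates on four small dataclasses: a 4D BOLD image
with its repetition time and voxel->mm affine, a labelled 3D head volume,
a per-volume motion trace, and a spherical region of interest resolved to
voxel indices.  NIfTI round-tripping goes through nibabel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

#: fixed tissue vocabulary for labelled head volumes
TISSUES = (
    "skin",
    "bone",
    "CSF",
    "GM",
    "WM",
    "air",
    "gel",
    "electrode",
    "tumor_enhancing",
    "tumor_nonenhancing",
    "necrosis",
    "edema",
)

MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")


@dataclass
class BoldImage:
    """A 4D BOLD run: (x, y, z, t) samples, TR in seconds, voxel->mm affine."""

    data: np.ndarray
    tr_seconds: float
    affine: np.ndarray
    run_id: str = "run-1"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D, got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise ValueError("BOLD run needs at least 2 volumes")
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (…,3) to mm coordinates via the affine."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        out = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
        return out.squeeze()

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms((*img.header.get_zooms()[:3], self.tr_seconds))
        return img

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path: str | Path, run_id: str | None = None) -> "BoldImage":
        img = nib.load(str(path))
        tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 1.0
        return cls(
            data=np.asanyarray(img.dataobj, dtype=float),
            tr_seconds=tr,
            affine=np.asarray(img.affine),
            run_id=run_id or Path(path).name,
        )


@dataclass
class LabelVolume:
    """Integer-labelled 3D volume with a label->tissue map and voxel size."""

    data: np.ndarray
    label_map: dict[int, str]
    voxel_size_mm: float
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("label volume must be 3D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label volume must be integer typed")
        present = set(np.unique(self.data)) - {0}
        missing = present - set(self.label_map)
        if missing:
            raise ValueError(f"labels {sorted(missing)} not in label_map")
        bad = [t for t in self.label_map.values() if t not in TISSUES]
        if bad:
            raise ValueError(f"unknown tissue names {bad}; allowed: {TISSUES}")
        if self.affine is None:
            # centred scaling affine: mm origin at the grid centre
            c = (np.array(self.data.shape) - 1) / 2.0
            aff = np.eye(4)
            aff[:3, :3] *= self.voxel_size_mm
            aff[:3, 3] = -c * self.voxel_size_mm
            self.affine = aff

    @property
    def tissue_of(self) -> dict[str, int]:
        return {v: k for k, v in self.label_map.items()}

    def mask(self, *tissues: str) -> np.ndarray:
        labels = [self.tissue_of[t] for t in tissues if t in self.tissue_of]
        return np.isin(self.data, labels)

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.int16), self.affine)
        nib.save(img, str(path))
        side = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + "_labels.json")
        side.write_text(json.dumps({str(k): v for k, v in self.label_map.items()}))

    @classmethod
    def load(cls, path: str | Path, label_map: dict[int, str] | None = None) -> "LabelVolume":
        img = nib.load(str(path))
        if label_map is None:
            side = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + "_labels.json")
            label_map = {int(k): v for k, v in json.loads(side.read_text()).items()}
        zoom = float(img.header.get_zooms()[0])
        return cls(
            data=np.asanyarray(img.dataobj).astype(np.int64),
            label_map=label_map,
            voxel_size_mm=zoom,
            affine=np.asarray(img.affine),
        )


@dataclass
class MotionTrace:
    """Per-volume rigid-body motion: 3 translations (mm) + 3 rotations (rad)."""

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion trace must be (n_volumes, 6)")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    def framewise_displacement(self, rotation_radius_mm: float = 50.0) -> np.ndarray:
        """Power-style FD: sum of |Δ| of the 6 parameters, rotations as arc
        length on a sphere of ``rotation_radius_mm``.  FD[0] = 0."""
        d = np.abs(np.diff(self.params, axis=0))
        d[:, 3:] *= rotation_radius_mm
        fd = np.zeros(self.n_volumes)
        fd[1:] = d.sum(axis=1)
        return fd

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.params, columns=list(MOTION_COLUMNS)).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MotionTrace":
        df = pd.read_csv(path, sep="\t")
        return cls(df[list(MOTION_COLUMNS)].to_numpy())


@dataclass
class RoiSphere:
    """6-mm-style spherical seed: centre in mm plus its resolved voxel set."""

    center_mm: np.ndarray
    radius_mm: float
    voxel_set: np.ndarray  # (k, 3) int voxel indices
    side: str = "left"

    def __post_init__(self) -> None:
        self.center_mm = np.asarray(self.center_mm, dtype=float).reshape(3)
        self.voxel_set = np.asarray(self.voxel_set, dtype=int).reshape(-1, 3)
        if self.voxel_set.shape[0] == 0:
            raise ValueError("ROI sphere resolved to zero voxels")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")

    @property
    def n_voxels(self) -> int:
        return self.voxel_set.shape[0]

    def indices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(self.voxel_set.T)  # type: ignore[return-value]

    def mask(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(grid_shape, dtype=bool)
        m[self.indices()] = True
        return m

    def mean_series(self, bold: BoldImage) -> np.ndarray:
        return bold.data[self.indices()].mean(axis=0)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "center_mm": self.center_mm.tolist(),
                    "radius_mm": self.radius_mm,
                    "side": self.side,
                    "n_voxels": int(self.n_voxels),
                }
            )
        )


def default_affine(voxel_size_mm: float | tuple[float, float, float], grid_shape) -> np.ndarray:
    """Scaling affine that puts mm (0,0,0) at the centre of the grid."""
    vs = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    c = (np.array(grid_shape[:3]) - 1) / 2.0
    aff = np.eye(4)
    aff[:3, :3] = np.diag(vs)
    aff[:3, 3] = -c * vs
    return aff
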