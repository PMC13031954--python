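"""Volume and mesh I/O with one fixed coordinate convention.

All world coordinates in this package are millimetres in a single RAS+ frame.
Voxel indices are 0-based; voxel ``(i, j, k)`` occupies the half-open cell
centered at ``affine @ (i, j, k, 1)`` with extent of one voxel spacing per
axis.  This makes the strict >50% partial-volume rule used downstream
unambiguous.  A fourth lattice axis, when present, is the cardiac phase.

Volumes travel as NIfTI-1; surfaces as STL or PLY (vertices in mm).  Phase
images are stored in radians, velocity volumes in cm/s; the velocity-encoding
limit (VENC) of a phase-contrast volume rides along in the NIfTI ``descrip``
field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import trimesh

__all__ = [
    "VolumeImage",
    "SurfaceMesh",
    "read_volume",
    "write_volume",
    "read_mesh",
    "write_mesh",
    "MeshIOError",
]

#: Triangulated surface with vertices in world millimetres.  Meshes are kept
#: verbatim on load (no implicit vertex welding).
SurfaceMesh = trimesh.Trimesh


class MeshIOError(ValueError):
    """Raised when a mesh file cannot be parsed or is empty."""


@dataclass
class VolumeImage:
    """A 3D (or 4D, trailing cardiac-phase axis) scalar lattice with an affine.

    Parameters
    ----------
    data:
        Array of shape ``(nx, ny, nz)`` or ``(nx, ny, nz, n_phases)``.
    affine:
        4x4 voxel-index -> world-mm map; must be invertible.
    units:
        Declared intensity units: ``"a.u."``, ``"cm/s"`` or ``"rad"``.
    venc:
        Velocity-encoding limit in cm/s for phase-contrast data, else None.
    """

    data: np.ndarray
    affine: np.ndarray
    units: str = "a.u."
    venc: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim not in (3, 4):
            raise ValueError(
                f"unsupported lattice dimensionality {self.data.ndim}; "
                "expected 3D or 4D (trailing cardiac-phase axis)"
            )
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("lattice contains non-finite values")

    # -- geometry -----------------------------------------------------------

    @property
    def shape3(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])

    @property
    def n_phases(self) -> int:
        return 1 if self.data.ndim == 3 else self.data.shape[3]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing per axis in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel cell in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel center, shape ``(*shape3, 3)``."""
        ii, jj, kk = np.meshgrid(
            *(np.arange(n, dtype=float) for n in self.shape3), indexing="ij"
        )
        idx = np.stack([ii, jj, kk], axis=-1)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def copy(self) -> "VolumeImage":
        return VolumeImage(self.data.copy(), self.affine.copy(), self.units, self.venc)


# -- NIfTI volumes ----------------------------------------------------------


def _encode_descrip(units: str, venc: float | None) -> str:
    s = f"units={units}"
    if venc is not None:
        s += f";venc={venc:.6g}"
    return s


def _decode_descrip(descrip: str) -> tuple[str, float | None]:
    units, venc = "a.u.", None
    for part in descrip.split(";"):
        if part.startswith("units="):
            units = part[len("units="):]
        elif part.startswith("venc="):
            venc = float(part[len("venc="):])
    return units, venc


def write_volume(vol: VolumeImage, path: str | Path) -> Path:
    """Write a :class:`VolumeImage` as NIfTI-1 (units/VENC in ``descrip``)."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.data), vol.affine)
    img.header["descrip"] = _encode_descrip(vol.units, vol.venc).encode()
    img.header.set_xyzt_units(xyz="mm")
    nib.save(img, path)
    return path


def read_volume(path: str | Path) -> VolumeImage:
    """Read a 3D/4D NIfTI volume; the 4th axis is the cardiac phase."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim not in (3, 4):
        raise ValueError(
            f"{path}: unsupported NIfTI layout with {data.ndim} dimensions"
        )
    descrip = img.header["descrip"].item().decode(errors="replace")
    units, venc = _decode_descrip(descrip)
    return VolumeImage(data, img.affine, units=units, venc=venc)


# -- meshes -----------------------------------------------------------------


def read_mesh(path: str | Path) -> SurfaceMesh:
    """Load an STL/PLY surface verbatim (no vertex welding); vertices in mm."""
    path = Path(path)
    try:
        mesh = trimesh.load(str(path), process=False, force="mesh")
    except Exception as exc:  # parse error: re-raise naming the file
        raise MeshIOError(f"{path}: failed to parse mesh ({exc})") from exc
    if mesh is None or len(getattr(mesh, "faces", ())) == 0:
        raise MeshIOError(f"{path}: mesh is empty (no faces)")
    return mesh


def write_mesh(mesh: SurfaceMesh, path: str | Path) -> Path:
    if len(mesh.faces) == 0:
        raise MeshIOError("refusing to write an empty mesh")
    path = Path(path)
    mesh.export(str(path))
    return path
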