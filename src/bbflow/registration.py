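"""Rigid surface registration and transform composition.

The VOI-transfer chain needs two rigid maps: ``T_lumen`` (TOF -> CAD frame,
estimated by aligning the TOF-segmented lumen with the CAD lumen) and
``T_wall`` (TOF -> BB frame, from the wall surfaces segmented on both
modalities).  CAD-defined VOIs are then carried into BB image space by the
composition ``T_wall @ T_lumen^-1``.

Transforms use the column-vector convention: ``p' = R p + t``.  ICP is
point-to-point with nearest-neighbour correspondence on the target vertex
cloud (surfaces here are dense marching-cubes meshes, so vertex spacing is on
the order of the voxel pitch).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .io import SurfaceMesh

__all__ = [
    "RigidTransform",
    "AlignmentReport",
    "icp_align",
    "compose_voi_transform",
    "apply_transform",
    "save_transform",
    "load_transform",
    "DegenerateSourceError",
]


class DegenerateSourceError(ValueError):
    """Source geometry has no well-defined rigid alignment (e.g. collinear)."""


class RigidTransform:
    """4x4 homogeneous rigid transform (rotation R, translation t in mm)."""

    __slots__ = ("matrix",)

    def __init__(self, matrix: np.ndarray):
        m = np.asarray(matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("rigid transform must be 4x4")
        R = m[:3, :3]
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation block is not orthonormal (1e-9)")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation block must be proper (det = +1)")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=1e-12):
            raise ValueError("last row must be (0, 0, 0, 1)")
        self.matrix = m

    # -- constructors -------------------------------------------------------

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(cls, R: np.ndarray, t: np.ndarray) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = np.asarray(t, dtype=float)
        return cls(m)

    @classmethod
    def from_axis_angle(
        cls, axis: np.ndarray, angle_rad: float, translation=(0.0, 0.0, 0.0)
    ) -> "RigidTransform":
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        K = np.array(
            [
                [0, -axis[2], axis[1]],
                [axis[2], 0, -axis[0]],
                [-axis[1], axis[0], 0],
            ]
        )
        R = np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)
        # re-orthonormalize against accumulated rounding
        u, _, vt = np.linalg.svd(R)
        return cls.from_rotation_translation(u @ vt, translation)

    @classmethod
    def random(
        cls, rng: np.random.Generator, max_angle_deg: float, max_translation_mm: float
    ) -> "RigidTransform":
        axis = rng.normal(size=3)
        angle = np.deg2rad(rng.uniform(-max_angle_deg, max_angle_deg))
        t = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
        return cls.from_axis_angle(axis, angle, t)

    # -- algebra ------------------------------------------------------------

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def inverse(self) -> "RigidTransform":
        R = self.rotation
        t = self.translation
        return RigidTransform.from_rotation_translation(R.T, -R.T @ t)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        m = self.matrix @ other.matrix
        # snap the product back onto SO(3) to keep invariants under chaining
        u, _, vt = np.linalg.svd(m[:3, :3])
        return RigidTransform.from_rotation_translation(u @ vt, m[:3, 3])

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def rotation_angle(self) -> float:
        """Rotation magnitude in radians."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.arccos(np.clip(c, -1.0, 1.0)))

    def __repr__(self) -> str:  # pragma: no cover
        return f"RigidTransform(angle={np.rad2deg(self.rotation_angle()):.3f}deg, t={self.translation})"


def apply_transform(mesh_or_points, T: RigidTransform):
    """Return a transformed copy; topology of meshes is unchanged."""
    if isinstance(mesh_or_points, SurfaceMesh):
        out = mesh_or_points.copy()
        out.vertices = T.apply(np.asarray(mesh_or_points.vertices))
        return out
    return T.apply(mesh_or_points)


def compose_voi_transform(T_wall: RigidTransform, T_lumen: RigidTransform) -> RigidTransform:
    """CAD -> BB map: ``T_wall @ T_lumen^-1`` (column-vector convention)."""
    return T_wall @ T_lumen.inverse()


@dataclass
class AlignmentReport:
    """Outcome of an ICP run."""

    transform: RigidTransform
    mean_error: float  # mm, post-alignment mean nearest-neighbour distance
    iterations: int
    converged: bool
    error_history: np.ndarray = field(default_factory=lambda: np.empty(0))


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid map src -> dst for paired points."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    u, _, vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    R = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform.from_rotation_translation(R, cd - R @ cs)


def _as_points(mesh_or_points) -> np.ndarray:
    if isinstance(mesh_or_points, SurfaceMesh):
        return np.asarray(mesh_or_points.vertices, dtype=float)
    return np.asarray(mesh_or_points, dtype=float)


def _subsample(points: np.ndarray, max_points: int) -> np.ndarray:
    if len(points) <= max_points:
        return points
    idx = np.linspace(0, len(points) - 1, max_points).astype(int)
    return points[np.unique(idx)]


def _pca_init_candidates(src: np.ndarray, dst: np.ndarray) -> list[RigidTransform]:
    """Centroid + principal-axes initializations (4 proper sign flips)."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    us = np.linalg.svd(src - cs, full_matrices=False)[2].T
    ud = np.linalg.svd(dst - cd, full_matrices=False)[2].T
    if np.linalg.det(us) < 0:
        us[:, 2] *= -1
    if np.linalg.det(ud) < 0:
        ud[:, 2] *= -1
    cands = []
    for signs in itertools.product([1.0, -1.0], repeat=3):
        if np.prod(signs) < 0:
            continue  # improper
        R = ud @ np.diag(signs) @ us.T
        cands.append(RigidTransform.from_rotation_translation(R, cd - R @ cs))
    return cands


def _point_to_plane_step(
    cur: np.ndarray, q: np.ndarray, n: np.ndarray, ridge: float = 1e-9
) -> RigidTransform:
    """One linearized point-to-plane update: minimize
    ``sum(n . (p + w x p + dt - q))^2`` over the twist ``(w, dt)``.
    A small ridge keeps unobservable directions (e.g. rotation about a
    cylinder axis) at zero instead of drifting."""
    A = np.hstack([np.cross(cur, n), n])  # (N, 6)
    b = np.einsum("ij,ij->i", n, q - cur)
    H = A.T @ A + ridge * len(cur) * np.eye(6)
    x = np.linalg.solve(H, A.T @ b)
    w, dt = x[:3], x[3:]
    angle = np.linalg.norm(w)
    if angle < 1e-15:
        return RigidTransform.from_rotation_translation(np.eye(3), dt)
    return RigidTransform.from_axis_angle(w / angle, angle, dt)


def icp_align(
    source,
    target,
    init: RigidTransform | str | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
    max_points: int = 20000,
    metric: str = "point",
) -> AlignmentReport:
    """ICP of ``source`` onto ``target``.

    Parameters
    ----------
    init:
        Starting transform; ``"pca"`` selects a centroid + principal-axes
        initialization (sign-disambiguated over the four proper-rotation
        combinations), ``None`` / ``"identity"`` starts from the identity.
    tol:
        Convergence threshold on the change of mean correspondence distance
        between iterations, in mm.
    metric:
        ``"point"`` for classic point-to-point (Kabsch) updates, whose
        recorded error is monotone non-increasing; ``"plane"`` for
        point-to-plane updates using target vertex normals — required to
        observe axial translation of near-cylindrical vessels, where end
        caps are a tiny fraction of the points.

    Deterministic given inputs and ``init`` (subsampling is evenly strided).
    """
    src_all = _as_points(source)
    dst_all = _as_points(target)
    if len(src_all) == 0 or len(dst_all) == 0:
        raise ValueError("cannot align empty geometry")
    if metric not in ("point", "plane"):
        raise ValueError("metric must be 'point' or 'plane'")
    normals = None
    if metric == "plane":
        if not isinstance(target, SurfaceMesh):
            raise ValueError("point-to-plane metric needs a target mesh with normals")
        normals = np.asarray(target.vertex_normals, dtype=float)
    src = _subsample(src_all, max_points)
    if metric == "plane":
        keep = np.linspace(0, len(dst_all) - 1, min(len(dst_all), max_points)).astype(int)
        keep = np.unique(keep)
        dst = dst_all[keep]
        normals = normals[keep]
    else:
        dst = _subsample(dst_all, max_points)

    sv = np.linalg.svd(src - src.mean(axis=0), compute_uv=False)
    if len(src) < 3 or sv[1] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateSourceError(
            "source vertices are (nearly) collinear; rigid alignment is ill-posed"
        )

    tree = cKDTree(dst)

    if init is None or init == "identity":
        T = RigidTransform.identity()
    elif init == "pca":
        best = None
        for cand in _pca_init_candidates(src, dst):
            err = tree.query(cand.apply(src))[0].mean()
            if best is None or err < best[0]:
                best = (err, cand)
        T = best[1]
    elif isinstance(init, RigidTransform):
        T = init
    else:
        raise ValueError(f"unknown init {init!r}")

    history = []
    prev_err = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        cur = T.apply(src)
        d, j = tree.query(cur)
        err = float(d.mean())
        history.append(err)
        if metric == "point":
            # refit absolute transform from the original source to the
            # correspondences: the recorded error is monotone non-increasing
            T = _kabsch(src, dst[j])
        else:
            T = _point_to_plane_step(cur, dst[j], normals[j]) @ T
        if prev_err - err < tol:
            converged = True
            break
        prev_err = err

    final_err = float(tree.query(T.apply(src))[0].mean())
    history.append(final_err)
    return AlignmentReport(
        transform=T,
        mean_error=final_err,
        iterations=it,
        converged=converged,
        error_history=np.asarray(history),
    )


# -- serialization ----------------------------------------------------------


def save_transform(T: RigidTransform, path: str | Path) -> Path:
    """Write the 4x4 matrix as row-major CSV."""
    path = Path(path)
    np.savetxt(path, T.matrix, delimiter=",", fmt="%.17g")
    return path


def load_transform(path: str | Path) -> RigidTransform:
    return RigidTransform(np.loadtxt(path, delimiter=","))
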