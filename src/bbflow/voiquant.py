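"""VOI -> per-slice masks -> agarose-normalized BB signal.

A closed VOI surface living in BB image space is cut by each image slice
plane, giving closed planar contours; each contour is voxelized with the
strict partial-volume rule: a pixel belongs to the mask iff the contour
covers *more than* 50% of the pixel cell.  Coverage is computed by exact
polygon–rectangle clipping (no sampling), which makes the rule
deterministic.  "Voxel volume" for this 2D step is the in-plane pixel area;
slice thickness is not re-weighted.

BB intensities inside the masks are divided by the pooled voxel-weighted
mean over both agarose reference cuboids and summarized as median with
first/third quartiles.  Voxels under an artifact mask are excluded from the
signal and counted separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon, box as shapely_box

from .io import SurfaceMesh, VolumeImage

__all__ = [
    "SliceMask",
    "NormalizedSignal",
    "clip_voi_with_plane",
    "voxelize_contour",
    "voi_to_masks",
    "masks_to_volume",
    "normalize_and_summarize",
    "NonClosedSurfaceError",
]


class NonClosedSurfaceError(ValueError):
    """A VOI surface must be closed (watertight) to be clipped/voxelized."""


@dataclass
class SliceMask:
    """Binary in-plane pixel set on one image slice."""

    slice_index: int
    mask: np.ndarray  # bool, shape (nx, ny) for slicing along the k axis
    label: str = ""


@dataclass
class NormalizedSignal:
    """Per-voxel normalized BB intensities (a.u.) and their summary."""

    label: str
    values: np.ndarray
    median: float
    q1: float
    q3: float
    n: int
    reference_mean: float
    n_artifact_excluded: int = 0


# ---------------------------------------------------------------------------
# plane clipping
# ---------------------------------------------------------------------------


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(normal @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, helper)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    return u, v


def clip_voi_with_plane(
    voi: SurfaceMesh, plane_point: np.ndarray, plane_normal: np.ndarray
) -> list[np.ndarray]:
    """Intersect a closed VOI surface with a plane.

    Returns a list of closed planar contours as ``(n, 3)`` arrays (first and
    last vertex coincide); the union of their interiors is the plane cut of
    the VOI interior.  A plane that misses (or is tangent to) the VOI gives
    an empty list or zero-area contours, never an exception.
    """
    if not voi.is_watertight:
        raise NonClosedSurfaceError("VOI surface is not closed")
    try:
        section = voi.section(plane_origin=np.asarray(plane_point, float),
                              plane_normal=np.asarray(plane_normal, float))
    except Exception:
        return []
    if section is None:
        return []
    contours = []
    for poly in section.discrete:
        poly = np.asarray(poly, float)
        if len(poly) < 3:
            continue
        if not np.allclose(poly[0], poly[-1]):
            poly = np.vstack([poly, poly[0]])
        contours.append(poly)
    return contours


def _contour_to_2d(contour: np.ndarray, image: VolumeImage, slice_index: int,
                   axis: int, tol: float) -> np.ndarray:
    idx = image.world_to_index(contour)
    off = np.abs(idx[:, axis] - slice_index)
    if np.any(off > tol):
        raise ValueError(
            f"contour lies {off.max():.3g} voxels off slice plane {slice_index} "
            f"(tolerance {tol:g})"
        )
    inplane = [a for a in range(3) if a != axis]
    return idx[:, inplane]


def _voxelize_polygon_2d(poly2d: np.ndarray, grid_shape: tuple[int, int]) -> np.ndarray:
    """Strict >50% coverage voxelization of one polygon in pixel-index coords.

    Pixel ``(i, j)`` spans the cell ``[i-0.5, i+0.5] x [j-0.5, j+0.5]``.
    Polygon parts falling off the lattice are clipped (only in-lattice
    pixels can be selected).
    """
    mask = np.zeros(grid_shape, dtype=bool)
    polygon = Polygon(poly2d)
    if not polygon.is_valid:
        polygon = polygon.buffer(0)
    if polygon.is_empty or polygon.area == 0.0:
        return mask
    minx, miny, maxx, maxy = polygon.bounds
    i_lo, i_hi = int(np.floor(minx - 0.5)), int(np.ceil(maxx + 0.5))
    j_lo, j_hi = int(np.floor(miny - 0.5)), int(np.ceil(maxy + 0.5))
    for i in range(max(i_lo, 0), min(i_hi + 1, grid_shape[0])):
        for j in range(max(j_lo, 0), min(j_hi + 1, grid_shape[1])):
            cell = shapely_box(i - 0.5, j - 0.5, i + 0.5, j + 0.5)
            if polygon.intersection(cell).area > 0.5:
                mask[i, j] = True
    return mask


def voxelize_contour(
    contour: np.ndarray,
    image: VolumeImage,
    slice_index: int,
    axis: int = 2,
    label: str = "",
    tol: float = 1e-3,
) -> SliceMask:
    """Voxelize one closed planar contour (world mm) on an image slice.

    The contour must lie on the plane of ``slice_index`` along ``axis``
    (within ``tol`` voxels).  Inclusion is strict: covered area fraction
    must exceed 0.5.
    """
    poly2d = _contour_to_2d(np.asarray(contour, float), image, slice_index, axis, tol)
    inplane = [a for a in range(3) if a != axis]
    shape2 = (image.shape3[inplane[0]], image.shape3[inplane[1]])
    mask = _voxelize_polygon_2d(poly2d, shape2)
    return SliceMask(slice_index=slice_index, mask=mask, label=label)


def voi_to_masks(
    voi: SurfaceMesh, image: VolumeImage, label: str = "", axis: int = 2
) -> list[SliceMask]:
    """Clip + voxelize a VOI across all intersecting image slices."""
    if not voi.is_watertight:
        raise NonClosedSurfaceError("VOI surface is not closed")
    # work in index coordinates: slice planes become k = const, pixel cells
    # become unit squares
    idx_verts = image.world_to_index(np.asarray(voi.vertices, float))
    voi_idx = voi.copy()
    voi_idx.vertices = idx_verts
    zmin, zmax = idx_verts[:, axis].min(), idx_verts[:, axis].max()
    ks = [k for k in range(int(np.ceil(zmin)), int(np.floor(zmax)) + 1)]
    if not ks:  # VOI thinner than one slice spacing: nearest slice, possibly empty
        ks = [int(round((zmin + zmax) / 2.0))]
    if min(ks) < 0 or max(ks) >= image.shape3[axis]:
        raise ValueError("VOI extends outside the image slice range")
    normal = np.zeros(3)
    normal[axis] = 1.0
    inplane = [a for a in range(3) if a != axis]
    shape2 = (image.shape3[inplane[0]], image.shape3[inplane[1]])
    out = []
    for k in ks:
        origin = np.zeros(3)
        origin[axis] = k
        mask = np.zeros(shape2, dtype=bool)
        for contour in clip_voi_with_plane(voi_idx, origin, normal):
            mask |= _voxelize_polygon_2d(contour[:, inplane], shape2)
        out.append(SliceMask(slice_index=k, mask=mask, label=label))
    return out


def masks_to_volume(masks: list[SliceMask], image: VolumeImage, axis: int = 2) -> np.ndarray:
    """Stack slice masks into a full 3D boolean mask."""
    vol = np.zeros(image.shape3, dtype=bool)
    for sm in masks:
        sl = [slice(None)] * 3
        sl[axis] = sm.slice_index
        vol[tuple(sl)] |= sm.mask
    return vol


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def normalize_and_summarize(
    bb_image: VolumeImage,
    voi_masks: dict[str, np.ndarray],
    agarose_masks: list[np.ndarray],
    artifact_mask: np.ndarray | None = None,
) -> dict[str, NormalizedSignal]:
    """Normalize BB intensities by the pooled agarose mean and summarize.

    ``voi_masks`` maps VOI labels to 3D boolean masks (see
    :func:`masks_to_volume`); ``agarose_masks`` are the reference cuboid
    masks, pooled into one voxel-weighted mean.
    """
    if bb_image.data.ndim != 3:
        raise ValueError("BB image must be 3D")
    ref_union = np.zeros(bb_image.shape3, dtype=bool)
    for m in agarose_masks:
        ref_union |= m
    if artifact_mask is not None:
        ref_union &= ~artifact_mask
    if not np.any(ref_union):
        raise ValueError("agarose reference masks are empty in-image")
    reference = float(bb_image.data[ref_union].mean())
    if reference <= 0:
        raise ValueError(f"non-positive agarose reference mean ({reference:g})")

    out: dict[str, NormalizedSignal] = {}
    for label, mask in voi_masks.items():
        use = mask.copy()
        n_excl = 0
        if artifact_mask is not None:
            n_excl = int((use & artifact_mask).sum())
            use &= ~artifact_mask
        values = np.asarray(bb_image.data[use], dtype=float) / reference
        if values.size:
            q1, med, q3 = np.percentile(values, [25.0, 50.0, 75.0])
        else:
            q1 = med = q3 = float("nan")
        out[label] = NormalizedSignal(
            label=label,
            values=values,
            median=float(med),
            q1=float(q1),
            q3=float(q3),
            n=int(values.size),
            reference_mean=reference,
            n_artifact_excluded=n_excl,
        )
    return out
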