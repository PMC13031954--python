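"""Synthetic vascular-phantom scenes: geometry, pulsatile flow, MR rendering.

The generator emulates the in vitro setup the pipeline is built for: 3D-printed
vessel models (straight tubes of 4/6 mm inner diameter, and saccular-aneurysm
models with a 3 mm artificial wall) embedded in agarose gel, perfused by a
pulsatile pump, and imaged with TOF, spin-echo black-blood (BB, four variants)
and phase-contrast (PC) sequences.

Key modelling choices
---------------------
* Lumen flow is Poiseuille (parabolic axial profile) scaled by a unit-mean
  periodic cardiac waveform; the aneurysm sac carries a solid-body-like
  recirculation whose speed scale is ``k * (parent mean speed)`` where ``k``
  is the treatment factor (1 = untreated, 0 = total flow arrest).  Only the
  ordering and scaling of median speeds matter downstream, not the detailed
  flow topology.
* The BB intensity model is exponential-with-floor,
  ``S(|v|) = S_agar * (beta + (1 - beta) * exp(-|v| / v0))``,
  monotone non-increasing in speed.  ``v0`` controls how gradual the
  suppression is: the perpendicular-readout variant decays slowly
  (v0 = 20 cm/s) while MSDE/parallel variants suppress sharply (v0 = 2 cm/s).
  The functional form is a calibration stand-in constrained only by
  monotonicity; it is not measured physics.
* PC phase is ``pi * v / VENC`` wrapped to (-pi, pi]; VENC defaults to 1.1x
  the maximum true speed.
* Each modality can be rendered under a rigid misalignment of its frame
  relative to the scene (CAD) frame; Rician noise is added last.  The exact
  applied transforms and noiseless summaries go into a ground-truth registry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh
from skimage import measure

from .io import SurfaceMesh, VolumeImage, write_mesh, write_volume
from .registration import RigidTransform

__all__ = [
    "GeometrySpec",
    "FlowSpec",
    "CardiacWaveform",
    "SequenceVariant",
    "Geometry",
    "VelocitySeries",
    "PhantomScene",
    "SceneTruth",
    "build_geometry",
    "build_velocity_field",
    "render_sequence",
    "inject_artifact",
    "make_scene",
    "default_bb_variants",
    "auto_venc",
    "AGAROSE_BOX_MM",
]

#: Agarose reference cuboid dimensions (x, y, z) in mm.
AGAROSE_BOX_MM = (19.5, 16.3, 23.4)

S_AGAR = 100.0  # agarose intensity level, a.u.
BB_WALL = 140.0  # wall level on BB images (separable from gel and fluid)
TOF_LUMEN, TOF_WALL, TOF_GEL = 200.0, 60.0, 20.0
PC_MAG_FLUID, PC_MAG_GEL, PC_MAG_WALL = 100.0, 80.0, 40.0


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeometrySpec:
    """Declarative description of one vascular model.

    ``sac_dims`` is ``(height, neck_width, dome_width)`` in mm, matching how
    saccular aneurysms are conventionally measured (height along the
    protrusion axis, neck at the parent-vessel opening, dome at the widest
    point).
    """

    kind: str  # straight_tube | sidewall_aneurysm | bifurcation_aneurysm
    inner_diameter: float = 4.0
    tube_length: float = 60.0
    wall_thickness: float = 3.0
    sac_dims: tuple[float, float, float] | None = None
    dome_to_neck: float | None = None

    def __post_init__(self):
        kinds = ("straight_tube", "sidewall_aneurysm", "bifurcation_aneurysm")
        if self.kind not in kinds:
            raise ValueError(f"unknown geometry kind {self.kind!r}")
        for name in ("inner_diameter", "tube_length", "wall_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.kind == "straight_tube":
            if self.sac_dims is not None:
                raise ValueError("a straight tube cannot carry an aneurysm sac")
        else:
            if self.sac_dims is None:
                raise ValueError(f"{self.kind} requires sac_dims")
            h, nw, dw = self.sac_dims
            if min(h, nw, dw) <= 0:
                raise ValueError("sac dimensions must be > 0")
            if nw > dw + 1e-12:
                raise ValueError("neck width cannot exceed dome width")
            dtn = self.effective_dome_to_neck()
            if self.kind == "bifurcation_aneurysm" and dtn < 1.0 - 1e-12:
                raise ValueError("dome-to-neck ratio must be >= 1 for bifurcation sacs")

    def effective_dome_to_neck(self) -> float | None:
        if self.sac_dims is None:
            return None
        if self.dome_to_neck is not None:
            return self.dome_to_neck
        _, nw, dw = self.sac_dims
        return dw / nw


class CardiacWaveform:
    """Unit-mean periodic waveform with a raised-cosine systolic peak.

    ``w(tau) = 1 + amplitude * (p(tau) - width/2)`` where ``p`` is a raised
    cosine of support ``width`` (as a fraction of the cycle) centered at
    ``peak_phase``; the subtraction makes the time average exactly 1.  With
    the defaults the peak sits at 0.2 s of a 0.8 s cycle and peak flow is
    about 2.5x the mean, a realistic pulsatile-pump profile.
    """

    def __init__(self, peak_phase: float = 0.25, width: float = 0.45, amplitude: float = 2.0):
        if not 0 < width < 1:
            raise ValueError("width must be in (0, 1)")
        if amplitude * width / 2.0 > 1.0:
            raise ValueError("amplitude too large: waveform would go negative")
        self.peak_phase = peak_phase
        self.width = width
        self.amplitude = amplitude

    def __call__(self, tau: np.ndarray) -> np.ndarray:
        """Evaluate at cycle fraction ``tau`` (any real; periodic with 1)."""
        tau = np.asarray(tau, dtype=float)
        d = (tau - self.peak_phase + 0.5) % 1.0 - 0.5
        pulse = np.where(
            np.abs(d) < self.width / 2.0,
            0.5 * (1.0 + np.cos(2.0 * np.pi * d / self.width)),
            0.0,
        )
        return 1.0 + self.amplitude * (pulse - self.width / 2.0)


@dataclass(frozen=True)
class FlowSpec:
    """Pulsatile flow conditions for one scene.

    ``treatment_factor`` (k) scales the intra-sac velocity: 1 means untreated,
    values < 1 emulate a flow-modulating device without modelling its struts.
    """

    mean_flow_rate: float  # ml/s
    cardiac_period: float = 0.8  # s
    waveform: CardiacWaveform = field(default_factory=CardiacWaveform)
    treatment_factor: float = 1.0

    def __post_init__(self):
        if self.mean_flow_rate < 0:
            raise ValueError("mean flow rate must be >= 0")
        if self.cardiac_period <= 0:
            raise ValueError("cardiac period must be > 0")
        if not 0 <= self.treatment_factor <= 1:
            raise ValueError("treatment factor k must be in [0, 1]")
        tau = (np.arange(20000) + 0.5) / 20000
        if abs(float(np.mean(self.waveform(tau))) - 1.0) > 1e-6:
            raise ValueError("waveform time-average must be 1 within 1e-6")


@dataclass(frozen=True)
class SequenceVariant:
    """A BB sequence variant and its suppression parameters.

    ``suppression_scale`` (v0, cm/s) sets how fast signal decays with speed;
    ``suppression_floor`` (beta) is the residual signal fraction at high speed.
    """

    name: str
    suppression_scale: float = 20.0
    suppression_floor: float = 0.05

    def __post_init__(self):
        if self.suppression_scale <= 0:
            raise ValueError("suppression scale v0 must be > 0")
        if not 0 <= self.suppression_floor < 1:
            raise ValueError("suppression floor beta must be in [0, 1)")


def default_bb_variants() -> tuple[SequenceVariant, ...]:
    """The four BB variants: perpendicular readout decays gradually, the
    MSDE-prepared and parallel-readout variants suppress sharply."""
    return (
        SequenceVariant("BB_perp", suppression_scale=20.0),
        SequenceVariant("BB_perp_MSDE", suppression_scale=2.0),
        SequenceVariant("BB_par", suppression_scale=2.0),
        SequenceVariant("BB_par_MSDE", suppression_scale=2.0),
    )


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


@dataclass
class Geometry:
    """Analytic phantom geometry plus derived meshes and VOIs.

    The vessel axis is z, centered at the origin.  Sidewall sacs protrude
    along +x from the tube; bifurcation sacs sit past the +z tube end.  All
    region predicates are analytic so images can be rendered at arbitrary
    (misaligned) sample points without resampling error.
    """

    spec: GeometrySpec
    cad_lumen: SurfaceMesh | None = None
    cad_wall: SurfaceMesh | None = None
    vois: dict[str, SurfaceMesh] = field(default_factory=dict)

    # -- derived scalars ----------------------------------------------------

    @property
    def radius(self) -> float:
        return self.spec.inner_diameter / 2.0

    @property
    def half_length(self) -> float:
        return self.spec.tube_length / 2.0

    @property
    def outer_radius(self) -> float:
        return self.radius + self.spec.wall_thickness

    @property
    def sac_axis(self) -> np.ndarray | None:
        if self.spec.kind == "sidewall_aneurysm":
            return np.array([1.0, 0.0, 0.0])
        if self.spec.kind == "bifurcation_aneurysm":
            return np.array([0.0, 0.0, 1.0])
        return None

    @property
    def sac_center(self) -> np.ndarray | None:
        axis = self.sac_axis
        if axis is None:
            return None
        h, nw, dw = self.spec.sac_dims
        a = h / 2.0
        # offset the ellipsoid so its cross-section at the attachment plane
        # has diameter = neck width
        d = a * math.sqrt(max(0.0, 1.0 - (nw / dw) ** 2))
        base = self.radius if self.spec.kind == "sidewall_aneurysm" else self.half_length
        return axis * (base + d)

    @property
    def sac_radii(self) -> np.ndarray | None:
        """Ellipsoid semi-axes in world (x, y, z) order."""
        if self.spec.sac_dims is None:
            return None
        h, nw, dw = self.spec.sac_dims
        a, b = h / 2.0, dw / 2.0
        if self.spec.kind == "sidewall_aneurysm":
            return np.array([a, b, b])
        return np.array([b, b, a])

    # -- region predicates --------------------------------------------------

    def inside_cylinder(self, pts: np.ndarray, extra: float = 0.0) -> np.ndarray:
        pts = np.atleast_2d(pts)
        r = self.radius + extra
        rho2 = pts[:, 0] ** 2 + pts[:, 1] ** 2
        return (rho2 <= r * r) & (np.abs(pts[:, 2]) <= self.half_length + extra)

    def inside_sac(self, pts: np.ndarray, extra: float = 0.0) -> np.ndarray:
        if self.sac_center is None:
            return np.zeros(len(np.atleast_2d(pts)), dtype=bool)
        pts = np.atleast_2d(pts)
        rel = (pts - self.sac_center) / (self.sac_radii + extra)
        return np.einsum("ij,ij->i", rel, rel) <= 1.0

    def inside_lumen(self, pts: np.ndarray) -> np.ndarray:
        return self.inside_cylinder(pts) | self.inside_sac(pts)

    def inside_wall(self, pts: np.ndarray) -> np.ndarray:
        t = self.spec.wall_thickness
        dilated = self.inside_cylinder(pts, extra=t) | self.inside_sac(pts, extra=t)
        return dilated & ~self.inside_lumen(pts)

    def implicit(self, pts: np.ndarray, inflate: float = 0.0) -> np.ndarray:
        """Smooth inside-positive field for the fluid region (optionally
        inflated by ``inflate`` mm, giving the outer wall surface).  Zero
        level set = the region boundary; used for sub-voxel-accurate
        marching-cubes meshing."""
        pts = np.atleast_2d(pts)
        r = self.radius + inflate
        hl = self.half_length + inflate
        rho = np.sqrt(pts[:, 0] ** 2 + pts[:, 1] ** 2)
        f = np.minimum(r - rho, hl - np.abs(pts[:, 2]))
        if self.sac_center is not None:
            radii = self.sac_radii + inflate
            rel = (pts - self.sac_center) / radii
            rho_n = np.sqrt(np.einsum("ij,ij->i", rel, rel))
            f_sac = (1.0 - rho_n) * float(np.min(radii))
            f = np.maximum(f, f_sac)
        return f

    # -- layout helpers -----------------------------------------------------

    def vessel_voi_center(self) -> np.ndarray:
        return np.array([0.0, 0.0, -self.half_length / 2.0])

    def agarose_centers(self, clearance: float = 4.0) -> list[np.ndarray]:
        y_wall = self.outer_radius
        if self.sac_radii is not None:
            # the sac (plus its wall) may reach further laterally than the tube
            y_wall = max(y_wall, abs(self.sac_center[1]) + self.sac_radii[1]
                         + self.spec.wall_thickness)
        y = y_wall + clearance + AGAROSE_BOX_MM[1] / 2.0
        return [np.array([0.0, -y, 0.0]), np.array([0.0, y, 0.0])]

    def fov_bounds(self, margin: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
        """World-space axis-aligned bounds covering wall, sac and agarose."""
        lo = np.array([-self.outer_radius, 0.0, -self.half_length - margin])
        hi = np.array([self.outer_radius, 0.0, self.half_length + margin])
        lo[0] -= margin
        hi[0] += margin
        if self.sac_center is not None:
            c, rr = self.sac_center, self.sac_radii + self.spec.wall_thickness
            lo = np.minimum(lo, c - rr - margin)
            hi = np.maximum(hi, c + rr + margin)
        box = np.asarray(AGAROSE_BOX_MM) / 2.0
        for ac in self.agarose_centers():
            lo = np.minimum(lo, ac - box - margin)
            hi = np.maximum(hi, ac + box + margin)
        return lo, hi

    def make_grid(self, spacing: float = 0.6, margin: float = 3.0):
        """Image lattice covering the field of view: ``(shape, affine)``."""
        lo, hi = self.fov_bounds(margin)
        shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
        affine = np.eye(4)
        affine[:3, :3] *= spacing
        affine[:3, 3] = lo + spacing / 2.0
        return tuple(int(n) for n in shape), affine


def _mesh_from_implicit(field, lo, hi, pitch: float) -> SurfaceMesh:
    """Closed surface of the zero level set of an inside-positive field,
    sampled on a fine lattice (marching cubes interpolates the crossing, so
    the surface is sub-voxel accurate)."""
    lo = np.asarray(lo, dtype=float)
    shape = np.ceil((np.asarray(hi) - lo) / pitch).astype(int) + 3
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    pts = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) * pitch + (lo - pitch)
    vals = field(pts).reshape(shape).astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(vals, level=0.0)
    verts = verts * pitch + (lo - pitch)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def build_geometry(spec: GeometrySpec, mesh_pitch: float = 0.35) -> Geometry:
    """Construct CAD lumen/wall meshes and the labelled VOI set.

    VOIs: a cylindrical ``vessel`` VOI inside the parent segment (80% of the
    lumen radius, 10 mm long, away from the sac), an ellipsoidal ``aneurysm``
    VOI (75% of the sac semi-axes) when a sac exists, and two agarose
    reference cuboids of 19.5 x 16.3 x 23.4 mm placed laterally in the gel.
    """
    geom = Geometry(spec=spec)
    pad = spec.wall_thickness + 2.0
    lo = np.array([-geom.outer_radius - pad, -geom.outer_radius - pad, -geom.half_length - pad])
    hi = np.array([geom.outer_radius + pad, geom.outer_radius + pad, geom.half_length + pad])
    if geom.sac_center is not None:
        c, rr = geom.sac_center, geom.sac_radii + pad
        lo = np.minimum(lo, c - rr)
        hi = np.maximum(hi, c + rr)
    geom.cad_lumen = _mesh_from_implicit(geom.implicit, lo, hi, mesh_pitch)
    geom.cad_wall = _mesh_from_implicit(
        lambda p: geom.implicit(p, inflate=spec.wall_thickness), lo, hi, mesh_pitch
    )

    vois: dict[str, SurfaceMesh] = {}
    vessel = trimesh.creation.cylinder(radius=0.8 * geom.radius, height=10.0, sections=48)
    vessel.apply_translation(geom.vessel_voi_center())
    vois["vessel"] = vessel
    if geom.sac_center is not None:
        sphere = trimesh.creation.icosphere(subdivisions=3)
        sphere.vertices = sphere.vertices * (0.75 * geom.sac_radii) + geom.sac_center
        vois["aneurysm"] = sphere
    for label, center in zip(("agarose_left", "agarose_right"), geom.agarose_centers()):
        box = trimesh.creation.box(extents=AGAROSE_BOX_MM)
        box.apply_translation(center)
        vois[label] = box
    geom.vois = vois
    return geom


# ---------------------------------------------------------------------------
# flow
# ---------------------------------------------------------------------------


@dataclass
class VelocitySeries:
    """Per-voxel, per-cardiac-phase velocity components in cm/s.

    ``data`` has shape ``(3, nx, ny, nz, n_phases)``.
    """

    data: np.ndarray
    affine: np.ndarray
    times: np.ndarray  # s, phase centers
    venc: float | None = None

    def __post_init__(self):
        if self.data.ndim != 5 or self.data.shape[0] != 3:
            raise ValueError("velocity data must have shape (3, nx, ny, nz, n_phases)")
        if self.venc is not None and self.venc <= 0:
            raise ValueError("VENC must be > 0")

    @property
    def n_phases(self) -> int:
        return self.data.shape[-1]

    def speed(self) -> np.ndarray:
        """Speed magnitude, shape ``(nx, ny, nz, n_phases)``."""
        return np.sqrt(np.einsum("c...,c...->...", self.data, self.data))

    def copy(self) -> "VelocitySeries":
        return VelocitySeries(self.data.copy(), self.affine.copy(), self.times.copy(), self.venc)


def _unit_flow_field(geom: Geometry, flow: FlowSpec, pts: np.ndarray) -> np.ndarray:
    """Velocity vectors (cm/s) at world points for unit mean parent speed.

    The actual field is this times ``v_mean(t) = Q(t) / (pi r^2)``.
    """
    n = len(pts)
    out = np.zeros((n, 3), dtype=np.float64)
    r = geom.radius
    in_cyl = geom.inside_cylinder(pts)
    if np.any(in_cyl):
        rho2 = pts[in_cyl, 0] ** 2 + pts[in_cyl, 1] ** 2
        out[in_cyl, 2] = 2.0 * (1.0 - rho2 / (r * r))  # Poiseuille, peak 2x mean
    if geom.sac_center is not None:
        in_sac = geom.inside_sac(pts) & ~in_cyl
        if np.any(in_sac):
            rel = pts[in_sac] - geom.sac_center
            radii = geom.sac_radii
            rho_n = np.sqrt(np.einsum("ij,ij->i", (rel / radii), (rel / radii)))
            # solid-body-like recirculation about the y axis, capped at the
            # neck mean speed (k * v_mean)
            tangent = np.stack(
                [rel[:, 2], np.zeros(in_sac.sum()), -rel[:, 0]], axis=1
            )
            norm = np.linalg.norm(tangent, axis=1)
            ok = norm > 1e-12
            tangent[ok] /= norm[ok, None]
            tangent[~ok] = 0.0
            k = flow.treatment_factor
            out[in_sac] = tangent * (k * np.clip(rho_n, 0.0, 1.0))[:, None]
    return out


def _mean_speed_cms(geom: Geometry, flow: FlowSpec) -> float:
    """Cross-section mean parent-vessel speed in cm/s: Q / (pi r^2)."""
    r_cm = geom.radius / 10.0
    area = math.pi * r_cm * r_cm
    return flow.mean_flow_rate / area


def build_velocity_field(
    geom: Geometry,
    flow: FlowSpec,
    shape: tuple[int, int, int],
    affine: np.ndarray,
    n_phases: int = 10,
) -> VelocitySeries:
    """Sample the analytic velocity field on an image lattice.

    Returns per-phase velocities ``S(p) * v_mean * w(t)`` with ``w`` the
    cardiac waveform; zero outside the fluid.
    """
    grid = VolumeImage(np.zeros(shape, dtype=np.float32), affine)
    pts = grid.voxel_centers().reshape(-1, 3)
    unit = _unit_flow_field(geom, flow, pts)  # (N, 3)
    v_mean = _mean_speed_cms(geom, flow)
    times = (np.arange(n_phases) + 0.5) / n_phases * flow.cardiac_period
    w = flow.waveform(times / flow.cardiac_period)
    data = np.empty((3,) + tuple(shape) + (n_phases,), dtype=np.float32)
    base = (unit * v_mean).T.reshape((3,) + tuple(shape))
    for t in range(n_phases):
        data[..., t] = base * w[t]
    return VelocitySeries(data=data, affine=np.asarray(affine, float), times=times)


def auto_venc(series_or_max: VelocitySeries | float, fallback: float = 10.0) -> float:
    """VENC rule: 1.1x the maximum true speed; ``fallback`` for static scenes."""
    if isinstance(series_or_max, VelocitySeries):
        vmax = float(series_or_max.speed().max())
    else:
        vmax = float(series_or_max)
    return 1.1 * vmax if vmax > 0 else fallback


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _rician(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma <= 0:
        return signal
    g1 = rng.normal(0.0, sigma, signal.shape)
    g2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + g1) ** 2 + g2 ** 2)


def _wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    return np.pi - np.mod(np.pi - phi, 2.0 * np.pi)


def _scene_points(shape, affine, misalignment: RigidTransform) -> np.ndarray:
    """Scene-frame coordinates of the (misaligned) image's voxel centers."""
    grid = VolumeImage(np.zeros(shape, dtype=np.float32), affine)
    pts = grid.voxel_centers().reshape(-1, 3)
    return misalignment.inverse().apply(pts)


def _bb_signal(speed: np.ndarray, variant: SequenceVariant) -> np.ndarray:
    b = variant.suppression_floor
    return S_AGAR * (b + (1.0 - b) * np.exp(-speed / variant.suppression_scale))


def render_sequence(
    geom: Geometry,
    flow: FlowSpec,
    variant: SequenceVariant | str,
    shape: tuple[int, int, int],
    affine: np.ndarray,
    noise_sigma: float = 0.0,
    misalignment: RigidTransform | None = None,
    rng: np.random.Generator | None = None,
    n_phases: int = 10,
    venc: float | None = None,
) -> dict[str, VolumeImage]:
    """Render one MR sequence of the scene on the given lattice.

    ``variant`` is a BB :class:`SequenceVariant`, or the string ``"TOF"`` or
    ``"PC"``.  Returns a dict of named volumes: BB and TOF produce a single
    entry; PC produces ``magnitude`` plus one wrapped-phase 4D volume per
    velocity component (``phase_x|y|z``).  Noiseless truth is what you get
    with ``noise_sigma=0``; the noisy render equals truth plus Rician noise
    added last.
    """
    if misalignment is None:
        misalignment = RigidTransform.identity()
    if noise_sigma > 0 and rng is None:
        raise ValueError("rng is mandatory when noise_sigma > 0")
    pts = _scene_points(shape, affine, misalignment)
    in_lumen = geom.inside_lumen(pts)
    in_wall = geom.inside_wall(pts)
    unit = _unit_flow_field(geom, flow, pts)
    v_mean = _mean_speed_cms(geom, flow)
    # waveform is non-negative, so the time-averaged speed is just the
    # spatial profile times the mean speed
    s0 = np.linalg.norm(unit, axis=1) * v_mean

    name = variant if isinstance(variant, str) else variant.name
    out: dict[str, VolumeImage] = {}
    if isinstance(variant, SequenceVariant):
        img = np.full(len(pts), S_AGAR)
        img[in_wall] = BB_WALL
        img[in_lumen] = _bb_signal(s0[in_lumen], variant)
        img = img.reshape(shape)
        if noise_sigma > 0:
            img = _rician(img, noise_sigma, rng)
        out[name] = VolumeImage(img.astype(np.float32), np.asarray(affine, float))
    elif name == "TOF":
        img = np.full(len(pts), TOF_GEL)
        img[in_wall] = TOF_WALL
        img[in_lumen] = TOF_LUMEN
        img = img.reshape(shape)
        if noise_sigma > 0:
            img = _rician(img, noise_sigma, rng)
        out["TOF"] = VolumeImage(img.astype(np.float32), np.asarray(affine, float))
    elif name == "PC":
        if venc is None:
            venc = auto_venc(2.0 * v_mean)  # peak Poiseuille speed
        if venc <= 0:
            raise ValueError("VENC must be > 0 for PC rendering")
        times = (np.arange(n_phases) + 0.5) / n_phases * flow.cardiac_period
        w = flow.waveform(times / flow.cardiac_period)
        mag = np.full(len(pts), PC_MAG_GEL)
        mag[in_wall] = PC_MAG_WALL
        mag[in_lumen] = PC_MAG_FLUID
        mag = mag.reshape(shape)
        if noise_sigma > 0:
            mag = _rician(mag, noise_sigma, rng)
        out["magnitude"] = VolumeImage(mag.astype(np.float32), np.asarray(affine, float))
        for ci, comp in enumerate("xyz"):
            phase = np.empty(tuple(shape) + (n_phases,), dtype=np.float32)
            base = (unit[:, ci] * v_mean).reshape(shape)
            for t in range(n_phases):
                phi = np.pi * (base * w[t]) / venc
                if noise_sigma > 0:
                    # phase noise of a complex signal: sigma / magnitude
                    phi = phi + rng.normal(0.0, noise_sigma / PC_MAG_FLUID, phi.shape)
                phase[..., t] = _wrap_phase(phi)
            out[f"phase_{comp}"] = VolumeImage(
                phase, np.asarray(affine, float), units="rad", venc=venc
            )
    else:
        raise ValueError(f"unknown sequence variant {variant!r}")
    return out


def inject_artifact(
    image: VolumeImage, center: np.ndarray, radius: float, level: float = 0.0
) -> tuple[VolumeImage, np.ndarray]:
    """Simulate a metal-artifact signal void: voxels whose centers lie
    strictly inside the sphere are set to ``level``; returns the modified
    image and the boolean artifact mask (for overlap reporting and exclusion
    downstream)."""
    if radius < 0:
        raise ValueError("artifact radius must be >= 0")
    pts = image.voxel_centers().reshape(-1, 3)
    d2 = np.einsum("ij,ij->i", pts - np.asarray(center, float), pts - np.asarray(center, float))
    mask = (d2 < radius * radius).reshape(image.shape3)
    out = image.copy()
    if image.data.ndim == 4:
        out.data[mask, :] = level
    else:
        out.data[mask] = level
    return out, mask


# ---------------------------------------------------------------------------
# scenes
# ---------------------------------------------------------------------------


@dataclass
class SceneTruth:
    """Ground-truth registry for a rendered scene."""

    misalignments: dict[str, RigidTransform]
    median_speed: dict[str, float]  # per VOI, time-averaged speed, cm/s
    bb_median_noiseless: dict[tuple[str, str], float]  # (variant, voi) -> a.u.


@dataclass
class PhantomScene:
    geometry: Geometry
    flow: FlowSpec
    shape: tuple[int, int, int]
    affine: np.ndarray
    images: dict[str, VolumeImage]
    velocity_truth: VelocitySeries
    truth: SceneTruth
    seed: int | None = None

    @property
    def vois(self) -> dict[str, SurfaceMesh]:
        return self.geometry.vois

    def export(self, out_dir: str | Path) -> None:
        """Write volumes (NIfTI), meshes (STL) and the truth registry (CSV)."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, img in self.images.items():
            write_volume(img, out_dir / f"{name}.nii")
        write_mesh(self.geometry.cad_lumen, out_dir / "cad_lumen.stl")
        write_mesh(self.geometry.cad_wall, out_dir / "cad_wall.stl")
        for label, voi in self.vois.items():
            write_mesh(voi, out_dir / f"voi_{label}.stl")
        import csv

        with open(out_dir / "truth.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["key", "value"])
            for voi, v in self.truth.median_speed.items():
                w.writerow([f"median_speed/{voi}", f"{v:.9g}"])
            for (variant, voi), v in self.truth.bb_median_noiseless.items():
                w.writerow([f"bb_median/{variant}/{voi}", f"{v:.9g}"])
            for mod, T in self.truth.misalignments.items():
                for i in range(4):
                    for j in range(4):
                        w.writerow([f"misalignment/{mod}/{i}{j}", f"{T.matrix[i, j]:.17g}"])


def _voi_region_mask(geom: Geometry, label: str, pts: np.ndarray) -> np.ndarray:
    """Analytic interior test for the built-in VOIs (used for truth only)."""
    if label == "vessel":
        c = geom.vessel_voi_center()
        rel = pts - c
        return (rel[:, 0] ** 2 + rel[:, 1] ** 2 <= (0.8 * geom.radius) ** 2) & (
            np.abs(rel[:, 2]) <= 5.0
        )
    if label == "aneurysm":
        rel = (pts - geom.sac_center) / (0.75 * geom.sac_radii)
        return np.einsum("ij,ij->i", rel, rel) <= 1.0
    raise KeyError(label)


def make_scene(
    geometry_spec: GeometrySpec,
    flow_spec: FlowSpec,
    variants: tuple[SequenceVariant, ...] | None = None,
    spacing: float = 0.6,
    n_phases: int = 10,
    noise_sigma: float = 2.0,
    misalign: bool = True,
    max_misalign_deg: float = 4.0,
    max_misalign_mm: float = 2.5,
    seed: int = 0,
    mesh_pitch: float = 0.35,
    pc_misaligned: bool = False,
    fov_margin: float | None = None,
) -> PhantomScene:
    """Build a fully specified scene: geometry, flow truth and all images.

    TOF and the BB variants are rendered under per-modality rigid
    misalignments (all BB variants share one BB frame, as in a single
    scanning session).  PC is rendered in the scene frame by default,
    emulating marker-based plane planning; set ``pc_misaligned`` to move it
    too.  Deterministic given the config and ``seed``.
    """
    if variants is None:
        variants = default_bb_variants()
    geom = build_geometry(geometry_spec, mesh_pitch=mesh_pitch)
    if fov_margin is None:
        # misaligned renders must still contain the whole model: allow for
        # the maximum translation plus the rotational lever arm
        fov_margin = 3.0
        if misalign:
            lo0, hi0 = geom.fov_bounds(0.0)
            lever = float(max(np.linalg.norm(lo0), np.linalg.norm(hi0)))
            # translation + rotational lever arm + slack for the azimuthal
            # freedom of the estimated transform on symmetric geometry
            fov_margin += max_misalign_mm + lever * math.sin(math.radians(max_misalign_deg)) + 2.0
    shape, affine = geom.make_grid(spacing=spacing, margin=fov_margin)
    vel = build_velocity_field(geom, flow_spec, shape, affine, n_phases=n_phases)
    venc = auto_venc(vel)
    vel.venc = venc

    ss = np.random.SeedSequence(seed)
    rngs = {name: np.random.default_rng(s) for name, s in zip(
        ("misalign", "TOF", "BB", "PC"), ss.spawn(4))}

    ident = RigidTransform.identity()
    if misalign:
        m_tof = RigidTransform.random(rngs["misalign"], max_misalign_deg, max_misalign_mm)
        m_bb = RigidTransform.random(rngs["misalign"], max_misalign_deg, max_misalign_mm)
        m_pc = (
            RigidTransform.random(rngs["misalign"], max_misalign_deg, max_misalign_mm)
            if pc_misaligned
            else ident
        )
    else:
        m_tof = m_bb = m_pc = ident

    images: dict[str, VolumeImage] = {}
    images.update(
        render_sequence(geom, flow_spec, "TOF", shape, affine, noise_sigma, m_tof, rngs["TOF"])
    )
    for variant in variants:
        images.update(
            render_sequence(
                geom, flow_spec, variant, shape, affine, noise_sigma, m_bb, rngs["BB"]
            )
        )
    pc = render_sequence(
        geom, flow_spec, "PC", shape, affine, noise_sigma, m_pc, rngs["PC"],
        n_phases=n_phases, venc=venc,
    )
    images.update({f"PC_{k}": v for k, v in pc.items()})

    # ground truth: noiseless medians over the analytic VOI interiors
    grid = VolumeImage(np.zeros(shape, dtype=np.float32), affine)
    pts = grid.voxel_centers().reshape(-1, 3)
    unit = _unit_flow_field(geom, flow_spec, pts)
    s0 = np.linalg.norm(unit, axis=1) * _mean_speed_cms(geom, flow_spec)
    median_speed: dict[str, float] = {}
    bb_medians: dict[tuple[str, str], float] = {}
    labels = ["vessel"] + (["aneurysm"] if geom.sac_center is not None else [])
    for label in labels:
        m = _voi_region_mask(geom, label, pts)
        if np.any(m):
            median_speed[label] = float(np.median(s0[m]))
            for variant in variants:
                bb_medians[(variant.name, label)] = float(
                    np.median(_bb_signal(s0[m], variant)) / S_AGAR
                )

    truth = SceneTruth(
        misalignments={"TOF": m_tof, "BB": m_bb, "PC": m_pc},
        median_speed=median_speed,
        bb_median_noiseless=bb_medians,
    )
    return PhantomScene(
        geometry=geom,
        flow=flow_spec,
        shape=shape,
        affine=affine,
        images=images,
        velocity_truth=vel,
        truth=truth,
        seed=seed,
    )
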