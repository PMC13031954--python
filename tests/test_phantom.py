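"""Synthetic-scene generator: geometry, flow truth, image formation."""

import numpy as np
import pytest

from bbflow import phantom
from bbflow.io import VolumeImage
from bbflow.registration import RigidTransform


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


def test_geometry_spec_validation():
    with pytest.raises(ValueError, match="sac"):
        phantom.GeometrySpec(kind="straight_tube", sac_dims=(3, 2, 3))
    with pytest.raises(ValueError, match="sac_dims"):
        phantom.GeometrySpec(kind="sidewall_aneurysm")
    with pytest.raises(ValueError, match="> 0"):
        phantom.GeometrySpec(kind="straight_tube", inner_diameter=-1)
    with pytest.raises(ValueError, match="neck"):
        phantom.GeometrySpec(kind="bifurcation_aneurysm", sac_dims=(5.0, 4.0, 3.0))


def test_flow_spec_validation():
    with pytest.raises(ValueError):
        phantom.FlowSpec(mean_flow_rate=-1.0)
    with pytest.raises(ValueError):
        phantom.FlowSpec(mean_flow_rate=1.0, cardiac_period=0.0)
    with pytest.raises(ValueError):
        phantom.FlowSpec(mean_flow_rate=1.0, treatment_factor=1.5)


def test_waveform_unit_mean_and_peak():
    w = phantom.CardiacWaveform()
    tau = (np.arange(200000) + 0.5) / 200000
    vals = w(tau)
    assert abs(vals.mean() - 1.0) < 1e-6
    assert vals.min() >= 0.0
    # systolic peak at 0.2 s of the 0.8 s cycle
    assert tau[np.argmax(vals)] == pytest.approx(0.25, abs=0.01)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def test_tube_lumen_volume_matches_cylinder(tube_geometry):
    expected = np.pi * 2.0**2 * 60.0  # 753.98 mm^3
    assert tube_geometry.cad_lumen.volume == pytest.approx(expected, rel=0.02)


def test_wall_outer_diameter_is_lumen_plus_thickness(tube_geometry):
    verts = np.asarray(tube_geometry.cad_wall.vertices)
    mid = np.abs(verts[:, 2]) < 20.0  # away from end caps
    rho = np.sqrt(verts[mid, 0] ** 2 + verts[mid, 1] ** 2)
    assert rho.max() == pytest.approx(5.0, abs=0.3)  # ID 4 mm + 3 mm wall


def test_bifurcation_voi_fits_inside_sac_bbox():
    spec = phantom.GeometrySpec(
        kind="bifurcation_aneurysm", inner_diameter=3.2, tube_length=40.0,
        sac_dims=(3.5, 2.7, 3.2),
    )
    geom = phantom.build_geometry(spec)
    voi = geom.vois["aneurysm"]
    lo = geom.sac_center - geom.sac_radii
    hi = geom.sac_center + geom.sac_radii
    assert np.all(voi.vertices >= lo - 1e-6) and np.all(voi.vertices <= hi + 1e-6)


def test_meshes_and_vois_are_closed(sidewall_geometry):
    assert sidewall_geometry.cad_lumen.is_watertight
    assert sidewall_geometry.cad_wall.is_watertight
    for voi in sidewall_geometry.vois.values():
        assert voi.is_watertight


def test_agarose_cuboids_outside_lumen(tube_geometry):
    for label in ("agarose_left", "agarose_right"):
        pts = np.asarray(tube_geometry.vois[label].vertices)
        assert not np.any(tube_geometry.inside_lumen(pts))


# ---------------------------------------------------------------------------
# velocity field
# ---------------------------------------------------------------------------


def _tube_field(geom, Q, spacing=0.5, n_phases=4, k=1.0, steady=False):
    wave = phantom.CardiacWaveform(amplitude=0.0) if steady else phantom.CardiacWaveform()
    flow = phantom.FlowSpec(mean_flow_rate=Q, waveform=wave, treatment_factor=k)
    shape, affine = geom.make_grid(spacing=spacing)
    return flow, phantom.build_velocity_field(geom, flow, shape, affine, n_phases=n_phases)


def test_flow_conservation_across_sections(tube_geometry):
    """Spatial-mean axial velocity x lumen area recovers Q(t) within 2%."""
    flow, vel = _tube_field(tube_geometry, Q=4.7, spacing=0.5)
    grid = VolumeImage(np.zeros(vel.data.shape[1:4], np.float32), vel.affine)
    pts = grid.voxel_centers()
    w = flow.waveform(vel.times / flow.cardiac_period)
    for t in range(vel.n_phases):
        vz = vel.data[2, ..., t]
        for k_slice in (20, 40, 60):
            sl_pts = pts[:, :, k_slice, :].reshape(-1, 3)
            in_lumen = tube_geometry.inside_cylinder(sl_pts).reshape(vz.shape[:2])
            # cm/s * mm^2 -> ml/s is a factor 1/100
            flux = vz[:, :, k_slice][in_lumen].sum() * 0.5 * 0.5 / 100.0
            assert flux == pytest.approx(4.7 * w[t], rel=0.02)


def test_zero_flow_gives_zero_field(tube_geometry):
    _, vel = _tube_field(tube_geometry, Q=0.0, spacing=0.8)
    assert np.all(vel.data == 0.0)


def test_sac_speed_scales_linearly_with_treatment_factor(sidewall_geometry):
    geom = sidewall_geometry
    speeds = {}
    for k in (1.0, 0.1):
        _, vel = _tube_field(geom, Q=4.5, spacing=0.8, k=k)
        grid = VolumeImage(np.zeros(vel.data.shape[1:4], np.float32), vel.affine)
        pts = grid.voxel_centers().reshape(-1, 3)
        sac = geom.inside_sac(pts) & ~geom.inside_cylinder(pts)
        speeds[k] = np.median(vel.speed()[..., 0].reshape(-1)[sac])
    assert speeds[0.1] / speeds[1.0] == pytest.approx(0.1, abs=1e-6)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def test_static_bb_equals_agarose_level(tube_geometry):
    flow = phantom.FlowSpec(mean_flow_rate=0.0)
    shape, affine = tube_geometry.make_grid(spacing=0.8)
    out = phantom.render_sequence(
        tube_geometry, flow, phantom.SequenceVariant("BB_perp"), shape, affine
    )
    img = out["BB_perp"]
    pts = VolumeImage(np.zeros(shape, np.float32), affine).voxel_centers().reshape(-1, 3)
    lumen = tube_geometry.inside_lumen(pts).reshape(shape)
    np.testing.assert_allclose(img.data[lumen], phantom.S_AGAR, rtol=1e-6)


def test_bb_monotone_in_speed_voxelwise(tube_geometry):
    """Faster flow never brightens any BB voxel (noiseless renders)."""
    shape, affine = tube_geometry.make_grid(spacing=0.8)
    variant = phantom.SequenceVariant("BB_perp")
    imgs = {}
    for Q in (1.4, 4.7):
        flow = phantom.FlowSpec(mean_flow_rate=Q)
        imgs[Q] = phantom.render_sequence(tube_geometry, flow, variant, shape, affine)[
            "BB_perp"
        ].data
    assert np.all(imgs[4.7] <= imgs[1.4] + 1e-6)


def test_identity_misalignment_renders_bit_identical(tube_geometry):
    flow = phantom.FlowSpec(mean_flow_rate=3.0)
    shape, affine = tube_geometry.make_grid(spacing=0.8)
    variant = phantom.SequenceVariant("BB_perp")
    a = phantom.render_sequence(tube_geometry, flow, variant, shape, affine)["BB_perp"]
    b = phantom.render_sequence(
        tube_geometry, flow, variant, shape, affine,
        misalignment=RigidTransform.identity(),
    )["BB_perp"]
    np.testing.assert_array_equal(a.data, b.data)


def test_pc_phase_in_range_and_venc_rule(tube_scene):
    for comp in "xyz":
        phi = tube_scene.images[f"PC_phase_{comp}"]
        assert phi.data.max() <= np.pi + 1e-6
        assert phi.data.min() > -np.pi - 1e-6
        assert phi.venc == pytest.approx(1.1 * tube_scene.velocity_truth.speed().max(), rel=1e-5)


def test_scene_determinism(tube_spec):
    kw = dict(spacing=0.9, n_phases=4, noise_sigma=2.0, seed=42)
    flow = phantom.FlowSpec(mean_flow_rate=3.0)
    s1 = phantom.make_scene(tube_spec, flow, **kw)
    s2 = phantom.make_scene(tube_spec, flow, **kw)
    for name in s1.images:
        np.testing.assert_array_equal(s1.images[name].data, s2.images[name].data)
    for mod in s1.truth.misalignments:
        np.testing.assert_array_equal(
            s1.truth.misalignments[mod].matrix, s2.truth.misalignments[mod].matrix
        )


def test_truth_transforms_identity_when_misalignment_disabled(tube_spec):
    scene = phantom.make_scene(
        tube_spec, phantom.FlowSpec(mean_flow_rate=1.4),
        spacing=0.9, n_phases=2, noise_sigma=0.0, misalign=False, seed=0,
    )
    for T in scene.truth.misalignments.values():
        np.testing.assert_allclose(T.matrix, np.eye(4), atol=1e-12)


# ---------------------------------------------------------------------------
# artifacts
# ---------------------------------------------------------------------------


def test_artifact_zero_radius_is_noop(tube_scene):
    img = tube_scene.images["BB_perp"]
    out, mask = phantom.inject_artifact(img, center=[0.0, 0.0, 0.0], radius=0.0)
    np.testing.assert_array_equal(out.data, img.data)
    assert mask.sum() == 0


def test_artifact_modifies_exactly_inside_voxels(tube_scene):
    img = tube_scene.images["BB_perp"]
    center, radius = np.array([0.0, 0.0, 5.0]), 4.0
    out, mask = phantom.inject_artifact(img, center, radius, level=0.0)
    # brute-force voxel enumeration oracle
    pts = img.voxel_centers().reshape(-1, 3)
    inside = (np.linalg.norm(pts - center, axis=1) < radius).reshape(img.shape3)
    np.testing.assert_array_equal(mask, inside)
    assert np.all(out.data[inside] == 0.0)
    np.testing.assert_array_equal(out.data[~inside], img.data[~inside])


def test_artifact_overlap_fraction_matches_enumeration(sidewall_geometry):
    geom = sidewall_geometry
    shape, affine = geom.make_grid(spacing=0.8)
    img = VolumeImage(np.full(shape, 100.0, np.float32), affine)
    center = geom.sac_center + np.array([2.0, 0.0, 0.0])
    _, mask = phantom.inject_artifact(img, center, 3.0)
    pts = img.voxel_centers().reshape(-1, 3)
    voi = geom.inside_sac(pts).reshape(shape)
    overlap = (mask & voi).sum() / voi.sum()
    brute = (
        (np.linalg.norm(pts - center, axis=1) < 3.0).reshape(shape) & voi
    ).sum() / voi.sum()
    assert overlap == pytest.approx(brute, abs=0)


def test_artifact_negative_radius_rejected(tube_scene):
    with pytest.raises(ValueError):
        phantom.inject_artifact(tube_scene.images["BB_perp"], [0, 0, 0], -1.0)


def test_scene_export_roundtrip(tmp_path, tube_spec):
    scene = phantom.make_scene(
        tube_spec, phantom.FlowSpec(mean_flow_rate=1.4),
        spacing=1.0, n_phases=2, noise_sigma=0.0, seed=3,
    )
    scene.export(tmp_path)
    from bbflow.io import read_mesh, read_volume

    back = read_volume(tmp_path / "BB_perp.nii")
    np.testing.assert_allclose(back.data, scene.images["BB_perp"].data, rtol=1e-6)
    mesh = read_mesh(tmp_path / "cad_lumen.stl")
    assert len(mesh.faces) == len(scene.geometry.cad_lumen.faces)
    assert (tmp_path / "truth.csv").exists()
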