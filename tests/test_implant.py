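"""Implant design: measurements, cut plans, component/plate construction."""

import numpy as np
import pytest
import trimesh

from autoknee import implant as imp


@pytest.fixture(scope="module")
def femur_mesh(tiny_population):
    return tiny_population[0].femur_mesh


@pytest.fixture(scope="module")
def tibia_mesh(tiny_population):
    return tiny_population[0].tibia_mesh


# -- measurement ------------------------------------------------------------
def test_box_measures():
    box = trimesh.creation.box(extents=(60, 70, 40))
    m = imp.measure_ap_ml(box, condylar_fraction=1.0)
    assert m.ml_mm == pytest.approx(60.0)
    assert m.ap_mm == pytest.approx(70.0)


def test_measures_scale_homogeneously(femur_mesh):
    m1 = imp.measure_ap_ml(femur_mesh)
    scaled = trimesh.Trimesh(femur_mesh.vertices * 1.1, femur_mesh.faces, process=False)
    m2 = imp.measure_ap_ml(scaled)
    assert m2.ap_mm == pytest.approx(1.1 * m1.ap_mm, abs=1e-6)
    assert m2.ml_mm == pytest.approx(1.1 * m1.ml_mm, abs=1e-6)


def test_phantom_measures_match_generator_extents(femur_mesh):
    m = imp.measure_ap_ml(femur_mesh)
    lo, hi = femur_mesh.bounds
    assert m.ml_mm == pytest.approx(hi[0] - lo[0], abs=2.0)


def test_empty_mesh_rejected():
    with pytest.raises(imp.ImplantError):
        imp.measure_ap_ml(trimesh.Trimesh())


# -- cut planning -----------------------------------------------------------
def test_plan_scales_linearly_with_ap(femur_mesh):
    m = imp.measure_ap_ml(femur_mesh)
    m2 = imp.CondylarMeasures(2 * m.ap_mm, m.ml_mm, m.condylar_bounds)
    p1 = imp.plan_femur_cuts(m)
    p2 = imp.plan_femur_cuts(m2)
    (x0, y0, z0) = m.condylar_bounds[0]
    for (n1, pt1, _), (n2, pt2, _) in zip(p1.planes, p2.planes):
        off1 = pt1 - np.array([0, y0, z0]) * np.array([0, 1, 1])
        off2 = pt2 - np.array([0, y0, z0]) * np.array([0, 1, 1])
        if n1 in ("anterior", "posterior", "distal", "anterior_chamfer", "posterior_chamfer"):
            np.testing.assert_allclose(off2[1:], 2 * off1[1:], atol=1e-9)


def test_plan_is_deterministic_and_unit_normals(femur_mesh):
    m = imp.measure_ap_ml(femur_mesh)
    p1, p2 = imp.plan_femur_cuts(m), imp.plan_femur_cuts(m)
    for (n1, pt1, nv1), (n2, pt2, nv2) in zip(p1.planes, p2.planes):
        assert n1 == n2
        np.testing.assert_array_equal(pt1, pt2)
        assert np.linalg.norm(nv1) == pytest.approx(1.0)


def test_nonpositive_measures_rejected(femur_mesh):
    m = imp.measure_ap_ml(femur_mesh)
    with pytest.raises(imp.ImplantError):
        imp.plan_femur_cuts(imp.CondylarMeasures(0.0, m.ml_mm, m.condylar_bounds))


# -- femur component --------------------------------------------------------
@pytest.fixture(scope="module")
def femur_component(femur_mesh):
    plan = imp.plan_femur_cuts(imp.measure_ap_ml(femur_mesh))
    return imp.design_femur_component(femur_mesh, plan)


def test_component_watertight_and_smaller(femur_component, femur_mesh):
    assert femur_component.mesh.is_watertight
    assert femur_component.mesh.volume < femur_mesh.volume


def test_bone_facing_surface_within_shell_tolerance(femur_component, femur_mesh):
    from autoknee.geometry import MeshDistance, sample_mesh_surface

    pts = sample_mesh_surface(femur_component.inner_patch, 500, seed=0)
    d = MeshDistance(femur_mesh).query(pts)[1]
    assert d.max() <= 1.5 + 0.2


def test_component_has_two_pin_cross_sections(femur_component):
    """A plane through the pin shafts cuts exactly two small circles."""
    pin_z = np.mean([p.bounds.mean(axis=0)[2] for p in femur_component.pins])
    sec = trimesh.util.concatenate(femur_component.pins).section(
        plane_origin=[0, 0, pin_z], plane_normal=[0, 0, 1]
    )
    loops = [e for e in sec.entities]
    assert len(loops) == 2
    for e in loops:
        pts = e.discrete(sec.vertices)
        r = np.linalg.norm(pts[:, :2] - pts[:, :2].mean(axis=0), axis=1)
        assert r.mean() == pytest.approx(3.0, abs=0.2)


def test_design_is_deterministic(femur_mesh):
    plan = imp.plan_femur_cuts(imp.measure_ap_ml(femur_mesh))
    c1 = imp.design_femur_component(femur_mesh, plan)
    c2 = imp.design_femur_component(femur_mesh, plan)
    np.testing.assert_array_equal(c1.mesh.vertices, c2.mesh.vertices)


def test_degenerate_plan_rejected(femur_mesh):
    bad = imp.CutPlan([("wipeout", femur_mesh.bounds[1] + 10.0, (0.0, 0.0, 1.0))])
    with pytest.raises(imp.ImplantError, match="degenerate cut plan"):
        imp.clip_by_plan(femur_mesh, bad)


# -- tibia plateau / profile / plate ----------------------------------------
def test_plateau_plane_of_flat_topped_cylinder():
    cyl = trimesh.creation.cylinder(radius=20, height=40, sections=64)
    plane = imp.tibia_plateau_plane(cyl, top_fraction=0.02)
    assert abs(np.dot(plane.normal, [0, 0, -1])) >= np.cos(1e-3)
    assert plane.normal[2] < 0  # oriented distally, away from the femur


def test_plateau_slope_recovered_within_one_degree():
    """A z-sheared cylinder has an exactly planar tilted top face."""
    slope = 0.08
    cyl = trimesh.creation.cylinder(radius=25, height=40, sections=96)
    V = cyl.vertices.copy()
    V[:, 2] += slope * V[:, 0]
    tilted = trimesh.Trimesh(V, cyl.faces, process=False)
    plane = imp.tibia_plateau_plane(tilted, top_fraction=0.08)
    measured = np.arccos(np.clip(-plane.normal[2], -1, 1))
    assert abs(measured - np.arctan(slope)) <= np.radians(1.0)


def test_cylinder_profile_area():
    cyl = trimesh.creation.cylinder(radius=20, height=40, sections=128)
    plane = imp.tibia_plateau_plane(cyl, top_fraction=0.02)
    prof = imp.extract_tibia_profile(cyl, plane, offset_mm=2.0)
    assert prof.polygon.area == pytest.approx(np.pi * 400, rel=0.02)


def test_frustum_sections_shrink_distally():
    """On a cone narrowing downward, deeper sections are smaller."""
    cone = trimesh.creation.cone(radius=25, height=50, sections=96)
    cone.apply_transform(trimesh.transformations.rotation_matrix(np.pi, [1, 0, 0]))
    cone.apply_translation([0, 0, 50])  # apex at z=0, base (radius 25) at z=50
    plane = imp.OrientedPlane(np.array([0, 0, 50.0]), np.array([0, 0, -1.0]))
    p0 = imp.extract_tibia_profile(cone, plane, offset_mm=5.0)
    p2 = imp.extract_tibia_profile(cone, plane, offset_mm=10.0)
    assert p2.polygon.area < p0.polygon.area


@pytest.fixture(scope="module")
def plate(tibia_mesh):
    plane = imp.tibia_plateau_plane(tibia_mesh)
    prof = imp.extract_tibia_profile(tibia_mesh, plane)
    return imp.design_tibia_plate(prof), prof


def test_plate_extents_and_volume(plate):
    comp, prof = plate
    spec = comp.provenance["spec"]
    z0, z1 = comp.mesh.bounds[:, 2]
    assert z1 - z0 == pytest.approx(spec.thickness_mm + spec.pin_length_mm - 0.5, abs=1e-6)
    assert comp.mesh.is_watertight
    # cuts remove material from the full extrusion
    body = trimesh.util.concatenate([b for b in comp.mesh.split() if b.bounds[0][2] > -1e-6])
    assert body.volume < prof.polygon.area * spec.thickness_mm


def test_tibia_resection_self_consistency(tibia_mesh, plate):
    comp, prof = plate
    gt_profile = imp.resect_bone(tibia_mesh, prof)["profile"]
    sym = gt_profile.symmetric_difference(prof.polygon)
    assert sym.area <= 0.01 * prof.polygon.area


def test_femur_resection_matches_component_outline(femur_mesh, femur_component):
    resec = imp.resect_bone(femur_mesh, femur_component.provenance["plan"])
    B = np.vstack(resec["edge_loops"])
    C = np.vstack(femur_component.edge_loops)
    from scipy.spatial import cKDTree

    d, _ = cKDTree(B).query(C)
    assert d.max() <= 1e-6
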