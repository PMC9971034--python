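"""Shape models: PCA properties, ICP registration, morph fitting."""

import numpy as np
import pytest

from autoknee.geometry import (
    MeshDistance,
    RigidTransform,
    rotation_about_axis,
    sample_mesh_surface,
)
from autoknee.ssm import (
    ShapeModelError,
    align_stack_to_base,
    morph_to_stack,
    rigid_icp,
    synthesize,
    train_ssm,
)
from helpers import stack_points_from


# -- training ---------------------------------------------------------------
def test_two_meshes_mean_is_midpoint_single_mode(tiny_population):
    a, b = tiny_population[0].femur_mesh, tiny_population[1].femur_mesh
    model = train_ssm([a, b])
    assert model.n_modes_available == 1
    # mean equals the vertex-wise midpoint of the Procrustes-aligned pair
    from autoknee.ssm import _procrustes_align

    V = np.stack([a.vertices, b.vertices])
    centroid = V.mean(axis=(0, 1))
    aligned = _procrustes_align(V.copy())
    mid = aligned.mean(axis=0) + centroid
    np.testing.assert_allclose(model.mean_vertices, mid, atol=1e-8)


def test_topology_mismatch_rejected(tiny_population):
    with pytest.raises(ShapeModelError, match="topology"):
        train_ssm([tiny_population[0].femur_mesh, tiny_population[0].tibia_mesh])


def test_modes_orthonormal_and_variances_ordered(tiny_population):
    model = train_ssm([s.tibia_mesh for s in tiny_population])
    G = model.components @ model.components.T
    np.testing.assert_allclose(G, np.eye(len(G)), atol=1e-9)
    assert (np.diff(model.variances) <= 1e-9).all()


def test_three_mode_population_concentrates_variance(tiny_population):
    model = train_ssm([s.femur_mesh for s in tiny_population])
    frac = model.variances[:3].sum() / model.variances.sum()
    assert frac >= 0.95


def test_training_mesh_reconstruction_is_exact(tiny_population):
    """Full-mode projection reproduces a training mesh to < 1e-6 mm RMS."""
    meshes = [s.femur_mesh for s in tiny_population]
    model = train_ssm(meshes, smooth_iters=0)
    from autoknee.ssm import _procrustes_align

    V = np.stack([m.vertices for m in meshes])
    X = _procrustes_align(V.copy()).reshape(len(meshes), -1)
    mean = X.mean(axis=0)
    rec = mean + model.components.T @ (model.components @ (X[0] - mean))
    rms = np.sqrt(np.mean(np.sum((rec - X[0]).reshape(-1, 3) ** 2, axis=1)))
    assert rms <= 1e-6


# -- synthesis --------------------------------------------------------------
def test_synthesize_identity_and_linearity(tiny_population):
    model = train_ssm([s.tibia_mesh for s in tiny_population])
    base = synthesize(model, [])
    np.testing.assert_allclose(base.vertices, model.mean_vertices)
    w = np.array([3.0, -2.0])
    plus, minus = synthesize(model, w), synthesize(model, -w)
    np.testing.assert_allclose((plus.vertices + minus.vertices) / 2, base.vertices, atol=1e-9)
    # matches brute-force vertex arithmetic
    brute = model.mean_vertices + (
        w[0] * model.components[0] + w[1] * model.components[1]
    ).reshape(-1, 3)
    np.testing.assert_allclose(plus.vertices, brute)


def test_too_many_weights_rejected(tiny_population):
    model = train_ssm([s.tibia_mesh for s in tiny_population[:3]])
    with pytest.raises(ShapeModelError):
        synthesize(model, np.zeros(model.n_modes_available + 1))


# -- ICP --------------------------------------------------------------------
@pytest.fixture(scope="module")
def base_model(tiny_population):
    return train_ssm([s.femur_mesh for s in tiny_population])


def test_icp_recovers_known_transform(base_model):
    base = base_model.base_mesh()
    pts = sample_mesh_surface(base, 500, seed=2)
    R = rotation_about_axis([0.2, -0.5, 1.0], 0.25)
    T_true = RigidTransform(R, np.array([4.0, -3.0, 2.0]))
    T_est, resid = rigid_icp(T_true.apply(pts), base, max_iters=200, tol_mm=1e-9)
    err = T_est.compose(T_true)
    assert err.rotation_angle_rad <= 1e-4
    assert np.linalg.norm(err.translation) <= 1e-4


def test_icp_identity_when_already_aligned(base_model):
    base = base_model.base_mesh()
    pts = sample_mesh_surface(base, 300, seed=3)
    T, resid = rigid_icp(pts, base, max_iters=50)
    assert resid <= 1e-6
    assert T.rotation_angle_rad <= 1e-6


def test_icp_mean_distance_non_increasing(base_model):
    """The returned transform is at least as good as the initialisation."""
    base = base_model.base_mesh()
    pts = sample_mesh_surface(base, 300, seed=4)
    moved = RigidTransform(rotation_about_axis([0, 0, 1], 0.1), np.array([2.0, 1.0, 0.0])).apply(pts)
    md = MeshDistance(base)
    d0 = md.query(moved)[1].mean()
    T, d_final = rigid_icp(moved, md, max_iters=100)
    assert d_final <= d0 + 1e-12


def test_icp_degenerate_source_rejected(base_model):
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(ShapeModelError, match="degenerate"):
        rigid_icp(line, base_model.base_mesh())


# -- stack alignment & morphing --------------------------------------------
def test_align_self_stack_residual_small(base_model):
    pts = stack_points_from(base_model.base_mesh())
    aligned, T = align_stack_to_base(pts, base_model)
    resid = MeshDistance(base_model.base_mesh()).query(aligned)[1].mean()
    assert resid <= 0.1


def test_align_translation_invariant(base_model):
    pts = stack_points_from(base_model.base_mesh())
    a1, _ = align_stack_to_base(pts, base_model)
    a2, _ = align_stack_to_base(pts + np.array([25.0, -10.0, 5.0]), base_model)
    md = MeshDistance(base_model.base_mesh())
    assert md.query(a2)[1].mean() == pytest.approx(md.query(a1)[1].mean(), abs=0.05)


def test_align_empty_stack_rejected(base_model):
    with pytest.raises(ShapeModelError, match="empty"):
        align_stack_to_base(np.zeros((0, 3)), base_model)


def test_morph_recovers_generating_weights(base_model):
    sds = np.sqrt(base_model.variances[:2])
    w_true = np.array([1.1 * sds[0], -0.9 * sds[1]])
    target = synthesize(base_model, w_true)
    pts = stack_points_from(target)
    aligned, _ = align_stack_to_base(pts, base_model)
    mesh, w, info = morph_to_stack(base_model, aligned, n_pc=2)
    assert (np.abs(w - w_true) <= 0.1 * np.abs(w_true)).all()
    assert np.sqrt(info["objective_mm2"]) <= 0.3


def test_morph_zero_pc_returns_base(base_model):
    pts = stack_points_from(base_model.base_mesh())
    mesh, w, info = morph_to_stack(base_model, pts, n_pc=0)
    np.testing.assert_allclose(mesh.vertices, base_model.mean_vertices)
    assert len(w) == 0


def test_morph_rejects_excess_modes(base_model):
    pts = stack_points_from(base_model.base_mesh())
    with pytest.raises(ShapeModelError):
        morph_to_stack(base_model, pts, n_pc=base_model.n_modes_available + 1)


def test_shape_model_round_trips_through_archive(base_model, tmp_path):
    p = tmp_path / "model.npz"
    base_model.save(p)
    from autoknee.ssm import ShapeModel

    loaded = ShapeModel.load(p)
    np.testing.assert_array_equal(loaded.mean_vertices, base_model.mean_vertices)
    np.testing.assert_array_equal(loaded.components, base_model.components)
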