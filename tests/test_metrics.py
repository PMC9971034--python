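"""Fit metrics: RMSE, directed Hausdorff OUH, flags, cohort statistics."""

import numpy as np
import pandas as pd
import pytest
import trimesh

from autoknee.metrics import (
    EdgeSet,
    cohort_stats,
    component_fit,
    distance_heatmap,
    max_ouh,
    ouh_flag,
    remove_outliers_iqr,
    rmse_from_distances,
    surface_rmse,
)


# -- RMSE -------------------------------------------------------------------
def test_rmse_direct_arithmetic():
    assert rmse_from_distances([3.0, 4.0]) == pytest.approx(np.sqrt(12.5))


def test_identical_meshes_rmse_zero():
    m = trimesh.creation.icosphere(subdivisions=3, radius=15.0)
    assert surface_rmse(m, m, align=False) <= 1e-9


def test_parallel_planes_unaligned_rmse_is_separation():
    a = trimesh.Trimesh(
        [[0, 0, 0], [10, 0, 0], [10, 10, 0], [0, 10, 0]], [[0, 1, 2], [0, 2, 3]]
    )
    b = a.copy()
    b.apply_translation([0, 0, 1.0])
    assert surface_rmse(a, b, align=False, n_samples=500) == pytest.approx(1.0, abs=1e-9)


def test_rmse_invariant_under_rigid_motion_with_icp(tiny_population):
    from autoknee.geometry import rotation_about_axis

    m = tiny_population[0].femur_mesh
    R = rotation_about_axis([1, 2, 3], 0.15)
    moved = trimesh.Trimesh(m.vertices @ R.T + [5, -2, 3], m.faces, process=False)
    assert surface_rmse(m, moved, align=True, n_samples=800) <= 0.05


def test_empty_region_rejected():
    m = trimesh.creation.icosphere(radius=10.0)
    with pytest.raises(ValueError, match="empty region"):
        surface_rmse(m, m, region=(100.0, 200.0))


# -- OUH --------------------------------------------------------------------
def test_ouh_examples():
    assert max_ouh(EdgeSet([[0, 0]], [[3, 4]])) == pytest.approx(5.0)
    pts = np.random.default_rng(0).random((20, 3))
    assert max_ouh(EdgeSet(pts, pts)) == 0.0
    assert max_ouh(EdgeSet([[0, 0], [10, 0]], [[0, 0]])) == pytest.approx(10.0)


def test_ouh_matches_brute_force_double_loop(rng):
    for _ in range(20):
        C = rng.normal(size=(rng.integers(2, 80), 3))
        B = rng.normal(size=(rng.integers(2, 80), 3))
        brute = max(min(np.linalg.norm(c - b) for b in B) for c in C)
        assert max_ouh(EdgeSet(C, B)) == pytest.approx(brute)


def test_ouh_empty_set_rejected():
    with pytest.raises(ValueError):
        EdgeSet(np.zeros((0, 3)), np.zeros((3, 3)))


@pytest.mark.parametrize("h,flag", [(2.99, False), (3.0, True), (5.2, True)])
def test_flag_threshold_inclusive(h, flag):
    assert ouh_flag(h) is flag


def test_flag_threshold_overridable():
    assert ouh_flag(3.5, threshold=4.0) is False


# -- component self-fit -----------------------------------------------------
def test_component_self_fit(tiny_population):
    from autoknee import implant as imp

    femur = tiny_population[0].femur_mesh
    comp = imp.design_femur_component(femur, imp.plan_femur_cuts(imp.measure_ap_ml(femur)))
    rep = component_fit(comp, femur)
    assert rep.max_ouh_mm <= 1e-6
    assert not rep.ouh_flag
    assert rep.rmse_mm <= 1.5


def test_inflated_tibia_profile_gives_known_ouh():
    """A ground-truth profile uniformly 4 mm larger gives OUH = 4 (flagged)."""
    from shapely.geometry import Point

    from autoknee import implant as imp

    ellipse = Point(0, 0).buffer(1.0, quad_segs=128)
    import shapely.affinity as aff

    profile_poly = aff.scale(ellipse, 30.0, 22.0)
    prof = imp.TibiaProfile(profile_poly, np.eye(3), 0.0, np.zeros(3))
    plate = imp.design_tibia_plate(prof)
    inflated = profile_poly.buffer(4.0)
    rep = component_fit(plate, inflated, align=False)
    assert rep.max_ouh_mm == pytest.approx(4.0, abs=0.1)
    assert rep.ouh_flag


# -- heatmap ----------------------------------------------------------------
def test_heatmap_distances_match_recomputation(tmp_path, tiny_population):
    from autoknee.geometry import MeshDistance

    a = tiny_population[0].tibia_mesh
    b = tiny_population[1].tibia_mesh
    d = distance_heatmap(a, b, tmp_path / "map.png", tmp_path / "map.csv")
    ref = MeshDistance(b).query(a.vertices)[1]
    np.testing.assert_allclose(d, ref)
    table = pd.read_csv(tmp_path / "map.csv")
    np.testing.assert_allclose(table["distance_mm"].to_numpy(), ref, atol=1e-9)
    assert (tmp_path / "map.png").exists()


# -- cohort stats -----------------------------------------------------------
def test_identical_groups_not_significant():
    df = pd.DataFrame({"m": [1.0, 1.1, 0.9, 1.0, 1.1, 0.9], "g": list("aaabbb")})
    out = cohort_stats(df, ["m"], group_cols=["g"])
    row = out[out.test == "t:g"].iloc[0]
    assert row.p_or_r == pytest.approx(1.0, abs=1e-9)
    assert row.significant in (False,)


def test_monotone_covariate_gives_r_one():
    df = pd.DataFrame({"m": [1, 2, 3, 4, 5.0], "x": [10, 20, 30, 40, 50.0]})
    out = cohort_stats(df, ["m"], continuous_cols=["x"])
    assert out.iloc[0].statistic == pytest.approx(1.0)
    assert out.iloc[0].significant


def test_welch_matches_textbook_formula():
    a = np.array([1.0, 2.0, 3.0])
    b = np.array([2.0, 4.0, 9.0])
    df = pd.DataFrame({"m": np.concatenate([a, b]), "g": list("aaabbb")})
    out = cohort_stats(df, ["m"], group_cols=["g"])
    t = out.iloc[0].statistic
    va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
    t_manual = (a.mean() - b.mean()) / np.sqrt(va + vb)
    assert t == pytest.approx(t_manual)


def test_insufficient_n_marked_na():
    df = pd.DataFrame({"m": [1.0, 2.0], "g": ["a", "b"]})
    out = cohort_stats(df, ["m"], group_cols=["g"])
    assert out.iloc[0].significant == "n/a"


def test_iqr_outlier_rule():
    x = np.array([1.0, 1.1, 0.9, 1.0, 50.0])
    kept = remove_outliers_iqr(x)
    assert 50.0 not in kept and len(kept) == 4
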