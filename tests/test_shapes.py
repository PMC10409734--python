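"""Shape statistics (GPA, PCA) and ASM/AAM training and fitting."""

import numpy as np
import pytest

from htoplan.exceptions import ModelTrainingError
from htoplan.geometry import Laterality
from htoplan.phantom import render, sample_specs
from htoplan.shapes import (
    LandmarkShape,
    align_similarity,
    fit_aam,
    fit_asm,
    knee_points,
    load_models,
    procrustes_align,
    save_models,
    train_aam,
    train_asm,
    train_shape_model,
)
from htoplan.training import knee_training_data
from htoplan.utils import crop, hist_equalize


# --------------------------------------------------------------------------
# generalized Procrustes


def naive_gpa(shapes, n_iter=3000):
    """Independent oracle: plain alternating minimization, no gauge fixing.

    Normalizes every shape, then repeatedly (a) computes the mean, (b)
    renormalizes it, (c) re-aligns each shape to it with an explicit
    closed-form similarity fit, for a fixed large number of sweeps.
    """

    def norm(s):
        c = s - s.mean(0)
        return c / np.linalg.norm(c)

    def fit_to(a, m):
        # closed-form 2-D similarity via complex least squares
        za = (a[:, 0] + 1j * a[:, 1])
        zm = (m[:, 0] + 1j * m[:, 1])
        za = za - za.mean()
        w = np.vdot(za, zm) / np.vdot(za, za)
        z = w * za
        return np.stack([z.real, z.imag], 1) + m.mean(0)

    cur = [norm(np.asarray(s, float)) for s in shapes]
    for _ in range(n_iter):
        m = norm(np.mean(cur, axis=0))
        cur = [fit_to(a, m) for a in cur]
    return norm(np.mean(cur, axis=0))


def procrustes_distance(a, b):
    """Residual after optimally similarity-aligning a onto b."""
    s, rot, t = align_similarity(a, b)
    return float(np.linalg.norm(s * a @ rot.T + t - b))


def test_single_shape_mean_is_the_centered_unit_shape():
    tri = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 3.0]])
    aligned, mean = procrustes_align([tri])
    centered = tri - tri.mean(0)
    expected = centered / np.linalg.norm(centered)
    assert np.allclose(mean, expected, atol=1e-12)
    assert np.allclose(aligned[0], expected, atol=1e-12)


def test_similarity_related_shapes_align_identically():
    rng = np.random.default_rng(1)
    base = rng.normal(size=(9, 2))
    th = 0.7
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    other = 2.3 * base @ R.T + [5.0, -7.0]
    aligned, _ = procrustes_align([base, other])
    assert np.allclose(aligned[0], aligned[1], atol=1e-9)


def test_gpa_mean_matches_naive_alternating_minimization_oracle():
    triangles = [
        np.array([[0.0, 0.0], [5.0, 0.2], [2.0, 4.0]]),
        np.array([[0.1, -0.2], [4.0, 0.5], [1.5, 3.0]]),
        np.array([[-1.0, 0.3], [4.5, -0.5], [2.5, 5.0]]),
    ]
    _, mean = procrustes_align(triangles, tol=1e-14, max_iter=500)
    oracle = naive_gpa(triangles)
    assert procrustes_distance(mean, oracle) < 1e-9


def test_all_coincident_shape_is_rejected():
    with pytest.raises(ModelTrainingError):
        procrustes_align([np.ones((5, 2))])


# --------------------------------------------------------------------------
# PCA shape model


def test_no_variation_yields_zero_modes():
    tri = np.array([[0.0, 0.0], [4.0, 0.0], [1.0, 3.0]])
    model = train_shape_model([tri.copy() for _ in range(4)])
    assert model.n_modes == 0


def test_single_direction_of_variation_yields_one_full_mode():
    base = np.array([[0.0, 0.0], [4.0, 0.0], [1.0, 3.0], [2.0, 5.0]])
    direction = np.array([[0.0, 0.1], [0.0, -0.1], [0.2, 0.0], [-0.1, 0.0]])
    shapes = [base + c * direction for c in (-2.0, -1.0, 1.0, 2.0)]
    model = train_shape_model(shapes, variance_fraction=0.98)
    assert model.n_modes == 1


def test_full_rank_pca_reconstructs_every_training_shape():
    rng = np.random.default_rng(2)
    shapes = [rng.normal(size=(7, 2)) for _ in range(10)]
    model = train_shape_model(shapes, variance_fraction=1.0)
    aligned, _ = procrustes_align(shapes)
    for a in aligned:
        recon = model.reconstruct(model.project(a))
        assert np.allclose(recon, a, atol=1e-9)


def test_modes_orthonormal_and_variances_non_increasing():
    for seed in range(3):
        specs = sample_specs(8, seed=seed)
        shapes = [render(s)[1].knee_shape for s in specs]
        model = train_shape_model(shapes)
        gram = model.modes.T @ model.modes
        assert np.allclose(gram, np.eye(model.n_modes), atol=1e-8)
        assert np.all(np.diff(model.variances) <= 1e-12)


def test_too_few_shapes_rejected():
    with pytest.raises(ModelTrainingError):
        train_shape_model([np.zeros((5, 2))])


# --------------------------------------------------------------------------
# ASM profile model


def _step_edge_training_pair(n_landmarks=7, size=64):
    """Vertical step edge with landmarks on it: known derivative profile."""
    img = np.zeros((size, size))
    img[:, size // 2:] = 1.0
    ys = np.linspace(10, size - 10, n_landmarks)
    pts = np.stack([np.full_like(ys, size / 2 - 0.5), ys], 1)
    return img, LandmarkShape(pts, {"outer": 0, "inner": n_landmarks - 1})


def test_step_edge_profiles_match_the_discrete_step_derivative():
    img, shape = _step_edge_training_pair()
    _, pm = train_asm([img, img], [shape, shape], profile_halfwidth=4)
    # landmarks run along +y, so normals point in -x: the profile crosses
    # the step from bright to dark and its normalized derivative is the
    # (negated) discrete step response, symmetric about the center
    center = pm.halfwidth
    mid = pm.means[3]
    assert np.argmax(np.abs(mid)) == center
    assert abs(np.abs(mid).sum() - 1.0) < 1e-9  # L1-normalized
    assert np.allclose(pm.means, pm.means[3], atol=1e-9)  # identical landmarks


def test_constant_images_give_zero_profiles_with_regularized_covariance():
    img = np.full((64, 64), 0.5)
    _, shape = _step_edge_training_pair()
    _, pm = train_asm([img, img], [shape, shape], profile_halfwidth=4)
    assert np.allclose(pm.means, 0.0)
    assert np.all(np.isfinite(pm.inv_covs))


def test_asm_fixed_point_from_ground_truth_init(bundle_right_59):
    spec = sample_specs(1, seed=901)[0]
    img, truth = render(spec)
    box = truth.boxes["knee"]
    roi, (x0, y0) = crop(img, box.x_min, box.y_min, box.x_max, box.y_max)
    roi = hist_equalize(roi)
    gt = truth.knee_shape.translated(-x0, -y0)
    res = fit_asm(roi, bundle_right_59.shape_model, bundle_right_59.profile_model, gt.points)
    rms = np.sqrt(np.mean(np.sum((res.shape.points - gt.points) ** 2, axis=1)))
    assert rms <= 0.5
    assert res.converged


def test_asm_recovers_from_5px_perturbed_init(bundle_right_59, rng):
    errs = []
    for spec in sample_specs(20, seed=902):
        img, truth = render(spec)
        box = truth.boxes["knee"]
        roi, (x0, y0) = crop(img, box.x_min, box.y_min, box.x_max, box.y_max)
        roi = hist_equalize(roi)
        gt = truth.knee_shape.translated(-x0, -y0)
        off = rng.normal(size=2)
        off = 5.0 * off / np.hypot(*off)
        res = fit_asm(roi, bundle_right_59.shape_model, bundle_right_59.profile_model,
                      gt.points + off)
        gi, go = knee_points(gt)
        fi, fo = knee_points(res.shape)
        errs.append(np.sqrt((np.hypot(fi.x - gi.x, fi.y - gi.y) ** 2
                             + np.hypot(fo.x - go.x, fo.y - go.y) ** 2) / 2))
    assert np.median(errs) <= 1.5


def test_asm_blank_image_reports_unconverged_without_raising(bundle_right_59):
    blank = np.full((80, 110), 0.5)
    init = bundle_right_59.shape_model.mean_shape * 60 + [55, 40]
    res = fit_asm(blank, bundle_right_59.shape_model, bundle_right_59.profile_model, init)
    assert not res.converged


# --------------------------------------------------------------------------
# AAM


def test_aam_identical_pairs_have_zero_texture_variance():
    img = np.zeros((64, 64))
    img[20:44, 16:48] = 1.0
    t = np.linspace(0, 2 * np.pi, 13, endpoint=False)
    pts = np.stack([32 + 18 * np.cos(t), 32 + 14 * np.sin(t)], 1)
    shape = LandmarkShape(pts, {"outer": 0, "inner": 6})
    am = train_aam([img, img], [shape, LandmarkShape(pts.copy(), shape.index_map)])
    assert am.texture_modes.shape[1] == 0 or np.allclose(am.texture_variances, 0.0)


def test_aam_training_texture_reconstruction_is_exact_with_all_modes():
    specs = sample_specs(6, seed=31)
    images, shapes = knee_training_data(specs)
    am = train_aam(images, shapes, variance_fraction=1.0, seed=0)
    from scipy.ndimage import gaussian_filter

    for img, shp in zip(images, shapes):
        g = am.sample_texture(gaussian_filter(np.asarray(img, float), am.smooth_sigma),
                              shp.points)
        resid = am.texture_residual(g)
        assert np.linalg.norm(resid) <= 1e-6 * max(np.linalg.norm(g - am.texture_mean), 1e-12)


def test_aam_fixed_point_from_ground_truth_init(bundle_right_59):
    spec = sample_specs(1, seed=903)[0]
    img, truth = render(spec)
    box = truth.boxes["knee"]
    roi, (x0, y0) = crop(img, box.x_min, box.y_min, box.x_max, box.y_max)
    roi = hist_equalize(roi)
    gt = truth.knee_shape.translated(-x0, -y0)
    res = fit_aam(roi, bundle_right_59.appearance_model, gt.points)
    drift = np.max(np.hypot(*(res.shape.points - gt.points).T))
    assert drift <= 0.5


def test_aam_recovers_from_5px_perturbed_init(bundle_right_59, rng):
    errs = []
    for spec in sample_specs(20, seed=904):
        img, truth = render(spec)
        box = truth.boxes["knee"]
        roi, (x0, y0) = crop(img, box.x_min, box.y_min, box.x_max, box.y_max)
        roi = hist_equalize(roi)
        gt = truth.knee_shape.translated(-x0, -y0)
        off = rng.normal(size=2)
        off = 5.0 * off / np.hypot(*off)
        res = fit_aam(roi, bundle_right_59.appearance_model, gt.points + off)
        gi, go = knee_points(gt)
        fi, fo = knee_points(res.shape)
        errs.append(np.sqrt((np.hypot(fi.x - gi.x, fi.y - gi.y) ** 2
                             + np.hypot(fo.x - go.x, fo.y - go.y) ** 2) / 2))
    assert np.median(errs) <= 1.5


def test_fits_never_leave_the_expanded_roi(bundle_right_59, rng):
    spec = sample_specs(1, seed=905)[0]
    img, truth = render(spec)
    box = truth.boxes["knee"]
    roi, (x0, y0) = crop(img, box.x_min, box.y_min, box.x_max, box.y_max)
    roi = hist_equalize(roi)
    gt = truth.knee_shape.translated(-x0, -y0)
    local = box.translated(-x0, -y0)
    bounds = (local.x_min, local.y_min, local.x_max, local.y_max)
    mx, my = 0.10 * local.width, 0.10 * local.height
    for fitter in ("asm", "aam"):
        init = gt.points + rng.normal(scale=4.0, size=2)
        if fitter == "asm":
            res = fit_asm(roi, bundle_right_59.shape_model,
                          bundle_right_59.profile_model, init, roi_bounds=bounds)
        else:
            res = fit_aam(roi, bundle_right_59.appearance_model, init, roi_bounds=bounds)
        pts = res.shape.points
        assert pts[:, 0].min() >= local.x_min - mx - 1e-9
        assert pts[:, 0].max() <= local.x_max + mx + 1e-9
        assert pts[:, 1].min() >= local.y_min - my - 1e-9
        assert pts[:, 1].max() <= local.y_max + my + 1e-9


def test_fitting_is_deterministic(bundle_right_59):
    spec = sample_specs(1, seed=906)[0]
    img, truth = render(spec)
    box = truth.boxes["knee"]
    roi, (x0, y0) = crop(img, box.x_min, box.y_min, box.x_max, box.y_max)
    roi = hist_equalize(roi)
    init = truth.knee_shape.translated(-x0, -y0).points + [3.0, -2.0]
    a1 = fit_aam(roi, bundle_right_59.appearance_model, init)
    a2 = fit_aam(roi, bundle_right_59.appearance_model, init)
    assert np.array_equal(a1.shape.points, a2.shape.points)
    s1 = fit_asm(roi, bundle_right_59.shape_model, bundle_right_59.profile_model, init)
    s2 = fit_asm(roi, bundle_right_59.shape_model, bundle_right_59.profile_model, init)
    assert np.array_equal(s1.shape.points, s2.shape.points)


def test_knee_points_resolve_documented_indices_and_mirroring(bundle_left_59, clean_phantom):
    _, _, truth = clean_phantom
    inner, outer = knee_points(truth.knee_shape)
    assert tuple(inner) == tuple(truth.landmarks.medial_plateau_edge)
    assert tuple(outer) == tuple(truth.landmarks.lateral_plateau_edge)
    # left-leg model resolves its own (mirrored) indices
    lm = bundle_left_59.shape_model
    assert lm.laterality is Laterality.LEFT
    assert {"inner", "outer"} <= set(lm.index_map)


def test_model_serialization_round_trip(tmp_path, bundle_right_59):
    path = tmp_path / "models.npz"
    save_models(path, shape_model=bundle_right_59.shape_model,
                profile_model=bundle_right_59.profile_model,
                appearance_model=bundle_right_59.appearance_model)
    sm, pm, am = load_models(path)
    assert np.array_equal(sm.mean_shape, bundle_right_59.shape_model.mean_shape)
    assert np.array_equal(pm.means, bundle_right_59.profile_model.means)
    assert np.array_equal(am.update_matrix, bundle_right_59.appearance_model.update_matrix)
    assert am.smooth_sigma == bundle_right_59.appearance_model.smooth_sigma
    assert sm.index_map == bundle_right_59.shape_model.index_map
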