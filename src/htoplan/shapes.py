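"""Active Shape and Active Appearance Models for knee landmark detection.

Both models are trained on sets of annotated landmark shapes (17, 31 or 59
points outlining the tibial plateau; the characteristic outer and inner
knee points sit at fixed indices recorded in the shape's index map) and
fitted to a histogram-equalized knee region of interest.

The ASM couples a PCA shape model with per-landmark statistical profiles of
the normalized intensity derivative along the shape normals; fitting
alternates a Mahalanobis-distance profile search with a projection onto the
shape subspace (mode coefficients clamped to three standard deviations).

The AAM additionally models texture in the shape-normalized frame obtained
by piecewise-affine warping over a Delaunay triangulation of the mean
shape; fitting is driven by a linear update matrix, estimated from training
perturbations, that maps texture residuals to parameter corrections, with
step-halving ([1, 1/2, 1/4, 1/8]) when a full step fails to reduce the
residual.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.spatial import Delaunay

from .exceptions import ModelTrainingError
from .geometry import Laterality, Point

__all__ = [
    "LandmarkShape",
    "ShapeModel",
    "ProfileModel",
    "AppearanceModel",
    "FitResult",
    "align_similarity",
    "procrustes_align",
    "train_shape_model",
    "train_asm",
    "fit_asm",
    "train_aam",
    "fit_aam",
    "knee_points",
    "save_models",
    "load_models",
]

#: Canonical landmark counts (contour points plus the two knee points).
CANONICAL_COUNTS = (17, 31, 59)


@dataclass
class LandmarkShape:
    """An ordered landmark set with named characteristic points.

    ``points`` is an (n, 2) array of (x, y) pixel coordinates; ``index_map``
    names special indices, at minimum ``outer`` and ``inner`` for the
    lateral and medial knee points.
    """

    points: np.ndarray
    index_map: dict[str, int] = field(default_factory=dict)
    laterality: Laterality | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError(f"points must be (n, 2), got {self.points.shape}")
        if len(self.points) >= 2 and np.any(
            np.all(np.diff(self.points, axis=0) == 0, axis=1)
        ):
            raise ValueError("consecutive duplicate landmark points")

    def __len__(self) -> int:
        return len(self.points)

    def point(self, name: str) -> Point:
        return Point.of(self.points[self.index_map[name]])

    def translated(self, dx: float, dy: float) -> "LandmarkShape":
        return LandmarkShape(self.points + [dx, dy], dict(self.index_map), self.laterality)


def knee_points(fitted: LandmarkShape) -> tuple[Point, Point]:
    """The characteristic (inner, outer) knee points of a fitted shape."""
    return fitted.point("inner"), fitted.point("outer")


# ---------------------------------------------------------------------------
# generalized Procrustes alignment


def align_similarity(src: np.ndarray, dst: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares similarity (s, R, t) mapping src onto dst (Umeyama)."""
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    xs, xd = src - mu_s, dst - mu_d
    cov = xd.T @ xs / len(src)
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    D = np.diag([1.0, d])
    rot = u @ D @ vt
    var_s = (xs**2).sum() / len(src)
    if var_s == 0:
        raise ModelTrainingError("degenerate shape: all points coincide")
    scale = float(np.trace(np.diag(s) @ D) / var_s)
    t = mu_d - scale * rot @ mu_s
    return scale, rot, t


def _normalize(shape: np.ndarray) -> np.ndarray:
    centered = shape - shape.mean(axis=0)
    size = np.linalg.norm(centered)
    if size == 0:
        raise ModelTrainingError("degenerate shape: all points coincide")
    return centered / size


def procrustes_align(
    shapes: list[np.ndarray], tol: float = 1e-10, max_iter: int = 100
) -> tuple[list[np.ndarray], np.ndarray]:
    """Generalized Procrustes alignment to a common frame.

    Iteratively aligns every shape to the current mean with a similarity
    transform and renormalizes the mean to zero centroid / unit size, until
    the mean moves less than ``tol``.  Returns the aligned shapes and the
    converged mean.
    """
    arrs = [np.asarray(s, float) for s in shapes]
    if not arrs:
        raise ValueError("need at least one shape")
    n = arrs[0].shape
    if any(a.shape != n for a in arrs):
        raise ValueError("all shapes must have the same number of points")
    aligned = [_normalize(a) for a in arrs]
    mean = aligned[0].copy()
    for _ in range(max_iter):
        for i, a in enumerate(aligned):
            s, rot, t = align_similarity(a, mean)
            aligned[i] = s * a @ rot.T + t
        new_mean = _normalize(np.mean(aligned, axis=0))
        # fix rotational gauge: keep the mean aligned with the previous one
        _, rot, _ = align_similarity(new_mean, mean)
        new_mean = new_mean @ rot.T
        delta = np.linalg.norm(new_mean - mean)
        mean = new_mean
        if delta < tol:
            break
    for i, a in enumerate(aligned):
        s, rot, t = align_similarity(a, mean)
        aligned[i] = s * a @ rot.T + t
    return aligned, mean


# ---------------------------------------------------------------------------
# PCA shape model


@dataclass
class ShapeModel:
    """PCA statistics of aligned landmark shapes."""

    mean_shape: np.ndarray            # (n, 2), aligned frame
    modes: np.ndarray                 # (2n, m), orthonormal columns
    variances: np.ndarray             # (m,), non-increasing
    index_map: dict[str, int]
    laterality: Laterality | None = None

    @property
    def n_points(self) -> int:
        return len(self.mean_shape)

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    def reconstruct(self, b: np.ndarray) -> np.ndarray:
        """Aligned-frame shape for mode coefficients ``b``."""
        vec = self.mean_shape.ravel() + self.modes @ np.asarray(b, float)
        return vec.reshape(-1, 2)

    def project(self, shape_aligned: np.ndarray) -> np.ndarray:
        return self.modes.T @ (np.asarray(shape_aligned, float).ravel() - self.mean_shape.ravel())

    def clamp(self, b: np.ndarray, n_sd: float = 3.0) -> np.ndarray:
        lim = n_sd * np.sqrt(self.variances)
        return np.clip(b, -lim, lim)


def train_shape_model(
    shapes: list[LandmarkShape] | list[np.ndarray],
    variance_fraction: float = 0.98,
    index_map: dict[str, int] | None = None,
    laterality: Laterality | None = None,
) -> ShapeModel:
    """Procrustes-align the training shapes and PCA the aligned vectors.

    Retains the smallest number of modes explaining at least
    ``variance_fraction`` of the total variance (zero modes when the
    training set has no variation).
    """
    if len(shapes) < 2:
        raise ModelTrainingError("need at least two training shapes")
    if isinstance(shapes[0], LandmarkShape):
        if index_map is None:
            index_map = dict(shapes[0].index_map)
        if laterality is None:
            laterality = shapes[0].laterality
        arrs = [s.points for s in shapes]
    else:
        arrs = list(shapes)
    aligned, mean = procrustes_align(arrs)
    X = np.stack([a.ravel() - mean.ravel() for a in aligned])
    # PCA via SVD of the centered data matrix
    _, svals, vt = np.linalg.svd(X, full_matrices=False)
    variances = svals**2 / max(len(X) - 1, 1)
    total = variances.sum()
    if total <= 1e-24:
        m = 0
    else:
        keep = variances > 1e-12 * total
        cum = np.cumsum(variances[keep]) / total
        m = int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)
        m = min(m, int(keep.sum()))
    return ShapeModel(
        mean_shape=mean,
        modes=vt[:m].T.copy(),
        variances=variances[:m].copy(),
        index_map=index_map or {},
        laterality=laterality,
    )


# ---------------------------------------------------------------------------
# ASM: gray-level profile model


@dataclass
class ProfileModel:
    """Per-landmark statistics of normalized derivative profiles."""

    means: np.ndarray       # (n, 2k+1)
    inv_covs: np.ndarray    # (n, 2k+1, 2k+1), regularized inverses
    halfwidth: int


def _shape_normals(points: np.ndarray) -> np.ndarray:
    """Unit normals at each landmark from central-difference tangents."""
    tang = np.empty_like(points)
    tang[1:-1] = points[2:] - points[:-2]
    tang[0] = points[1] - points[0]
    tang[-1] = points[-1] - points[-2]
    norms = np.hypot(tang[:, 0], tang[:, 1])
    norms[norms == 0] = 1.0
    tang = tang / norms[:, None]
    return np.stack([-tang[:, 1], tang[:, 0]], axis=1)


def _sample_profiles(image: np.ndarray, points: np.ndarray, halfwidth: int) -> np.ndarray:
    """Raw intensity profiles of length 2k+1 along each landmark normal."""
    normals = _shape_normals(points)
    offs = np.arange(-halfwidth, halfwidth + 1)
    # (n, 2k+1, 2) sample coordinates
    coords = points[:, None, :] + offs[None, :, None] * normals[:, None, :]
    vals = map_coordinates(
        np.asarray(image, float),
        [coords[..., 1].ravel(), coords[..., 0].ravel()],
        order=1,
        mode="nearest",
    )
    return vals.reshape(points.shape[0], offs.size)


def _normalized_derivative(profiles: np.ndarray) -> np.ndarray:
    deriv = np.gradient(profiles, axis=-1)
    scale = np.abs(deriv).sum(axis=-1, keepdims=True)
    return deriv / np.maximum(scale, 1e-12)


def train_asm(
    images: list[np.ndarray],
    shapes: list[LandmarkShape],
    profile_halfwidth: int = 6,
    variance_fraction: float = 0.98,
) -> tuple[ShapeModel, ProfileModel]:
    """Train the shape model plus per-landmark gray-profile statistics.

    ``images`` must already be histogram-equalized; one shape per image.
    Landmarks whose profile extends past the image border are sampled with
    edge replication.  Covariances are regularized with
    ``eps = 1e-6 * trace / dim`` before inversion.
    """
    if len(images) != len(shapes):
        raise ValueError("one shape per image required")
    sm = train_shape_model(shapes, variance_fraction=variance_fraction)
    k = profile_halfwidth
    samples = []
    for img, shp in zip(images, shapes):
        prof = _sample_profiles(np.asarray(img, float), shp.points, k)
        samples.append(_normalized_derivative(prof))
    stack = np.stack(samples)                      # (N, n, 2k+1)
    means = stack.mean(axis=0)
    dim = 2 * k + 1
    inv_covs = np.empty((means.shape[0], dim, dim))
    for i in range(means.shape[0]):
        dev = stack[:, i, :] - means[i]
        cov = dev.T @ dev / max(len(stack) - 1, 1)
        eps = max(1e-6 * np.trace(cov) / dim, 1e-9)
        inv_covs[i] = np.linalg.inv(cov + eps * np.eye(dim))
    return sm, ProfileModel(means=means, inv_covs=inv_covs, halfwidth=k)


@dataclass
class FitResult:
    """Outcome of an iterative model fit."""

    shape: LandmarkShape
    converged: bool
    n_iter: int
    final_metric: float
    reason: str = ""


def _clip_to_roi(points: np.ndarray, roi_bounds) -> np.ndarray:
    if roi_bounds is None:
        return points
    x0, y0, x1, y1 = roi_bounds
    mx, my = 0.10 * (x1 - x0), 0.10 * (y1 - y0)
    out = points.copy()
    out[:, 0] = np.clip(out[:, 0], x0 - mx, x1 + mx)
    out[:, 1] = np.clip(out[:, 1], y0 - my, y1 + my)
    return out


def fit_asm(
    image: np.ndarray,
    shape_model: ShapeModel,
    profile_model: ProfileModel,
    init_shape: LandmarkShape | np.ndarray,
    max_iter: int = 40,
    search_range: int = 6,
    clamp_sd: float = 3.0,
    movement_tol: float = 0.1,
    roi_bounds=None,
) -> FitResult:
    """Fit the ASM to a histogram-equalized image from an initial shape.

    Each iteration moves every landmark to the offset (within
    ``+-search_range`` pixels along its normal) minimizing the Mahalanobis
    distance of the local profile to the trained profile statistics, then
    projects the moved shape back onto the shape subspace with clamped mode
    coefficients.  Stops when the mean point movement drops below
    ``movement_tol`` pixels — kept deliberately small because the mean is
    dominated by landmarks that settle long before the characteristic
    corner points do.
    """
    img = np.asarray(image, float)
    init_pts = init_shape.points if isinstance(init_shape, LandmarkShape) else np.asarray(init_shape, float)
    if len(init_pts) != shape_model.n_points:
        raise ValueError("init shape length does not match the model")
    k, m = profile_model.halfwidth, search_range
    window = 2 * k + 1
    pts = init_pts.copy()
    converged = False
    reason = ""
    it = 0
    for it in range(1, max_iter + 1):
        long_prof = _sample_profiles(img, pts, k + m)
        energy = np.abs(np.gradient(long_prof, axis=-1)).sum(axis=-1)
        best_off = np.zeros(len(pts))
        for i in range(len(pts)):
            best_d, best_j = np.inf, 0
            for j in sorted(range(-m, m + 1), key=abs):
                seg = long_prof[i, j + m : j + m + window]
                g = np.gradient(seg)
                g = g / max(np.abs(g).sum(), 1e-12)
                dev = g - profile_model.means[i]
                d = float(dev @ profile_model.inv_covs[i] @ dev)
                if d < best_d - 1e-12:
                    best_d, best_j = d, j
            best_off[i] = best_j
        normals = _shape_normals(pts)
        targets = pts + best_off[:, None] * normals
        # project onto the shape subspace: pose + clamped mode coefficients
        s, rot, t = align_similarity(shape_model.mean_shape, targets)
        in_frame = ((targets - t) @ rot) / s
        b = shape_model.clamp(shape_model.project(in_frame), clamp_sd)
        new_pts = s * shape_model.reconstruct(b) @ rot.T + t
        new_pts = _clip_to_roi(new_pts, roi_bounds)
        movement = float(np.mean(np.hypot(*(new_pts - pts).T)))
        pts = new_pts
        if movement < movement_tol:
            converged = True
            break
    if converged and float(np.mean(energy < 1e-6)) > 0.5:
        converged, reason = False, "no image evidence along profiles"
    fitted = LandmarkShape(pts, dict(shape_model.index_map), shape_model.laterality)
    return FitResult(fitted, converged, it, final_metric=float(np.mean(np.abs(best_off))), reason=reason)


# ---------------------------------------------------------------------------
# AAM: texture model in the shape-normalized frame


@dataclass
class AppearanceModel:
    """Shape + texture statistics and the trained parameter-update matrix.

    Parameters are ordered ``[shape mode coefficients..., a, b, tx, ty]``
    where the pose ``(a, b, tx, ty)`` encodes the similarity transform
    ``x' = (1+a) x - b y + tx, y' = b x + (1+a) y + ty`` applied to the
    base shape (aligned frame scaled by ``base_scale``).
    """

    shape_model: ShapeModel
    base_scale: float
    ref_shape: np.ndarray            # (n, 2) in texture-frame coords
    frame_shape: tuple[int, int]
    mask_pixels: np.ndarray          # (npix, 2) integer (y, x)
    pix_vertices: np.ndarray         # (npix, 3) landmark indices
    pix_bary: np.ndarray             # (npix, 3) barycentric weights
    texture_mean: np.ndarray         # (npix,)
    texture_modes: np.ndarray        # (npix, mt)
    texture_variances: np.ndarray    # (mt,)
    update_matrix: np.ndarray        # (n_params, npix)
    smooth_sigma: float = 4.0        # image pre-smoothing before texture sampling

    @property
    def n_shape_modes(self) -> int:
        return self.shape_model.n_modes

    @property
    def n_params(self) -> int:
        return self.n_shape_modes + 4

    def points_from_params(self, p: np.ndarray) -> np.ndarray:
        b, (a, brot, tx, ty) = p[: self.n_shape_modes], p[self.n_shape_modes :]
        base = self.shape_model.reconstruct(b) * self.base_scale
        M = np.array([[1 + a, -brot], [brot, 1 + a]])
        return base @ M.T + [tx, ty]

    def params_from_points(self, points: np.ndarray, clamp_sd: float | None = 3.0) -> np.ndarray:
        s, rot, t = align_similarity(self.shape_model.mean_shape * self.base_scale, points)
        in_frame = ((points - t) @ rot) / s / self.base_scale
        b = self.shape_model.project(in_frame)
        if clamp_sd is not None:
            b = self.shape_model.clamp(b, clamp_sd)
        M = s * rot
        a = 0.5 * (M[0, 0] + M[1, 1]) - 1.0
        brot = 0.5 * (M[1, 0] - M[0, 1])
        return np.concatenate([b, [a, brot, t[0], t[1]]])

    def sample_texture(self, image: np.ndarray, points: np.ndarray) -> np.ndarray:
        """Shape-normalized, photometrically normalized texture vector."""
        img_xy = np.einsum("pk,pkc->pc", self.pix_bary, points[self.pix_vertices])
        g = map_coordinates(
            np.asarray(image, float), [img_xy[:, 1], img_xy[:, 0]], order=1, mode="nearest"
        )
        g = g - g.mean()
        return g / max(np.linalg.norm(g), 1e-12)

    def texture_residual(self, g: np.ndarray) -> np.ndarray:
        c = self.texture_modes.T @ (g - self.texture_mean)
        return (g - self.texture_mean) - self.texture_modes @ c


def _build_reference_frame(mean_shape: np.ndarray, base_scale: float, margin: int = 3):
    ref = mean_shape * base_scale
    ref = ref - ref.min(axis=0) + margin
    w = int(np.ceil(ref[:, 0].max())) + margin + 1
    h = int(np.ceil(ref[:, 1].max())) + margin + 1
    tri = Delaunay(ref)
    ys, xs = np.mgrid[0:h, 0:w]
    pix = np.stack([xs.ravel(), ys.ravel()], axis=1).astype(float)
    simplex = tri.find_simplex(pix)
    inside = simplex >= 0
    pix = pix[inside]
    simplex = simplex[inside]
    T = tri.transform[simplex]          # (npix, 3, 2)
    bary2 = np.einsum("pij,pj->pi", T[:, :2], pix - T[:, 2])
    bary = np.concatenate([bary2, 1 - bary2.sum(axis=1, keepdims=True)], axis=1)
    verts = tri.simplices[simplex]
    mask_pixels = np.stack([pix[:, 1], pix[:, 0]], axis=1).astype(int)
    return ref, (h, w), mask_pixels, verts, bary


def train_aam(
    images: list[np.ndarray],
    shapes: list[LandmarkShape],
    variance_fraction: float = 0.98,
    ref_width: float = 64.0,
    smooth_sigma: float = 4.0,
    seed: int = 0,
) -> AppearanceModel:
    """Train an appearance model from histogram-equalized image/shape pairs.

    Builds the shape PCA, warps every training image into the mean-shape
    reference frame (piecewise-affine over a Delaunay triangulation) for a
    texture PCA, and estimates the parameter-update matrix by regressing
    known single-parameter perturbations against the texture residuals they
    induce.
    """
    if len(images) < 2 or len(images) != len(shapes):
        raise ModelTrainingError("need at least two image/shape pairs")
    sm = train_shape_model(shapes, variance_fraction=variance_fraction)
    mean_width = np.ptp(sm.mean_shape[:, 0])
    if mean_width == 0:
        raise ModelTrainingError("mean shape has zero width; texture frame would be empty")
    base_scale = ref_width / mean_width
    ref, frame_shape, mask_pixels, verts, bary = _build_reference_frame(sm.mean_shape, base_scale)

    model = AppearanceModel(
        shape_model=sm,
        base_scale=base_scale,
        ref_shape=ref,
        frame_shape=frame_shape,
        mask_pixels=mask_pixels,
        pix_vertices=verts,
        pix_bary=bary,
        texture_mean=np.zeros(len(mask_pixels)),
        texture_modes=np.zeros((len(mask_pixels), 0)),
        texture_variances=np.zeros(0),
        update_matrix=np.zeros((sm.n_modes + 4, len(mask_pixels))),
        smooth_sigma=smooth_sigma,
    )

    # pre-smoothing widens the capture range of the linear update: sharp
    # boundary textures decorrelate within a few pixels, blurred ones do not
    smoothed = [
        gaussian_filter(np.asarray(img, float), smooth_sigma) if smooth_sigma > 0 else np.asarray(img, float)
        for img in images
    ]
    textures = np.stack(
        [model.sample_texture(img, shp.points) for img, shp in zip(smoothed, shapes)]
    )
    model.texture_mean = textures.mean(axis=0)
    X = textures - model.texture_mean
    _, svals, vt = np.linalg.svd(X, full_matrices=False)
    tvar = svals**2 / max(len(X) - 1, 1)
    total = tvar.sum()
    if total <= 1e-24:
        mt = 0
    else:
        keep = tvar > 1e-12 * total
        cum = np.cumsum(tvar[keep]) / total
        mt = min(int(np.searchsorted(cum, variance_fraction - 1e-12) + 1), int(keep.sum()))
    model.texture_modes = vt[:mt].T.copy()
    model.texture_variances = tvar[:mt].copy()

    # update matrix from seeded single-parameter perturbations
    rng = np.random.default_rng(seed)
    sds = np.sqrt(sm.variances)
    deltas: list[np.ndarray] = []
    for j in range(sm.n_modes):
        if sds[j] > 0:
            for step in (0.5 * sds[j], 1.0 * sds[j]):
                for sgn in (1, -1):
                    d = np.zeros(model.n_params)
                    d[j] = sgn * step
                    deltas.append(d)
    for idx, steps in zip(
        range(sm.n_modes, sm.n_modes + 4),
        ([0.03, 0.08], [0.03, 0.08], [2.0, 4.0, 6.0], [2.0, 4.0, 6.0]),
    ):
        for step in steps:
            for sgn in (1, -1):
                d = np.zeros(model.n_params)
                d[idx] = sgn * step
                deltas.append(d)

    dP, dG = [], []
    for img, shp in zip(smoothed, shapes):
        p_star = model.params_from_points(shp.points, clamp_sd=None)
        for d in deltas:
            jitter = 1.0 + 0.2 * (rng.random() - 0.5)
            pd = p_star + d * jitter
            g = model.sample_texture(img, model.points_from_params(pd))
            dG.append(model.texture_residual(g))
            dP.append(d * jitter)
    G = np.stack(dG, axis=1)             # (npix, n_samples)
    P = np.stack(dP, axis=1)             # (n_params, n_samples)
    model.update_matrix = P @ np.linalg.pinv(G, rcond=1e-8)
    return model


def fit_aam(
    image: np.ndarray,
    model: AppearanceModel,
    init_shape: LandmarkShape | np.ndarray,
    max_iter: int = 30,
    step_factors=(1.0, 0.5, 0.25, 0.125),
    rel_tol: float = 1e-4,
    clamp_sd: float = 3.0,
    roi_bounds=None,
) -> FitResult:
    """Fit the AAM to a histogram-equalized image from an initial shape.

    Each iteration samples the texture under the current shape, computes
    the residual against the texture subspace, and applies the update
    matrix scaled by the first step factor that reduces the residual norm.
    Stops on relative residual improvement below ``rel_tol``; three
    consecutive iterations without any accepted step abort the fit with
    ``converged=False``.
    """
    img = np.asarray(image, float)
    if model.smooth_sigma > 0:
        img = gaussian_filter(img, model.smooth_sigma)
    init_pts = init_shape.points if isinstance(init_shape, LandmarkShape) else np.asarray(init_shape, float)
    if len(init_pts) != model.shape_model.n_points:
        raise ValueError("init shape length does not match the model")
    p = model.params_from_points(init_pts, clamp_sd=clamp_sd)
    g = model.sample_texture(img, model.points_from_params(p))
    r = model.texture_residual(g)
    err = float(r @ r)
    converged = False
    reason = ""
    fails = 0
    it = 0
    ns = model.n_shape_modes
    for it in range(1, max_iter + 1):
        dp = model.update_matrix @ r
        accepted = False
        best_trial = np.inf
        for factor in step_factors:
            p_new = p - factor * dp
            p_new[:ns] = model.shape_model.clamp(p_new[:ns], clamp_sd)
            g_new = model.sample_texture(img, model.points_from_params(p_new))
            r_new = model.texture_residual(g_new)
            err_new = float(r_new @ r_new)
            best_trial = min(best_trial, err_new)
            if err_new < err:
                improvement = (err - err_new) / max(err, 1e-300)
                p, r, err = p_new, r_new, err_new
                accepted = True
                break
        if accepted:
            fails = 0
            if improvement < rel_tol:
                converged = True
                break
        elif best_trial <= err * (1 + rel_tol):
            # flat minimum: no factor helps, but none hurts either
            converged = True
            break
        else:
            fails += 1
            if fails >= 3:
                reason = "no step factor reduced the residual"
                break
    pts = _clip_to_roi(model.points_from_params(p), roi_bounds)
    fitted = LandmarkShape(pts, dict(model.shape_model.index_map), model.shape_model.laterality)
    return FitResult(fitted, converged, it, final_metric=err, reason=reason)


# ---------------------------------------------------------------------------
# serialization


def save_models(path, shape_model: ShapeModel | None = None,
                profile_model: ProfileModel | None = None,
                appearance_model: AppearanceModel | None = None) -> None:
    """Serialize trained models to a single ``.npz`` archive."""
    arrays: dict[str, np.ndarray] = {}
    meta: dict = {}
    if appearance_model is not None:
        shape_model = appearance_model.shape_model
        am = appearance_model
        arrays.update(
            am_ref_shape=am.ref_shape, am_mask_pixels=am.mask_pixels,
            am_pix_vertices=am.pix_vertices, am_pix_bary=am.pix_bary,
            am_texture_mean=am.texture_mean, am_texture_modes=am.texture_modes,
            am_texture_variances=am.texture_variances, am_update=am.update_matrix,
        )
        meta["aam"] = {"base_scale": am.base_scale, "frame_shape": list(am.frame_shape), "smooth_sigma": am.smooth_sigma}
    if shape_model is not None:
        arrays.update(
            sm_mean=shape_model.mean_shape, sm_modes=shape_model.modes,
            sm_variances=shape_model.variances,
        )
        meta["shape"] = {
            "index_map": shape_model.index_map,
            "laterality": shape_model.laterality.value if shape_model.laterality else None,
        }
    if profile_model is not None:
        arrays.update(pm_means=profile_model.means, pm_inv_covs=profile_model.inv_covs)
        meta["profile"] = {"halfwidth": profile_model.halfwidth}
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_models(path):
    """Load models saved by :func:`save_models`.

    Returns ``(shape_model, profile_model, appearance_model)``; entries not
    present in the archive are ``None``.
    """
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        sm = pm = am = None
        if "shape" in meta:
            lat = meta["shape"]["laterality"]
            sm = ShapeModel(
                mean_shape=z["sm_mean"], modes=z["sm_modes"], variances=z["sm_variances"],
                index_map={k: int(v) for k, v in meta["shape"]["index_map"].items()},
                laterality=Laterality(lat) if lat else None,
            )
        if "profile" in meta:
            pm = ProfileModel(
                means=z["pm_means"], inv_covs=z["pm_inv_covs"],
                halfwidth=int(meta["profile"]["halfwidth"]),
            )
        if "aam" in meta:
            am = AppearanceModel(
                shape_model=sm,
                base_scale=float(meta["aam"]["base_scale"]),
                ref_shape=z["am_ref_shape"],
                frame_shape=tuple(meta["aam"]["frame_shape"]),
                mask_pixels=z["am_mask_pixels"],
                pix_vertices=z["am_pix_vertices"],
                pix_bary=z["am_pix_bary"],
                texture_mean=z["am_texture_mean"],
                texture_modes=z["am_texture_modes"],
                texture_variances=z["am_texture_variances"],
                update_matrix=z["am_update"],
                smooth_sigma=float(meta["aam"].get("smooth_sigma", 4.0)),
            )
    return sm, pm, am
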