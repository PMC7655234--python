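"""Image similarity, smoothness penalty, and single-region FFD registration.

The registration implemented here is the compact non-sliding free-form
deformation used to parameterize the motion seen in the surrogate slice
(the CPD_s that global PCA surrogates are built from): locally normalized
cross-correlation (LNCC) as similarity, bending energy as regularization,
coarse-to-fine control-point levels, gradient-based (L-BFGS) optimization.
The sliding-preserving registration used to measure reference motion in
patient data is deliberately not implemented; reference motion comes from
synthetic ground truth or imported control-point displacement files.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.ndimage import gaussian_filter, map_coordinates

from .grid import ControlPointGrid, _image_basis, evaluate_bspline

__all__ = ["lncc", "bending_energy", "register_ffd", "project_dvf_to_grid", "RegistrationResult"]


def _local_stats(a, b, sigma_px):
    mu_a = gaussian_filter(a, sigma_px, mode="reflect")
    mu_b = gaussian_filter(b, sigma_px, mode="reflect")
    var_a = gaussian_filter(a * a, sigma_px, mode="reflect") - mu_a**2
    var_b = gaussian_filter(b * b, sigma_px, mode="reflect") - mu_b**2
    cov = gaussian_filter(a * b, sigma_px, mode="reflect") - mu_a * mu_b
    return mu_a, mu_b, var_a, var_b, cov


def _eps_for(a, b, eps):
    if eps is not None:
        return float(eps)
    rng = max(np.ptp(a), np.ptp(b), 1e-12)
    return 1e-8 * rng**2


def _lncc_map(a, b, sigma_px, eps):
    """Per-pixel correlation map with a variance floor.

    Pixels whose local variance (in either image) falls below the floor
    carry no usable local contrast; their correlation is defined as zero,
    which also keeps the analytic gradient bounded there.
    """
    mu_a, mu_b, var_a, var_b, cov = _local_stats(a, b, sigma_px)
    valid = (var_a > eps) & (var_b > eps)
    denom = np.where(valid, np.sqrt(np.where(valid, var_a * var_b, 1.0)), 1.0)
    c = np.where(valid, cov / denom, 0.0)
    return c, valid, denom, mu_a, mu_b, var_a


def lncc(a: np.ndarray, b: np.ndarray, sigma_px: float = 2.0, mask=None, eps=None) -> float:
    """Mean locally normalized cross-correlation of two images, in [-1, 1].

    Local means/variances/covariance are taken under a Gaussian window of
    ``sigma_px`` pixels; a variance floor ``eps`` (scaled to the image
    dynamic range when not given) zeroes the correlation where either
    image is locally flat.  The mean is taken over ``mask`` when
    supplied, otherwise over all pixels.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    eps = _eps_for(a, b, eps)
    c, *_ = _lncc_map(a, b, sigma_px, eps)
    if mask is not None:
        mask = np.asarray(mask, bool)
        return float(c[mask].mean())
    return float(c.mean())


def _lncc_value_and_grad(a, b, sigma_px, eps):
    """Mean LNCC and its gradient with respect to image ``a``."""
    c, valid, denom, mu_a, mu_b, var_a = _lncc_map(a, b, sigma_px, eps)
    n = a.size
    alpha = np.where(valid, 1.0 / denom, 0.0)
    beta = np.where(valid, c / np.where(valid, var_a, 1.0), 0.0)
    g = (
        b * gaussian_filter(alpha, sigma_px, mode="reflect")
        - gaussian_filter(alpha * mu_b, sigma_px, mode="reflect")
        - a * gaussian_filter(beta, sigma_px, mode="reflect")
        + gaussian_filter(beta * mu_a, sigma_px, mode="reflect")
    ) / n
    return float(c.mean()), g


def bending_energy(grid: ControlPointGrid, image_shape, pixel_spacing_mm) -> float:
    """Mean squared second derivative of the displacement field over the image.

    Sum of squared second spatial derivatives of both displacement
    components, with the mixed term counted twice; zero for any globally
    affine displacement.
    """
    mats = _bending_mats(grid, image_shape, pixel_spacing_mm)
    return _bending_value(grid.displacements, mats, np.prod(image_shape))


def _bending_mats(grid, image_shape, pixel_spacing_mm):
    w20 = _image_basis(grid, image_shape, pixel_spacing_mm, deriv=(2, 0))
    w11 = _image_basis(grid, image_shape, pixel_spacing_mm, deriv=(1, 1))
    w02 = _image_basis(grid, image_shape, pixel_spacing_mm, deriv=(0, 2))
    return w20, w11, w02


def _bending_value(disp, mats, n_pix, scales=(1.0, 1.0, 1.0)):
    (wr2, wc0), (wr1, wc1), (wr0, wc2) = mats
    total = 0.0
    for k in range(2):
        d = disp[..., k]
        total += scales[0] * np.sum((wr2 @ d @ wc0.T) ** 2)
        total += 2.0 * scales[1] * np.sum((wr1 @ d @ wc1.T) ** 2)
        total += scales[2] * np.sum((wr0 @ d @ wc2.T) ** 2)
    return float(total / n_pix)


def _bending_grad(disp, mats, n_pix, scales=(1.0, 1.0, 1.0)):
    (wr2, wc0), (wr1, wc1), (wr0, wc2) = mats
    grad = np.empty_like(disp)
    for k in range(2):
        d = disp[..., k]
        grad[..., k] = (
            scales[0] * wr2.T @ (wr2 @ d @ wc0.T) @ wc0
            + 2.0 * scales[1] * wr1.T @ (wr1 @ d @ wc1.T) @ wc1
            + scales[2] * wr0.T @ (wr0 @ d @ wc2.T) @ wc2
        ) * (2.0 / n_pix)
    return grad


def project_dvf_to_grid(
    displacements: np.ndarray, grid: ControlPointGrid, image_shape, pixel_spacing_mm
) -> ControlPointGrid:
    """Least-squares fit of control-point displacements to a pixel DVF.

    Because the B-spline evaluation is separable the projection reduces to
    two small least-squares solves per component.  When the target grid can
    represent the field exactly (e.g. dyadic refinement) the projection is
    exact to round-off.
    """
    wr, wc = _image_basis(grid, image_shape, pixel_spacing_mm)
    out = np.empty(grid.grid_shape + (2,))
    for k in range(2):
        x, *_ = np.linalg.lstsq(wr, displacements[..., k], rcond=None)
        d, *_ = np.linalg.lstsq(wc, x.T, rcond=None)
        out[..., k] = d.T
    return grid.with_displacements(out)


def _downsample(image, factor):
    if factor == 1:
        return np.asarray(image, float)
    sm = gaussian_filter(np.asarray(image, float), factor / 2.0, mode="reflect")
    return sm[::factor, ::factor]


@dataclass
class RegistrationResult:
    grid: ControlPointGrid
    converged: bool
    trace: list  # objective value per accepted iterate, per level
    similarity: float


def register_ffd(
    source: np.ndarray,
    target: np.ndarray,
    pixel_spacing_mm,
    levels_px=(20, 10, 5),
    bend_weight: float = 0.005,
    lncc_sigma_px: float = 2.0,
    max_iter: int = 40,
    init_grid: ControlPointGrid | None = None,
) -> RegistrationResult:
    """Multi-resolution single-region FFD registration of 2D images.

    Maximizes mean LNCC minus ``bend_weight`` times the bending energy over
    cubic B-spline control-point displacements, coarse-to-fine through the
    ``levels_px`` control-point spacings (in pixels of the original image),
    each level warm-started from the previous one.  When ``init_grid`` is
    given (e.g. the result for a neighbouring frame of a cine series), only
    the finest level is run, starting from it.  Deterministic given inputs
    and budget.

    Returns the finest-level grid together with the per-iteration objective
    trace; if the optimizer hits the iteration budget the best-so-far grid
    is returned with ``converged=False``.
    """
    source = np.asarray(source, float)
    target = np.asarray(target, float)
    if source.shape != target.shape:
        raise ValueError("source and target must share shape")
    if list(levels_px) != sorted(levels_px, reverse=True):
        raise ValueError("levels_px must be strictly decreasing")
    pixel_spacing_mm = np.broadcast_to(np.asarray(pixel_spacing_mm, float), (2,))
    eps = _eps_for(source, target, None)

    levels = list(levels_px)
    if init_grid is not None:
        levels = levels[-1:]

    grid = None
    trace: list[list[float]] = []
    converged = True
    finest = levels_px[-1]
    for spacing_px in levels:
        factor = max(1, int(round(spacing_px / finest)))
        src_l = _downsample(source, factor)
        tgt_l = _downsample(target, factor)
        sp_l = pixel_spacing_mm * factor
        cp_mm = spacing_px * pixel_spacing_mm
        level_grid = ControlPointGrid.covering(src_l.shape, sp_l, cp_mm)
        if grid is not None:
            prev_dvf = evaluate_bspline(grid, src_l.shape, sp_l)
            level_grid = project_dvf_to_grid(
                prev_dvf.displacements, level_grid, src_l.shape, sp_l
            )
        elif init_grid is not None:
            level_grid = init_grid.copy()

        level_trace, level_grid, ok = _optimize_level(
            src_l, tgt_l, sp_l, level_grid, bend_weight, lncc_sigma_px, max_iter, eps
        )
        trace.append(level_trace)
        converged = converged and ok
        grid = level_grid

    sim = lncc(
        warp_source(source, grid, pixel_spacing_mm), target, lncc_sigma_px, eps=eps
    )
    return RegistrationResult(grid=grid, converged=converged, trace=trace, similarity=sim)


def warp_source(source, grid, pixel_spacing_mm):
    """Pull the source image back through the grid's displacement field."""
    dvf = evaluate_bspline(grid, source.shape, pixel_spacing_mm)
    rr, cc = np.meshgrid(
        np.arange(source.shape[0], dtype=float), np.arange(source.shape[1], dtype=float), indexing="ij"
    )
    coords = [
        rr + dvf.displacements[..., 0] / pixel_spacing_mm[0],
        cc + dvf.displacements[..., 1] / pixel_spacing_mm[1],
    ]
    return map_coordinates(source, coords, order=1, mode="nearest")


def _optimize_level(src, tgt, sp, grid0, bend_weight, sigma, max_iter, eps):
    shape = src.shape
    wr, wc = _image_basis(grid0, shape, sp)
    bend_mats = _bending_mats(grid0, shape, sp)
    # the penalty weight is calibrated for bending energy in control-grid
    # index units (the registration-package convention); rescale the
    # physical-unit second derivatives accordingly
    hr, hc = grid0.spacing_mm
    bend_scales = (hr**4, (hr * hc) ** 2, hc**4)
    n_pix = src.size
    g_src = np.gradient(src)  # per-pixel-index units
    rr, cc = np.meshgrid(np.arange(shape[0], dtype=float), np.arange(shape[1], dtype=float), indexing="ij")
    gshape = grid0.grid_shape + (2,)

    last: dict = {}

    def objective(x):
        disp = x.reshape(gshape)
        u0 = wr @ disp[..., 0] @ wc.T
        u1 = wr @ disp[..., 1] @ wc.T
        coords = [rr + u0 / sp[0], cc + u1 / sp[1]]
        warped = map_coordinates(src, coords, order=1, mode="nearest")
        sim, g_img = _lncc_value_and_grad(warped, tgt, sigma, eps)
        val = -sim + bend_weight * _bending_value(disp, bend_mats, n_pix, bend_scales)
        grad = np.empty(gshape)
        for k in range(2):
            gk = map_coordinates(g_src[k], coords, order=1, mode="nearest")
            pix = -g_img * gk / sp[k]
            grad[..., k] = wr.T @ pix @ wc
        grad += bend_weight * _bending_grad(disp, bend_mats, n_pix, bend_scales)
        last["x"] = x.copy()
        last["f"] = val
        return val, grad.ravel()

    level_trace: list[float] = []

    def callback(xk):
        if "x" in last and np.array_equal(xk, last["x"]):
            level_trace.append(last["f"])
        else:
            level_trace.append(objective(xk)[0])

    x0 = grid0.displacements.ravel().copy()
    level_trace.append(objective(x0)[0])
    res = optimize.minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        callback=callback,
        options={"maxiter": max_iter, "ftol": 1e-9, "gtol": 1e-7},
    )
    grid = grid0.with_displacements(res.x.reshape(gshape))
    return level_trace, grid, bool(res.success)
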