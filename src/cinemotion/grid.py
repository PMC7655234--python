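"""Cubic B-spline displacement fields on control-point grids.

Conventions used throughout the package (stated once, here):

* images are 2D arrays indexed ``(row, col)``; row = superior-inferior
  (SI, increasing inferior), col = anterior-posterior for sagittal slices
  (AP, increasing anterior) or left-right for coronal slices;
* physical positions are ``index * pixel_spacing_mm`` (mm), origin at
  pixel (0, 0);
* displacements are forward displacements of the reference (source)
  anatomy, stored in mm as ``(row_displacement, col_displacement)``.

A deformation is parameterized by the displacements of a regular grid of
cubic B-spline control points (the free-form deformation model).  Sliding
motion between the thoracic wall and the lung/abdomen compartment is
represented by two full grids, one per region, selected per pixel by a
fixed segmentation of the source image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .exceptions import CoverageError

__all__ = [
    "ControlPointGrid",
    "SlidingTransform",
    "Dvf",
    "bspline_basis",
    "basis_matrix",
    "evaluate_bspline",
    "compose_sliding_dvf",
    "jacobian_determinant",
    "warp_image",
    "warp_mask",
    "invert_dvf",
]


def bspline_basis(t: np.ndarray, deriv: int = 0) -> np.ndarray:
    """Values of the four cubic B-spline basis functions at local offset t.

    ``t`` in [0, 1) is the fractional grid coordinate; returns an array of
    shape ``t.shape + (4,)`` with the weights of control points
    ``i-1, i, i+1, i+2`` (``i = floor(u)``, ``t = u - i``).  ``deriv``
    selects the 0th, 1st or 2nd derivative with respect to the grid
    coordinate ``u``.
    """
    t = np.asarray(t, dtype=float)
    if deriv == 0:
        b = np.stack(
            [
                (1.0 - t) ** 3 / 6.0,
                (3.0 * t**3 - 6.0 * t**2 + 4.0) / 6.0,
                (-3.0 * t**3 + 3.0 * t**2 + 3.0 * t + 1.0) / 6.0,
                t**3 / 6.0,
            ],
            axis=-1,
        )
    elif deriv == 1:
        b = np.stack(
            [
                -((1.0 - t) ** 2) / 2.0,
                (9.0 * t**2 - 12.0 * t) / 6.0,
                (-9.0 * t**2 + 6.0 * t + 3.0) / 6.0,
                t**2 / 2.0,
            ],
            axis=-1,
        )
    elif deriv == 2:
        b = np.stack([1.0 - t, 3.0 * t - 2.0, 1.0 - 3.0 * t, t], axis=-1)
    else:  # pragma: no cover - internal misuse
        raise ValueError(f"deriv must be 0, 1 or 2, got {deriv}")
    return b


@dataclass
class ControlPointGrid:
    """Regular grid of cubic B-spline control points with mm displacements.

    ``origin_mm`` is the physical position of control point (0, 0); it is
    normally negative so that the grid extends at least one control point
    beyond every image border (cubic support).
    """

    origin_mm: np.ndarray
    spacing_mm: np.ndarray
    displacements: np.ndarray  # (grid_rows, grid_cols, 2), mm

    def __post_init__(self) -> None:
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float)
        self.displacements = np.asarray(self.displacements, dtype=float)
        if np.any(self.spacing_mm <= 0):
            raise CoverageError(f"control-point spacing must be > 0, got {self.spacing_mm}")
        if self.displacements.ndim != 3 or self.displacements.shape[2] != 2:
            raise CoverageError(
                f"displacements must have shape (rows, cols, 2), got {self.displacements.shape}"
            )

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.displacements.shape[:2]

    def point_positions_mm(self) -> np.ndarray:
        """Physical positions of all control points, shape (rows, cols, 2)."""
        gr, gc = self.grid_shape
        rr = self.origin_mm[0] + np.arange(gr) * self.spacing_mm[0]
        cc = self.origin_mm[1] + np.arange(gc) * self.spacing_mm[1]
        out = np.empty((gr, gc, 2))
        out[..., 0] = rr[:, None]
        out[..., 1] = cc[None, :]
        return out

    def with_displacements(self, displacements: np.ndarray) -> "ControlPointGrid":
        return ControlPointGrid(self.origin_mm.copy(), self.spacing_mm.copy(), displacements)

    def copy(self) -> "ControlPointGrid":
        return self.with_displacements(self.displacements.copy())

    @classmethod
    def covering(
        cls,
        image_shape: tuple[int, int],
        pixel_spacing_mm,
        cp_spacing_mm,
    ) -> "ControlPointGrid":
        """Zero-displacement grid covering the image with cubic support.

        One control point is placed one spacing before the image origin and
        enough points are added so that every pixel has its full 4x4
        neighbourhood inside the grid.
        """
        pixel_spacing_mm = np.broadcast_to(np.asarray(pixel_spacing_mm, float), (2,))
        cp_spacing_mm = np.broadcast_to(np.asarray(cp_spacing_mm, float), (2,))
        if np.any(cp_spacing_mm <= 0) or np.any(pixel_spacing_mm <= 0):
            raise CoverageError("spacings must be positive")
        origin = -cp_spacing_mm.copy()
        n = []
        for ax in range(2):
            extent = (image_shape[ax] - 1) * pixel_spacing_mm[ax]
            u_max = (extent - origin[ax]) / cp_spacing_mm[ax]
            n.append(int(np.ceil(u_max)) + 3)
        return cls(origin, cp_spacing_mm, np.zeros((n[0], n[1], 2)))


@dataclass
class SlidingTransform:
    """Two-region sliding deformation: one full grid per region.

    ``region_grids[0]`` is the chest wall / rest of the body,
    ``region_grids[1]`` the lung/mediastinum/abdomen compartment.
    ``source_segmentation`` is the fixed binary segmentation of the source
    image (1 = compartment 1) that selects which grid drives each pixel.
    """

    region_grids: list
    source_segmentation: np.ndarray

    def __post_init__(self) -> None:
        if len(self.region_grids) != 2:
            raise ValueError("exactly two region grids are required")
        g0, g1 = self.region_grids
        if g0.grid_shape != g1.grid_shape or not np.allclose(
            g0.spacing_mm, g1.spacing_mm
        ) or not np.allclose(g0.origin_mm, g1.origin_mm):
            raise ValueError("both region grids must share geometry")
        self.source_segmentation = np.asarray(self.source_segmentation).astype(bool)

    def copy(self) -> "SlidingTransform":
        return SlidingTransform(
            [g.copy() for g in self.region_grids], self.source_segmentation.copy()
        )


@dataclass
class Dvf:
    """Per-pixel forward displacement field in mm on the reference grid."""

    displacements: np.ndarray  # (rows, cols, 2), mm
    pixel_spacing_mm: np.ndarray = field(default_factory=lambda: np.array([1.0, 1.0]))

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=float)
        self.pixel_spacing_mm = np.broadcast_to(
            np.asarray(self.pixel_spacing_mm, float), (2,)
        ).copy()
        if not np.all(np.isfinite(self.displacements)):
            raise ValueError("DVF contains non-finite displacements")

    @property
    def shape(self) -> tuple[int, int]:
        return self.displacements.shape[:2]

    def magnitude(self) -> np.ndarray:
        return np.sqrt(np.sum(self.displacements**2, axis=-1))


def bspline_support(
    positions_mm: np.ndarray,
    origin_mm: float,
    spacing_mm: float,
    n_ctrl: int,
    deriv: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Support indices and weights of the cubic basis at given positions.

    Returns ``(first_index, weights)`` where ``weights`` has shape
    ``(n, 4)`` and control points ``first_index .. first_index + 3``
    carry the four nonzero weights; derivative weights are in physical
    units (per mm).
    """
    positions_mm = np.asarray(positions_mm, dtype=float)
    u = (positions_mm - origin_mm) / spacing_mm
    i = np.floor(u).astype(int)
    # positions exactly on the last supported knot reuse the previous span
    i = np.minimum(i, n_ctrl - 3)
    t = u - i
    if np.any(i < 1) or np.any(i > n_ctrl - 3):
        raise CoverageError(
            "control-point grid does not cover the requested positions "
            f"(grid index range [{i.min()}, {i.max()}], need [1, {n_ctrl - 3}])"
        )
    w = bspline_basis(t, deriv=deriv) / spacing_mm**deriv
    return i - 1, w


def basis_matrix(
    positions_mm: np.ndarray,
    origin_mm: float,
    spacing_mm: float,
    n_ctrl: int,
    deriv: int = 0,
) -> np.ndarray:
    """Dense 1D basis-weight matrix mapping control values to positions.

    Row ``p`` of the returned ``(len(positions), n_ctrl)`` matrix holds the
    cubic B-spline weights of every control point at ``positions_mm[p]``;
    derivative weights are returned in physical units (per mm).
    """
    positions_mm = np.asarray(positions_mm, dtype=float)
    i0, w = bspline_support(positions_mm, origin_mm, spacing_mm, n_ctrl, deriv=deriv)
    mat = np.zeros((positions_mm.size, n_ctrl))
    rows = np.arange(positions_mm.size)
    for k in range(4):
        mat[rows, i0 + k] += w[:, k]
    return mat


def _image_basis(grid: ControlPointGrid, image_shape, pixel_spacing_mm, deriv=(0, 0)):
    pixel_spacing_mm = np.broadcast_to(np.asarray(pixel_spacing_mm, float), (2,))
    gr, gc = grid.grid_shape
    wr = basis_matrix(
        np.arange(image_shape[0]) * pixel_spacing_mm[0],
        grid.origin_mm[0],
        grid.spacing_mm[0],
        gr,
        deriv=deriv[0],
    )
    wc = basis_matrix(
        np.arange(image_shape[1]) * pixel_spacing_mm[1],
        grid.origin_mm[1],
        grid.spacing_mm[1],
        gc,
        deriv=deriv[1],
    )
    return wr, wc


def evaluate_bspline(
    grid: ControlPointGrid, image_shape: tuple[int, int], pixel_spacing_mm
) -> Dvf:
    """Evaluate the control-point grid as a per-pixel displacement field.

    Tensor-product cubic B-spline interpolation; exact partition of unity,
    so a uniform control-point displacement reproduces itself exactly.
    """
    wr, wc = _image_basis(grid, image_shape, pixel_spacing_mm)
    disp = np.stack(
        [wr @ grid.displacements[..., k] @ wc.T for k in range(2)], axis=-1
    )
    return Dvf(disp, pixel_spacing_mm)


def compose_sliding_dvf(
    transform: SlidingTransform, image_shape: tuple[int, int], pixel_spacing_mm
) -> Dvf:
    """Per-pixel DVF of a two-region sliding transform.

    Each pixel takes its displacement from the grid of the region it
    belongs to in the fixed source segmentation; discontinuities across the
    region boundary are permitted (that is the point of sliding).
    """
    d0 = evaluate_bspline(transform.region_grids[0], image_shape, pixel_spacing_mm)
    d1 = evaluate_bspline(transform.region_grids[1], image_shape, pixel_spacing_mm)
    seg = transform.source_segmentation
    if seg.shape != tuple(image_shape):
        raise ValueError(
            f"segmentation shape {seg.shape} does not match image shape {tuple(image_shape)}"
        )
    disp = np.where(seg[..., None], d1.displacements, d0.displacements)
    return Dvf(disp, pixel_spacing_mm)


def jacobian_determinant(
    field, image_shape=None, pixel_spacing_mm=None
) -> np.ndarray:
    """Per-pixel determinant of (identity + spatial displacement gradient).

    Values of 1 indicate local volume preservation; negative values would
    indicate folding.  Analytic B-spline derivatives are used when a
    :class:`ControlPointGrid` is supplied, central differences for a raw
    :class:`Dvf`.
    """
    if isinstance(field, ControlPointGrid):
        if image_shape is None or pixel_spacing_mm is None:
            raise ValueError("image_shape and pixel_spacing_mm required for a grid")
        wr, wc = _image_basis(field, image_shape, pixel_spacing_mm)
        wr_d, wc_d = _image_basis(field, image_shape, pixel_spacing_mm, deriv=(1, 1))
        dr = field.displacements[..., 0]
        dc = field.displacements[..., 1]
        j_rr = wr_d @ dr @ wc.T
        j_rc = wr @ dr @ wc_d.T
        j_cr = wr_d @ dc @ wc.T
        j_cc = wr @ dc @ wc_d.T
    elif isinstance(field, Dvf):
        sp = field.pixel_spacing_mm
        j_rr, j_rc = np.gradient(field.displacements[..., 0], sp[0], sp[1])
        j_cr, j_cc = np.gradient(field.displacements[..., 1], sp[0], sp[1])
    else:
        raise TypeError(f"expected ControlPointGrid or Dvf, got {type(field)}")
    return (1.0 + j_rr) * (1.0 + j_cc) - j_rc * j_cr


def warp_image(image: np.ndarray, dvf: Dvf, interpolation: str = "linear") -> np.ndarray:
    """Resample ``image`` through the displacement field (pull-back).

    ``output(x) = image(x + u(x) / pixel_spacing)``; reads outside the
    image return 0.
    """
    if image.shape != dvf.shape:
        raise ValueError(f"image shape {image.shape} does not match DVF {dvf.shape}")
    order = {"linear": 1, "nearest": 0}[interpolation]
    rr, cc = np.meshgrid(
        np.arange(image.shape[0], dtype=float),
        np.arange(image.shape[1], dtype=float),
        indexing="ij",
    )
    coords = [
        rr + dvf.displacements[..., 0] / dvf.pixel_spacing_mm[0],
        cc + dvf.displacements[..., 1] / dvf.pixel_spacing_mm[1],
    ]
    return map_coordinates(
        np.asarray(image, float), coords, order=order, mode="grid-constant", cval=0.0
    )


def warp_mask(mask: np.ndarray, dvf: Dvf) -> np.ndarray:
    """Transport a binary mask through the displacement field."""
    warped = warp_image(np.asarray(mask, float), dvf, interpolation="nearest")
    return warped > 0.5


def invert_dvf(dvf: Dvf, n_iter: int = 20, tol_px: float = 0.01) -> Dvf:
    """Numerically invert a forward DVF by fixed-point iteration.

    Solves ``v(x) = -u(x + v(x))`` so that pulling the reference image back
    through ``v`` renders the deformed frame.  Iteration stops early when
    the maximum update falls below ``tol_px`` pixels.
    """
    sp = dvf.pixel_spacing_mm
    nr, nc = dvf.shape
    rr, cc = np.meshgrid(np.arange(nr, dtype=float), np.arange(nc, dtype=float), indexing="ij")
    v = np.zeros_like(dvf.displacements)
    u = dvf.displacements
    for _ in range(n_iter):
        coords = [rr + v[..., 0] / sp[0], cc + v[..., 1] / sp[1]]
        sampled = np.stack(
            [
                map_coordinates(u[..., k], coords, order=1, mode="nearest")
                for k in range(2)
            ],
            axis=-1,
        )
        v_new = -sampled
        step = np.max(np.abs(v_new - v) / sp)
        v = v_new
        if step < tol_px:
            break
    return Dvf(v, sp)
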