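"""Surrogate-signal extraction from the surrogate cine series.

Local signals follow a single anatomical edge (diaphragm in SI, skin
surface in AP) with sub-pixel precision; global signals are principal
component scores computed over the whole image (pixel intensities) or
over the control-point displacements of a non-sliding registration of the
surrogate slice (CPD_s).  All signals are resampled to the motion-frame
times with a cubic smoothing spline, whose analytic derivative provides
the temporal-derivative surrogates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import UnivariateSpline
from scipy.ndimage import binary_closing, gaussian_filter1d, label
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .exceptions import MaskError, SteadyStateError, TrackingError
from .series import CineSeries

__all__ = [
    "SurrogateSignal",
    "PcaResult",
    "discard_pre_steady_state",
    "track_edge",
    "diaphragm_signal",
    "skin_signal",
    "make_body_mask",
    "select_reference_frame",
    "pca_intensity",
    "pca_cpd",
    "resample_signal",
    "derivative_signal",
]


@dataclass
class SurrogateSignal:
    """Named 1D signal sampled at frame times.

    ``spline`` is the fitted smoothing-spline representation (set by
    :func:`resample_signal`), used both for interpolation at motion-frame
    times and for the analytic temporal derivative.
    """

    name: str
    sample_times_s: np.ndarray
    sample_values: np.ndarray
    units: str = "mm"
    spline: object = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.sample_times_s = np.asarray(self.sample_times_s, float)
        self.sample_values = np.asarray(self.sample_values, float)
        if self.sample_times_s.shape != self.sample_values.shape:
            raise ValueError("times and values must have the same length")
        if not np.all(np.isfinite(self.sample_values)):
            raise ValueError(f"signal {self.name!r} contains non-finite values")


@dataclass
class PcaResult:
    """Scores, spatial loadings and variance fractions of a PCA surrogate."""

    component_scores: np.ndarray  # (n_frames, k)
    coefficient_maps: np.ndarray  # (k, rows, cols) or (k, grid_rows, grid_cols, 2)
    explained_variance_fraction: np.ndarray  # (k,)
    variance_spectrum: np.ndarray  # all possible components, sums to 1
    mean_vector_reference: np.ndarray
    retained_mask: np.ndarray | None = None

    def score_signal(self, component: int, times_s, name: str) -> SurrogateSignal:
        return SurrogateSignal(
            name, times_s, self.component_scores[:, component], units="a.u."
        )


def discard_pre_steady_state(
    series: CineSeries, relative_threshold: float = 0.05
) -> tuple[CineSeries, int]:
    """Trim leading frames acquired before the intensity steady state.

    Removes the maximal leading run of frames whose mean intensity exceeds
    ``(1 + relative_threshold)`` times the median frame mean intensity;
    only leading frames are ever removed.
    """
    if len(series) == 0:
        raise ValueError("series is empty")
    means = series.mean_intensities()
    cutoff = (1.0 + relative_threshold) * np.median(means)
    n = 0
    while n < len(series) and means[n] > cutoff:
        n += 1
    if n == len(series):
        raise SteadyStateError("every frame exceeds the steady-state threshold")
    if n == 0:
        return series, 0
    return series.subset(np.arange(n, len(series))), n


def _track_frame(frame, r0, r1, c0, c1, axis, min_gradient):
    window = frame[r0:r1, c0:c1]
    profiles = window if axis == "SI" else window.T
    # profiles: (position along tracked axis, line index)
    smoothed = gaussian_filter1d(profiles.astype(float), sigma=1.0, axis=0, mode="nearest")
    grad = np.abs(np.gradient(smoothed, axis=0))
    positions = []
    for j in range(grad.shape[1]):
        g = grad[:, j]
        i = int(np.argmax(g[1:-1])) + 1
        if g[i] < min_gradient:
            continue
        denom = g[i - 1] - 2.0 * g[i] + g[i + 1]
        delta = 0.0 if abs(denom) < 1e-12 else 0.5 * (g[i - 1] - g[i + 1]) / denom
        positions.append(i + np.clip(delta, -0.5, 0.5))
    if not positions:
        return None
    offset = r0 if axis == "SI" else c0
    return offset + float(np.mean(positions))


def track_edge(
    series: CineSeries,
    seed_point: tuple[int, int],
    window: tuple[int, int],
    axis: str,
    positive_direction: int = -1,
    min_gradient: float | None = None,
    name: str = "edge",
) -> SurrogateSignal:
    """Track an intensity edge through the series with sub-pixel precision.

    Within a window centred on ``seed_point`` (full extents
    ``(SI, AP)`` in pixels), each line parallel to ``axis`` is Gaussian
    smoothed (sigma 1 px), the maximum-|gradient| sample located and
    refined by a quadratic fit to its three neighbouring gradient values;
    the per-frame edge position is the mean of the per-line sub-pixel
    locations.  The signal is the position relative to its own mean,
    in mm, with ``positive_direction`` chosen so that end-exhale
    (superior diaphragm / posterior skin) is positive.
    """
    if axis not in ("SI", "AP"):
        raise ValueError("axis must be 'SI' or 'AP'")
    nr, nc = series.frame_shape
    hr, hc = window[0] // 2, window[1] // 2
    r0, r1 = seed_point[0] - hr, seed_point[0] + window[0] - hr
    c0, c1 = seed_point[1] - hc, seed_point[1] + window[1] - hc
    if r0 < 0 or c0 < 0 or r1 > nr or c1 > nc:
        raise ValueError(
            f"window rows [{r0}, {r1}) cols [{c0}, {c1}) not inside frame {series.frame_shape}"
        )
    if min_gradient is None:
        min_gradient = 0.02 * np.ptp(series.frames[0])
    positions = []
    failed = []
    for idx, frame in enumerate(series.frames):
        pos = _track_frame(frame, r0, r1, c0, c1, axis, min_gradient)
        if pos is None:
            failed.append(idx)
        positions.append(pos)
    if failed:
        raise TrackingError(
            f"no line exceeded the minimum gradient in frame(s) {failed}"
        )
    positions = np.asarray(positions, float)
    spacing = series.pixel_spacing_mm[0 if axis == "SI" else 1]
    values = positive_direction * (positions - positions.mean()) * spacing
    sig = SurrogateSignal(name, series.times_s, values, units="mm")
    sig.positions_px = positions  # raw tracked positions, for reference-frame choice
    return sig


def diaphragm_signal(
    series: CineSeries, seed_point=None, window: tuple[int, int] = (20, 10)
) -> SurrogateSignal:
    """SI displacement of the diaphragm relative to its average position (mm).

    Superior displacement (end-exhale) is positive.
    """
    if seed_point is None:
        raise ValueError("a diaphragm seed point is required")
    return track_edge(
        series, seed_point, window, axis="SI", positive_direction=-1, name="diaphragm"
    )


def skin_signal(
    series: CineSeries, seed_point=None, window: tuple[int, int] = (10, 20)
) -> SurrogateSignal:
    """AP displacement of the skin surface relative to its average position (mm).

    Posterior displacement (end-exhale) is positive.
    """
    if seed_point is None:
        raise ValueError("a skin seed point is required")
    return track_edge(
        series, seed_point, window, axis="AP", positive_direction=-1, name="skin"
    )


def make_body_mask(reference_frame: np.ndarray, closing_radius_px: int = 30) -> np.ndarray:
    """Binary body mask: Otsu threshold, morphological closing, largest component."""
    frame = np.asarray(reference_frame, float)
    if frame.size == 0:
        raise MaskError("reference frame is empty")
    try:
        thr = threshold_otsu(frame)
    except ValueError as err:  # constant image
        raise MaskError("no foreground found (constant image)") from err
    fg = frame > thr
    if not fg.any():
        raise MaskError("no foreground found above the Otsu threshold")
    if closing_radius_px > 0:
        fg = binary_closing(fg, structure=disk(closing_radius_px))
    labels, n = label(fg)
    if n == 0:
        raise MaskError("foreground vanished after closing")
    sizes = np.bincount(labels.ravel())[1:]
    return labels == (1 + int(np.argmax(sizes)))


def select_reference_frame(
    series: CineSeries, diaphragm: SurrogateSignal, k: int = 30
) -> int:
    """Index of the frame whose diaphragm is closest to its average position.

    The average is taken over the first ``k`` frames (covering a few breath
    cycles); ties break to the earliest index.
    """
    values = diaphragm.sample_values
    if len(values) < k:
        warnings.warn(
            f"series has only {len(values)} frames; using all for the reference choice"
        )
        k = len(values)
    head = values[:k]
    return int(np.argmin(np.abs(head - head.mean())))


def _apply_sign_convention(scores, components, align_with):
    for j in range(scores.shape[1]):
        flip = False
        if align_with is not None:
            a = np.asarray(align_with, float)
            sa, sj = np.std(a), np.std(scores[:, j])
            r = 0.0
            if sa > 0 and sj > 0:
                r = float(np.corrcoef(a, scores[:, j])[0, 1])
            if abs(r) >= 0.1:
                flip = r < 0
            else:
                flip = components[j][np.argmax(np.abs(components[j]))] < 0
        else:
            flip = components[j][np.argmax(np.abs(components[j]))] < 0
        if flip:
            scores[:, j] *= -1.0
            components[j] *= -1.0
    return scores, components


def _pca(matrix: np.ndarray, n_components: int, align_with=None):
    n = matrix.shape[0]
    if n < n_components + 1:
        raise ValueError(f"need at least {n_components + 1} frames, got {n}")
    mean = matrix.mean(axis=0)
    centred = matrix - mean
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    spectrum = s**2
    total = spectrum.sum()
    spectrum = spectrum / total if total > 0 else spectrum
    scores = u[:, :n_components] * s[:n_components]
    components = vt[:n_components].copy()
    scores, components = _apply_sign_convention(scores, components, align_with)
    return scores, components, spectrum[:n_components], spectrum, mean


def pca_intensity(
    series: CineSeries, n_components: int = 3, align_with=None
) -> PcaResult:
    """PCA on the image intensities of all pixels of the surrogate images.

    Frames are flattened, the per-pixel temporal mean subtracted, and the
    principal axes computed; the loading of each pixel on a component is
    returned as a coefficient map.  ``align_with`` (typically the
    diaphragm signal at the same frames) fixes the arbitrary component
    signs so that scores correlate positively with it.
    """
    flat = series.frames.reshape(len(series), -1)
    scores, components, evar, spectrum, mean = _pca(flat, n_components, align_with)
    maps = components.reshape((n_components,) + series.frame_shape)
    return PcaResult(
        component_scores=scores,
        coefficient_maps=maps,
        explained_variance_fraction=evar,
        variance_spectrum=spectrum,
        mean_vector_reference=mean.reshape(series.frame_shape),
    )


def pca_cpd(
    cpd_series: list,
    body_mask: np.ndarray,
    pixel_spacing_mm,
    n_components: int = 3,
    align_with=None,
) -> PcaResult:
    """PCA on the surrogate-slice control-point displacements (CPD_s).

    Control points are retained iff their image-space location falls inside
    the body mask; the retained points' AP and SI displacement components
    are concatenated into one vector per frame before mean-centred PCA.
    Coefficient maps are returned per displacement direction on the full
    grid (zero outside the retained set).
    """
    if not cpd_series:
        raise ValueError("cpd_series is empty")
    g0 = cpd_series[0]
    pixel_spacing_mm = np.broadcast_to(np.asarray(pixel_spacing_mm, float), (2,))
    pos = g0.point_positions_mm()
    idx = np.round(pos / pixel_spacing_mm).astype(int)
    inside = (
        (idx[..., 0] >= 0)
        & (idx[..., 0] < body_mask.shape[0])
        & (idx[..., 1] >= 0)
        & (idx[..., 1] < body_mask.shape[1])
    )
    retained = np.zeros(g0.grid_shape, bool)
    retained[inside] = body_mask[idx[inside, 0], idx[inside, 1]]
    if not retained.any():
        raise MaskError("no control points inside the body mask")

    rows = []
    for g in cpd_series:
        if g.grid_shape != g0.grid_shape or not np.allclose(g.spacing_mm, g0.spacing_mm):
            raise ValueError("all CPD grids must share geometry")
        rows.append(
            np.concatenate([g.displacements[retained][:, 1], g.displacements[retained][:, 0]])
        )
    matrix = np.stack(rows)
    scores, components, evar, spectrum, mean = _pca(matrix, n_components, align_with)

    n_ret = int(retained.sum())
    maps = np.zeros((n_components,) + g0.grid_shape + (2,))
    for j in range(n_components):
        maps[j][retained, 1] = components[j][:n_ret]
        maps[j][retained, 0] = components[j][n_ret:]
    mean_maps = np.zeros(g0.grid_shape + (2,))
    mean_maps[retained, 1] = mean[:n_ret]
    mean_maps[retained, 0] = mean[n_ret:]
    return PcaResult(
        component_scores=scores,
        coefficient_maps=maps,
        explained_variance_fraction=evar,
        variance_spectrum=spectrum,
        mean_vector_reference=mean_maps,
        retained_mask=retained,
    )


def resample_signal(
    signal: SurrogateSignal,
    target_times,
    smoothing_level: float = 0.0,
) -> tuple[SurrogateSignal, list[int]]:
    """Resample a signal at the motion-frame times with a cubic spline.

    A cubic smoothing spline is fitted to the extracted samples
    (``smoothing_level`` is the spline's residual sum-of-squares budget)
    and evaluated at ``target_times``.  The default of 0 interpolates the
    samples: at a couple of frames per second a breath cycle is only
    sampled ~8 times, so successive differences are dominated by the
    breathing itself and any difference-based noise estimate would
    over-smooth, while the sub-pixel trackers leave little noise to
    remove.  Target times outside the sampled span are rejected and their
    indices returned so the caller can discard those motion frames rather
    than extrapolate.
    """
    target_times = np.asarray(target_times, float)
    t, v = signal.sample_times_s, signal.sample_values
    spline = UnivariateSpline(t, v, k=3, s=float(smoothing_level))
    inside = (target_times >= t[0]) & (target_times <= t[-1])
    rejected = list(np.nonzero(~inside)[0])
    kept = target_times[inside]
    out = SurrogateSignal(
        signal.name, kept, spline(kept), units=signal.units, spline=spline
    )
    return out, rejected


def derivative_signal(signal: SurrogateSignal) -> SurrogateSignal:
    """Analytic temporal derivative of a spline-fitted signal (units/s)."""
    if signal.spline is None:
        raise ValueError(f"signal {signal.name!r} has no fitted spline")
    dspline = signal.spline.derivative()
    return SurrogateSignal(
        signal.name + "_deriv",
        signal.sample_times_s,
        dspline(signal.sample_times_s),
        units=signal.units + "/s",
        spline=dspline,
    )
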