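"""Ground-truth sliding motion constructed on the correspondence model.

The true motion is defined directly on the B-spline control-point grids as
an exact linear function of the two latent respiratory components,

    CPD(p, t) = c1(p) * primary(t) + c2(p) * secondary(t) + c0(p),

independently for each of the two sliding regions.  Because the ground
truth lies exactly in the model class, an ordinary-least-squares fit
against the true signals must recover the generating coefficients exactly,
which is the strongest available end-to-end check of the fitting stage.
The intercepts are chosen so that the reference frame (respiratory state
closest to the trace average) has zero displacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..exceptions import ConfigurationError
from ..grid import ControlPointGrid, SlidingTransform, compose_sliding_dvf
from .breathing import BreathingTrace
from .phantom import PhantomAnatomy

__all__ = ["CoefficientSpec", "GroundTruth", "generate_ground_truth"]


@dataclass
class CoefficientSpec:
    """Spatial pattern of the true linear coefficients, in mm per unit signal.

    The visceral compartment (region 1) moves dominantly in SI near the
    diaphragm, decaying toward the lung apex; the chest wall (region 0)
    moves a few mm in AP.  The secondary component adds the hysteresis
    part of the motion.
    """

    diaphragm_si_mm: float = 15.0
    region1_ap_mm: float = 1.0
    hysteresis_si_mm: float = 1.0
    hysteresis_ap_mm: float = 2.5
    chest_wall_ap_mm: float = 3.0
    chest_wall_si_mm: float = 0.5
    chest_wall_hysteresis_ap_mm: float = 0.3

    @classmethod
    def zero(cls) -> "CoefficientSpec":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class GroundTruth:
    """True transforms, signals and generating coefficients of a dataset."""

    coefficients: np.ndarray  # (2 regions, grid_rows, grid_cols, 2 comps, 3) [c1, c2, c0]
    grid_template: ControlPointGrid
    source_segmentation: np.ndarray
    true_signals: BreathingTrace
    motion_times_s: np.ndarray
    transforms: list  # SlidingTransform per motion time
    reference_index: int
    reference_time_s: float
    pixel_spacing_mm: np.ndarray
    image_shape: tuple
    seed: int | None = None

    def transform_at(self, time_s: float) -> SlidingTransform:
        """Exact sliding transform at an arbitrary acquisition time."""
        p, s = self.true_signals.value_at([time_s])
        return self._assemble(p[0], s[0])

    def _assemble(self, primary: float, secondary: float) -> SlidingTransform:
        grids = []
        for region in range(2):
            c = self.coefficients[region]
            disp = c[..., 0] * primary + c[..., 1] * secondary + c[..., 2]
            grids.append(self.grid_template.with_displacements(disp))
        return SlidingTransform(grids, self.source_segmentation)

    def dvf_at(self, time_s: float):
        return compose_sliding_dvf(
            self.transform_at(time_s), self.image_shape, self.pixel_spacing_mm
        )


def _smoothstep(x):
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def generate_ground_truth(
    phantom: PhantomAnatomy,
    trace: BreathingTrace,
    motion_times_s,
    cp_spacing_mm: float = 10.0,
    coeff_spec: CoefficientSpec | None = None,
    seed: int | None = None,
) -> GroundTruth:
    """Build exact linear ground-truth motion for a phantom and trace.

    ``motion_times_s`` must lie within the span of the trace; the control
    grid covers the image with at least one control point of margin on
    every side (enforced by the covering constructor).
    """
    spec = coeff_spec or CoefficientSpec()
    motion_times_s = np.asarray(motion_times_s, float)
    if motion_times_s.min() < trace.times_s[0] - 1e-9:
        raise ConfigurationError("motion times start before the breathing trace")
    shape = phantom.reference_image.shape
    spacing = phantom.pixel_spacing_mm
    if cp_spacing_mm <= 0:
        raise ConfigurationError("control-point spacing must be positive")
    template = ControlPointGrid.covering(shape, spacing, cp_spacing_mm)
    gr, gc = template.grid_shape
    pos = template.point_positions_mm()  # (gr, gc, 2)

    # SI profile: 0 at the lung apex, 1 at the diaphragm and below
    region_rows = np.where(phantom.region_mask.any(axis=1))[0]
    apex_mm = region_rows[0] * spacing[0]
    dia_mm = phantom.diaphragm_seed_point[0] * spacing[0]
    g = _smoothstep((pos[..., 0] - apex_mm) / max(dia_mm - apex_mm, 1e-6))

    # AP profile for the chest wall: emphasise the anterior wall
    body_cols = np.where(phantom.body_mask.any(axis=0))[0]
    post_mm = body_cols[0] * spacing[1]
    ant_mm = body_cols[-1] * spacing[1]
    w = _smoothstep((pos[..., 1] - post_mm) / max(ant_mm - post_mm, 1e-6))

    coeffs = np.zeros((2, gr, gc, 2, 3))
    # region 1: viscera.  Exhale-positive primary moves the diaphragm superior
    # (negative row displacement).
    coeffs[1, ..., 0, 0] = -spec.diaphragm_si_mm * g
    coeffs[1, ..., 1, 0] = -spec.region1_ap_mm * g
    coeffs[1, ..., 0, 1] = -spec.hysteresis_si_mm * g
    coeffs[1, ..., 1, 1] = spec.hysteresis_ap_mm * g
    # region 0: chest wall.  Inhale expands the chest anteriorly.
    coeffs[0, ..., 1, 0] = -spec.chest_wall_ap_mm * w
    coeffs[0, ..., 0, 0] = -spec.chest_wall_si_mm * g
    coeffs[0, ..., 1, 1] = spec.chest_wall_hysteresis_ap_mm * w

    # reference frame: motion time whose primary value is closest to the mean
    p_m, s_m = trace.value_at(motion_times_s)
    ref_idx = int(np.argmin(np.abs(p_m - p_m.mean())))
    # intercepts cancel the displacement at the reference state exactly
    coeffs[..., 2] = -(coeffs[..., 0] * p_m[ref_idx] + coeffs[..., 1] * s_m[ref_idx])

    gt = GroundTruth(
        coefficients=coeffs,
        grid_template=template,
        source_segmentation=phantom.region_mask,
        true_signals=trace,
        motion_times_s=motion_times_s,
        transforms=[],
        reference_index=ref_idx,
        reference_time_s=float(motion_times_s[ref_idx]),
        pixel_spacing_mm=spacing,
        image_shape=shape,
        seed=seed,
    )
    gt.transforms = [gt._assemble(p, s) for p, s in zip(p_m, s_m)]
    return gt
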