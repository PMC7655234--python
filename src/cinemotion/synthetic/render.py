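"""Render interleaved surrogate/motion cine series from ground-truth motion.

Each frame is the phantom reference image resampled through the frame's
ground-truth sliding transform.  The forward DVF (the quantity the rest of
the pipeline consumes) is numerically inverted by fixed-point iteration
and the reference intensities are pulled back through the inverse, then
Gaussian noise is added.  Optionally the first few surrogate frames are
intensity-inflated to emulate frames acquired before the scanner reached
its magnetization steady state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..exceptions import ConfigurationError
from ..grid import compose_sliding_dvf, invert_dvf, warp_image
from ..series import CineSeries
from .phantom import PhantomAnatomy
from .truth import GroundTruth

__all__ = ["AcquisitionConfig", "render_series"]


@dataclass
class AcquisitionConfig:
    """Acquisition emulation parameters.

    Surrogate and motion frames are alternately acquired from two fixed
    slice locations, each at ``frame_rate_hz``; motion frames fall halfway
    between consecutive surrogate frames.  Noise is additive Gaussian with
    SD ``noise_sd_frac`` of the reference dynamic range.
    """

    duration_s: float = 63.5
    frame_rate_hz: float = 1.9
    orientation: str = "sagittal"
    noise_sd_frac: float = 0.02
    pre_steady_state_frames: int = 3
    pre_steady_state_factors: tuple = (1.25, 1.18, 1.12)
    invert_iterations: int = 20
    invert_tol_px: float = 0.01


def render_series(
    phantom: PhantomAnatomy,
    ground_truth: GroundTruth,
    acquisition: AcquisitionConfig | None = None,
    seed: int = 0,
) -> tuple[CineSeries, CineSeries]:
    """Render the surrogate and motion series for one synthetic dataset."""
    cfg = acquisition or AcquisitionConfig()
    if cfg.noise_sd_frac < 0:
        raise ConfigurationError("noise level must be >= 0")
    if cfg.duration_s <= 0 or cfg.frame_rate_hz <= 0:
        raise ConfigurationError("duration and frame rate must be positive")

    dt = 1.0 / cfg.frame_rate_hz
    surr_times = np.arange(0.0, cfg.duration_s, dt)
    motion_times = surr_times + 0.5 * dt
    motion_times = motion_times[motion_times < cfg.duration_s]

    rng = np.random.default_rng(seed)
    ref = phantom.reference_image
    noise_sd = cfg.noise_sd_frac * np.ptp(ref)

    def render_at(t: float) -> np.ndarray:
        transform = ground_truth.transform_at(t)
        dvf = compose_sliding_dvf(transform, ref.shape, phantom.pixel_spacing_mm)
        if np.max(np.abs(dvf.displacements)) < 1e-12:
            return ref.copy()
        inv = invert_dvf(dvf, n_iter=cfg.invert_iterations, tol_px=cfg.invert_tol_px)
        return warp_image(ref, inv, interpolation="linear")

    surr_frames = np.stack([render_at(t) for t in surr_times])
    motion_frames = np.stack([render_at(t) for t in motion_times])

    n_pre = min(cfg.pre_steady_state_frames, len(surr_frames))
    for i in range(n_pre):
        factor = (
            cfg.pre_steady_state_factors[i]
            if i < len(cfg.pre_steady_state_factors)
            else cfg.pre_steady_state_factors[-1]
        )
        surr_frames[i] *= factor

    if noise_sd > 0:
        surr_frames += rng.normal(0.0, noise_sd, surr_frames.shape)
        motion_frames += rng.normal(0.0, noise_sd, motion_frames.shape)

    surrogate = CineSeries(
        surr_frames, surr_times, phantom.pixel_spacing_mm, "sagittal", "surrogate"
    )
    motion = CineSeries(
        motion_frames, motion_times, phantom.pixel_spacing_mm, cfg.orientation, "motion"
    )
    return surrogate, motion
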