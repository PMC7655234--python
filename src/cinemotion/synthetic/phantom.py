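"""Analytic 2D thoracic phantom for sagittal/coronal cine-MR emulation.

The phantom provides the anatomy the study needs and nothing more: a body
outline, a dark lung with bright vessels and a tumour, a bright
sub-diaphragmatic abdomen, a chest-wall band that the viscera slide
against, and analytic masks (sliding region, body, tumour, evaluation)
with the seed points used by the local surrogate-signal trackers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion, gaussian_filter
from skimage.morphology import disk

from ..exceptions import ConfigurationError

__all__ = ["PhantomConfig", "PhantomAnatomy", "make_phantom"]


@dataclass
class PhantomConfig:
    """Geometry and intensity parameters of the analytic phantom.

    Defaults give a 128 x 128 sagittal-like slice at 1.98 mm in-plane
    resolution; positions are in pixels of that default and scale with
    ``shape``.
    """

    shape: tuple[int, int] = (128, 128)
    pixel_spacing_mm: float = 1.98
    body_center: tuple[float, float] = (64.0, 58.0)
    body_semiaxes: tuple[float, float] = (60.0, 48.0)
    wall_thickness_px: int = 7
    lung_center: tuple[float, float] = (42.0, 55.0)
    lung_semiaxes: tuple[float, float] = (28.0, 32.0)
    diaphragm_row: float = 72.0
    tumour_center: tuple[float, float] = (55.0, 42.0)
    tumour_radius_px: float = 8.0
    vessel_centers: tuple = ((32.0, 48.0), (40.0, 68.0), (52.0, 60.0))
    vessel_radius_px: float = 3.0
    evaluation_margin_px: int = 2
    edge_smoothing_px: float = 0.8
    # smooth multiplicative-free tissue texture inside the body; MR soft
    # tissue is textured well above the noise floor, which is what makes
    # intensity-based registration well-posed away from organ boundaries
    texture_amplitude: float = 0.08  # fraction of the intensity range
    texture_sigma_px: float = 1.5
    texture_seed: int = 7
    intensities: dict = field(
        default_factory=lambda: {
            "soft_tissue": 0.55,
            "chest_wall": 0.60,
            "lung": 0.08,
            "abdomen": 0.85,
            "vessel": 0.70,
            "tumour": 0.90,
        }
    )


@dataclass
class PhantomAnatomy:
    """Reference image, masks and tracker seed points of the phantom."""

    reference_image: np.ndarray
    pixel_spacing_mm: np.ndarray
    region_mask: np.ndarray  # 1 = lung/mediastinum/abdomen sliding compartment
    body_mask: np.ndarray
    tumour_mask: np.ndarray
    evaluation_mask: np.ndarray
    diaphragm_seed_point: tuple[int, int]
    skin_seed_point: tuple[int, int]

    def __post_init__(self) -> None:
        shape = self.reference_image.shape
        for name in ("region_mask", "body_mask", "tumour_mask", "evaluation_mask"):
            m = getattr(self, name)
            if m.shape != shape:
                raise ConfigurationError(f"{name} shape {m.shape} != image shape {shape}")
        if np.any(self.tumour_mask & ~self.region_mask):
            raise ConfigurationError("tumour_mask must be inside region_mask")
        if np.any(self.region_mask & ~self.body_mask):
            raise ConfigurationError("region_mask must be inside body_mask")
        if np.any(self.evaluation_mask & ~self.body_mask):
            raise ConfigurationError("evaluation_mask must be inside body_mask")


def _ellipse(shape, center, semiaxes):
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return ((rr - center[0]) / semiaxes[0]) ** 2 + ((cc - center[1]) / semiaxes[1]) ** 2 <= 1.0


def _disk_mask(shape, center, radius):
    if radius <= 0:
        return np.zeros(shape, bool)
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def make_phantom(config: PhantomConfig | None = None) -> PhantomAnatomy:
    """Build the analytic phantom anatomy from a configuration."""
    cfg = config or PhantomConfig()
    if cfg.shape[0] < 64 or cfg.shape[1] < 64:
        raise ConfigurationError(f"image shape must be >= 64x64, got {cfg.shape}")
    if cfg.pixel_spacing_mm <= 0:
        raise ConfigurationError("pixel spacing must be positive")
    if cfg.tumour_radius_px < 0:
        raise ConfigurationError("tumour radius must be >= 0")

    # scale default pixel geometry to the requested shape
    s = np.array(cfg.shape, float) / 128.0

    def sc(pt):
        return (pt[0] * s[0], pt[1] * s[1])

    shape = cfg.shape
    body = _ellipse(shape, sc(cfg.body_center), (cfg.body_semiaxes[0] * s[0], cfg.body_semiaxes[1] * s[1]))
    wall_px = max(1, int(round(cfg.wall_thickness_px * s.mean())))
    region = binary_erosion(body, disk(wall_px))
    dia_row = cfg.diaphragm_row * s[0]
    lung = _ellipse(
        shape, sc(cfg.lung_center), (cfg.lung_semiaxes[0] * s[0], cfg.lung_semiaxes[1] * s[1])
    )
    rr = np.arange(shape[0])[:, None]
    lung &= rr < dia_row
    lung &= region
    tumour = _disk_mask(shape, sc(cfg.tumour_center), cfg.tumour_radius_px * s.mean()) & lung
    vessels = np.zeros(shape, bool)
    for vc in cfg.vessel_centers:
        vessels |= _disk_mask(shape, sc(vc), cfg.vessel_radius_px * s.mean())
    vessels &= lung & ~tumour

    ints = cfg.intensities
    img = np.zeros(shape, float)
    img[body] = ints["soft_tissue"]
    img[body & ~region] = ints["chest_wall"]
    abdomen = region & (rr >= dia_row)
    img[abdomen] = ints["abdomen"]
    img[lung] = ints["lung"]
    img[vessels] = ints["vessel"]
    img[tumour] = ints["tumour"]
    if cfg.edge_smoothing_px > 0:
        img = gaussian_filter(img, cfg.edge_smoothing_px)
    if cfg.texture_amplitude > 0:
        tex = np.random.default_rng(cfg.texture_seed).normal(size=shape)
        tex = gaussian_filter(tex, cfg.texture_sigma_px)
        img = img + cfg.texture_amplitude * np.ptp(img) * (tex / tex.std()) * body

    evaluation = binary_erosion(body, disk(max(1, cfg.evaluation_margin_px)))

    # diaphragm seed: on the lung/abdomen SI edge, away from the tumour
    dia_col = int(round(cfg.lung_center[1] * s[1] + 8 * s[1]))
    dia_seed = (int(round(dia_row)), dia_col)
    # skin seed: on the anterior body/background AP edge
    skin_row = int(round(cfg.body_center[0] * s[0]))
    body_cols = np.where(body[skin_row])[0]
    skin_seed = (skin_row, int(body_cols[-1]))

    return PhantomAnatomy(
        reference_image=img,
        pixel_spacing_mm=np.array([cfg.pixel_spacing_mm, cfg.pixel_spacing_mm]),
        region_mask=region,
        body_mask=body,
        tumour_mask=tumour,
        evaluation_mask=evaluation,
        diaphragm_seed_point=dia_seed,
        skin_seed_point=skin_seed,
    )
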