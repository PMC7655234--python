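"""In-memory container for a timed 2D cine-MR image series."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CineSeries"]


@dataclass
class CineSeries:
    """Timed sequence of 2D frames acquired at one fixed slice location.

    ``role`` distinguishes the surrogate slice (used to derive surrogate
    signals) from the motion slice (whose anatomy the model estimates);
    ``orientation`` is ``"sagittal"`` or ``"coronal"``.
    """

    frames: np.ndarray  # (n_frames, rows, cols)
    times_s: np.ndarray
    pixel_spacing_mm: np.ndarray
    orientation: str = "sagittal"
    role: str = "surrogate"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.pixel_spacing_mm = np.broadcast_to(
            np.asarray(self.pixel_spacing_mm, float), (2,)
        ).copy()
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (n, rows, cols), got {self.frames.shape}")
        if len(self.times_s) != len(self.frames):
            raise ValueError("one timestamp per frame is required")
        if len(self.times_s) > 1 and np.any(np.diff(self.times_s) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if self.orientation not in ("sagittal", "coronal"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.role not in ("surrogate", "motion"):
            raise ValueError(f"unknown role {self.role!r}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def subset(self, indices) -> "CineSeries":
        indices = np.asarray(indices)
        return CineSeries(
            self.frames[indices],
            self.times_s[indices],
            self.pixel_spacing_mm,
            self.orientation,
            self.role,
        )

    def mean_intensities(self) -> np.ndarray:
        return self.frames.mean(axis=(1, 2))
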