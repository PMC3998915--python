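"""In-memory container for an embryo time-lapse.

A movie is a sequence of timepoints, each a z-stack of grayscale
frames acquired at different focal depths.  Pixel data live in a
single ``(T, Z, H, W)`` float array; intensities are normalized gray
levels in [0, 1].  Optional ground truth (known event frames and the
true sharpest plane per timepoint) travels with the stack so synthetic
movies can be scored end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["MovieStack"]


@dataclass
class MovieStack:
    """Time-lapse z-stack with frame-interval metadata.

    Attributes
    ----------
    frames :
        Array of shape (timepoints, z_planes, height, width), float.
    frame_interval_min :
        Minutes between consecutive timepoints.
    embryo_id :
        Identifier carried through to event-call tables.
    truth :
        Optional ground truth: keys ``"event_frames"`` (event name ->
        0-based frame index) and ``"sharp_plane"`` (list of true
        sharpest plane per timepoint).  Empty dict when unknown.
    """

    frames: np.ndarray
    frame_interval_min: float = 1.0
    embryo_id: str = "embryo"
    truth: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4:
            raise ValueError(
                f"frames must be (T, Z, H, W), got shape {self.frames.shape}")
        if self.frame_interval_min <= 0:
            raise ValueError("frame interval must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.frames.shape[0]

    @property
    def n_planes(self) -> int:
        return self.frames.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of each frame."""
        return self.frames.shape[2], self.frames.shape[3]

    def zstack(self, t: int) -> np.ndarray:
        """The (Z, H, W) stack at timepoint ``t``."""
        return self.frames[t]

    def time_min(self, frame: int | np.ndarray):
        """Convert a frame index to minutes from movie start."""
        return frame * self.frame_interval_min
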