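"""Autofocus: pick the sharpest plane of each z-stack.

Ambient temperature and humidity drift shift the focal plane through
the mounting oil over a multi-hour time-lapse, so each timepoint is
acquired as a z-stack and the most in-focus plane selected afterwards.
The sharpness score is the classical autocorrelation focus measure
(Vollath's F4): on a mean-centered image I,

    F4 = sum_xy I(x, y) I(x+1, y)  -  sum_xy I(x, y) I(x+2, y)

Blur correlates neighbouring pixels at lag 1 and lag 2 almost equally,
so their difference shrinks as the image defocuses; a sharp image
keeps strong lag-1 structure and scores high.  The measure is
parameter-free and invariant to adding a constant offset to all
pixels.  By default only the row (x) direction is correlated, as in
the classical definition; ``symmetric=True`` averages row and column
passes for images with strongly oriented texture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FocusTrace", "focus_measure", "select_focal_plane"]


@dataclass(frozen=True)
class FocusTrace:
    """Per-plane sharpness scores and the selected plane."""

    scores: tuple[float, ...]
    selected: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite focus scores")
        if self.scores[self.selected] != max(self.scores):
            raise ValueError("selected plane does not attain maximal score")


def focus_measure(image: np.ndarray, symmetric: bool = False) -> float:
    """Autocorrelation sharpness score of a 2-D grayscale image.

    Higher is sharper.  A constant image scores exactly 0.

    Raises
    ------
    ValueError
        If the image has fewer than 3 columns (or rows when
        ``symmetric``), so the lag-2 term is undefined.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    if img.shape[1] < 3:
        raise ValueError("image must be at least 3 pixels wide")
    c = img - img.mean()

    def _f4(a: np.ndarray) -> float:
        lag1 = float(np.sum(a[:, :-1] * a[:, 1:]))
        lag2 = float(np.sum(a[:, :-2] * a[:, 2:]))
        return lag1 - lag2

    if not symmetric:
        return _f4(c)
    if img.shape[0] < 3:
        raise ValueError("image must be at least 3 pixels tall "
                         "for the symmetric measure")
    return 0.5 * (_f4(c) + _f4(c.T))


def score_stack(zstack, symmetric: bool = False) -> FocusTrace:
    """Score every plane of a z-stack and select the sharpest.

    Ties break toward the lower plane index.
    """
    planes = list(zstack)
    if len(planes) == 0:
        raise ValueError("empty z-stack")
    scores = tuple(focus_measure(p, symmetric=symmetric) for p in planes)
    selected = int(np.argmax(scores))  # argmax returns the first maximum
    return FocusTrace(scores=scores, selected=selected)


def select_focal_plane(zstack, symmetric: bool = False) -> int:
    """Index of the sharpest plane in a z-stack (0-based)."""
    return score_stack(zstack, symmetric=symmetric).selected


def best_planes(movie, symmetric: bool = False):
    """Select the sharpest plane at every timepoint of a movie.

    Returns
    -------
    (frames, indices) :
        ``frames`` — array (T, H, W) of the selected planes;
        ``indices`` — the selected plane index per timepoint.
    """
    idx = np.array([select_focal_plane(movie.zstack(t), symmetric=symmetric)
                    for t in range(movie.n_timepoints)])
    frames = movie.frames[np.arange(movie.n_timepoints), idx]
    return frames, idx
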