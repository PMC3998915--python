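"""Stage embryos by correlation to composite reference images.

The semi-automated event caller works in four steps.  Frames are first
normalized (embryo segmented, major axis rotated horizontal,
orientation resolved, intensities rescaled) so that images from
different embryos share one geometry.  Many same-stage frames are then
averaged into a composite reference image per event; a bank of such
composites built from one well-annotated species is reused for all
species for consistency.  Each movie frame is Pearson-correlated
against each composite, the running correlation trace is smoothed with
a Savitzky-Golay filter, and the event is called at the largest local
maximum inside an expected time window anchored on two manually
provided landmarks (cellularization end and trachea fill).  Automatic
calls are finally overridden from a corrections table standing in for
interactive review — single bad frames can badly mislead the
correlation, so a human pass remains part of the design.

Missing correlation scores (zero-variance frames) propagate as NaN
rather than zeros so that a few bad frames cannot fabricate peaks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy.signal import savgol_filter
from skimage import exposure, measure, transform

from .catalog import ANCHOR_END, ANCHOR_START, DEFAULT_CATALOG, EventCatalog
from .synthdata import EventProportions

__all__ = [
    "ReferenceBank",
    "EventCall",
    "EventCalls",
    "normalize_frame",
    "build_composite",
    "score_series",
    "smooth_trace",
    "call_event",
    "call_all_events",
    "apply_corrections",
]

#: Savitzky-Golay defaults: 9-frame window, quadratic — wide enough to
#: span short noise bursts at 1-5 min sampling without flattening
#: stage transitions.
DEFAULT_SMOOTH_WINDOW = 9
DEFAULT_SMOOTH_ORDER = 2
#: Default search-window half-width as a fraction of the anchor span.
DEFAULT_WINDOW_TOL = 0.10


# ---------------------------------------------------------------------------
# frame normalization
# ---------------------------------------------------------------------------

def _largest_region(mask: np.ndarray):
    labels = measure.label(mask)
    if labels.max() == 0:
        return None
    regions = measure.regionprops(labels)
    return max(regions, key=lambda r: r.area)


#: Canonical raster all normalized frames and composites share.
DEFAULT_FRAME_SHAPE = (64, 96)


def normalize_frame(image: np.ndarray, flip_lr: bool | None = None,
                    flip_ud: bool | None = None,
                    out_shape: tuple[int, int] = DEFAULT_FRAME_SHAPE
                    ) -> np.ndarray:
    """Orient and intensity-normalize an embryo frame.

    The embryo is segmented by Otsu thresholding (largest foreground
    component), its major axis rotated horizontal, and the frame
    cropped to the embryo's padded bounding box and resampled onto the
    canonical ``out_shape`` raster.  Left-right / up-down orientation
    is resolved from the ``flip_*`` metadata flags when given, else by
    an asymmetry heuristic: the embryo half with lower mean intensity
    goes to the left (anterior) and, independently, to the top
    (dorsal).  Intensities are finally rescaled linearly so the
    1st-99th percentile range (within the embryo) maps to [0, 1].

    Raises
    ------
    ValueError
        If no foreground object is found (e.g. a constant image); the
        caller should skip such frames.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 3:
        raise ValueError("expected a non-degenerate 2-D image")
    if np.ptp(img) == 0:
        raise ValueError("no foreground object found (constant image)")
    from skimage.filters import threshold_otsu
    mask = img > threshold_otsu(img)
    region = _largest_region(mask)
    if region is None or region.area < 9:
        raise ValueError("no foreground object found")

    # regionprops orientation: angle between the row axis and the major
    # axis; rotating by (90 - orientation_deg) puts the major axis
    # along the columns.
    angle = 90.0 - math.degrees(region.orientation)
    # shortest equivalent rotation, so near-horizontal frames stay put
    angle = (angle + 90.0) % 180.0 - 90.0
    center = region.centroid[::-1]
    rotated = transform.rotate(img, angle, center=center,
                               preserve_range=True, mode="edge")
    rot_mask = transform.rotate(mask.astype(float), angle, center=center,
                                preserve_range=True, mode="constant") > 0.5
    region = _largest_region(rot_mask)
    if region is None:
        raise ValueError("embryo lost during rotation")

    r0, c0, r1, c1 = region.bbox
    pad_r = max(2, int(0.05 * (r1 - r0)))
    pad_c = max(2, int(0.05 * (c1 - c0)))
    r0, c0 = max(0, r0 - pad_r), max(0, c0 - pad_c)
    r1 = min(rotated.shape[0], r1 + pad_r)
    c1 = min(rotated.shape[1], c1 + pad_c)
    crop = rotated[r0:r1, c0:c1]
    frame = transform.resize(crop, out_shape, preserve_range=True,
                             anti_aliasing=True)

    h, w = frame.shape
    if flip_lr is None:
        flip_lr = frame[:, w // 2:].mean() < frame[:, :w - w // 2].mean()
    if flip_lr:
        frame = frame[:, ::-1]
    if flip_ud is None:
        flip_ud = frame[h // 2:, :].mean() < frame[:h - h // 2, :].mean()
    if flip_ud:
        frame = frame[::-1, :]

    p1, p99 = np.percentile(frame, (1, 99))
    if p99 <= p1:
        raise ValueError("degenerate intensity range")
    return exposure.rescale_intensity(frame, in_range=(p1, p99),
                                      out_range=(0.0, 1.0))


# ---------------------------------------------------------------------------
# composite references
# ---------------------------------------------------------------------------

def build_composite(frames: Sequence[np.ndarray]) -> np.ndarray:
    """Pixel-wise mean of same-stage normalized frames."""
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    shapes = {np.asarray(f).shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"mixed frame geometries: {sorted(shapes)}")
    return np.mean([np.asarray(f, dtype=float) for f in frames], axis=0)


@dataclass
class ReferenceBank:
    """Composite reference image per event, on one raster geometry.

    ``provenance`` records how many source frames went into each
    composite; ``orientation`` tags the view (lateral or dorsal).
    """

    composites: dict[str, np.ndarray]
    orientation: str = "lateral"
    provenance: dict[str, int] = field(default_factory=dict)
    catalog: EventCatalog = field(default=DEFAULT_CATALOG)

    def __post_init__(self) -> None:
        self.catalog.validate_names(self.composites)
        shapes = {v.shape for v in self.composites.values()}
        if len(shapes) > 1:
            raise ValueError(f"composites differ in geometry: {sorted(shapes)}")

    @property
    def events(self) -> list[str]:
        return sorted(self.composites, key=self.catalog.index.__getitem__)

    @classmethod
    def from_frames(cls, frames_by_event: Mapping[str, Sequence[np.ndarray]],
                    orientation: str = "lateral",
                    catalog: EventCatalog = DEFAULT_CATALOG) -> "ReferenceBank":
        composites = {e: build_composite(fs)
                      for e, fs in frames_by_event.items()}
        prov = {e: len(fs) for e, fs in frames_by_event.items()}
        return cls(composites=composites, orientation=orientation,
                   provenance=prov, catalog=catalog)

    def save(self, directory: str | Path) -> None:
        """Write one TIFF per composite plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {"orientation": self.orientation, "events": {}}
        for event, img in self.composites.items():
            fname = f"{event}.tif"
            tifffile.imwrite(directory / fname, img.astype(np.float32))
            manifest["events"][event] = {
                "file": fname,
                "n_sources": int(self.provenance.get(event, 0)),
            }
        (directory / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))

    @classmethod
    def load(cls, directory: str | Path,
             catalog: EventCatalog = DEFAULT_CATALOG) -> "ReferenceBank":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        composites, prov = {}, {}
        for event, meta in manifest["events"].items():
            composites[event] = tifffile.imread(directory / meta["file"])
            prov[event] = meta.get("n_sources", 0)
        return cls(composites=composites,
                   orientation=manifest.get("orientation", "lateral"),
                   provenance=prov, catalog=catalog)


# ---------------------------------------------------------------------------
# correlation traces
# ---------------------------------------------------------------------------

def score_series(frames: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Pearson correlation of each frame with a composite reference.

    ``frames`` is (T, H, W), already normalized to the reference
    geometry.  Zero-variance frames score NaN (missing), never an
    arbitrary number.
    """
    f = np.asarray(frames, dtype=float)
    r = np.asarray(reference, dtype=float)
    if f.ndim != 3 or f.shape[1:] != r.shape:
        raise ValueError("frames must be (T, H, W) matching the reference")
    fv = f.reshape(f.shape[0], -1)
    rv = r.ravel()
    rc = rv - rv.mean()
    r_norm = float(np.sqrt(rc @ rc))
    if r_norm == 0:
        raise ValueError("reference image has zero variance")
    fc = fv - fv.mean(axis=1, keepdims=True)
    f_norm = np.sqrt((fc * fc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        trace = (fc @ rc) / (f_norm * r_norm)
    trace[f_norm == 0] = np.nan
    return np.clip(trace, -1.0, 1.0, out=trace)


def smooth_trace(trace: np.ndarray, window: int = DEFAULT_SMOOTH_WINDOW,
                 order: int = DEFAULT_SMOOTH_ORDER) -> np.ndarray:
    """Savitzky-Golay smooth a correlation trace, preserving NaN gaps.

    Missing values are linearly interpolated before filtering and
    re-flagged as NaN afterwards.  ``window=1`` is the identity.
    """
    t = np.asarray(trace, dtype=float).copy()
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window == 1:  # identity; the polynomial order is irrelevant
        return t
    if order >= window:
        raise ValueError("polynomial order must be < window")
    if t.size < window:
        raise ValueError("trace shorter than the smoothing window")
    missing = np.isnan(t)
    if missing.all():
        return t
    if missing.any():
        idx = np.arange(t.size)
        t[missing] = np.interp(idx[missing], idx[~missing], t[~missing])
    out = savgol_filter(t, window_length=window, polyorder=order)
    out[missing] = np.nan
    return out


def call_event(trace: np.ndarray, window: tuple[int, int]) -> int | None:
    """Frame of the largest local maximum of a trace inside a window.

    A local maximum is an interior frame whose value is >= both
    neighbours.  If the window contains no interior local maximum
    (e.g. the trace is monotone across it), the window argmax is
    returned.  Ties break toward the earliest frame; an all-missing
    window returns ``None`` (uncallable).
    """
    t = np.asarray(trace, dtype=float)
    lo, hi = int(window[0]), int(window[1])
    if not (0 <= lo <= hi < t.size):
        raise ValueError(f"window [{lo}, {hi}] outside trace of {t.size}")
    seg = t[lo:hi + 1]
    if np.isnan(seg).all():
        return None
    cand_lo, cand_hi = max(lo, 1), min(hi, t.size - 2)
    best, best_val = None, -np.inf
    for i in range(cand_lo, cand_hi + 1):
        v = t[i]
        if np.isnan(v):
            continue
        left, right = t[i - 1], t[i + 1]
        if (np.isnan(left) or v >= left) and (np.isnan(right) or v >= right):
            if v > best_val:
                best, best_val = i, v
    if best is not None:
        return best
    return lo + int(np.nanargmax(seg))


# ---------------------------------------------------------------------------
# per-movie calling
# ---------------------------------------------------------------------------

@dataclass
class EventCall:
    frame: int
    source: str  # "auto" | "corrected" | "anchor"
    peak_r: float = float("nan")


@dataclass
class EventCalls:
    """Called event frames for one embryo movie."""

    embryo_id: str
    calls: dict[str, EventCall]
    frame_interval_min: float = 1.0
    uncallable: list[str] = field(default_factory=list)
    catalog: EventCatalog = field(default=DEFAULT_CATALOG)

    def frame(self, event: str) -> int:
        return self.calls[event].frame

    def to_frame_table(self) -> pd.DataFrame:
        rows = [{
            "embryo_id": self.embryo_id,
            "event": e,
            "frame": c.frame,
            "time_min": c.frame * self.frame_interval_min,
            "source": c.source,
            "peak_r": c.peak_r,
        } for e, c in sorted(self.calls.items(),
                             key=lambda kv: self.catalog.order(kv[0]))]
        return pd.DataFrame(rows)


def call_all_events(
    frames: np.ndarray,
    bank: ReferenceBank,
    anchors: tuple[int, int],
    props: EventProportions,
    tol: float = DEFAULT_WINDOW_TOL,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    smooth_order: int = DEFAULT_SMOOTH_ORDER,
    embryo_id: str = "embryo",
    frame_interval_min: float = 1.0,
) -> EventCalls:
    """Call every bank event in one movie from its correlation traces.

    ``anchors`` are the manually determined frames of cellularization
    end and trachea fill.  For each other event the expected frame is
    ``anchor_lo + p_e * span`` and the search window extends
    ``tol * span`` either side, clipped to the movie; the event is
    then called on the smoothed correlation trace against its
    composite.  Events whose window clips to nothing, or whose trace
    is entirely missing there, are flagged uncallable.
    """
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[0]
    a_lo, a_hi = int(anchors[0]), int(anchors[1])
    if not (0 <= a_lo < a_hi < n):
        raise ValueError(f"invalid anchor frames ({a_lo}, {a_hi}) "
                         f"for a {n}-frame movie")
    span = a_hi - a_lo
    calls: dict[str, EventCall] = {
        ANCHOR_START: EventCall(frame=a_lo, source="anchor"),
        ANCHOR_END: EventCall(frame=a_hi, source="anchor"),
    }
    uncallable: list[str] = []
    for event in bank.events:
        if event in (ANCHOR_START, ANCHOR_END) or event not in props:
            continue
        expected = a_lo + props[event] * span
        half = tol * span
        lo = max(0, int(math.floor(expected - half)))
        hi = min(n - 1, int(math.ceil(expected + half)))
        if hi < lo:
            uncallable.append(event)
            continue
        trace = score_series(frames, bank.composites[event])
        smoothed = smooth_trace(trace, smooth_window, smooth_order) \
            if n >= smooth_window else trace
        frame = call_event(smoothed, (lo, hi))
        if frame is None:
            uncallable.append(event)
            continue
        calls[event] = EventCall(frame=frame, source="auto",
                                 peak_r=float(smoothed[frame]))
    return EventCalls(embryo_id=embryo_id, calls=calls,
                      frame_interval_min=frame_interval_min,
                      uncallable=uncallable, catalog=bank.catalog)


def apply_corrections(calls: EventCalls,
                      corrections: pd.DataFrame) -> EventCalls:
    """Override automatic calls from a review table.

    ``corrections`` has columns embryo_id, event, frame; only rows
    matching ``calls.embryo_id`` apply.  A correction that breaks
    developmental order against the neighbouring called events is
    rejected, naming the offending pair.
    """
    required = {"embryo_id", "event", "frame"}
    if not required.issubset(corrections.columns):
        missing = sorted(required - set(corrections.columns))
        raise ValueError(f"corrections table missing columns: {missing}")
    new_calls = {e: EventCall(c.frame, c.source, c.peak_r)
                 for e, c in calls.calls.items()}
    mine = corrections[corrections["embryo_id"] == calls.embryo_id]
    corrected: list[str] = []
    for _, row in mine.iterrows():
        event = row["event"]
        if event not in new_calls:
            raise ValueError(f"correction for uncalled event {event!r}")
        new_calls[event] = EventCall(frame=int(row["frame"]),
                                     source="corrected")
        corrected.append(event)
    # re-validate developmental order around every corrected event
    ordered = sorted(new_calls, key=calls.catalog.order)
    for e1, e2 in zip(ordered, ordered[1:]):
        if e1 in corrected or e2 in corrected:
            if new_calls[e2].frame <= new_calls[e1].frame:
                raise ValueError(
                    f"correction violates catalog order: {e2!r} at frame "
                    f"{new_calls[e2].frame} not after {e1!r} at frame "
                    f"{new_calls[e1].frame}")
    return EventCalls(embryo_id=calls.embryo_id, calls=new_calls,
                      frame_interval_min=calls.frame_interval_min,
                      uncallable=list(calls.uncallable),
                      catalog=calls.catalog)
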