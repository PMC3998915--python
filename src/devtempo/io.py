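"""Readers, writers and run configuration.

On-disk conventions:

* movies — one multi-page TIFF per timepoint (``t0000.tif`` ... with
  one page per z-plane) plus a ``movie.json`` sidecar carrying the
  frame interval, embryo id and, for synthetic movies, ground truth;
* event tables — long CSV with columns embryo_id, species,
  temperature_C, event, time_min (minutes from movie start; summaries
  report hours);
* run configuration — one YAML file round-tripping ``RunConfig``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .catalog import DEFAULT_CATALOG, EventCatalog
from .movie import MovieStack

__all__ = [
    "RunConfig",
    "write_movie",
    "read_movie",
    "write_event_table",
    "read_event_table",
    "read_corrections",
]

EVENT_TABLE_COLUMNS = ["embryo_id", "species", "temperature_C", "event",
                       "time_min"]

MINUTES_PER_HOUR = 60.0


def minutes_to_hours(m):
    return np.asarray(m, dtype=float) / MINUTES_PER_HOUR


# ---------------------------------------------------------------------------
# movies
# ---------------------------------------------------------------------------

def write_movie(movie: MovieStack, directory: str | Path) -> None:
    """Write one multi-page TIFF per timepoint plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for t in range(movie.n_timepoints):
        tifffile.imwrite(directory / f"t{t:04d}.tif",
                         movie.frames[t].astype(np.float32),
                         photometric="minisblack")
    sidecar = {
        "embryo_id": movie.embryo_id,
        "frame_interval_min": movie.frame_interval_min,
        "truth": movie.truth,
    }
    (directory / "movie.json").write_text(json.dumps(sidecar, indent=2))


def read_movie(directory: str | Path) -> MovieStack:
    """Load a movie directory written by :func:`write_movie`.

    The sidecar is optional (a real acquisition has no truth); a
    missing or unreadable page raises an error naming the timepoint,
    and inconsistent stack geometry across timepoints is rejected.
    """
    directory = Path(directory)
    paths = sorted(directory.glob("t[0-9][0-9][0-9][0-9].tif"))
    if not paths:
        raise FileNotFoundError(f"no timepoint TIFFs in {directory}")
    stacks = []
    shape = None
    for path in paths:
        m = re.match(r"t(\d{4})\.tif", path.name)
        t = int(m.group(1))
        try:
            stack = tifffile.imread(path)
        except Exception as exc:
            raise ValueError(f"corrupt page at timepoint {t}: {exc}") from exc
        if stack.ndim == 2:
            stack = stack[None]
        if shape is None:
            shape = stack.shape
        elif stack.shape != shape:
            raise ValueError(
                f"timepoint {t} geometry {stack.shape} inconsistent "
                f"with {shape}")
        stacks.append(stack)
    frames = np.stack(stacks)
    sidecar_path = directory / "movie.json"
    interval, embryo_id, truth = 1.0, directory.name, {}
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        interval = float(sidecar.get("frame_interval_min", 1.0))
        embryo_id = sidecar.get("embryo_id", embryo_id)
        truth = sidecar.get("truth") or {}
    return MovieStack(frames=frames, frame_interval_min=interval,
                      embryo_id=embryo_id, truth=truth)


# ---------------------------------------------------------------------------
# event tables
# ---------------------------------------------------------------------------

def write_event_table(table: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in EVENT_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    table[EVENT_TABLE_COLUMNS].to_csv(path, index=False)


def read_event_table(path: str | Path,
                     catalog: EventCatalog = DEFAULT_CATALOG) -> pd.DataFrame:
    """Read and validate a long event-time CSV.

    Rejects missing columns, non-numeric times, event names absent
    from the catalog, and duplicated (embryo, event) records.
    """
    table = pd.read_csv(path)
    missing = [c for c in EVENT_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    times = pd.to_numeric(table["time_min"], errors="coerce")
    if times.isna().any():
        bad = table.loc[times.isna()].index[0]
        raise ValueError(f"non-numeric time_min at row {bad}")
    table["time_min"] = times
    catalog.validate_names(table["event"].unique())
    dup = table.duplicated(subset=["embryo_id", "event"])
    if dup.any():
        r = table.loc[dup.idxmax()]
        raise ValueError(f"duplicated record for embryo "
                         f"{r['embryo_id']!r}, event {r['event']!r}")
    return table


def read_corrections(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    required = ["embryo_id", "event", "frame"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"corrections table missing columns: {missing}")
    return table


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline configuration, YAML round-trippable.

    Numeric parameters are validated against their documented bounds
    at construction time.
    """

    catalog_profile: str = "full"         # "full" | "primary"
    reference_bank: str | None = None
    smooth_window: int = 9
    smooth_order: int = 2
    window_tol: float = 0.10
    outlier_k: float = 5.0
    alpha: float = 0.05
    thermal_form: str = "inverse_kelvin"
    fit_range: tuple[float, float] = (17.5, 27.5)
    seed: int = 0
    output_dir: str = "out"

    def __post_init__(self) -> None:
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be a positive odd integer")
        if not 0 <= self.smooth_order < self.smooth_window:
            raise ValueError("smooth_order must be in [0, smooth_window)")
        if not 0 < self.window_tol <= 0.5:
            raise ValueError("window_tol must be in (0, 0.5]")
        if self.outlier_k <= 0:
            raise ValueError("outlier_k must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.thermal_form not in ("inverse_kelvin", "linear_celsius"):
            raise ValueError(f"unknown thermal form {self.thermal_form!r}")
        if self.fit_range[0] >= self.fit_range[1]:
            raise ValueError("fit_range must be increasing")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["fit_range"] = list(self.fit_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "fit_range" in d:
            d["fit_range"] = tuple(d["fit_range"])
        return cls(**d)
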