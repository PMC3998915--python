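"""Ground-truthed synthetic inputs for the chronometry pipeline.

Two generators, both seeded and reproducible:

``simulate_event_table``
    Draws per-embryo event-time tables from the exponential
    temperature-duration law.  Each embryo's anchor-to-anchor duration
    is D = exp(a + b*g(T)) * eps with eps multiplicative lognormal
    noise of unit mean, and each event falls at its fixed proportion
    p_e of that span — i.e. the generator realizes exactly the
    uniform-scaling hypothesis the statistics layer tests.  Optional
    per-event proportion jitter models landmark-calling error on top
    of the embryo-level tempo noise.

``render_movie``
    Renders a toy embryo time-lapse: an ellipsoidal embryo whose
    appearance morphs continuously between stage-specific templates
    (a developmental front sweeping anterior to posterior plus
    stage-keyed blobs), stacked over z-planes blurred in proportion to
    their distance from a drifting true focal plane, with additive
    sensor noise.  Scheduled event frames and the true sharp plane are
    recorded as ground truth.

Per-embryo random streams are split from the master seed with
``numpy.random.SeedSequence`` spawn keys, so enlarging a simulated
cohort never perturbs embryos already drawn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .catalog import ANCHOR_END, ANCHOR_START, DEFAULT_CATALOG, EventCatalog
from .movie import MovieStack
from .thermal import ThermalForm, transform_temperature

__all__ = [
    "ThermalParams",
    "EventProportions",
    "RenderConfig",
    "DEFAULT_PROPORTIONS",
    "PRIMARY_PROPORTIONS",
    "simulate_event_table",
    "simulate_grid",
    "stage_template",
    "render_movie",
]


# ---------------------------------------------------------------------------
# thermal generating model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThermalParams:
    """Generating parameters of the log-linear temperature-duration law.

    ``duration(T) = exp(a + b * g(T))`` hours, with g the covariate
    transform of ``form``.  ``noise_cv`` is the coefficient of
    variation of the multiplicative lognormal per-embryo noise
    (unit-mean), applied to the total duration.
    """

    a: float
    b: float
    form: ThermalForm = "inverse_kelvin"
    noise_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        # the law must predict positive, finite durations over 0-45 C
        for t in (0.0, 45.0):
            if not math.isfinite(self.duration(t)) or self.duration(t) <= 0:
                raise ValueError("model predicts non-positive duration")

    def duration(self, temp_c) -> float | np.ndarray:
        """Noise-free duration in hours at temperature ``temp_c``."""
        g = transform_temperature(temp_c, self.form)
        out = np.exp(self.a + self.b * g)
        return float(out) if np.isscalar(temp_c) else out

    @classmethod
    def from_endpoints(
        cls,
        t1_c: float,
        d1_h: float,
        t2_c: float,
        d2_h: float,
        form: ThermalForm = "inverse_kelvin",
        noise_cv: float = 0.0,
    ) -> "ThermalParams":
        """Solve (a, b) exactly from two (temperature, duration) points."""
        if t1_c == t2_c:
            raise ValueError("endpoints need distinct temperatures")
        if d1_h <= 0 or d2_h <= 0:
            raise ValueError("durations must be positive")
        g1 = float(transform_temperature(t1_c, form))
        g2 = float(transform_temperature(t2_c, form))
        b = (math.log(d1_h) - math.log(d2_h)) / (g1 - g2)
        a = math.log(d1_h) - b * g1
        return cls(a=a, b=b, form=form, noise_cv=noise_cv)


#: D. melanogaster-like defaults: 33 h at 17.5 C, 16 h at 27.5 C.
def melanogaster_like(form: ThermalForm = "inverse_kelvin",
                      noise_cv: float = 0.05) -> ThermalParams:
    return ThermalParams.from_endpoints(17.5, 33.0, 27.5, 16.0,
                                        form=form, noise_cv=noise_cv)


# ---------------------------------------------------------------------------
# event proportions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EventProportions:
    """Fixed event proportions of the cellularization->trachea-fill span.

    ``p_e = 0`` at the cellularization anchor and ``p_e = 1`` at
    trachea fill, by definition; pre-cellularization events carry
    negative proportions.  Proportions must be strictly increasing in
    catalog order.  The shipped default profiles are illustrative
    stand-ins with realistic spacing, not measured values.
    """

    values: Mapping[str, float]
    catalog: EventCatalog = field(default=DEFAULT_CATALOG)

    def __post_init__(self) -> None:
        self.catalog.validate_names(self.values)
        v = dict(self.values)
        if v.get(ANCHOR_START) != 0.0:
            raise ValueError(f"{ANCHOR_START} must have proportion 0")
        if v.get(ANCHOR_END) != 1.0:
            raise ValueError(f"{ANCHOR_END} must have proportion 1")
        ordered = self.ordered_events()
        ps = [v[e] for e in ordered]
        for (e1, p1), (e2, p2) in zip(zip(ordered, ps),
                                      zip(ordered[1:], ps[1:])):
            if p2 <= p1:
                raise ValueError(
                    f"proportions not strictly increasing: {e1}={p1} "
                    f"followed by {e2}={p2}")

    def ordered_events(self) -> list[str]:
        """Event names in developmental order."""
        idx = self.catalog.index
        return sorted(self.values, key=idx.__getitem__)

    def __getitem__(self, event: str) -> float:
        return self.values[event]

    def __contains__(self, event: str) -> bool:
        return event in self.values

    def shifted(self, event: str, delta: float) -> "EventProportions":
        """Copy with one event's proportion shifted by ``delta``."""
        v = dict(self.values)
        if event not in v:
            raise ValueError(f"unknown event {event!r}")
        v[event] = v[event] + delta
        return EventProportions(values=v, catalog=self.catalog)


_FULL_PROPORTIONS: dict[str, float] = {
    "posterior_gap_appears": -0.140,
    "pole_bud_appears": -0.125,
    "nuclei_at_periphery": -0.105,
    "pole_cells_form": -0.090,
    "yolk_contraction": -0.070,
    "cellularization_begins": -0.045,
    ANCHOR_START: 0.0,
    "pole_cells_migrate": 0.020,
    "cephalic_furrow_forms": 0.035,
    "pole_cells_invaginate": 0.050,
    "transversal_fold_formation": 0.065,
    "cephalic_furrow_reclines": 0.080,
    "amnioproctodeal_invagination": 0.095,
    "anterior_midgut_primordial": 0.115,
    "stomodeal_plate_forms": 0.140,
    "stomodeum_invagination": 0.170,
    "clypeolabral_lobe_forms": 0.200,
    "germ_band_maxima": 0.240,
    "clypeolabrum_rotates": 0.290,
    "posterior_gap": 0.330,
    "gnathal_bud_appears": 0.370,
    "germband_retraction_begins": 0.400,
    "amnioserosa_exposed": 0.445,
    "germband_retracted": 0.480,
    "dorsal_divot": 0.510,
    "clypeolabrum_retracts": 0.550,
    "anal_plate_forms": 0.585,
    "midgut_unified": 0.620,
    "heart_shaped_midgut": 0.660,
    "clypeolabrum_even_with_ventral_lobes": 0.710,
    "gnathal_lobes_pinch": 0.760,
    "convoluted_gut": 0.810,
    "head_involution_done": 0.870,
    "muscle_contractions": 0.930,
    ANCHOR_END: 1.0,
}

#: Illustrative full profile: all catalog events except hatch.
DEFAULT_PROPORTIONS = EventProportions(values=_FULL_PROPORTIONS)

#: Profile restricted to the eight primary landmarks.
PRIMARY_PROPORTIONS = EventProportions(values={
    e: _FULL_PROPORTIONS[e] for e in DEFAULT_CATALOG.primary_names
})


# ---------------------------------------------------------------------------
# event-table simulation
# ---------------------------------------------------------------------------

def _lognormal_unit_mean(rng: np.random.Generator, cv: float) -> float:
    """Draw eps ~ lognormal with E[eps] = 1 and CV = cv."""
    if cv == 0:
        return 1.0
    sigma2 = math.log1p(cv * cv)
    mu = -sigma2 / 2.0
    return float(rng.lognormal(mean=mu, sigma=math.sqrt(sigma2)))


def _embryo_rng(seed: int, temp_index: int, embryo_index: int,
                species_index: int = 0) -> np.random.Generator:
    ss = np.random.SeedSequence(
        entropy=seed, spawn_key=(species_index, temp_index, embryo_index))
    return np.random.default_rng(ss)


def simulate_event_table(
    params: ThermalParams,
    props: EventProportions,
    temps_c: Sequence[float],
    n_per_temp: int,
    seed: int,
    species: str = "synthetic",
    prop_noise_sd: float = 0.0,
    pre_roll_min: float = 10.0,
    _species_index: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a long-format event-time table with known truth.

    For each embryo the total anchor span is
    ``D = params.duration(T) * eps`` (eps multiplicative lognormal,
    unit mean, CV ``params.noise_cv``), and each event falls at
    ``t_cell + p_e * D`` minutes from movie start, where ``t_cell`` is
    chosen so the earliest (most negative-proportion) event sits
    ``pre_roll_min`` minutes into the movie.  With
    ``prop_noise_sd > 0``, each non-anchor event's proportion is
    additionally jittered by independent Gaussian noise — modelling
    event-calling error; anchors stay exactly at 0 and 1.

    Returns
    -------
    (table, truth) :
        ``table`` with columns embryo_id, species, temperature_C,
        event, time_min; ``truth`` with one row per embryo giving the
        sampled duration (hours) and the cellularization time.

    Raises
    ------
    ValueError
        If ``n_per_temp < 1`` or temperatures fall outside 0-45 C.
    """
    if n_per_temp < 1:
        raise ValueError("n_per_temp must be >= 1")
    temps = [float(t) for t in temps_c]
    if any(t < 0 or t > 45 for t in temps):
        raise ValueError("temperatures must lie within 0-45 C")
    events = props.ordered_events()
    base_p = np.array([props[e] for e in events])
    anchored = np.array([e in (ANCHOR_START, ANCHOR_END) for e in events])

    rows: list[dict] = []
    truth_rows: list[dict] = []
    for ti, temp in enumerate(temps):
        d0_h = float(params.duration(temp))
        for ei in range(n_per_temp):
            rng = _embryo_rng(seed, ti, ei, _species_index)
            eps = _lognormal_unit_mean(rng, params.noise_cv)
            d_min = d0_h * eps * 60.0
            p = base_p.copy()
            if prop_noise_sd > 0:
                p = p + np.where(anchored, 0.0,
                                 rng.normal(0.0, prop_noise_sd, p.size))
            t_cell = pre_roll_min - min(0.0, base_p.min()) * d_min
            embryo_id = f"{species}_T{temp:g}_e{ei:02d}"
            for ev, pe in zip(events, p):
                rows.append({
                    "embryo_id": embryo_id,
                    "species": species,
                    "temperature_C": temp,
                    "event": ev,
                    "time_min": t_cell + pe * d_min,
                })
            truth_rows.append({
                "embryo_id": embryo_id,
                "species": species,
                "temperature_C": temp,
                "duration_h": d_min / 60.0,
                "t_cell_min": t_cell,
            })
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def simulate_grid(
    params_by_species: Mapping[str, ThermalParams],
    props: EventProportions,
    temps_c: Sequence[float],
    n_per_temp: int,
    seed: int,
    prop_noise_sd: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full species x temperature condition grid.

    Each species uses its own thermal parameters; random streams are
    split per (species, temperature, embryo) so the grid is stable
    under reordering or extension of the species map.
    """
    tables, truths = [], []
    for si, (species, params) in enumerate(params_by_species.items()):
        t, tr = simulate_event_table(
            params, props, temps_c, n_per_temp, seed, species=species,
            prop_noise_sd=prop_noise_sd, _species_index=si)
        tables.append(t)
        truths.append(tr)
    return (pd.concat(tables, ignore_index=True),
            pd.concat(truths, ignore_index=True))


def schedule_from_proportions(
    props: EventProportions,
    anchor_lo: int,
    anchor_hi: int,
    n_frames: int,
    jitter_frames: float = 0.0,
    rng: np.random.Generator | None = None,
) -> dict[str, int]:
    """Place each event at its proportional frame between two anchors.

    With ``jitter_frames > 0`` each non-anchor event is perturbed by
    uniform noise of that half-width (rounded), modelling biological
    spread around the proportional expectation; order is preserved by
    construction as long as the jitter is smaller than half the
    smallest inter-event gap.
    """
    if not 0 <= anchor_lo < anchor_hi < n_frames:
        raise ValueError("anchors must satisfy 0 <= lo < hi < n_frames")
    rng = rng or np.random.default_rng()
    span = anchor_hi - anchor_lo
    schedule: dict[str, int] = {}
    prev = -1
    for event in props.ordered_events():
        f = anchor_lo + props[event] * span
        if jitter_frames > 0 and event not in (ANCHOR_START, ANCHOR_END):
            f += rng.uniform(-jitter_frames, jitter_frames)
        f = int(round(min(max(f, 0), n_frames - 1)))
        f = max(f, prev + 1)  # keep strictly increasing after clipping
        schedule[event] = f
        prev = f
    return schedule


# ---------------------------------------------------------------------------
# movie rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RenderConfig:
    """Parameters of the toy embryo renderer.

    ``drift`` gives the true sharpest z-plane per timepoint; planes at
    offset k from it are blurred with Gaussian sigma
    ``k * blur_increment`` pixels.  ``noise_sigma`` is additive
    Gaussian sensor noise in normalized gray levels (images in [0, 1]).
    """

    shape: tuple[int, int] = (64, 96)
    n_frames: int = 300
    n_planes: int = 3
    blur_increment: float = 1.5
    noise_sigma: float = 0.01
    frame_interval_min: float = 1.0
    drift: tuple[int, ...] | None = None
    appearance_seed: int = 20140101

    def __post_init__(self) -> None:
        if self.n_planes < 1 or self.n_frames < 2:
            raise ValueError("need >= 1 plane and >= 2 frames")
        if self.blur_increment < 0 or self.noise_sigma < 0:
            raise ValueError("blur increment and noise sigma must be >= 0")

    def drift_schedule(self) -> np.ndarray:
        """True sharp plane index per timepoint.

        Defaults to a slow triangular sweep across the stack,
        mimicking focal drift through the mounting oil.
        """
        if self.drift is not None:
            sched = np.asarray(self.drift, dtype=int)
            if sched.size != self.n_frames:
                raise ValueError("drift schedule length != n_frames")
            if sched.min() < 0 or sched.max() >= self.n_planes:
                raise ValueError("drift indices out of range")
            return sched
        if self.n_planes == 1:
            return np.zeros(self.n_frames, dtype=int)
        period = 2 * (self.n_planes - 1)
        saw = np.arange(self.n_frames) // 25 % period
        return np.where(saw < self.n_planes, saw, period - saw).astype(int)


def _ellipse_mask(shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ry, rx = 0.33 * h, 0.42 * w
    return ((yy - cy) ** 2 / ry ** 2 + (xx - cx) ** 2 / rx ** 2) <= 1.0


def stage_template(
    event: str,
    shape: tuple[int, int] = (64, 96),
    catalog: EventCatalog = DEFAULT_CATALOG,
    appearance_seed: int = 20140101,
) -> np.ndarray:
    """Deterministic grayscale appearance of one developmental stage.

    The embryo is a bright ellipse on a dark field.  Two features
    change with catalog position: a dark "developmental front" sweeps
    from the anterior (left) pole toward the posterior as development
    proceeds — a monotone progression that orders the templates — and
    two stage-keyed blobs (position, radius and contrast drawn from an
    RNG seeded by the stage index) give each stage a distinctive local
    texture for correlation matching.
    """
    order = catalog.order(event)
    frac = order / max(1, len(catalog) - 1)
    h, w = shape
    mask = _ellipse_mask(shape)
    img = np.full(shape, 0.25, dtype=float)
    img[mask] = 0.60

    yy, xx = np.mgrid[0:h, 0:w]
    # front position in embryo-length units, swept left to right
    front_x = (0.08 + 0.84 * frac) * w
    front = 1.0 / (1.0 + np.exp(-(xx - front_x) / (0.02 * w)))
    img[mask] -= 0.25 * (1.0 - front[mask])

    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=appearance_seed, spawn_key=(order,)))
    for _ in range(2):
        bx = rng.uniform(0.2, 0.8) * w
        by = rng.uniform(0.3, 0.7) * h
        br = rng.uniform(0.05, 0.12) * w
        amp = rng.uniform(0.15, 0.30) * rng.choice([-1.0, 1.0])
        blob = amp * np.exp(-((xx - bx) ** 2 + (yy - by) ** 2) / (2 * br ** 2))
        img[mask] += blob[mask]
    return np.clip(img, 0.0, 1.0)


def render_movie(
    schedule: Mapping[str, int],
    cfg: RenderConfig = RenderConfig(),
    seed: int = 0,
    catalog: EventCatalog = DEFAULT_CATALOG,
    embryo_id: str = "synthetic",
) -> MovieStack:
    """Render a toy embryo time-lapse with ground-truth event frames.

    ``schedule`` maps event names to the frame index at which the
    embryo's appearance exactly matches that stage's template; between
    consecutive scheduled events the appearance is a linear blend, so
    the Pearson correlation of the sharp frame with a stage template
    peaks precisely at the scheduled frame.  Before the first and
    after the last scheduled event the appearance is held.

    Raises
    ------
    ValueError
        If scheduled frames fall outside the movie or violate catalog
        order.
    """
    if not schedule:
        raise ValueError("schedule must contain at least one event")
    catalog.validate_names(schedule)
    events = sorted(schedule, key=catalog.index.__getitem__)
    frames_at = [int(schedule[e]) for e in events]
    for e, f in zip(events, frames_at):
        if not 0 <= f < cfg.n_frames:
            raise ValueError(f"event {e!r} scheduled at frame {f}, outside "
                             f"movie of {cfg.n_frames} frames")
    for (e1, f1), (e2, f2) in zip(zip(events, frames_at),
                                  zip(events[1:], frames_at[1:])):
        if f2 <= f1:
            raise ValueError(
                f"schedule out of order: {e2} at {f2} not after {e1} at {f1}")

    templates = [stage_template(e, cfg.shape, catalog, cfg.appearance_seed)
                 for e in events]
    drift = cfg.drift_schedule()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))

    t_grid = np.arange(cfg.n_frames)
    movie = np.empty((cfg.n_frames, cfg.n_planes) + cfg.shape,
                     dtype=np.float32)
    for t in t_grid:
        # piecewise-linear morph between bracketing stage templates
        if t <= frames_at[0]:
            sharp = templates[0]
        elif t >= frames_at[-1]:
            sharp = templates[-1]
        else:
            i = int(np.searchsorted(frames_at, t, side="right")) - 1
            f1, f2 = frames_at[i], frames_at[i + 1]
            w = (t - f1) / (f2 - f1)
            sharp = (1.0 - w) * templates[i] + w * templates[i + 1]
        k = drift[t]
        for z in range(cfg.n_planes):
            off = abs(z - k)
            img = sharp if off == 0 or cfg.blur_increment == 0 else \
                ndimage.gaussian_filter(sharp, sigma=off * cfg.blur_increment)
            if cfg.noise_sigma > 0:
                img = img + rng.normal(0.0, cfg.noise_sigma, cfg.shape)
            movie[t, z] = img
    truth = {
        "event_frames": {e: f for e, f in zip(events, frames_at)},
        "sharp_plane": drift.tolist(),
    }
    return MovieStack(frames=movie, frame_interval_min=cfg.frame_interval_min,
                      embryo_id=embryo_id, truth=truth)
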