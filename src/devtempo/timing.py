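"""Uniform-scaling statistics for developmental event times.

Event times are first rescaled per embryo to proportions of the
cellularization-to-trachea-fill span, p = (t - t_cell)/(t_trach -
t_cell), so that embryos developing at different tempos become
directly comparable; events before cellularization carry negative
proportions.  The module then asks whether those proportions are
invariant across conditions (temperatures, species, strains):

* ``compare_scaling`` — per-event pairwise Welch t-tests across
  groups with a blanket Bonferroni correction over every event x pair
  comparison; condition means and SDs use a median/MAD outlier gate so
  gross mis-calls cannot drag them.
* ``fit_event_predictor`` — per-event least-squares line of event
  time (hours post cellularization) against total duration, with a
  percent error summarizing how well total time predicts each event.
* ``slope_contrast`` — tests, per event, whether the proportion's
  linear trend over temperature differs between a low- and a
  high-temperature regime, the signature of heat-stress breaking
  uniform scaling for pre-cellularization stages.

Hatching is excluded from all scaling statistics: its timing reflects
assay conditions more than developmental state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import ANCHOR_END, ANCHOR_START

__all__ = [
    "ScalingReport",
    "EventPredictor",
    "SlopeContrast",
    "normalize_times",
    "robust_moments",
    "compare_scaling",
    "fit_event_predictor",
    "slope_contrast",
]

#: Events never entered into scaling statistics.
EXCLUDED_EVENTS = ("hatch",)

#: Default median/MAD outlier gate width (in SD-consistent MAD units).
DEFAULT_OUTLIER_K = 5.0

_MAD_SCALE = 1.4826  # makes MAD consistent with the SD under normality


# ---------------------------------------------------------------------------
# proportional rescaling
# ---------------------------------------------------------------------------

def normalize_times(table: pd.DataFrame) -> pd.DataFrame:
    """Rescale event times per embryo to anchor-span proportions.

    Input is a long event table (embryo_id, species, temperature_C,
    event, time_min).  Each embryo must carry both anchors with a
    positive span; embryos missing an anchor are dropped (their ids
    reported in the result's ``attrs["excluded"]``).

    Returns the same long format with a ``proportion`` column in place
    of ``time_min``.  Proportions are invariant to any affine change
    of the embryo's clock.
    """
    required = {"embryo_id", "event", "time_min"}
    if not required.issubset(table.columns):
        raise ValueError(f"event table missing columns: "
                         f"{sorted(required - set(table.columns))}")
    out_rows = []
    excluded: list[str] = []
    for embryo_id, grp in table.groupby("embryo_id", sort=False):
        times = dict(zip(grp["event"], grp["time_min"]))
        if ANCHOR_START not in times or ANCHOR_END not in times:
            excluded.append(str(embryo_id))
            continue
        t0, t1 = times[ANCHOR_START], times[ANCHOR_END]
        if t1 <= t0:
            excluded.append(str(embryo_id))
            continue
        g = grp.copy()
        g["proportion"] = (g["time_min"] - t0) / (t1 - t0)
        out_rows.append(g.drop(columns="time_min"))
    if not out_rows:
        raise ValueError("no embryo carries both anchors")
    out = pd.concat(out_rows, ignore_index=True)
    out.attrs["excluded"] = excluded
    return out


def robust_moments(values, k: float = DEFAULT_OUTLIER_K
                   ) -> tuple[float, float, int]:
    """Mean and SD after a median/MAD outlier gate.

    Values farther than ``k`` SD-consistent MADs from the median are
    discarded; when the MAD is zero (a majority of identical values)
    every value differing from the median is discarded.  Returns
    (mean, sd, n_kept); the SD uses n-1 degrees of freedom and is 0
    when a single value survives.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("no values to summarize")
    med = float(np.median(v))
    mad = float(np.median(np.abs(v - med)))
    if mad == 0:
        keep = v == med
    else:
        keep = np.abs(v - med) <= k * _MAD_SCALE * mad
    kept = v[keep]
    sd = float(kept.std(ddof=1)) if kept.size > 1 else 0.0
    return float(kept.mean()), sd, int(kept.size)


# ---------------------------------------------------------------------------
# cross-condition comparison
# ---------------------------------------------------------------------------

@dataclass
class ScalingReport:
    """Per-condition proportion summaries and pairwise comparisons.

    ``moments``: one row per (event, group) with outlier-gated mean,
    sd, n.  ``comparisons``: one row per (event, group pair) with the
    Welch t statistic, raw p, and Bonferroni-adjusted p (adjusted =
    min(1, raw * m) with m the total number of comparisons in this
    report).  ``uniform`` is True when no comparison is significant at
    ``alpha`` after adjustment.
    """

    moments: pd.DataFrame
    comparisons: pd.DataFrame
    alpha: float
    n_comparisons: int
    uniform: bool
    grouping: str = "temperature_C"

    def summary(self) -> str:
        flagged = self.comparisons[
            self.comparisons["p_adjusted"] <= self.alpha]
        lines = [
            f"Uniform-scaling report (grouping: {self.grouping})",
            f"  comparisons: {self.n_comparisons} "
            f"(Bonferroni family), alpha = {self.alpha}",
            f"  verdict: {'uniform' if self.uniform else 'NON-uniform'} "
            f"scaling across conditions",
        ]
        for _, row in flagged.iterrows():
            lines.append(
                f"  deviates: {row['event']} between {row['group_1']} and "
                f"{row['group_2']} (t={row['t']:.2f}, "
                f"adj p={row['p_adjusted']:.2e})")
        return "\n".join(lines)


def compare_scaling(
    props: pd.DataFrame,
    grouping: str = "temperature_C",
    alpha: float = 0.05,
    k: float = DEFAULT_OUTLIER_K,
) -> ScalingReport:
    """Test uniform scaling of event proportions across conditions.

    For every event (anchors and hatch excluded — anchors are 0 and 1
    by construction) and every pair of groups, a two-sample Welch
    t-test compares the proportions.  The median/MAD outlier gate
    applies to the reported per-condition moments only; the t-tests
    see the raw values, keeping their null calibration intact.  All
    event x pair tests form one Bonferroni family.  Groups with fewer
    than 2 embryos are skipped for testing but still summarized.
    """
    if grouping not in props.columns:
        raise ValueError(f"grouping column {grouping!r} not in table")
    groups = sorted(props[grouping].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare")

    events = [e for e in props["event"].unique()
              if e not in EXCLUDED_EVENTS]
    moment_rows, comp_rows = [], []
    for event in events:
        sub = props[props["event"] == event]
        vals_by_group: dict = {}
        for g in groups:
            vals = sub.loc[sub[grouping] == g, "proportion"].to_numpy()
            if vals.size == 0:
                continue
            mean, sd, n_kept = robust_moments(vals, k=k)
            moment_rows.append({"event": event, "group": g, "mean": mean,
                                "sd": sd, "n": n_kept})
            vals_by_group[g] = vals[~np.isnan(vals)]
        if event in (ANCHOR_START, ANCHOR_END):
            continue  # proportions 0/1 by construction; nothing to test
        for i, g1 in enumerate(groups):
            for g2 in groups[i + 1:]:
                v1 = vals_by_group.get(g1)
                v2 = vals_by_group.get(g2)
                if v1 is None or v2 is None or len(v1) < 2 or len(v2) < 2:
                    continue
                if np.var(v1) == 0 and np.var(v2) == 0:
                    t, p = (0.0, 1.0) if v1.mean() == v2.mean() \
                        else (np.inf, 0.0)
                else:
                    t, p = stats.ttest_ind(v1, v2, equal_var=False)
                comp_rows.append({"event": event, "group_1": g1,
                                  "group_2": g2, "t": float(t),
                                  "p_raw": float(p)})
    comparisons = pd.DataFrame(
        comp_rows, columns=["event", "group_1", "group_2", "t", "p_raw"])
    m = len(comparisons)
    comparisons["p_adjusted"] = np.minimum(1.0, comparisons["p_raw"] * m)
    uniform = bool((comparisons["p_adjusted"] > alpha).all()) if m else True
    return ScalingReport(
        moments=pd.DataFrame(moment_rows,
                             columns=["event", "group", "mean", "sd", "n"]),
        comparisons=comparisons, alpha=alpha, n_comparisons=m,
        uniform=uniform, grouping=grouping)


# ---------------------------------------------------------------------------
# event-time predictors
# ---------------------------------------------------------------------------

@dataclass
class EventPredictor:
    """Per-event linear predictors from total developmental time.

    ``lines``: one row per event with slope, intercept (hours post
    cellularization vs total anchor-span duration in hours) and
    percent error, the mean absolute relative residual x 100.
    """

    lines: pd.DataFrame

    def predict(self, event: str, total_h: float) -> float:
        row = self.lines.set_index("event").loc[event]
        return float(row["slope"] * total_h + row["intercept"])


def fit_event_predictor(table: pd.DataFrame) -> EventPredictor:
    """Fit event time (h post cellularization) vs total duration.

    Requires >= 3 embryos spanning at least two distinct total
    durations.  The trachea-fill anchor fits slope 1, intercept 0,
    percent error 0 identically; under exact uniform scaling every
    event's slope equals its proportion and the intercepts vanish.
    """
    props_like = table.pivot_table(index="embryo_id", columns="event",
                                   values="time_min")
    if ANCHOR_START not in props_like or ANCHOR_END not in props_like:
        raise ValueError("both anchors required")
    t0 = props_like[ANCHOR_START]
    total_h = (props_like[ANCHOR_END] - t0) / 60.0
    ok = total_h.notna() & (total_h > 0)
    if ok.sum() < 3:
        raise ValueError("need >= 3 embryos with both anchors")
    if np.isclose(total_h[ok].max(), total_h[ok].min()):
        raise ValueError("total durations have no variance")
    rows = []
    for event in props_like.columns:
        if event in EXCLUDED_EVENTS:
            continue
        y = ((props_like[event] - t0) / 60.0)[ok]
        x = total_h[ok]
        use = y.notna()
        if use.sum() < 3:
            continue
        slope, intercept = np.polyfit(x[use], y[use], 1)
        pred = slope * x[use] + intercept
        obs = y[use]
        nonzero = obs != 0
        pct = float(np.mean(np.abs((pred[nonzero] - obs[nonzero])
                                   / obs[nonzero])) * 100) \
            if nonzero.any() else 0.0
        rows.append({"event": event, "slope": float(slope),
                     "intercept": float(intercept), "percent_error": pct,
                     "n": int(use.sum())})
    return EventPredictor(lines=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# high- vs low-temperature slope contrast
# ---------------------------------------------------------------------------

@dataclass
class SlopeContrast:
    """Per-event test of proportion-vs-temperature slope equality."""

    table: pd.DataFrame
    low_max_c: float
    high_min_c: float
    alpha: float = 0.05

    @property
    def flagged(self) -> list[str]:
        return self.table.loc[self.table["p_adjusted"] <= self.alpha,
                              "event"].tolist()


def _regress(x: np.ndarray, y: np.ndarray):
    n = x.size
    res = stats.linregress(x, y)
    return res.slope, res.stderr, n


def slope_contrast(
    table: pd.DataFrame,
    low_max_c: float = 25.0,
    high_min_c: float = 27.5,
    alpha: float = 0.05,
) -> SlopeContrast:
    """Contrast each event's temperature trend across two regimes.

    Event proportions are regressed on temperature separately within
    the low (T <= ``low_max_c``) and high (T >= ``high_min_c``)
    regimes; the two slopes are compared with a Welch-style t-test on
    their difference and the per-event p-values Bonferroni-adjusted.
    Under uniform scaling the proportion has no temperature trend in
    either regime; a heat-stress contraction of a stage shows up as a
    significant slope difference for that event only.

    Requires >= 2 distinct temperatures on each side of the split.
    """
    props = normalize_times(table) if "proportion" not in table.columns \
        else table
    low = props[props["temperature_C"] <= low_max_c]
    high = props[props["temperature_C"] >= high_min_c]
    for name, side in (("low", low), ("high", high)):
        if side["temperature_C"].nunique() < 2:
            raise ValueError(
                f"need >= 2 temperatures in the {name} regime")
    rows = []
    for event in sorted(props["event"].unique()):
        if event in EXCLUDED_EVENTS or event in (ANCHOR_START, ANCHOR_END):
            continue
        s_lo = low[low["event"] == event]
        s_hi = high[high["event"] == event]
        if len(s_lo) < 3 or len(s_hi) < 3:
            continue
        b1, se1, n1 = _regress(s_lo["temperature_C"].to_numpy(),
                               s_lo["proportion"].to_numpy())
        b2, se2, n2 = _regress(s_hi["temperature_C"].to_numpy(),
                               s_hi["proportion"].to_numpy())
        diff = b1 - b2
        se = math.hypot(se1, se2)
        if se == 0:
            # exact regimes: any "difference" at float-rounding scale
            # is no difference
            same = math.isclose(b1, b2, rel_tol=1e-9, abs_tol=1e-12)
            t, p = (0.0, 1.0) if same else (math.inf, 0.0)
            df = n1 + n2 - 4
        else:
            t = diff / se
            # Welch-Satterthwaite df from the two regression SEs
            df = (se1 ** 2 + se2 ** 2) ** 2 / (
                (se1 ** 4 / max(n1 - 2, 1)) + (se2 ** 4 / max(n2 - 2, 1)))
            p = 2 * stats.t.sf(abs(t), df)
        rows.append({"event": event, "slope_low": b1, "slope_high": b2,
                     "slope_diff": diff, "t": float(t), "df": float(df),
                     "p_raw": float(p)})
    out = pd.DataFrame(rows, columns=["event", "slope_low", "slope_high",
                                      "slope_diff", "t", "df", "p_raw"])
    m = len(out)
    out["p_adjusted"] = np.minimum(1.0, out["p_raw"] * m)
    return SlopeContrast(table=out, low_max_c=low_max_c,
                         high_min_c=high_min_c, alpha=alpha)
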