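"""Exponential temperature-duration models of embryogenesis.

Total developmental time D (hours between the cellularization and
trachea-fill anchors) depends on rearing temperature approximately as

    ln D = a + b * g(T)

where g is either the inverse absolute temperature g(T) = 1/(T + 273.15)
(the Arrhenius form, the default) or simply g(T) = T in degrees Celsius
(log-linear form).  Both transforms are straight lines in log-duration,
so ordinary least squares on the log scale fits either.  The module
computes the fit, its coefficient of determination on the log scale,
the Q10 ratio (fold-change of duration across a 10 degree interval),
the developmental rate v = 1/D, and frequentist prediction intervals
for a single future observation.

Fitting is by default restricted to the non-stress temperature range
(17.5-27.5 degrees C): at and above roughly 30 degrees heat stress
lengthens development and breaks the log-linear trend, so those points
are excluded unless explicitly requested.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Iterable, Literal

import numpy as np
from scipy import stats

__all__ = [
    "KELVIN_OFFSET",
    "ThermalForm",
    "ThermalFit",
    "transform_temperature",
    "fit_thermal",
    "predict_duration",
    "q10",
    "prediction_interval",
    "rate",
]

KELVIN_OFFSET = 273.15

ThermalForm = Literal["inverse_kelvin", "linear_celsius"]

#: Default fitting range in degrees C; heat-stress points above are excluded.
DEFAULT_FIT_RANGE = (17.5, 27.5)


def transform_temperature(temp_c, form: ThermalForm):
    """Covariate transform g(T) for the chosen model form."""
    t = np.asarray(temp_c, dtype=float)
    if form == "inverse_kelvin":
        return 1.0 / (t + KELVIN_OFFSET)
    if form == "linear_celsius":
        return t
    raise ValueError(f"unknown thermal form {form!r}")


@dataclass(frozen=True)
class ThermalFit:
    """Least-squares fit of ln(duration) on transformed temperature.

    Attributes
    ----------
    form :
        Covariate transform used ("inverse_kelvin" or "linear_celsius").
    a, b :
        Intercept and slope of the log-duration line.
    n :
        Number of (temperature, duration) points fitted.
    resid_var :
        Residual variance of log-duration (SSE / (n - 2)); 0.0 for an
        exact fit.
    g_mean, g_ss :
        Mean and centered sum of squares of the transformed covariate,
        retained for prediction-interval leverage terms.
    r_squared :
        1 - SSE/SST on the log scale; equals the squared Pearson
        correlation between observed and fitted log-durations.
    fit_range :
        Temperature range (degrees C) the fit was restricted to.
    """

    form: ThermalForm
    a: float
    b: float
    n: int
    resid_var: float
    g_mean: float
    g_ss: float
    r_squared: float
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE

    def to_json(self) -> str:
        d = asdict(self)
        d["fit_range"] = list(self.fit_range)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ThermalFit":
        d = json.loads(text)
        d["fit_range"] = tuple(d["fit_range"])
        return cls(**d)


def fit_thermal(
    temps_c: Iterable[float],
    durations_h: Iterable[float],
    form: ThermalForm = "inverse_kelvin",
    fit_range: tuple[float, float] | None = DEFAULT_FIT_RANGE,
) -> ThermalFit:
    """Fit ln(duration) = a + b*g(T) by ordinary least squares.

    Parameters
    ----------
    temps_c, durations_h :
        Paired observations: rearing temperature in degrees C and total
        anchor-to-anchor duration in hours (strictly positive).
    form :
        Covariate transform; see :data:`ThermalForm`.
    fit_range :
        Inclusive temperature range to fit within; points outside are
        dropped first.  Pass ``None`` to use every point (e.g. for a
        species whose trend holds through 30 degrees C).

    Returns
    -------
    ThermalFit

    Raises
    ------
    ValueError
        On fewer than 3 usable points, fewer than 2 distinct
        temperatures, or non-positive durations.
    """
    t = np.asarray(list(temps_c), dtype=float)
    d = np.asarray(list(durations_h), dtype=float)
    if t.shape != d.shape:
        raise ValueError("temperature and duration arrays differ in length")
    if np.any(d <= 0):
        raise ValueError("durations must be strictly positive")
    if fit_range is not None:
        lo, hi = fit_range
        keep = (t >= lo) & (t <= hi)
        t, d = t[keep], d[keep]
    else:
        fit_range = (float(np.min(t)), float(np.max(t)))
    if t.size < 3:
        raise ValueError("need at least 3 points within the fit range")
    if np.unique(t).size < 2:
        raise ValueError("need at least 2 distinct temperatures")

    g = transform_temperature(t, form)
    y = np.log(d)
    n = t.size
    g_mean = float(g.mean())
    gc = g - g_mean
    g_ss = float(gc @ gc)
    b = float((gc @ (y - y.mean())) / g_ss)
    a = float(y.mean() - b * g_mean)
    resid = y - (a + b * g)
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    resid_var = sse / (n - 2) if n > 2 else 0.0
    return ThermalFit(form=form, a=a, b=b, n=n, resid_var=resid_var,
                      g_mean=g_mean, g_ss=g_ss, r_squared=float(r2),
                      fit_range=(float(fit_range[0]), float(fit_range[1])))


def predict_duration(fit: ThermalFit, temp_c) -> np.ndarray | float:
    """Predicted duration in hours: exp(a + b*g(T))."""
    g = transform_temperature(temp_c, fit.form)
    out = np.exp(fit.a + fit.b * g)
    return float(out) if np.isscalar(temp_c) else out


def rate(fit: ThermalFit, temp_c):
    """Developmental rate v = 1/D in inverse hours."""
    d = predict_duration(fit, temp_c)
    return 1.0 / d


def q10(fit: ThermalFit, t_low_c: float = 17.5) -> float:
    """Fold-change in developmental time across a 10 degree interval.

    Defined here as D(t_low) / D(t_low + 10): a value of 2.2 means
    development takes 2.2 times as long at ``t_low`` as at
    ``t_low + 10``.  For the linear-Celsius form this is exp(-10 b),
    independent of ``t_low``; for the Arrhenius form it depends weakly
    on ``t_low``.
    """
    return float(predict_duration(fit, t_low_c)
                 / predict_duration(fit, t_low_c + 10.0))


def prediction_interval(
    fit: ThermalFit, temp_c: float, level: float = 0.95
) -> tuple[float, float]:
    """Prediction interval in hours for one future observation at T.

    Standard OLS interval on the log scale,

        yhat +/- t_{df, (1+level)/2} * s * sqrt(1 + 1/n + (g-gbar)^2/Sgg),

    exponentiated to hours; asymmetric about the predicted duration on
    the raw scale.  Requires n >= 4 so the residual degrees of freedom
    (n - 2) are at least 2.
    """
    if fit.n < 4:
        raise ValueError("prediction interval requires n >= 4")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    g = transform_temperature(temp_c, fit.form)
    yhat = fit.a + fit.b * g
    s = math.sqrt(fit.resid_var)
    se = s * math.sqrt(1.0 + 1.0 / fit.n + (g - fit.g_mean) ** 2 / fit.g_ss)
    tq = stats.t.ppf(0.5 + level / 2.0, df=fit.n - 2)
    return (float(np.exp(yhat - tq * se)), float(np.exp(yhat + tq * se)))
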