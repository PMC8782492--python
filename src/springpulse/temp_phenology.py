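"""Temperature-derived spring-onset metrics.

From a daily basin-mean temperature series this module derives, per calendar
year:

* the cumulative growing-degree-day curve ``GDD_i = sum_{k<=i} max(<T_k> - T_base, 0)``
  (the floor is standard growing-degree-day practice and keeps the curve
  monotone; the unfloored accumulation is available via ``floor_at_zero=False``);
* the *GDD-180* day — the first day the cumulative sum strictly exceeds
  180 degC·day, a conventional first-day-of-spring index;
* a logistic (sigmoid) fit ``f(t) = Asym / (1 + exp((xmid - t)/scal))`` to the
  annual GDD curve, self-started from the curve itself;
* the *jerk* day — the day the third derivative of the fitted sigmoid is
  maximal, i.e. the moment spring warm-up accelerates fastest. For the
  logistic form the maximum sits at ``xmid + scal * logit(p*)`` with
  ``p* = 1/2 - sqrt(6)/6`` (the earlier of the two symmetric extrema), about
  ``xmid - 2.2924 * scal``.

The base temperature follows the latitude rule ``T_base = -0.25 * latitude + 13``
with a single, basin-representative latitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import FitError, IncompleteYearError, InsufficientDataError
from .io_formats import DailySeries

__all__ = [
    "SigmoidParams",
    "AnnualPhenoFeature",
    "base_temperature",
    "gdd_series",
    "gdd180_day",
    "fit_sigmoid",
    "jerk_day",
    "jerk_day_numeric",
    "jerk_covariate",
    "basin_mean_temperature",
    "annual_pheno_features",
]

#: logit of the smaller root of 12 p^2 - 12 p + 1 = 0, i.e. p* = 1/2 - sqrt(6)/6.
_JERK_LOGIT = math.log((0.5 - math.sqrt(6) / 6) / (0.5 + math.sqrt(6) / 6))


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters of ``f(t) = asym / (1 + exp((xmid - t)/scal))``."""

    asym: float   # degC·day, upper asymptote
    xmid: float   # Julian day of the inflection
    scal: float   # days, rise time scale (> 0)
    converged: bool = True


@dataclass(frozen=True)
class AnnualPhenoFeature:
    """Per-year phenology summary: GDD curve plus derived spring-onset days."""

    year: int
    gdd_curve: np.ndarray
    gdd180_day: int | None
    sigmoid_params: SigmoidParams | None
    jerk_day: float | None
    fit_converged: bool


def base_temperature(latitude: float) -> float:
    """Latitude-dependent base temperature, degC: ``-0.25 * latitude + 13``."""
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude {latitude} out of range")
    return -0.25 * latitude + 13.0


def basin_mean_temperature(grid_values) -> float:
    """Arithmetic mean of grid-cell temperatures over the basin subset."""
    arr = np.asarray(grid_values, dtype=float)
    if arr.size == 0:
        raise InsufficientDataError("no grid values to average")
    return float(arr.mean())


def gdd_series(temps, t_base: float, floor_at_zero: bool = True) -> np.ndarray:
    """Cumulative growing-degree-day curve for one complete calendar year.

    ``temps`` is a full-year array of daily mean temperatures (365/366 values)
    or a single-year :class:`DailySeries`. Daily growing-degree units are
    ``<T_i> - t_base``, floored at zero by default; any missing day raises
    :class:`IncompleteYearError`.
    """
    if isinstance(temps, DailySeries):
        years = temps.years()
        if len(years) != 1:
            raise IncompleteYearError("gdd_series expects a single-year series")
        arr = temps.year_values(years[0])
    else:
        arr = np.asarray(temps, dtype=float)
    if arr.ndim != 1 or arr.size not in (365, 366):
        raise IncompleteYearError(f"expected a full calendar year, got {arr.size} days")
    if np.isnan(arr).any():
        missing = int(np.isnan(arr).sum())
        raise IncompleteYearError(f"{missing} missing days in temperature year")
    gdu = arr - t_base
    if floor_at_zero:
        gdu = np.maximum(gdu, 0.0)
    return np.cumsum(gdu)


def gdd180_day(gdd_curve, threshold: float = 180.0) -> int | None:
    """First Julian day the cumulative GDD strictly exceeds *threshold*.

    Returns None when the curve never exceeds it.
    """
    curve = np.asarray(gdd_curve, dtype=float)
    above = np.nonzero(curve > threshold)[0]
    return int(above[0]) + 1 if above.size else None


def _logistic(t, asym, xmid, scal):
    return asym / (1.0 + np.exp((xmid - t) / scal))


def fit_sigmoid(gdd_curve) -> SigmoidParams:
    """Least-squares logistic fit to an annual GDD curve.

    Self-start: ``asym0 = 1.05 * max``, ``xmid0`` = first day the curve reaches
    half of ``asym0``, ``scal0`` = a quarter of the 10%->90% rise span. A fit
    that fails to converge is returned with ``converged=False``; a flat curve
    raises :class:`FitError`.
    """
    y = np.asarray(gdd_curve, dtype=float)
    t = np.arange(1, y.size + 1, dtype=float)
    ymax = float(y.max())
    if ymax <= y.min() or ymax <= 0:
        raise FitError("flat GDD curve: no rise to fit")
    asym0 = 1.05 * ymax
    xmid0 = float(t[np.argmax(y >= asym0 / 2.0)])
    lo = float(t[np.argmax(y >= 0.10 * ymax)])
    hi = float(t[np.argmax(y >= 0.90 * ymax)])
    scal0 = max((hi - lo) / 4.0, 1.0)
    try:
        popt, _ = curve_fit(
            _logistic, t, y, p0=(asym0, xmid0, scal0),
            bounds=([0.0, -np.inf, 1e-6], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        converged = True
    except RuntimeError:
        return SigmoidParams(asym=asym0, xmid=xmid0, scal=scal0, converged=False)
    return SigmoidParams(asym=float(popt[0]), xmid=float(popt[1]),
                         scal=float(popt[2]), converged=converged)


def jerk_day(params: SigmoidParams) -> float:
    """Day of maximal third derivative of the fitted sigmoid (closed form).

    ``xmid + scal * logit(1/2 - sqrt(6)/6)``, about ``xmid - 2.2924 * scal``;
    the earlier of the sigmoid's two symmetric third-derivative maxima, which
    is the one that marks the onset of spring acceleration.
    """
    if params.scal <= 0:
        raise ValueError("scal must be positive")
    return params.xmid + params.scal * _JERK_LOGIT


def jerk_day_numeric(params: SigmoidParams, step: float = 0.001) -> float:
    """Grid argmax of the finite-difference third derivative of the sigmoid.

    Independent numeric route over ``xmid ± 6 scal``; ties resolve to the
    earliest grid point.
    """
    if params.scal <= 0:
        raise ValueError("scal must be positive")
    # Work on the scale-free grid tau = (t - xmid)/scal so the triple
    # difference is equally well conditioned for every scal; d^3f/dt^3 is a
    # positive multiple of d^3f/dtau^3, so the argmax is unaffected.
    tau = np.arange(-6.0, 6.0, step, dtype=np.longdouble)
    f = np.longdouble(params.asym) / (1.0 + np.exp(-tau))
    d3 = np.diff(f, n=3).astype(float)
    centers = (tau[:-3] + 1.5 * step).astype(float)  # triple-difference centroid
    # The logistic third derivative has two analytically equal maxima
    # (symmetric about the inflection). Take the earliest near-maximal lobe
    # and refine its peak with a parabola fit, which also averages out
    # rounding noise amplified by the triple difference.
    near = np.flatnonzero(d3 >= d3.max() * (1.0 - 1e-6))
    gaps = np.flatnonzero(np.diff(near) > 1)
    first_run = near[: gaps[0] + 1] if gaps.size else near
    i_peak = int(first_run[np.argmax(d3[first_run])])
    lo, hi = max(i_peak - 25, 0), min(i_peak + 26, d3.size)
    x = centers[lo:hi] - centers[i_peak]
    a, b, _ = np.polyfit(x, d3[lo:hi], 2)
    tau_star = centers[i_peak] - b / (2 * a)
    return float(params.xmid + params.scal * tau_star)


def jerk_covariate(julian: float, jerk: float) -> float:
    """Daily covariate: Julian day minus the year's jerk day."""
    return julian - jerk


def annual_pheno_features(
    temps: DailySeries,
    latitude: float,
    *,
    floor_at_zero: bool = True,
    threshold: float = 180.0,
) -> list[AnnualPhenoFeature]:
    """Per-year phenology features for every complete year of *temps*.

    Years with missing days are skipped; sigmoid non-convergence leaves the
    jerk day undefined but keeps the GDD metrics.
    """
    t_base = base_temperature(latitude)
    feats: list[AnnualPhenoFeature] = []
    for year in temps.years():
        arr = temps.year_values(year)
        if np.isnan(arr).any():
            continue
        curve = gdd_series(arr, t_base, floor_at_zero=floor_at_zero)
        d180 = gdd180_day(curve, threshold)
        try:
            params = fit_sigmoid(curve)
        except FitError:
            feats.append(AnnualPhenoFeature(year, curve, d180, None, None, False))
            continue
        jd = jerk_day(params) if params.converged else None
        feats.append(AnnualPhenoFeature(year, curve, d180, params, jd, params.converged))
    return feats
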