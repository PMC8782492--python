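"""Synthetic study systems with known ground truth.

Every pipeline stage can be exercised without external data:

* a seasonal basin temperature — sinusoid with a spring warm-up plus Gaussian
  noise;
* a baseflow-plus-snowmelt-pulse hydrograph — constant baseflow until a known
  onset day, then a short linear ramp (default 5 days) to the pulse magnitude
  followed by an exponential recession, with multiplicative lognormal noise;
* daily migration responses drawn from a known Bernoulli-logit model, either
  as independent daily draws (model-consistent, for parameter recovery) or as
  a monotone step starting at the first daily success (structure-consistent,
  matching how observed group responses look);
* annual trend series with a known linear slope.

Defaults mirror the study system's scale: two herds observed over nine years,
roughly 15 collared animals per herd-year, snowmelt pulse onsets between
Julian days 90 and 125, baseflow a tenth of the pulse magnitude. All
generators are pure functions of (scenario, seed).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import ScenarioError
from .io_formats import DailySeries, MigrationRecord, year_length
from .migration_response import DEFAULT_HORIZON, HerdYearResponse, binary_response

__all__ = [
    "SyntheticScenario",
    "gen_temperature",
    "gen_hydrograph",
    "gen_migration_responses",
    "gen_trend_series",
    "records_from_summary",
]


@dataclass(frozen=True)
class SyntheticScenario:
    """Ground-truth parameters for one synthetic study system."""

    seed: int = 0
    years: tuple[int, ...] = tuple(range(2001, 2010))
    latitude: float = 41.0
    # temperature: annual mean (degC), amplitude (degC), phase day, noise sd (degC)
    temp_mean: float = 4.5
    temp_amplitude: float = 12.0
    temp_phase_day: float = 106.0
    temp_noise_sd: float = 2.0
    # hydrograph: baseflow, per-year pulse onset day, magnitude, recession, noise
    baseflow: float = 2.0
    pulse_onsets: tuple[int, ...] = (104, 96, 118, 110, 90, 122, 100, 115, 108)
    pulse_magnitude: float = 20.0
    rise_days: int = 5
    recession_rate: float = 0.05     # per day
    noise_fraction: float = 0.05
    # migration model: logit(theta) = b0 + b_dsm * Dsm + b_herd * herd
    beta: tuple[float, ...] = (0.0, 0.25, -0.25)
    herds: tuple[str, ...] = ("NAR", "SAR")

    def __post_init__(self):
        if len(self.pulse_onsets) != len(self.years):
            raise ScenarioError("one pulse onset per year required")
        if self.baseflow <= 0 or self.pulse_magnitude < 0 or self.temp_noise_sd < 0:
            raise ScenarioError("scale parameters must be positive")
        if any(not (30 <= d <= 180) for d in self.pulse_onsets):
            raise ScenarioError("pulse onsets must lie in 30..180")


def _dates_of_year(year: int) -> tuple[dt.date, ...]:
    start = dt.date(year, 1, 1)
    return tuple(start + dt.timedelta(days=i) for i in range(year_length(year)))


def gen_temperature(scenario: SyntheticScenario, year: int) -> DailySeries:
    """Daily basin-mean temperature for *year*: sinusoid plus N(0, sd) noise."""
    n = year_length(year)
    i = np.arange(1, n + 1, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, year, 1]))
    temps = (
        scenario.temp_mean
        + scenario.temp_amplitude * np.sin(2 * np.pi * (i - scenario.temp_phase_day) / n)
        + rng.normal(0.0, scenario.temp_noise_sd, n)
    )
    return DailySeries("synthetic-basin", "temperature", "degC",
                       _dates_of_year(year), temps)


def gen_hydrograph(scenario: SyntheticScenario, year: int) -> tuple[DailySeries, int]:
    """Daily streamflow for *year* and the true pulse-onset day.

    Baseflow until the onset; a linear ramp to the pulse magnitude over
    ``rise_days``; exponential recession after the crest; multiplicative
    lognormal noise at ``noise_fraction``.
    """
    onset = scenario.pulse_onsets[scenario.years.index(year)]
    n = year_length(year)
    if onset + scenario.rise_days > n:
        raise ScenarioError(f"onset {onset} too late to complete the rise")
    i = np.arange(1, n + 1, dtype=float)
    shape = np.zeros(n)
    rising = (i >= onset) & (i < onset + scenario.rise_days)
    shape[rising] = (i[rising] - onset + 1) / scenario.rise_days
    after = i >= onset + scenario.rise_days
    shape[after] = np.exp(-scenario.recession_rate * (i[after] - onset - scenario.rise_days))
    q = scenario.baseflow + scenario.pulse_magnitude * shape
    if scenario.noise_fraction > 0:
        rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, year, 2]))
        sigma = np.sqrt(np.log1p(scenario.noise_fraction**2))
        q = q * rng.lognormal(-0.5 * sigma**2, sigma, n)
    series = DailySeries("synthetic-gage", "discharge", "m3/s",
                         _dates_of_year(year), q)
    return series, onset


def gen_migration_responses(
    scenario: SyntheticScenario,
    covariates: dict,
    mode: str = "first_success_step",
    horizon: int = DEFAULT_HORIZON,
) -> tuple[list[HerdYearResponse], dict]:
    """Draw daily migration responses from the scenario's true logit model.

    ``covariates`` maps (herd, year) to a DataFrame indexed by day 1..horizon
    with a ``Dsm`` column and a ``herd`` dummy column. Modes:

    * ``bernoulli_iid`` — independent daily Bernoulli(theta) outcomes; the
      ground-truth "initiation day" recorded is the first day theta exceeds
      0.5 (the estimand of the prediction rule);
    * ``first_success_step`` — initiation at the first day a Bernoulli(theta)
      draw succeeds, followed by a filled step (the shape observed responses
      actually have); the recorded truth is that step day.

    Returns the responses plus ``{(herd, year): true_initiation_day}``.
    """
    if mode not in ("bernoulli_iid", "first_success_step"):
        raise ValueError(f"unknown mode {mode!r}")
    beta = np.asarray(scenario.beta, dtype=float)
    responses, truth = [], {}
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 3]))
    for (herd, year), frame in sorted(covariates.items()):
        days = np.arange(1, horizon + 1)
        x = np.column_stack([
            np.ones(horizon),
            frame.loc[days, "Dsm"].to_numpy(dtype=float),
            frame.loc[days, "herd"].to_numpy(dtype=float),
        ])
        theta = expit(x @ beta)
        if theta.max() < 1e-6:
            import warnings

            warnings.warn(f"degenerate scenario: theta never exceeds 1e-6 for {herd} {year}")
        draws = rng.random(horizon) < theta
        if mode == "bernoulli_iid":
            daily = draws.astype(int)
            above = np.nonzero(theta > 0.5)[0]
            init = int(above[0]) + 1 if above.size else None
        else:
            hit = np.nonzero(draws)[0]
            init = int(hit[0]) + 1 if hit.size else None
            daily = binary_response(init, horizon) if init else np.zeros(horizon, dtype=int)
        truth[(herd, year)] = init
        responses.append(
            HerdYearResponse(
                herd=herd, year=year, n_collared=0, max_simultaneous=0,
                group_initiation_day=init if init else horizon + 1,
                earliest_individual_day=init if init else horizon + 1,
                daily_response=daily,
            )
        )
    return responses, truth


def gen_trend_series(
    n_years: int, true_slope: float, noise_sd: float, seed: int, intercept: float = 120.0
) -> tuple[np.ndarray, np.ndarray]:
    """Annual series ``y_j = intercept + slope * j + eps_j``; returns (x, y)."""
    if n_years < 10:
        raise ScenarioError("need >= 10 years for a trend series")
    rng = np.random.default_rng(seed)
    x = np.arange(n_years, dtype=float)
    y = intercept + true_slope * x + rng.normal(0.0, noise_sd, n_years)
    return x, y


def records_from_summary(summary: pd.DataFrame) -> list[MigrationRecord]:
    """Engineer per-animal intervals reproducing a herd-year summary table.

    For each row (n animals, earliest individual day d0, group day dg, maximum
    simultaneous count m, median displacement): one animal spans [d0, dg+5],
    m-1 more span [dg, dg+5] so the count first reaches m exactly on dg, and
    the remaining n-m animals get disjoint one-day intervals after the pulse
    so the maximum stays m. All displacements equal the row median.
    """
    records: list[MigrationRecord] = []
    for _, row in summary.iterrows():
        herd, year = row["herd"], int(row["year"])
        n, m = int(row["n"]), int(row["max_simultaneous"])
        d0, dg = int(row["earliest_individual_day"]), int(row["group_initiation_day"])
        disp = float(row["median_displacement_km"])
        if not (1 <= m <= n and d0 <= dg):
            raise ScenarioError(f"inconsistent summary row for {herd} {year}")
        end = dg + 5
        records.append(MigrationRecord(f"{herd}{year}a0", herd, year, d0, end, disp))
        for k in range(1, m):
            records.append(MigrationRecord(f"{herd}{year}a{k}", herd, year, dg, end, disp))
        for k in range(m, n):
            day = end + 2 + 2 * (k - m)
            records.append(MigrationRecord(f"{herd}{year}a{k}", herd, year, day, day, disp))
    return records
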