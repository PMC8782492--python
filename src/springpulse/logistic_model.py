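"""Bayesian Bernoulli-logit model of daily migration-initiation probability.

The daily binary group-migration response ``y_i`` is modeled as

    y_i | theta_i ~ Bernoulli(theta_i),   logit(theta_i) = x_i . beta,

with diffuse independent normal priors ``beta_k ~ N(0, sd=100)`` (precision
1e-4). Covariates (basin temperature, cumulative GDD, jerk-day offset,
pulse-day offsets for one or two gages, lagged pulse offset, herd dummy) enter
on their raw scales; the herd dummy codes NAR = 0, SAR = 1.

Sampling uses random-walk Metropolis, vectorized across chains, with the
proposal covariance taken from the Laplace approximation at the posterior mode
(scale 2.4/sqrt(k)); chains start overdispersed around the mode. Convergence
is summarized per coefficient by the Gelman-Rubin statistic.

Model scoring follows standard Bayesian practice: DIC = Dbar + pD with
pD = Dbar - D(posterior-mean beta) and deviance D = -2 log-likelihood; a day
is classified "migrating" when the posterior-median theta_i exceeds 0.5, from
which recall = TP/(TP+FN) and precision = TP/(TP+FP). The predicted group
initiation day for a year is the first day the posterior-median probability
exceeds 50%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .exceptions import (
    AssemblyError,
    FitError,
    SeparationError,
    UndefinedStatisticError,
)
from .migration_response import DEFAULT_HORIZON, HerdYearResponse

__all__ = [
    "DesignMatrix",
    "PosteriorFit",
    "ModelScores",
    "TABLE2_SPECS",
    "HERD_DUMMY",
    "assemble_design",
    "collinearity_screen",
    "fit_bayes_logistic",
    "gelman_rubin",
    "model_scores",
    "predict_initiation_day",
    "prediction_rmse",
    "period_summaries",
    "DEFAULT_PERIOD_BREAKS",
]

#: Herd dummy coding: the southern herd is the indicator's 1 level.
HERD_DUMMY = {"NAR": 0.0, "SAR": 1.0}

#: The ten candidate covariate sets of the model suite (ids follow run order).
TABLE2_SPECS: dict[str, list[str]] = {
    "1": ["T_mean", "herd"],
    "2": ["GDD", "herd"],
    "3": ["JERK", "herd"],
    "4": ["Dsm_lily", "herd"],
    "5": ["Dsm_slater", "herd"],
    "6": ["Dpsm_slater", "herd"],
    "7": ["T_mean", "Dsm_slater", "herd"],
    "8": ["T_mean", "Dpsm_slater", "herd"],
    "9": ["T_mean", "GDD", "Dsm_slater", "herd"],
    "10": ["T_mean", "GDD", "Dpsm_slater", "herd"],
}

#: Historical summary periods for the long-record prediction exercise.
DEFAULT_PERIOD_BREAKS = ((1943, 1959), (1960, 1979), (1980, 1999), (2000, 2018))


@dataclass(frozen=True)
class DesignMatrix:
    """Daily design matrix: one row per (herd, year, day), intercept first."""

    X: np.ndarray                # (n, k) incl. leading column of ones
    y: np.ndarray                # (n,) binary
    columns: tuple[str, ...]     # k names; columns[0] == "intercept"
    index: pd.DataFrame          # herd, year, day per row

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1]


@dataclass
class PosteriorFit:
    model_id: str
    columns: tuple[str, ...]
    draws: np.ndarray            # (chains, kept_steps, k), burn-in removed
    chains: int
    steps: int
    burn_in: int
    gelman_rubin: np.ndarray     # per coefficient
    accept_rate: float
    converged: bool
    scores: "ModelScores | None" = field(default=None)

    def flat_draws(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def coef_mean(self) -> np.ndarray:
        return self.flat_draws().mean(axis=0)

    def credible_interval(self, level: float = 0.95) -> np.ndarray:
        """(k, 2) equal-tailed posterior interval per coefficient."""
        a = (1.0 - level) / 2.0
        flat = self.flat_draws()
        return np.quantile(flat, [a, 1.0 - a], axis=0).T

    def summary(self) -> pd.DataFrame:
        ci = self.credible_interval()
        return pd.DataFrame(
            {
                "coefficient": self.columns,
                "mean": self.coef_mean(),
                "ci_2.5%": ci[:, 0],
                "ci_97.5%": ci[:, 1],
                "rhat": self.gelman_rubin,
            }
        )


@dataclass(frozen=True)
class ModelScores:
    dic: float
    recall: float
    precision: float


def assemble_design(
    responses: list[HerdYearResponse],
    covariates: dict,
    spec: list[str],
    horizon: int = DEFAULT_HORIZON,
) -> DesignMatrix:
    """Join daily covariates onto daily responses, one row per herd-year-day.

    ``covariates`` maps year (or ``(herd, year)``) to a DataFrame indexed by
    Julian day 1..horizon whose columns are covariate names. ``spec`` lists the
    covariates to include; the name ``"herd"`` appends the NAR=0/SAR=1 dummy.
    Missing years or columns raise :class:`AssemblyError` listing the gaps.
    """
    want = [c for c in spec if c != "herd"]
    add_herd = "herd" in spec
    blocks, ys, idx = [], [], []
    missing = []
    for r in responses:
        frame = covariates.get((r.herd, r.year), covariates.get(r.year))
        if frame is None:
            missing.append((r.herd, r.year))
            continue
        absent = [c for c in want if c not in frame.columns]
        if absent:
            raise AssemblyError(f"covariate column(s) {absent} absent for {r.herd} {r.year}")
        days = np.arange(1, horizon + 1)
        if not np.isin(days, frame.index).all():
            raise AssemblyError(f"covariates for {r.herd} {r.year} do not cover days 1..{horizon}")
        sub = frame.loc[days, want].to_numpy(dtype=float) if want else np.empty((horizon, 0))
        if np.isnan(sub).any():
            raise AssemblyError(f"missing covariate cells for {r.herd} {r.year}")
        cols = [np.ones(horizon), *sub.T]
        if add_herd:
            cols.append(np.full(horizon, HERD_DUMMY[r.herd]))
        blocks.append(np.column_stack(cols))
        ys.append(r.daily_response[:horizon])
        idx.append(pd.DataFrame({"herd": r.herd, "year": r.year, "day": days}))
    if missing:
        raise AssemblyError(f"no covariates for herd-years: {missing}")
    if not blocks:
        raise AssemblyError("no responses to assemble")
    names = ["intercept", *want] + (["herd"] if add_herd else [])
    return DesignMatrix(
        X=np.vstack(blocks),
        y=np.concatenate(ys).astype(float),
        columns=tuple(names),
        index=pd.concat(idx, ignore_index=True),
    )


def collinearity_screen(matrix: DesignMatrix, threshold: float = 0.20) -> pd.DataFrame:
    """Pairwise Pearson R among non-intercept covariates; |R| > threshold is
    flagged as a multicollinearity risk."""
    names = [c for c in matrix.columns if c != "intercept"]
    cols = [matrix.X[:, matrix.columns.index(c)] for c in names]
    if len(names) < 2:
        raise UndefinedStatisticError("need >= 2 covariates to screen")
    for name, col in zip(names, cols):
        if np.std(col) == 0:
            raise UndefinedStatisticError(f"zero-variance covariate {name!r}")
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r = float(np.corrcoef(cols[i], cols[j])[0, 1])
            rows.append({"a": names[i], "b": names[j], "pearson_r": r,
                         "flagged": abs(r) > threshold})
    return pd.DataFrame(rows)


def _log_posterior(B: np.ndarray, X: np.ndarray, y: np.ndarray, prior_sd: float) -> np.ndarray:
    """Vectorized over chains: B is (chains, k). Bernoulli-logit likelihood
    plus independent N(0, prior_sd^2) log-prior (constant terms dropped)."""
    eta = X @ B.T                                   # (n, chains)
    ll = y @ eta - np.logaddexp(0.0, eta).sum(axis=0)
    lp = -0.5 * np.sum(B * B, axis=1) / prior_sd**2
    return ll + lp


def _posterior_mode(X, y, prior_sd):
    n, k = X.shape

    def negpost(b):
        eta = X @ b
        val = -(y @ eta - np.logaddexp(0.0, eta).sum()) + 0.5 * b @ b / prior_sd**2
        p = expit(eta)
        grad = -(X.T @ (y - p)) + b / prior_sd**2
        return val, grad

    res = minimize(negpost, np.zeros(k), jac=True, method="L-BFGS-B")
    b = res.x
    p = expit(X @ b)
    w = p * (1.0 - p)
    hess = X.T @ (X * w[:, None]) + np.eye(k) / prior_sd**2
    cov = np.linalg.inv(hess)
    return b, cov


def gelman_rubin(draws: np.ndarray) -> np.ndarray:
    """Potential scale reduction factor per coefficient.

    ``draws`` has shape (chains, steps, k). Classic between/within variance
    ratio; values near 1 indicate the chains agree.
    """
    m, n, k = draws.shape
    if m < 2:
        return np.full(k, np.nan)
    chain_means = draws.mean(axis=1)              # (m, k)
    chain_vars = draws.var(axis=1, ddof=1)        # (m, k)
    w = chain_vars.mean(axis=0)
    b = n * chain_means.var(axis=0, ddof=1)
    var_hat = (n - 1) / n * w + b / n
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.sqrt(var_hat / w)


def fit_bayes_logistic(
    matrix: DesignMatrix,
    chains: int = 3,
    steps: int = 20000,
    burn_in: int = 1000,
    seed: int | None = None,
    prior_sd: float = 100.0,
    model_id: str = "",
) -> PosteriorFit:
    """Random-walk Metropolis fit of the Bernoulli-logit model.

    ``steps`` counts post-start iterations per chain; the first ``burn_in``
    are discarded. Chains start overdispersed around the posterior mode and
    propose from the Laplace covariance scaled by 2.4/sqrt(k). The fit is
    flagged unconverged when any Gelman-Rubin statistic exceeds 1.1.
    """
    X, y = matrix.X, matrix.y
    classes = np.unique(y)
    if classes.size < 2:
        raise SeparationError("response has a single class; logistic fit is degenerate")
    for name, col in zip(matrix.columns[1:], X[:, 1:].T):
        if np.std(col) == 0:
            raise FitError(f"zero-variance covariate {name!r}")
    if burn_in >= steps:
        raise ValueError("burn_in must be smaller than steps")
    rng = np.random.default_rng(seed)
    k = X.shape[1]
    mode, cov = _posterior_mode(X, y, prior_sd)
    chol = np.linalg.cholesky(cov)
    scale = 2.4 / np.sqrt(k)
    # overdispersed starts: mode +/- 2 sd along the Laplace ellipse
    current = mode[None, :] + 2.0 * (rng.standard_normal((chains, k)) @ chol.T)
    lp = _log_posterior(current, X, y, prior_sd)
    out = np.empty((chains, steps, k))
    accepted = 0
    for s in range(steps):
        prop = current + scale * (rng.standard_normal((chains, k)) @ chol.T)
        lpp = _log_posterior(prop, X, y, prior_sd)
        take = np.log(rng.random(chains)) < (lpp - lp)
        current[take] = prop[take]
        lp[take] = lpp[take]
        accepted += int(take.sum())
        out[:, s, :] = current
    kept = out[:, burn_in:, :]
    rhat = gelman_rubin(kept)
    return PosteriorFit(
        model_id=model_id,
        columns=matrix.columns,
        draws=kept,
        chains=chains,
        steps=steps,
        burn_in=burn_in,
        gelman_rubin=rhat,
        accept_rate=accepted / (chains * steps),
        converged=bool(np.all(rhat[np.isfinite(rhat)] < 1.1)),
    )


def _theta_stats(draws_flat: np.ndarray, X: np.ndarray, max_draws: int = 4000,
                 block: int = 512):
    """Posterior-median theta per row plus mean deviance, chunked over rows.

    Draws are thinned deterministically to at most *max_draws* for the row-wise
    median; the deviance average uses the same thinned set.
    """
    nd = draws_flat.shape[0]
    if nd > max_draws:
        stride = int(np.ceil(nd / max_draws))
        draws_flat = draws_flat[::stride]
    med = np.empty(X.shape[0])
    for lo in range(0, X.shape[0], block):
        hi = min(lo + block, X.shape[0])
        eta = X[lo:hi] @ draws_flat.T        # (block, ndraws)
        med[lo:hi] = np.median(expit(eta), axis=1)
    return med, draws_flat


def _deviance(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    eta = X @ beta
    return float(-2.0 * (y @ eta - np.logaddexp(0.0, eta).sum()))


def model_scores(fit: PosteriorFit, matrix: DesignMatrix,
                 threshold: float = 0.5) -> ModelScores:
    """DIC plus posterior-predictive recall and precision.

    DIC = Dbar + pD, pD = Dbar - D(posterior-mean beta). A row is predicted
    positive when its posterior-median probability exceeds *threshold*.
    Recall or precision is NaN when its denominator is zero (no observed,
    respectively no predicted, positives); DIC is always defined.
    """
    flat = fit.flat_draws()
    X, y = matrix.X, matrix.y
    med, thinned = _theta_stats(flat, X)
    dbar = float(np.mean([_deviance(b, X, y) for b in thinned[:: max(1, len(thinned) // 1000)]]))
    dhat = _deviance(flat.mean(axis=0), X, y)
    dic = 2.0 * dbar - dhat          # Dbar + (Dbar - Dhat)
    pred = med > threshold
    obs = y > 0.5
    tp = int(np.sum(pred & obs))
    fn = int(np.sum(~pred & obs))
    fp = int(np.sum(pred & ~obs))
    recall = tp / (tp + fn) if (tp + fn) else float("nan")
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    scores = ModelScores(dic=dic, recall=recall, precision=precision)
    fit.scores = scores
    return scores


def predict_initiation_day(
    fit: PosteriorFit,
    year_covariates: pd.DataFrame,
    threshold: float = 0.5,
    max_draws: int = 4000,
) -> int | None:
    """First day the posterior-median migration probability exceeds 50%.

    ``year_covariates`` is indexed by Julian day and must contain every
    non-intercept column of the fit (including ``herd``). Returns None when
    the probability never crosses the threshold.
    """
    names = [c for c in fit.columns if c != "intercept"]
    absent = [c for c in names if c not in year_covariates.columns]
    if absent:
        raise AssemblyError(f"prediction covariates lack column(s) {absent}")
    days = np.asarray(year_covariates.index)
    X = np.column_stack([np.ones(len(days)),
                         year_covariates[names].to_numpy(dtype=float)])
    med, _ = _theta_stats(fit.flat_draws(), X, max_draws=max_draws)
    above = np.nonzero(med > threshold)[0]
    return int(days[above[0]]) if above.size else None


def prediction_rmse(predicted: dict, observed: dict) -> float:
    """Root-mean-square error between predicted and observed initiation days,
    paired by key (typically (herd, year))."""
    keys = sorted(set(predicted) & set(observed))
    unpaired = (set(predicted) | set(observed)) - set(keys)
    if unpaired:
        raise ValueError(f"unpaired entries: {sorted(unpaired)}")
    if not keys:
        raise ValueError("no pairs to score")
    diff = np.array([predicted[k] - observed[k] for k in keys], dtype=float)
    return float(np.sqrt(np.mean(diff**2)))


def period_summaries(
    predicted_by_year: dict[int, int],
    period_breaks=DEFAULT_PERIOD_BREAKS,
) -> pd.DataFrame:
    """Median and interquartile range of predicted initiation days per period."""
    rows = []
    for lo, hi in period_breaks:
        days = [d for y, d in predicted_by_year.items() if lo <= y <= hi and d is not None]
        if days:
            q1, med, q3 = np.percentile(days, [25, 50, 75])
            rows.append({"period": f"{lo}-{hi}", "n_years": len(days),
                         "median_day": float(med), "iqr_days": float(q3 - q1)})
        else:
            rows.append({"period": f"{lo}-{hi}", "n_years": 0,
                         "median_day": float("nan"), "iqr_days": float("nan")})
    return pd.DataFrame(rows)
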