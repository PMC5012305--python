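"""Two-stage Monte Carlo trend inference for multi-decade population series.

Historical abundance estimates carry sampling error, and any trend model
fitted to them carries fit error.  Both are propagated by:

1. drawing R replicate datasets, each observation resampled from
   Normal(estimate, SE) (total counts, SE = 0, are reproduced exactly;
   missing SEs are imputed from a power-law regression of log variance on
   log estimate);
2. fitting each replicate with a semi-parametric count model — a GAM with a
   penalized spline of year plus additive unit (stratum/ecosystem) offsets on
   the log link, observation weights m_i / m-bar so units contribute in
   proportion to their mean size, and Poisson vs negative-binomial errors
   chosen by AIC majority across replicates; datasets with exactly two
   observations get a log-linear Poisson GLM instead;
3. redrawing each replicate's aggregated annual prediction from
   Normal(prediction, prediction SE), yielding R predicted time series that
   encode both sources of error.

Growth rates r are per-replicate OLS slopes of log population on year, and
all intervals are empirical percentiles over replicates.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from statsmodels.gam.api import BSplines, GLMGam

from .survey_data import HistoricalSeries

logger = logging.getLogger("gecpop")

__all__ = [
    "TrendModelConfig",
    "ReplicateSet",
    "TrendResult",
    "SEImputation",
    "impute_se",
    "make_replicates",
    "fit_replicate",
    "select_family",
    "resample_predictions",
    "growth_rate",
    "population_change",
    "halving_time",
    "estimate_trend",
    "plot_trend",
]


# ---------------------------------------------------------------------------
# Configuration and result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrendModelConfig:
    """Model settings for the per-replicate trend fits.

    family_rule: "aic_majority" (fit both families per replicate, keep the
    majority winner; ties go to the negative binomial as the more
    conservative family), or force_poisson / force_negbin.

    df_rule: "gcv" selects the spline penalty by generalized cross-
    validation over alpha_grid; "fixed" uses an unpenalized spline basis of
    fixed_df degrees of freedom; "auto" uses GCV when the dataset has at
    least fixed_df + 3 distinct survey years and falls back to fixed df
    otherwise (data-driven smoothness selection needs more distinct years
    than the df it would otherwise fix).
    """

    family_rule: str = "aic_majority"
    df_rule: str = "auto"
    fixed_df: int = 6
    end_year: int = 2014
    basis_df: int = 10
    alpha_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)
    negbin_alpha_grid: tuple[float, ...] = (0.001, 0.01, 0.05, 0.1, 0.3, 1.0)

    def __post_init__(self) -> None:
        if self.fixed_df < 2:
            raise ValueError("fixed_df must be >= 2")


@dataclass
class ReplicateSet:
    """Stage-1 Monte Carlo draws: one resampled dataset per replicate row."""

    records: list[HistoricalSeries]
    draws: np.ndarray  # (R, n_records)
    seed: int
    n_truncated: int = 0

    @property
    def n_replicates(self) -> int:
        return self.draws.shape[0]


@dataclass
class TrendResult:
    """R predicted annual time series plus summaries."""

    years: np.ndarray                      # (T,)
    predicted: np.ndarray                  # (R_ok, T) after stage-2 resampling
    annual_mean: np.ndarray                # (T,)
    annual_sd: np.ndarray                  # (T,)
    annual_ci95: np.ndarray                # (2, T)
    growth_rates: dict = field(default_factory=dict)
    family: str = "poisson"
    family_fraction: float = 1.0
    n_failed: int = 0
    basis: str = "bspline"
    df_rule_used: str = "fixed"


@dataclass(frozen=True)
class SEImputation:
    """Fitted power law var = exp(intercept) * estimate**slope."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def se_for(self, estimate: float) -> float:
        return math.sqrt(math.exp(self.intercept + self.slope * math.log(estimate)))


# ---------------------------------------------------------------------------
# Stage 1: SE imputation and replicate generation
# ---------------------------------------------------------------------------

def impute_se(
    known: Sequence[tuple[float, float]],
    targets: Sequence[float],
) -> tuple[list[float], SEImputation]:
    """Impute missing SEs from the power law linking variance to abundance.

    Count-survey variance generally scales as a power of population size, so
    log(variance) is regressed on log(estimate) over the records with
    reported SEs (OLS); imputed SE = sqrt(exp(fitted log-variance)).
    Non-positive estimates or variances are excluded with a warning.
    """
    pts = []
    for est, var in known:
        if est > 0 and var > 0:
            pts.append((math.log(est), math.log(var)))
        else:
            logger.warning(
                "impute_se: dropping non-positive regression point (%.4g, %.4g)",
                est, var,
            )
    if len(pts) < 3:
        raise ValueError("need >= 3 positive (estimate, variance) points")
    x = np.array([p[0] for p in pts])
    yv = np.array([p[1] for p in pts])
    X = np.column_stack([np.ones_like(x), x])
    res = sm.OLS(yv, X).fit()
    fit = SEImputation(
        slope=float(res.params[1]), intercept=float(res.params[0]),
        r_squared=float(res.rsquared), n_points=len(pts),
    )
    ses = [fit.se_for(t) for t in targets]
    return ses, fit


def fill_missing_se(
    series: Sequence[HistoricalSeries],
) -> tuple[list[HistoricalSeries], SEImputation | None]:
    """Return series with every missing SE imputed from the power-law fit."""
    known = [(r.estimate, r.se**2) for r in series
             if r.se is not None and r.se > 0]
    missing = [r for r in series if r.se is None]
    if not missing:
        return list(series), None
    ses, fit = impute_se(known, [r.estimate for r in missing])
    logger.info(
        "imputed %d missing SEs (power-law fit r^2 = %.3f)", len(missing),
        fit.r_squared,
    )
    imputed = iter(ses)
    out = [replace(r, se=next(imputed)) if r.se is None else r for r in series]
    return out, fit


def make_replicates(
    series: Sequence[HistoricalSeries], R: int, seed: int
) -> ReplicateSet:
    """Draw R resampled datasets: Normal(estimate, SE) per record.

    Total counts (SE = 0) are reproduced exactly in every replicate.
    Negative draws are truncated at 0 (populations cannot be negative);
    the truncation count is retained for auditing.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    filled, _ = fill_missing_se(series)
    est = np.array([r.estimate for r in filled])
    se = np.array([r.se for r in filled])
    rng = np.random.default_rng(seed)
    draws = est[None, :] + se[None, :] * rng.standard_normal((R, len(filled)))
    n_trunc = int(np.sum(draws < 0))
    if n_trunc:
        logger.info("make_replicates: truncated %d negative draws at 0", n_trunc)
    np.clip(draws, 0.0, None, out=draws)
    return ReplicateSet(records=list(filled), draws=draws, seed=seed,
                        n_truncated=n_trunc)


# ---------------------------------------------------------------------------
# Stage 2: per-replicate model fits
# ---------------------------------------------------------------------------

@dataclass
class _Dataset:
    """Design information shared by every replicate of one dataset."""

    units: list[str]
    unit_idx: np.ndarray        # (n,) index into units
    year: np.ndarray            # (n,) float
    weights: np.ndarray         # (n,) m_i / m-bar
    grid_years: np.ndarray      # (T,) prediction years
    X: np.ndarray               # (n, p) design matrix
    Xg: np.ndarray              # (T * n_units, p) grid design
    grid_unit: np.ndarray       # (T * n_units,) unit index per grid row
    grid_year: np.ndarray       # (T * n_units,) year per grid row
    df_rule_used: str = "fixed"
    smoother: BSplines | None = None
    n_fixed: int = 0            # columns of X before the spline basis


def observation_weights(series: Sequence[HistoricalSeries]) -> dict[str, float]:
    """Per-unit weights m_i / m-bar from mean point estimates across years."""
    means: dict[str, list[float]] = {}
    for r in series:
        means.setdefault(r.unit_id, []).append(r.estimate)
    m = {u: float(np.mean(v)) for u, v in means.items()}
    mbar = float(np.mean(list(m.values())))
    return {u: mi / mbar for u, mi in m.items()}


def build_dataset(
    series: Sequence[HistoricalSeries], config: TrendModelConfig
) -> _Dataset:
    """Build the shared design for one dataset (fixed effects + year basis)."""
    units = sorted({r.unit_id for r in series})
    uidx = {u: i for i, u in enumerate(units)}
    unit_idx = np.array([uidx[r.unit_id] for r in series])
    year = np.array([float(r.year) for r in series])
    wmap = observation_weights(series)
    weights = np.array([wmap[r.unit_id] for r in series])

    first = int(year.min())
    grid_years = np.arange(first, config.end_year + 1, dtype=float)
    n_units = len(units)
    grid_unit = np.repeat(np.arange(n_units), len(grid_years))
    grid_year = np.tile(grid_years, n_units)

    # fixed effects: intercept + unit dummies (first unit is the reference)
    def fixed_block(u, n):
        F = np.ones((len(u), n_units))
        F[:, 1:] = (u[:, None] == np.arange(1, n_units)[None, :])
        return F[:, :n_units]

    F = fixed_block(unit_idx, n_units)
    Fg = fixed_block(grid_unit, n_units)

    distinct_years = len(np.unique(year))
    if len(series) == 2:
        # two-point dataset: log-linear Poisson GLM in year only
        X = np.column_stack([np.ones(2), year - first])
        Xg = np.column_stack([np.ones_like(grid_year), grid_year - first])
        return _Dataset(units, unit_idx, year, weights, grid_years, X, Xg,
                        grid_unit, grid_year, df_rule_used="two_point")

    rule = config.df_rule
    if rule == "auto":
        rule = "gcv" if distinct_years >= config.fixed_df + 3 else "fixed"

    # knots must span the prediction grid, which can extend past the data
    kw = [{"lower_bound": float(min(year.min(), grid_year.min())),
           "upper_bound": float(max(year.max(), grid_year.max()))}]

    def _basis(df):
        df = max(df, 3)  # second-derivative penalty needs degree >= 2
        degree = min(3, df - 1)
        return BSplines(year, df=[df], degree=[degree],
                        include_intercept=False, knot_kwds=kw)

    if rule == "fixed":
        bs = _basis(min(config.fixed_df, distinct_years - 1))
        X = np.column_stack([F, bs.basis])
        Xg = np.column_stack([Fg, bs.transform(grid_year)])
        return _Dataset(units, unit_idx, year, weights, grid_years, X, Xg,
                        grid_unit, grid_year, df_rule_used="fixed")

    bs = _basis(min(config.basis_df, distinct_years - 1))
    X = np.column_stack([F, bs.basis])
    Xg = np.column_stack([Fg, bs.transform(grid_year)])
    return _Dataset(units, unit_idx, year, weights, grid_years, X, Xg,
                    grid_unit, grid_year, df_rule_used="gcv",
                    smoother=bs, n_fixed=n_units)


def _fit_glm(y, ds: _Dataset, family):
    res = sm.GLM(y, ds.X, family=family, var_weights=ds.weights).fit()
    edf = ds.X.shape[1]
    return res, float(edf)


def _fit_gam_gcv(y, ds: _Dataset, family, alpha_grid):
    """Penalized fit with the smoothing penalty chosen by GCV:
    n * deviance / (n - edf)^2 minimized over the alpha grid."""
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    n = len(y)
    best = None
    for alpha in alpha_grid:
        model = GLMGam(y, exog=ds.X[:, :ds.n_fixed], smoother=ds.smoother,
                       alpha=alpha, family=family, var_weights=ds.weights)
        try:
            res = model.fit()
            edf = float(np.sum(res.edf))
        except PerfectSeparationError:
            # the smooth interpolates the data; the penalty is inactive, so
            # the unpenalized fit on the same design is the limit solution
            res, edf = _fit_glm(y, ds, family)
        except Exception:
            continue
        denom = max(n - edf, 1e-8)
        gcv = n * res.deviance / denom**2
        if best is None or gcv < best[0]:
            best = (gcv, res, edf)
    if best is None:
        raise RuntimeError("no alpha in the GCV grid produced a fit")
    return best[1], best[2]


def _predict_with_se(res, Xg: np.ndarray):
    """Predicted mean and variance on the log link, delta-method to counts."""
    beta = np.asarray(res.params)
    V = np.asarray(res.cov_params())
    eta = Xg @ beta
    var_eta = np.einsum("ij,jk,ik->i", Xg, V, Xg)
    mu = np.exp(eta)
    return mu, mu**2 * np.clip(var_eta, 0.0, None)


def _negbin_fit(y, ds: _Dataset, config: TrendModelConfig, penalized: bool):
    """Profile the negative-binomial dispersion over a grid by likelihood."""
    best = None
    for alpha in config.negbin_alpha_grid:
        fam = sm.families.NegativeBinomial(alpha=alpha)
        try:
            if penalized:
                res, edf = _fit_gam_gcv(y, ds, fam, config.alpha_grid)
            else:
                res, edf = _fit_glm(y, ds, fam)
        except Exception:
            continue
        if not np.isfinite(res.llf):
            continue
        if best is None or res.llf > best[0]:
            best = (res.llf, res, edf)
    if best is None:
        raise RuntimeError("negative-binomial fit failed for every dispersion")
    return best[1], best[2] + 1.0  # +1 edf for the profiled dispersion


def fit_replicate(
    values: np.ndarray,
    dataset: _Dataset | Sequence[HistoricalSeries],
    config: TrendModelConfig | None = None,
    family: str = "poisson",
):
    """Fit one replicate; return (mu, var, aic) on the unit x year grid.

    mu and var are flat arrays over the dataset's grid rows (unit-major).
    AIC uses the effective degrees of freedom of the penalized smooth so
    Poisson / negative-binomial comparisons are well defined.
    """
    config = config or TrendModelConfig()
    ds = dataset if isinstance(dataset, _Dataset) else build_dataset(dataset, config)
    y = np.asarray(values, float)
    penalized = ds.df_rule_used == "gcv"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if family == "poisson":
            fam = sm.families.Poisson()
            if penalized:
                res, edf = _fit_gam_gcv(y, ds, fam, config.alpha_grid)
            else:
                res, edf = _fit_glm(y, ds, fam)
        elif family == "negbin":
            res, edf = _negbin_fit(y, ds, config, penalized)
        else:
            raise ValueError(f"unknown family {family!r}")
    if not np.all(np.isfinite(res.params)):
        raise RuntimeError("non-finite parameters")
    aic = -2.0 * res.llf + 2.0 * edf
    mu, var = _predict_with_se(res, ds.Xg)
    if not np.all(np.isfinite(mu)):
        raise RuntimeError("non-finite predictions")
    return mu, var, float(aic)


def select_family(
    replicates: ReplicateSet,
    config: TrendModelConfig | None = None,
    dataset: _Dataset | None = None,
) -> tuple[str, float, list]:
    """Choose Poisson vs negative binomial by AIC majority across replicates.

    Returns (family, fraction of replicates won, per-replicate fits for the
    winning family).  Ties go to the negative binomial, the more
    conservative family; replicates where a fit fails count toward neither.
    """
    config = config or TrendModelConfig()
    ds = dataset or build_dataset(replicates.records, config)
    wins = {"poisson": 0, "negbin": 0}
    fits = {"poisson": [], "negbin": []}
    for r in range(replicates.n_replicates):
        y = replicates.draws[r]
        row = {}
        for fam in ("poisson", "negbin"):
            try:
                row[fam] = fit_replicate(y, ds, config, family=fam)
            except Exception:
                row[fam] = None
        fits["poisson"].append(row["poisson"])
        fits["negbin"].append(row["negbin"])
        if row["poisson"] is not None and row["negbin"] is not None:
            if row["poisson"][2] < row["negbin"][2]:
                wins["poisson"] += 1
            else:
                wins["negbin"] += 1
    decided = wins["poisson"] + wins["negbin"]
    if decided == 0:
        raise RuntimeError("family selection: every replicate failed")
    family = "negbin" if wins["negbin"] >= wins["poisson"] else "poisson"
    return family, wins[family] / decided, fits[family]


# ---------------------------------------------------------------------------
# Stage 2b: prediction resampling and summaries
# ---------------------------------------------------------------------------

def resample_predictions(
    fits: Sequence, dataset: _Dataset, seed: int
) -> tuple[np.ndarray, int, int]:
    """Second Monte Carlo stage: redraw each aggregated annual prediction.

    Per replicate and year the unit predictions are summed (variance = sum
    of unit variances) and one Normal(total, sqrt(var)) draw is taken, so
    the output series carry model error on top of estimate error.  Negative
    draws are truncated at 0.  Returns (series array, n failed replicates,
    n truncated draws).
    """
    T = len(dataset.grid_years)
    rng = np.random.default_rng(seed)
    rows = []
    n_failed = 0
    for fit in fits:
        if fit is None:
            n_failed += 1
            continue
        mu, var, _ = fit
        tot = np.bincount(
            np.searchsorted(dataset.grid_years, dataset.grid_year), mu, minlength=T
        )
        tvar = np.bincount(
            np.searchsorted(dataset.grid_years, dataset.grid_year), var, minlength=T
        )
        rows.append(tot + np.sqrt(tvar) * rng.standard_normal(T))
    if not rows:
        raise RuntimeError("all replicates failed to fit")
    series = np.array(rows)
    n_trunc = int(np.sum(series < 0))
    np.clip(series, 0.0, None, out=series)
    if n_failed:
        logger.warning("resample_predictions: %d replicates failed", n_failed)
    if n_trunc:
        logger.info("resample_predictions: truncated %d negative draws", n_trunc)
    return series, n_failed, n_trunc


def growth_rate(
    result: TrendResult, start_year: int, end_year: int | None = None
) -> tuple[float, tuple[float, float]]:
    """Exponential growth rate r over [start_year, end_year].

    Per replicate, r is the OLS slope of log population on year; the point
    estimate is the mean over replicates and the CI the empirical 2.5/97.5
    percentiles.  Replicates containing a zero population in the window are
    excluded (log undefined) with a logged count.
    """
    years = result.years
    end_year = int(years[-1]) if end_year is None else end_year
    if not (years[0] <= start_year < end_year <= years[-1]):
        raise ValueError("requested window outside the predicted range")
    mask = (years >= start_year) & (years <= end_year)
    yr = years[mask]
    block = result.predicted[:, mask]
    ok = np.all(block > 0, axis=1)
    n_excluded = int(np.sum(~ok))
    if n_excluded:
        logger.info("growth_rate: excluded %d replicates with zero population",
                    n_excluded)
    if not np.any(ok):
        raise ValueError("no replicate has positive populations in the window")
    logp = np.log(block[ok])
    xc = yr - yr.mean()
    slopes = logp @ xc / (xc @ xc)
    r_mean = float(slopes.mean())
    lo, hi = np.percentile(slopes, [2.5, 97.5])
    return r_mean, (float(lo), float(hi))


def population_change(
    result: TrendResult, year1: int, year2: int
) -> tuple[float, float, float]:
    """(delta, SE, per-year rate) of predicted population from year1 to year2."""
    years = list(result.years)
    if year1 not in years or year2 not in years:
        raise ValueError("both years must be inside the predicted range")
    i1, i2 = years.index(year1), years.index(year2)
    delta = result.predicted[:, i2] - result.predicted[:, i1]
    return (float(delta.mean()), float(delta.std(ddof=1)),
            float(delta.mean() / (year2 - year1)))


def halving_time(r: float) -> float:
    """Years for a population declining at rate r < 0 to halve: ln 2 / |r|."""
    if r >= 0:
        raise ValueError("halving time requires r < 0")
    return math.log(2.0) / abs(r)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def estimate_trend(
    series: Sequence[HistoricalSeries],
    R: int = 1000,
    seed: int = 0,
    config: TrendModelConfig | None = None,
    start_years: Sequence[int] = (1995, 2005, 2010),
) -> TrendResult:
    """Run the full two-stage Monte Carlo trend pipeline on one dataset."""
    config = config or TrendModelConfig()
    ss = np.random.SeedSequence(seed)
    s1, s2 = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    reps = make_replicates(series, R, s1)
    ds = build_dataset(reps.records, config)

    if config.family_rule == "aic_majority":
        family, fraction, fits = select_family(reps, config, ds)
    else:
        family = "poisson" if config.family_rule == "force_poisson" else "negbin"
        fraction = 1.0
        fits = []
        for r in range(R):
            try:
                fits.append(fit_replicate(reps.draws[r], ds, config, family))
            except Exception:
                fits.append(None)

    predicted, n_failed, _ = resample_predictions(fits, ds, s2)
    annual_mean = predicted.mean(axis=0)
    annual_sd = predicted.std(axis=0, ddof=1)
    annual_ci = np.percentile(predicted, [2.5, 97.5], axis=0)
    result = TrendResult(
        years=ds.grid_years, predicted=predicted, annual_mean=annual_mean,
        annual_sd=annual_sd, annual_ci95=annual_ci, family=family,
        family_fraction=fraction, n_failed=n_failed,
        df_rule_used=ds.df_rule_used,
    )
    first = int(ds.grid_years[0])
    for start in start_years:
        s = max(start, first)
        if s < config.end_year:
            result.growth_rates[start] = growth_rate(result, s, config.end_year)
    return result


def plot_trend(result: TrendResult, path) -> None:
    """Band chart of the predicted series: mean, +/-1 SD, and 95% CI."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    y = result.years
    ax.fill_between(y, result.annual_ci95[0], result.annual_ci95[1],
                    color="0.85", label="95% CI")
    ax.fill_between(y, result.annual_mean - result.annual_sd,
                    result.annual_mean + result.annual_sd,
                    color="0.6", label="±1 SD")
    ax.plot(y, result.annual_mean, "k-", label="mean")
    ax.set_xlabel("Year")
    ax.set_ylabel("Estimated population")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
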