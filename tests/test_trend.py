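import math

import numpy as np
import pytest

from gecpop.survey_data import HistoricalSeries
from gecpop.synthetic_data import SimConfig, simulate_history
from gecpop.trend import (
    TrendModelConfig,
    TrendResult,
    build_dataset,
    estimate_trend,
    fit_replicate,
    growth_rate,
    halving_time,
    impute_se,
    make_replicates,
    observation_weights,
    population_change,
    resample_predictions,
    select_family,
)


def _series(unit, points, country="C", method="sample"):
    return [
        HistoricalSeries(unit, country, y, float(e),
                         None if se is None else float(se), method)
        for y, e, se in points
    ]


# ---------------------------------------------------------------------------
# SE imputation
# ---------------------------------------------------------------------------

def test_impute_se_recovers_noiseless_power_law():
    est = np.array([100.0, 300.0, 1000.0, 3000.0, 10000.0])
    var = 2.0 * est**1.8
    ses, fit = impute_se(list(zip(est, var)), [500.0, 2000.0])
    assert fit.slope == pytest.approx(1.8, abs=1e-10)
    assert fit.intercept == pytest.approx(math.log(2.0), abs=1e-10)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
    assert ses[0] == pytest.approx(math.sqrt(2.0 * 500**1.8), rel=1e-10)


def test_impute_se_matches_closed_form_ols():
    rng = np.random.default_rng(2)
    est = np.array([120.0, 450.0, 900.0, 2300.0, 8000.0])
    var = 1.5 * est**1.6 * np.exp(rng.normal(0, 0.3, 5))
    _, fit = impute_se(list(zip(est, var)), [])
    x, yv = np.log(est), np.log(var)
    slope = np.sum((x - x.mean()) * (yv - yv.mean())) / np.sum((x - x.mean()) ** 2)
    intercept = yv.mean() - slope * x.mean()
    assert fit.slope == pytest.approx(slope, abs=1e-8)
    assert fit.intercept == pytest.approx(intercept, abs=1e-8)


def test_impute_se_excludes_nonpositive_points():
    known = [(100.0, 200.0), (300.0, 900.0), (1000.0, 4000.0), (0.0, 5.0),
             (50.0, -1.0)]
    _, fit = impute_se(known, [])
    assert fit.n_points == 3
    with pytest.raises(ValueError):
        impute_se([(100.0, 200.0), (0.0, 1.0), (-5.0, 2.0)], [])


# ---------------------------------------------------------------------------
# Replicate generation
# ---------------------------------------------------------------------------

def test_total_counts_reproduced_exactly():
    series = _series("u1", [(2010, 743, 0), (2014, 743, 0)], method="total")
    reps = make_replicates(series, R=50, seed=1)
    assert np.all(reps.draws == 743.0)


def test_replicate_mean_within_monte_carlo_error():
    series = _series("u1", [(2010, 1000, 100), (2014, 900, 90)])
    reps = make_replicates(series, R=10_000, seed=3)
    # MC SE of the mean is 100 / sqrt(10,000) = 1
    assert reps.draws[:, 0].mean() == pytest.approx(1000.0, abs=3.0)


def test_single_replicate_shape_and_errors():
    series = _series("u1", [(2010, 100, 10), (2014, 90, 9)])
    reps = make_replicates(series, R=1, seed=0)
    assert reps.draws.shape == (1, 2)
    with pytest.raises(ValueError):
        make_replicates(series, R=0, seed=0)


def test_replicates_are_seed_deterministic():
    series = _series("u1", [(2010, 100, 10), (2014, 90, 9)])
    a = make_replicates(series, R=20, seed=5).draws
    b = make_replicates(series, R=20, seed=5).draws
    assert np.array_equal(a, b)


def test_missing_se_is_imputed_before_drawing():
    series = _series("u1", [
        (2000, 100, 20), (2004, 400, 50), (2008, 1600, 130),
        (2012, 800, None), (2014, 600, 70),
    ])
    reps = make_replicates(series, R=200, seed=7)
    filled = [r.se for r in reps.records]
    assert all(se is not None and se > 0 for se in filled)
    # the imputed column actually varies across replicates
    assert reps.draws[:, 3].std() > 0


# ---------------------------------------------------------------------------
# Per-replicate fits
# ---------------------------------------------------------------------------

def test_two_point_dataset_log_linear_interpolation():
    series = _series("u1", [(2005, 400, 0), (2014, 200, 0)], method="total")
    config = TrendModelConfig()
    ds = build_dataset(series, config)
    mu, var, _ = fit_replicate(np.array([400.0, 200.0]), ds, config)
    idx = list(ds.grid_years).index(2010)
    expected = 400.0 * (200.0 / 400.0) ** ((2010 - 2005) / 9)
    assert mu[idx] == pytest.approx(expected, rel=1e-6)
    assert mu[0] == pytest.approx(400.0, rel=1e-6)
    assert mu[-1] == pytest.approx(200.0, rel=1e-6)


def test_smooth_recovers_log_linear_signal():
    years = list(range(1995, 2005))
    series = _series("u1", [(y, 100 * math.exp(0.05 * (y - 1995)), 1.0)
                            for y in years])
    config = TrendModelConfig(end_year=2004, family_rule="force_poisson")
    ds = build_dataset(series, config)
    values = np.array([r.estimate for r in series])
    mu, _, _ = fit_replicate(values, ds, config)
    curve = 100 * np.exp(0.05 * (ds.grid_years - 1995))
    assert np.allclose(mu, curve, rtol=0.01)


def test_observation_weights_are_mean_normalized():
    series = _series("a", [(2010, 100, 5), (2014, 100, 5)]) + \
        _series("b", [(2010, 300, 5), (2014, 300, 5)])
    w = observation_weights(series)
    assert w == {"a": pytest.approx(0.5), "b": pytest.approx(1.5)}


def test_family_selection_prefers_negbin_for_overdispersed_counts():
    rng = np.random.default_rng(21)
    years = list(range(1995, 2015, 2))
    records = []
    for u in range(3):
        base = 500.0 * (u + 1)
        for y in years:
            # variance ~ 20x the mean: strongly overdispersed
            obs = max(rng.normal(base, math.sqrt(20 * base)), 1.0)
            records.append(HistoricalSeries(f"u{u}", "C", y, obs,
                                            math.sqrt(20 * base), "sample"))
    config = TrendModelConfig(df_rule="fixed")
    reps = make_replicates(records, R=30, seed=4)
    family, fraction, _ = select_family(reps, config)
    assert family == "negbin"
    assert fraction >= 0.95


def test_family_selection_prefers_poisson_for_equidispersed_counts():
    # total counts (SE = 0) so the replicates reproduce the Poisson counts
    # exactly; sample-count SEs would add dispersion on top of the counts
    rng = np.random.default_rng(22)
    years = list(range(1995, 2015, 2))
    records = []
    for u in range(3):
        base = 400.0 * (u + 1)
        for y in years:
            obs = float(rng.poisson(base))
            records.append(HistoricalSeries(f"u{u}", "C", y, obs, 0.0, "total"))
    config = TrendModelConfig(df_rule="fixed")
    reps = make_replicates(records, R=30, seed=8)
    family, fraction, _ = select_family(reps, config)
    assert family == "poisson"
    assert fraction > 0.5


# ---------------------------------------------------------------------------
# Prediction resampling and summaries
# ---------------------------------------------------------------------------

def _toy_dataset():
    series = _series("u1", [(2010, 100, 5), (2012, 90, 5), (2014, 80, 5)])
    return build_dataset(series, TrendModelConfig())


def test_zero_prediction_se_returns_fitted_series_exactly():
    ds = _toy_dataset()
    mu = np.linspace(100, 80, len(ds.grid_years))
    fits = [(mu, np.zeros_like(mu), 0.0)] * 5
    series, n_failed, _ = resample_predictions(fits, ds, seed=3)
    assert n_failed == 0
    assert np.allclose(series, mu[None, :])


def test_resampling_is_seed_deterministic():
    ds = _toy_dataset()
    mu = np.linspace(100, 80, len(ds.grid_years))
    fits = [(mu, np.full_like(mu, 25.0), 0.0)] * 4
    a, _, _ = resample_predictions(fits, ds, seed=11)
    b, _, _ = resample_predictions(fits, ds, seed=11)
    c, _, _ = resample_predictions(fits, ds, seed=12)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


def test_stage_two_adds_dispersion():
    ds = _toy_dataset()
    rng = np.random.default_rng(13)
    R = 1000
    fits = []
    stage1 = []
    for _ in range(R):
        mu = np.linspace(100, 80, len(ds.grid_years)) * rng.uniform(0.9, 1.1)
        fits.append((mu, np.full_like(mu, 16.0), 0.0))
        stage1.append(mu)
    final, _, _ = resample_predictions(fits, ds, seed=14)
    stage1 = np.array(stage1)
    assert np.all(final.std(axis=0) >= stage1.std(axis=0))


def test_failed_replicates_are_counted_and_excluded():
    ds = _toy_dataset()
    mu = np.linspace(100, 80, len(ds.grid_years))
    fits = [(mu, np.zeros_like(mu), 0.0), None, (mu, np.zeros_like(mu), 0.0)]
    series, n_failed, _ = resample_predictions(fits, ds, seed=0)
    assert n_failed == 1 and series.shape[0] == 2


def _result_from_series(series_2d, first_year=2000):
    arr = np.asarray(series_2d, float)
    years = np.arange(first_year, first_year + arr.shape[1])
    return TrendResult(
        years=years, predicted=arr, annual_mean=arr.mean(axis=0),
        annual_sd=arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(arr.shape[1]),
        annual_ci95=np.percentile(arr, [2.5, 97.5], axis=0),
    )


def test_growth_rate_constant_series_is_zero():
    res = _result_from_series(np.full((20, 10), 500.0))
    r, (lo, hi) = growth_rate(res, 2000, 2009)
    assert r == 0.0 and lo == 0.0 and hi == 0.0


def test_growth_rate_exponential_closed_form():
    years = np.arange(2000, 2011)
    series = 1000 * np.exp(0.05 * (years - 2000))
    res = _result_from_series(np.tile(series, (10, 1)))
    r, _ = growth_rate(res, 2000, 2010)
    assert r == pytest.approx(0.05, abs=1e-12)


def test_growth_rate_excludes_zero_replicates():
    years = np.arange(2000, 2006)
    good = 100 * np.exp(-0.1 * (years - 2000))
    bad = good.copy()
    bad[3] = 0.0
    res = _result_from_series(np.vstack([good, good, bad]))
    r, _ = growth_rate(res, 2000, 2005)
    assert r == pytest.approx(-0.1, abs=1e-12)


def test_growth_rate_window_validation():
    res = _result_from_series(np.full((3, 5), 10.0))
    with pytest.raises(ValueError):
        growth_rate(res, 1990, 2004)
    with pytest.raises(ValueError):
        growth_rate(res, 2004, 2004)


def test_population_change_closed_forms():
    res = _result_from_series(np.full((5, 8), 120.0))
    delta, se, rate = population_change(res, 2000, 2007)
    assert delta == 0.0 and rate == 0.0

    years = np.arange(2000, 2008)
    series = 1000 * np.exp(-0.1 * (years - 2000))
    res2 = _result_from_series(np.tile(series, (5, 1)))
    delta2, _, rate2 = population_change(res2, 2000, 2007)
    expected = 1000 * (math.exp(-0.7) - 1)
    assert delta2 == pytest.approx(expected, rel=1e-12)
    assert rate2 == pytest.approx(expected / 7, rel=1e-12)


@pytest.mark.parametrize(
    "r, expected",
    [(-0.078, 8.886), (-math.log(2), 1.0), (-0.01, 69.31)],
)
def test_halving_time(r, expected):
    assert halving_time(r) == pytest.approx(expected, abs=5e-3)


def test_halving_time_requires_decline():
    with pytest.raises(ValueError):
        halving_time(0.05)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def test_pipeline_is_bit_deterministic():
    series, _ = simulate_history(SimConfig(trend_r=-0.05, seed=31),
                                 [1995, 2000, 2005, 2010, 2014])
    config = TrendModelConfig(family_rule="force_poisson")
    a = estimate_trend(series, R=40, seed=9, config=config)
    b = estimate_trend(series, R=40, seed=9, config=config)
    assert np.array_equal(a.predicted, b.predicted)
    assert a.growth_rates == b.growth_rates


def test_ci_bands_are_nested():
    series, _ = simulate_history(SimConfig(trend_r=-0.03, seed=33),
                                 [1995, 2000, 2005, 2010, 2014])
    res = estimate_trend(series, R=100, seed=2,
                         config=TrendModelConfig(family_rule="force_poisson"))
    lo_sd = res.annual_mean - res.annual_sd
    hi_sd = res.annual_mean + res.annual_sd
    assert np.all(res.annual_ci95[0] <= lo_sd + 1e-9)
    assert np.all(hi_sd <= res.annual_ci95[1] + 1e-9)


def test_doubling_a_stratum_mean_doubles_its_weight():
    years = [2006, 2010, 2014]
    a = _series("a", [(y, 200.0, 10) for y in years])
    b1 = _series("b", [(y, 300.0, 10) for y in years])
    b2 = _series("b", [(y, 600.0, 10) for y in years])
    w1 = observation_weights(a + b1)
    w2 = observation_weights(a + b2)
    assert w2["b"] / w2["a"] == pytest.approx(2 * w1["b"] / w1["a"], rel=1e-12)


def test_aggregate_trend_follows_heavier_stratum():
    # two units with opposing trends; whichever carries the larger mean
    # population (hence the larger weight) dominates the aggregate trend
    years = [1995, 1999, 2003, 2007, 2011, 2014]

    def up(base):
        return _series("up", [(y, base * math.exp(0.04 * (y - 1995)), 30)
                              for y in years])

    def down(base):
        return _series("down", [(y, base * math.exp(-0.06 * (y - 1995)), 40)
                                for y in years])

    config = TrendModelConfig(family_rule="force_poisson")
    heavy_down = up(1000) + down(5200)
    w = observation_weights(heavy_down)
    assert w["down"] > 1.8 * w["up"]
    r_down, _ = estimate_trend(heavy_down, R=60, seed=17, config=config,
                               start_years=(1995,)).growth_rates[1995]
    heavy_up = up(4000) + down(1300)
    r_up, _ = estimate_trend(heavy_up, R=60, seed=17, config=config,
                             start_years=(1995,)).growth_rates[1995]
    assert r_down < 0 < r_up
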