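"""Synthetic survey and historical-series generators with known ground truth.

Every estimator in this package is validated against data whose generating
values are known exactly.  Two generators emulate the census inputs:

* simulate_survey builds one stratum as a rectangle, scatters herds (herd
  sizes lognormal, locations uniform) plus carcass points, and overlays
  parallel equal-width strips of unequal lengths covering a target fraction
  of the area.  Transect counts are herd-size sums over strip membership, so
  the expected count on a strip is density x strip area and the ratio
  estimator is unbiased by construction, while herd clustering produces the
  overdispersion real counts show.

* simulate_history draws multi-year estimate series around a (piecewise)
  exponential latent trend, with observation variance following a power law
  of population size — the same law the SE-imputation regression assumes.

All generators are seed-deterministic and return a machine-readable truth
record alongside the data.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .survey_data import HistoricalSeries, Stratum, Transect

__all__ = ["SimConfig", "simulate_survey", "simulate_history"]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings emulating census-like survey conditions.

    Defaults reflect typical survey conditions: strata of roughly 2,000 km2,
    densities near 0.4 animals km-2, strip samples covering 5-20% of a
    stratum (default 15%), herds of ~8 animals with lognormal size spread,
    and an all-carcass fraction of 10% of abundance with 1% fresh.
    trend_r is either a single per-year exponential rate or a
    (rate_before, breakpoint_year, rate_after) triple.
    """

    stratum_area: float = 2000.0
    true_abundance: int = 800
    mean_herd_size: float = 8.0
    herd_size_dispersion: float = 0.75   # SD of log herd size
    n_transects: int = 40
    sampling_fraction: float = 0.15
    carcass_fraction: float = 0.10
    fresh_fraction: float = 0.01
    trend_r: float | tuple = -0.05
    noise_power_coeff: float = 0.09
    noise_power_exp: float = 1.8
    n_units: int = 3
    se_missing_fraction: float = 0.0
    total_count_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.sampling_fraction <= 1):
            raise ValueError("sampling_fraction must be in (0, 1]")
        if not (0 <= self.carcass_fraction < 1):
            raise ValueError("carcass_fraction must be in [0, 1)")
        if self.fresh_fraction > self.carcass_fraction:
            raise ValueError("fresh_fraction must be <= carcass_fraction")
        if self.stratum_area <= 0 or self.true_abundance < 0:
            raise ValueError("need stratum_area > 0 and true_abundance >= 0")
        if self.n_transects < 1:
            raise ValueError("need at least one transect")


def _herd_sizes(rng, total: int, mean: float, log_sd: float) -> np.ndarray:
    """Integer herd sizes summing exactly to total."""
    if total == 0:
        return np.zeros(0, int)
    mu = math.log(mean) - 0.5 * log_sd**2
    sizes: list[int] = []
    acc = 0
    while acc < total:
        s = max(1, int(round(rng.lognormal(mu, log_sd))))
        s = min(s, total - acc)
        sizes.append(s)
        acc += s
    return np.asarray(sizes, int)


def simulate_survey(
    config: SimConfig, stratum_id: str = "S1", ecosystem_id: str = "E1",
    country: str = "Simland", protected: bool = True, seed: int | None = None,
) -> tuple[Stratum, list[Transect], dict]:
    """Simulate one stratum survey; returns (stratum, transects, truth).

    The stratum is a square of the configured area.  Strips are parallel,
    equal-width, non-overlapping, with unequal lengths (uniform between half
    and full stratum height), scaled so total sampled area equals
    sampling_fraction x area; at sampling_fraction = 1 the strips tile the
    stratum exactly and the counts sum to the true abundance.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    A = config.stratum_area
    side = math.sqrt(A)
    L = W = side
    n = config.n_transects
    f = config.sampling_fraction

    census = f >= 1.0 - 1e-12
    if census:
        lengths = np.full(n, W)
    else:
        lengths = W * rng.uniform(0.5, 1.0, n)
    width = f * A / lengths.sum()
    slot = L / n
    if width > slot * (1 + 1e-9):
        raise ValueError(
            "strips would overlap: sampling_fraction too high for "
            f"{n} transects of these lengths"
        )
    if width * lengths.min() <= 0:
        raise ValueError("sampled area per strip must be positive")
    x0 = np.arange(n) * slot
    x1 = x0 + width
    if census:
        x1[-1] = L  # close the tiling against float round-off

    def strip_counts(px: np.ndarray, py: np.ndarray, w: np.ndarray) -> np.ndarray:
        counts = np.zeros(n)
        if len(px) == 0:
            return counts
        idx = np.minimum((px / slot).astype(int), n - 1)
        inside = (px - x0[idx] < width) | (census & (px >= x0[-1]))
        inside &= py <= lengths[idx]
        np.add.at(counts, idx[inside], w[inside])
        return counts

    sizes = _herd_sizes(rng, config.true_abundance, config.mean_herd_size,
                        config.herd_size_dispersion)
    hx = rng.uniform(0, L, len(sizes))
    hy = rng.uniform(0, W, len(sizes))
    live = strip_counts(hx, hy, sizes.astype(float))

    n_carc = int(round(config.carcass_fraction * config.true_abundance))
    n_fresh = int(round(config.fresh_fraction * config.true_abundance))
    cx = rng.uniform(0, L, n_carc)
    cy = rng.uniform(0, W, n_carc)
    fresh_mask = np.zeros(n_carc, bool)
    fresh_mask[:n_fresh] = True
    fresh = strip_counts(cx, cy, fresh_mask.astype(float))
    old = strip_counts(cx, cy, (~fresh_mask).astype(float))

    stratum = Stratum(
        stratum_id=stratum_id, ecosystem_id=ecosystem_id, country=country,
        area=A, method="sample", protected=protected, survey_year=2014,
    )
    transects = [
        Transect(
            transect_id=f"{stratum_id}-T{i+1}", stratum_id=stratum_id,
            sampled_area=float(width * lengths[i]),
            live_count=int(live[i]),
            fresh_carcass_count=int(fresh[i]),
            old_carcass_count=int(old[i]),
        )
        for i in range(n)
    ]
    truth = {
        "true_abundance": config.true_abundance,
        "true_density": config.true_abundance / A,
        "n_carcasses": n_carc,
        "n_fresh_carcasses": n_fresh,
        "sampling_fraction": f,
        "n_herds": int(len(sizes)),
        "config": dataclasses.asdict(config),
    }
    return stratum, transects, truth


def _latent_population(n0: float, years: np.ndarray, trend_r) -> np.ndarray:
    if isinstance(trend_r, (tuple, list)):
        r1, brk, r2 = trend_r
        out = np.where(
            years <= brk,
            n0 * np.exp(r1 * (years - years[0])),
            n0 * math.exp(r1 * (brk - years[0])) * np.exp(r2 * (years - brk)),
        )
        return out
    return n0 * np.exp(float(trend_r) * (years - years[0]))


def simulate_history(
    config: SimConfig, years: Sequence[int], country: str = "Simland",
    seed: int | None = None,
) -> tuple[list[HistoricalSeries], dict]:
    """Simulate multi-year estimate series for n_units strata with truth.

    Latent populations follow the (piecewise) exponential trend from a
    per-unit starting size; observed estimates are normal around the latent
    truth with variance = noise_power_coeff * N ** noise_power_exp, the
    reported SE being the true sampling SD.  A se_missing_fraction of
    sample-count records has the SE withheld (for imputation tests) and a
    total_count_fraction is marked as complete counts with SE 0.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    yr = np.asarray(sorted(years), float)
    records: list[HistoricalSeries] = []
    latents = {}
    for u in range(config.n_units):
        # spread unit sizes around the configured abundance
        n0 = config.true_abundance * rng.uniform(0.5, 1.5)
        latent = _latent_population(n0, yr, config.trend_r)
        latents[f"U{u+1}"] = latent.tolist()
        sd = np.sqrt(config.noise_power_coeff * latent**config.noise_power_exp)
        is_total = rng.random(len(yr)) < config.total_count_fraction
        sd = np.where(is_total, 0.0, sd)
        obs = np.clip(latent + sd * rng.standard_normal(len(yr)), 0.0, None)
        obs = np.where(is_total, latent, obs)
        hide = (rng.random(len(yr)) < config.se_missing_fraction) & ~is_total
        for j, year in enumerate(yr):
            records.append(HistoricalSeries(
                unit_id=f"U{u+1}", country=country, year=int(year),
                estimate=float(obs[j]),
                se=None if hide[j] else float(sd[j]),
                method="total" if is_total[j] else "sample",
            ))
    truth = {
        "latent": latents,
        "years": [int(y) for y in yr],
        "trend_r": config.trend_r if not isinstance(config.trend_r, tuple)
        else list(config.trend_r),
        "noise_power_coeff": config.noise_power_coeff,
        "noise_power_exp": config.noise_power_exp,
        "config": dataclasses.asdict(config),
    }
    return records, truth
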