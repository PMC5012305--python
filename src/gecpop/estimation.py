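"""Ratio-estimator abundance estimation and hierarchical aggregation.

For a sample-count stratum of area A surveyed with n transects of unequal
sampled areas a_i carrying counts y_i, density and abundance are estimated by

    d-hat   = sum(y_i) / sum(a_i)
    Y-hat   = A * d-hat
    var(Y-hat) = N (N - n) / n * (s_y^2 - 2 d-hat s_ay + d-hat^2 s_a^2)

where N = A / a-bar is the number of transects that would tile the stratum and
s_y^2, s_ay, s_a^2 are the sample variance of counts, the count-area
covariance, and the variance of sampled areas (n-1 denominators).  Total-count
strata carry their observed count with variance 0.  Aggregates at any level
sum estimates and variances; 95% intervals use standard-normal percentiles.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .survey_data import (
    AggregateEstimate,
    Stratum,
    StratumEstimate,
    Transect,
    ValidationError,
)

logger = logging.getLogger("gecpop")

#: Exact normal 97.5th percentile used for all 95% intervals (not 1.96).
Z975: float = float(stats.norm.ppf(0.975))

__all__ = ["Z975", "estimate_stratum", "aggregate", "density", "estimate_survey"]


def estimate_stratum(
    stratum: Stratum,
    transects: Sequence[Transect],
    count_field: str = "live",
) -> StratumEstimate:
    """Estimate abundance for one stratum from its transects.

    count_field selects live animals, all carcasses, or fresh carcasses;
    carcasses use the same estimator as live animals.  A single-transect
    sample stratum has no defined variance; it is reported as 0 with a
    logged warning.  A negative variance bracket (possible in finite
    samples with strong positive count-area covariance) is floored at 0.
    """
    mine = [t for t in transects if t.stratum_id == stratum.stratum_id]
    counts = []
    for t in mine:
        c = t.count(count_field)
        if c is None:
            raise ValidationError(
                f"stratum {stratum.stratum_id!r}: transect {t.transect_id!r} "
                f"is missing {count_field} counts"
            )
        counts.append(float(c))
    y = np.asarray(counts, dtype=float)
    a = np.asarray([t.sampled_area for t in mine], dtype=float)
    n = len(mine)

    if stratum.method == "total":
        total = float(y.sum()) if n else 0.0
        return StratumEstimate(
            stratum_id=stratum.stratum_id, estimate=total, variance=0.0,
            density=total / stratum.area, n_transects=n,
            n_possible=float(n), count_field=count_field,
        )

    if n == 0:
        raise ValidationError(
            f"stratum {stratum.stratum_id!r}: sample-count stratum has no transects"
        )
    if a.sum() > stratum.area * (1 + 1e-9):
        raise ValidationError(
            f"stratum {stratum.stratum_id!r}: sampled area {a.sum():.6g} "
            f"exceeds stratum area {stratum.area:.6g}"
        )

    d_hat = float(y.sum() / a.sum())
    y_hat = stratum.area * d_hat
    n_possible = stratum.area / float(a.mean())

    if n == 1:
        logger.warning(
            "stratum %r: single transect, variance undefined; reporting 0",
            stratum.stratum_id,
        )
        variance = 0.0
    else:
        s_y2 = float(np.var(y, ddof=1))
        s_a2 = float(np.var(a, ddof=1))
        s_ay = float(np.cov(a, y, ddof=1)[0, 1])
        bracket = s_y2 - 2.0 * d_hat * s_ay + d_hat**2 * s_a2
        variance = n_possible * (n_possible - n) / n * bracket
        if variance < 0:
            logger.warning(
                "stratum %r: negative variance bracket (%.6g); flooring at 0",
                stratum.stratum_id, variance,
            )
            variance = 0.0

    return StratumEstimate(
        stratum_id=stratum.stratum_id, estimate=y_hat, variance=variance,
        density=y_hat / stratum.area, n_transects=n, n_possible=n_possible,
        count_field=count_field,
    )


def aggregate(
    estimates: Iterable[StratumEstimate | AggregateEstimate | tuple],
    level: str = "survey",
    z: float = Z975,
    unit_id: str = "",
) -> AggregateEstimate:
    """Sum estimates and variances into one aggregate with a normal 95% CI.

    Accepts StratumEstimate or AggregateEstimate objects, or plain
    (estimate, variance) pairs.  Aggregation is associative: summing strata
    directly equals summing intermediate ecosystem aggregates.
    """
    items = list(estimates)
    if not items:
        raise ValueError("cannot aggregate an empty list of estimates")
    total = 0.0
    var = 0.0
    for item in items:
        if isinstance(item, StratumEstimate):
            total += item.estimate
            var += item.variance
        elif isinstance(item, AggregateEstimate):
            total += item.estimate
            var += item.se**2
        else:
            e, v = item
            total += float(e)
            var += float(v)
    se = math.sqrt(var)
    return AggregateEstimate(
        level=level, estimate=total, se=se,
        ci95=(total - z * se, total + z * se), unit_id=unit_id,
    )


def density(estimate: AggregateEstimate | float, area: float) -> float:
    """Animals per km2 over the area an aggregate covers."""
    if not area > 0:
        raise ValueError(f"area must be > 0, got {area}")
    value = estimate.estimate if isinstance(estimate, AggregateEstimate) else float(estimate)
    return value / area


def estimate_survey(
    strata: Sequence[Stratum],
    transects: Sequence[Transect],
    level: str = "survey",
    count_field: str = "live",
) -> list[AggregateEstimate]:
    """Estimate every stratum, then aggregate to the requested level.

    level is one of stratum, ecosystem, country, survey.  Stratum level
    returns one AggregateEstimate per stratum (pass-through of the stratum
    estimate with its own CI).
    """
    per_stratum = {
        s.stratum_id: estimate_stratum(s, transects, count_field) for s in strata
    }
    if level == "stratum":
        return [
            aggregate([per_stratum[s.stratum_id]], level="stratum",
                      unit_id=s.stratum_id)
            for s in strata
        ]
    key = {
        "ecosystem": lambda s: s.ecosystem_id,
        "country": lambda s: s.country,
        "survey": lambda s: "survey",
    }.get(level)
    if key is None:
        raise ValueError(f"unknown aggregation level {level!r}")
    groups: dict[str, list[StratumEstimate]] = {}
    for s in strata:
        groups.setdefault(key(s), []).append(per_stratum[s.stratum_id])
    return [
        aggregate(ests, level=level, unit_id=unit)
        for unit, ests in groups.items()
    ]
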