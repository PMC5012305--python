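"""Carcass-ratio estimation and the stable/declining classification heuristic.

The carcass ratio — estimated dead elephants divided by estimated live plus
dead — is a lagging index of mortality over roughly the prior four years.
Ratios below 8% are typical of stable or growing populations; higher ratios
suggest mortality in excess of births.  Carcass abundance is estimated with
the same ratio estimator as live animals; the ratio's variance is the
binomial variance p(1-p)/m deflated by the finite population correction
(1 - f), where m is the number of live-plus-dead individuals actually
observed in the region and f the fraction of the region's area sampled.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

from .estimation import estimate_stratum
from .survey_data import Stratum, Transect

logger = logging.getLogger("gecpop")

#: Carcass ratios at or above this are classified as likely declining.
DECLINE_THRESHOLD: float = 0.08

__all__ = [
    "CarcassRatio",
    "DECLINE_THRESHOLD",
    "carcass_ratio",
    "classify_ratio",
    "carcass_ratios_by",
]


@dataclass(frozen=True)
class CarcassRatio:
    """A carcass ratio for one scope (stratum/ecosystem/country/survey/...).

    ratio is None for a scope with no live or dead animals observed
    (an explicit no-data result rather than a division by zero).
    """

    scope: str
    kind: str  # "all" or "fresh"
    ratio: float | None
    se: float | None

    @property
    def defined(self) -> bool:
        return self.ratio is not None


def carcass_ratio(
    live_est: float,
    carcass_est: float,
    total_observed: float,
    sampled_fraction: float,
    kind: str = "all",
    scope: str = "",
) -> CarcassRatio:
    """Carcass ratio p = carcass / (live + carcass) with binomial-fpc SE.

    total_observed (m) is the raw observed count of live + dead individuals
    in the region — the binomial sample size — and sampled_fraction (f) the
    fraction of the region's area sampled; var = p(1-p)/m * (1-f).  A total
    count (f = 1) has zero variance.
    """
    if live_est < 0 or carcass_est < 0:
        raise ValueError("estimates must be >= 0")
    if not (0 < sampled_fraction <= 1):
        raise ValueError(f"sampled_fraction must be in (0, 1], got {sampled_fraction}")
    denom = live_est + carcass_est
    if denom == 0:
        return CarcassRatio(scope=scope, kind=kind, ratio=None, se=None)
    p = carcass_est / denom
    if total_observed <= 0:
        raise ValueError("total_observed must be > 0 when animals were estimated")
    var = p * (1.0 - p) / total_observed * (1.0 - sampled_fraction)
    return CarcassRatio(scope=scope, kind=kind, ratio=p, se=math.sqrt(var))


def classify_ratio(ratio: CarcassRatio | float) -> str:
    """Classify a ratio against the 8% rule of thumb.

    Below 8% -> "stable_or_growing"; at or above 8% -> "likely_declining"
    (the boundary is assigned to the declining side).
    """
    p = ratio.ratio if isinstance(ratio, CarcassRatio) else float(ratio)
    if p is None:
        raise ValueError("cannot classify an undefined (no-data) ratio")
    return "stable_or_growing" if p < DECLINE_THRESHOLD else "likely_declining"


def _stratum_has_carcass_data(transects: Sequence[Transect], kind: str) -> bool:
    if kind == "fresh":
        return all(t.fresh_carcass_count is not None for t in transects)
    return all(t.all_carcass_count is not None for t in transects)


def carcass_ratios_by(
    strata: Sequence[Stratum],
    transects: Sequence[Transect],
    by: str = "country",
    kind: str = "all",
) -> list[CarcassRatio]:
    """Pooled carcass ratios per scope, built from stratum-level estimates.

    by is one of stratum, ecosystem, country, protection, survey.  Pooling
    uses summed carcass and live estimates (sum-carcass / sum-(live+carcass)),
    never a mean of ratios.  Strata whose transects lack carcass counts are
    excluded from the scope with a logged notice; the scope's sampled
    fraction and observed total are computed over the included strata only.
    """
    key = {
        "stratum": lambda s: s.stratum_id,
        "ecosystem": lambda s: s.ecosystem_id,
        "country": lambda s: s.country,
        "protection": lambda s: "protected" if s.protected else "unprotected",
        "survey": lambda s: "survey",
    }.get(by)
    if key is None:
        raise ValueError(f"unknown scope {by!r}")

    count_field = "all_carcass" if kind == "all" else "fresh_carcass"
    by_stratum: dict[str, list[Transect]] = {}
    for t in transects:
        by_stratum.setdefault(t.stratum_id, []).append(t)

    groups: dict[str, list[Stratum]] = {}
    for s in strata:
        groups.setdefault(key(s), []).append(s)

    out: list[CarcassRatio] = []
    for scope, members in groups.items():
        live_total = carc_total = 0.0
        observed = 0.0
        area = sampled = 0.0
        any_included = False
        for s in members:
            ts = by_stratum.get(s.stratum_id, [])
            if not ts or not _stratum_has_carcass_data(ts, kind):
                logger.info(
                    "scope %r: stratum %r lacks %s carcass data; excluded",
                    scope, s.stratum_id, kind,
                )
                continue
            any_included = True
            live = estimate_stratum(s, ts, "live")
            carc = estimate_stratum(s, ts, count_field)
            live_total += live.estimate
            carc_total += carc.estimate
            observed += sum(t.live_count + (t.count(count_field) or 0) for t in ts)
            area += s.area
            sampled += s.area if s.method == "total" else sum(t.sampled_area for t in ts)
        if not any_included:
            out.append(CarcassRatio(scope=scope, kind=kind, ratio=None, se=None))
            continue
        frac = min(sampled / area, 1.0)
        out.append(carcass_ratio(
            live_total, carc_total, observed, frac, kind=kind, scope=scope,
        ))
    return out
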