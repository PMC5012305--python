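"""Domain types, validation, and CSV I/O for aerial-survey and historical data.

The census data model is hierarchical: transects (flown sampling units with a
sampled area and live/carcass counts) nest in strata (survey polygons with a
total area, a survey method, and a protection status), which nest in ecosystems
and countries.  Historical population estimates are per-unit, per-year records
with a standard error (blank for estimates whose SE must be imputed, zero for
complete census counts).

All files are UTF-8, comma-separated CSV with a header row; an empty field
means missing.  Areas are km2 and counts are animals throughout; no unit
inference is attempted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger("gecpop")

__all__ = [
    "Transect",
    "Stratum",
    "StratumEstimate",
    "AggregateEstimate",
    "HistoricalSeries",
    "SchemaError",
    "CrossReferenceError",
    "ValidationError",
    "read_survey",
    "write_survey",
    "read_historical",
    "write_historical",
    "sampled_area_from_strip",
]


class SchemaError(ValueError):
    """A required column is missing from an input file."""


class CrossReferenceError(ValueError):
    """A record refers to an entity that does not exist."""


class ValidationError(ValueError):
    """A field value violates a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Transect:
    """One flown sampling unit: sampled area a_i (km2) and counts y_i.

    Carcass counts may be None for ecosystems where carcasses were not
    recorded; such strata are excluded from carcass-ratio scopes downstream.
    """

    transect_id: str
    stratum_id: str
    sampled_area: float
    live_count: int
    fresh_carcass_count: int | None = None
    old_carcass_count: int | None = None

    def __post_init__(self) -> None:
        if not self.sampled_area > 0:
            raise ValidationError(
                f"transect {self.transect_id!r}: sampled_area must be > 0, "
                f"got {self.sampled_area}"
            )
        for name in ("live_count", "fresh_carcass_count", "old_carcass_count"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(
                    f"transect {self.transect_id!r}: {name} must be >= 0, got {v}"
                )

    @property
    def all_carcass_count(self) -> int | None:
        """Fresh + old carcasses, or None if either category is missing."""
        if self.fresh_carcass_count is None or self.old_carcass_count is None:
            return None
        return self.fresh_carcass_count + self.old_carcass_count

    def count(self, count_field: str) -> int | None:
        if count_field == "live":
            return self.live_count
        if count_field == "fresh_carcass":
            return self.fresh_carcass_count
        if count_field == "all_carcass":
            return self.all_carcass_count
        raise ValueError(f"unknown count_field {count_field!r}")


@dataclass(frozen=True)
class Stratum:
    """A survey polygon: total area A (km2), method, and nesting metadata.

    method is "sample" (strip transects covering a fraction of the stratum,
    extrapolated by the ratio estimator) or "total" (complete census; the
    estimate is the observed count with variance zero).
    """

    stratum_id: str
    ecosystem_id: str
    country: str
    area: float
    method: str
    protected: bool
    survey_year: int

    def __post_init__(self) -> None:
        if not self.area > 0:
            raise ValidationError(
                f"stratum {self.stratum_id!r}: area must be > 0, got {self.area}"
            )
        if self.method not in ("sample", "total"):
            raise ValidationError(
                f"stratum {self.stratum_id!r}: method must be 'sample' or "
                f"'total', got {self.method!r}"
            )


@dataclass(frozen=True)
class StratumEstimate:
    """Ratio-estimator output for one stratum and one count field.

    estimate is Y-hat (animals), density is d-hat = estimate / A
    (animals km-2), n_transects is n, and n_possible is N = A / a-bar, the
    (real-valued) number of transects that would tile the stratum.
    """

    stratum_id: str
    estimate: float
    variance: float
    density: float
    n_transects: int
    n_possible: float
    count_field: str = "live"

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValidationError("variance must be >= 0")

    @property
    def se(self) -> float:
        return math.sqrt(self.variance)


@dataclass(frozen=True)
class AggregateEstimate:
    """A summed estimate at ecosystem, country, or survey level."""

    level: str
    estimate: float
    se: float
    ci95: tuple[float, float]
    unit_id: str = ""

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValidationError("se must be >= 0")


@dataclass(frozen=True)
class HistoricalSeries:
    """One historical population estimate: (unit, year, estimate, SE, method).

    se is None when the SE was not reported and must be imputed; method
    "total" forces se = 0 (complete counts carry no sampling error).
    """

    unit_id: str
    country: str
    year: int
    estimate: float
    se: float | None
    method: str

    def __post_init__(self) -> None:
        if self.method not in ("sample", "total"):
            raise ValidationError(
                f"historical record {self.unit_id!r}/{self.year}: method must "
                f"be 'sample' or 'total', got {self.method!r}"
            )
        if self.estimate < 0:
            raise ValidationError(
                f"historical record {self.unit_id!r}/{self.year}: estimate "
                f"must be >= 0, got {self.estimate}"
            )
        if self.method == "total" and self.se not in (0, 0.0):
            raise ValidationError(
                f"historical record {self.unit_id!r}/{self.year}: total "
                f"counts must have se = 0"
            )
        if self.se is not None and self.se < 0:
            raise ValidationError("se must be >= 0")


# ---------------------------------------------------------------------------
# CSV schemas
# ---------------------------------------------------------------------------

STRATA_COLUMNS = [
    "stratum_id", "ecosystem_id", "country", "area_km2", "method",
    "protected", "survey_year",
]
TRANSECT_COLUMNS = [
    "transect_id", "stratum_id", "sampled_area_km2", "live_count",
    "fresh_carcass_count", "old_carcass_count",
]
HISTORICAL_COLUMNS = ["unit_id", "country", "year", "estimate", "se", "method"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _parse_bool(value, context: str) -> bool:
    s = str(value).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValidationError(f"{context}: cannot parse boolean from {value!r}")


def _opt_int(value, context: str) -> int | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or str(value).strip() == "":
        return None
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"{context}: expected an integer, got {value!r}")
    if f != int(f):
        raise ValidationError(f"{context}: expected an integer, got {value!r}")
    return int(f)


def read_survey(
    strata_path, transects_path
) -> tuple[list[Stratum], list[Transect]]:
    """Read and cross-validate the strata and transects CSV files.

    Every transect must reference an existing stratum; any malformed field
    raises rather than yielding a partial dataset.
    """
    sdf = pd.read_csv(strata_path, dtype=str, keep_default_na=False)
    _require_columns(sdf, STRATA_COLUMNS, strata_path)
    strata: list[Stratum] = []
    for _, row in sdf.iterrows():
        ctx = f"stratum {row['stratum_id']!r}"
        try:
            area = float(row["area_km2"])
            year = int(float(row["survey_year"]))
        except ValueError:
            raise ValidationError(f"{ctx}: non-numeric area or survey_year")
        strata.append(Stratum(
            stratum_id=row["stratum_id"],
            ecosystem_id=row["ecosystem_id"],
            country=row["country"],
            area=area,
            method=row["method"].strip().lower(),
            protected=_parse_bool(row["protected"], ctx),
            survey_year=year,
        ))
    known = {s.stratum_id for s in strata}
    if len(known) != len(strata):
        raise ValidationError(f"{strata_path}: duplicate stratum_id values")

    tdf = pd.read_csv(transects_path, dtype=str, keep_default_na=False)
    _require_columns(tdf, TRANSECT_COLUMNS, transects_path)
    transects: list[Transect] = []
    for _, row in tdf.iterrows():
        ctx = f"transect {row['transect_id']!r}"
        if row["stratum_id"] not in known:
            raise CrossReferenceError(
                f"{ctx}: references unknown stratum {row['stratum_id']!r}"
            )
        try:
            area = float(row["sampled_area_km2"])
        except ValueError:
            raise ValidationError(f"{ctx}: non-numeric sampled_area_km2")
        live = _opt_int(row["live_count"], ctx)
        if live is None:
            raise ValidationError(f"{ctx}: live_count is required")
        transects.append(Transect(
            transect_id=row["transect_id"],
            stratum_id=row["stratum_id"],
            sampled_area=area,
            live_count=live,
            fresh_carcass_count=_opt_int(row["fresh_carcass_count"], ctx),
            old_carcass_count=_opt_int(row["old_carcass_count"], ctx),
        ))
    return strata, transects


def write_survey(
    strata: Iterable[Stratum], transects: Iterable[Transect],
    strata_path, transects_path,
) -> None:
    """Write strata and transects back to the canonical CSV schemas."""
    srows = [
        {
            "stratum_id": s.stratum_id, "ecosystem_id": s.ecosystem_id,
            "country": s.country, "area_km2": repr(s.area),
            "method": s.method, "protected": str(s.protected).lower(),
            "survey_year": s.survey_year,
        }
        for s in strata
    ]
    pd.DataFrame(srows, columns=STRATA_COLUMNS).to_csv(strata_path, index=False)
    trows = [
        {
            "transect_id": t.transect_id, "stratum_id": t.stratum_id,
            "sampled_area_km2": repr(t.sampled_area),
            "live_count": t.live_count,
            "fresh_carcass_count": "" if t.fresh_carcass_count is None else t.fresh_carcass_count,
            "old_carcass_count": "" if t.old_carcass_count is None else t.old_carcass_count,
        }
        for t in transects
    ]
    pd.DataFrame(trows, columns=TRANSECT_COLUMNS).to_csv(transects_path, index=False)


def read_historical(path) -> list[HistoricalSeries]:
    """Read historical estimate series, dropping single-record units.

    Trend inference needs at least two estimates per unit; units with a
    single record are dropped with a logged warning.  Blank SEs on sample
    counts are kept as missing (None) for downstream imputation.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, HISTORICAL_COLUMNS, path)
    records: list[HistoricalSeries] = []
    for _, row in df.iterrows():
        ctx = f"historical record {row['unit_id']!r}"
        try:
            year = int(float(row["year"]))
            est = float(row["estimate"])
        except ValueError:
            raise ValidationError(f"{ctx}: non-numeric year or estimate")
        se_raw = row["se"].strip()
        method = row["method"].strip().lower()
        se: float | None
        if se_raw == "":
            se = 0.0 if method == "total" else None
        else:
            try:
                se = float(se_raw)
            except ValueError:
                raise ValidationError(f"{ctx}: non-numeric se {se_raw!r}")
        records.append(HistoricalSeries(
            unit_id=row["unit_id"], country=row["country"],
            year=year, estimate=est, se=se, method=method,
        ))
    counts: dict[str, int] = {}
    for r in records:
        counts[r.unit_id] = counts.get(r.unit_id, 0) + 1
    kept = []
    for r in records:
        if counts[r.unit_id] < 2:
            logger.warning(
                "dropping unit %r: only one historical record (need >= 2)",
                r.unit_id,
            )
        else:
            kept.append(r)
    return kept


def write_historical(records: Iterable[HistoricalSeries], path) -> None:
    rows = [
        {
            "unit_id": r.unit_id, "country": r.country, "year": r.year,
            "estimate": repr(r.estimate),
            "se": "" if r.se is None else repr(r.se),
            "method": r.method,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=HISTORICAL_COLUMNS).to_csv(path, index=False)


def sampled_area_from_strip(strip_width_km: float, length_km: float) -> float:
    """Sampled area for a transect searched on both sides of the aircraft.

    a_i = 2 x strip_width x length; strip widths are assumed already
    calibrated to effective on-ground widths.
    """
    if strip_width_km <= 0 or length_km <= 0:
        raise ValidationError("strip width and length must be > 0")
    return 2.0 * strip_width_km * length_km
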