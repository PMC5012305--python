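"""Published country-level census results, used as worked-example inputs.

These are the printed per-country rows of the 2014-2015 continental savannah
elephant census: sampling effort (ecosystem area, transect length, area
surveyed) and population results (estimate, SE, density, carcass ratios).
They serve as inputs to the aggregation, density, and carcass-classification
operations — survey-wide totals are always recomputed from these rows, never
stored.  "W. Africa" is the W-Arly-Pendjari ecosystem spanning Benin,
Burkina Faso, and Niger, treated as a single country because its elephants
move freely among the three nations.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "sampling_effort",
    "population_results",
    "PROTECTED_ESTIMATE",
    "GROWTH_RATE_2010_2014",
]

# country, ecosystem_area_km2, transect_length_km, area_surveyed_km2
_EFFORT = [
    ("Angola", 43459, 9443, 3386),
    ("Botswana", 101599, 31486, 15458),
    ("Cameroon", 20598, 4955, 1509),
    ("Chad", 9799, 15967, 8789),
    ("DR Congo", 9349, 10209, 4707),
    ("Ethiopia", 32791, 3553, 32791),
    ("Kenya", 85711, 34505, 32401),
    ("Malawi", 2991, 1300, 2991),
    ("Mali", 3944, 3096, 3944),
    ("Mozambique", 101077, 30749, 12967),
    ("South Africa", 19809, 18139, 19809),
    ("Tanzania", 268250, 74047, 56902),
    ("Uganda", 10938, 8941, 4588),
    ("W. Africa", 29981, 9113, 2914),
    ("Zambia", 84814, 19065, 6643),
    ("Zimbabwe", 68851, 19949, 8441),
]

# country, elephants, se, all-carcass ratio %, all SE %, fresh ratio %, fresh SE %
# carcass entries are None where carcasses were not recorded
_RESULTS = [
    ("Angola", 3395, 797, 30.0, 2.2, 10.4, 1.7),
    ("Botswana", 130451, 6378, 6.9, 0.2, 0.1, 0.02),
    ("Cameroon", 148, 84, 83.4, 4.4, 10.3, 8.4),
    ("Chad", 743, 0, 17.4, 0.0, 0.1, 0.0),
    ("DR Congo", 1959, 150, 1.4, 0.2, 0.0, 0.0),
    ("Ethiopia", 799, 0, 0.2, 0.0, 0.1, 0.0),
    ("Kenya", 25959, 1805, 13.0, 0.7, 0.9, 0.2),
    ("Malawi", 817, 0, 2.0, 0.0, 0.5, 0.0),
    ("Mali", 253, 0, 10.0, 0.0, 0.0, 0.0),
    ("Mozambique", 9605, 1018, 31.6, 1.1, 3.0, 0.5),
    ("South Africa", 17433, 0, None, None, None, None),
    ("Tanzania", 42871, 3102, 26.4, 0.7, 1.0, 0.2),
    ("Uganda", 4864, 1031, 0.5, 0.2, 0.0, 0.0),
    ("W. Africa", 8911, 1299, 9.4, 0.1, 3.2, 0.1),
    ("Zambia", 21759, 2310, 4.5, 0.4, 0.1, 0.1),
    ("Zimbabwe", 82304, 4382, 7.8, 0.3, 0.4, 0.1),
]

#: Published estimate of elephants in protected areas, survey-wide.
PROTECTED_ESTIMATE: int = 295_978

#: Published survey-wide exponential growth rate for 2010-2014.
GROWTH_RATE_2010_2014: float = -0.078


def sampling_effort() -> pd.DataFrame:
    """Per-country sampling effort (areas in km2, transect length in km)."""
    return pd.DataFrame(
        _EFFORT,
        columns=["country", "ecosystem_area_km2", "transect_length_km",
                 "area_surveyed_km2"],
    )


def population_results() -> pd.DataFrame:
    """Per-country population estimates, SEs, and carcass ratios (percent)."""
    return pd.DataFrame(
        _RESULTS,
        columns=["country", "elephants", "se", "all_carcass_ratio_pct",
                 "all_carcass_se_pct", "fresh_carcass_ratio_pct",
                 "fresh_carcass_se_pct"],
    )
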