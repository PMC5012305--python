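import pytest

from gecpop.survey_data import Stratum, Transect


@pytest.fixture
def two_stratum_survey():
    """Two strata (one sample, one total count) with five transects."""
    strata = [
        Stratum("s1", "eco1", "Simland", 12.0, "sample", True, 2014),
        Stratum("s2", "eco1", "Simland", 8.0, "total", False, 2014),
    ]
    transects = [
        Transect("t1", "s1", 1.0, 5, 1, 0),
        Transect("t2", "s1", 2.0, 10, 0, 2),
        Transect("t3", "s1", 3.0, 15, 0, 1),
        Transect("t4", "s2", 4.0, 3, 0, 0),
        Transect("t5", "s2", 4.0, 4, 1, 1),
    ]
    return strata, transects
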