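"""Published worked example bundled for demonstrations and tests.

Individual JUC73, an adult male from a cist grave in the middle Chincha
Valley (Peru), is the standard worked example for diet-mixed
calibration: his marine-diet posterior (as a 100-bin percentage
histogram), the radiocarbon determination on his second right molar,
the molar's formation age, and his osteological age at death are all
public record.  The regional free-floating marine reservoir offset
estimated alongside him is Delta-R = -314 +/- 52 14C years.
"""

from __future__ import annotations

import numpy as np

from .calcurve import RadiocarbonDetermination, ReservoirOffset
from .diet import DietHistogram

__all__ = [
    "JUC73_LABEL",
    "JUC73_HISTOGRAM_COUNTS",
    "CHINCHA_DELTA_R",
    "juc73_histogram",
    "juc73_determination",
    "JUC73_TISSUE_OFFSET",
    "JUC73_AGE_AT_DEATH",
]

JUC73_LABEL = "UCIAMS-270835, JUC73, Sector B, Tomb U1"

#: marine-diet percentage histogram (bins [0,1) .. [99,100]) exported
#: from the individual's diet-mixing posterior
JUC73_HISTOGRAM_COUNTS = (
    140, 208, 211, 188, 177, 148, 166, 131, 125, 121, 110, 98, 112, 88, 76,
    69, 75, 72, 57, 70, 55, 49, 45, 40, 30, 31, 28, 34, 27, 21, 21, 19, 17,
    17, 11, 6, 12, 13, 7, 6, 8, 7, 4, 8, 2, 4, 3, 0, 1, 4, 5, 0, 2, 2, 2, 2,
    0, 2, 1, 0, 0, 1, 0, 1, 1, 1, 0, 3, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0,
    1, 0, 0, 0, 1, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1,
)

#: regional free-floating Bayesian reservoir offset for the central
#: Peruvian coast, AD ~1300-1500
CHINCHA_DELTA_R = ReservoirOffset("fixed", mean=-314.0, sd=52.0)

#: second right molar forms at age 11 +/- 1
JUC73_TISSUE_OFFSET = (11.0, 1.0)

#: osteological age at death: 40-55 years
JUC73_AGE_AT_DEATH = (40.0, 55.0)


def juc73_histogram() -> DietHistogram:
    return DietHistogram(np.array(JUC73_HISTOGRAM_COUNTS))


def juc73_determination() -> RadiocarbonDetermination:
    return RadiocarbonDetermination(
        JUC73_LABEL, 895.0, 20.0, material="human bone", tissue="second_molar"
    )
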