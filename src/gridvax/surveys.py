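"""Published weighted DHS summary counts used as worked-example inputs.

National weighted totals of surveyed children aged 12-23 months and the
numbers vaccinated, from the DHS reports the areal analyses draw on
(Afghanistan 2015, Pakistan 2013).  These are inputs for worked examples and
sanity checks — e.g. the national weighted measles coverage for Afghanistan
is 100 * 3443 / 5704 = 60.4%.
"""

from __future__ import annotations

import numpy as np

from .geometry import ArealCounts

__all__ = ["DHS_WEIGHTED_SUMMARIES", "weighted_coverage_percent"]

# survey -> {children: weighted number surveyed, <vaccine>: weighted number vaccinated}
DHS_WEIGHTED_SUMMARIES = {
    "afghanistan_2015": {
        "children": 5704,
        "measles": 3443,
        "dtp1": 4166,
        "dtp2": 3875,
        "dtp3": 3293,
    },
    "pakistan_2013": {
        "children": 2074,
        "measles": 1274,
        "dtp1": 1633,
        "dtp2": 1508,
        "dtp3": 1352,
    },
}


def weighted_coverage_percent(survey: str, vaccine: str) -> float:
    """National weighted vaccination percentage for one survey and vaccine."""
    rec = DHS_WEIGHTED_SUMMARIES[survey]
    counts = ArealCounts(
        Y=np.array([float(rec[vaccine])]), N=np.array([float(rec["children"])])
    )
    return counts.coverage_percent()
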