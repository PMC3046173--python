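"""Statistical (time-domain) HRV indexes.

Seven classical short-term statistics of the NN series: mean, SDNN,
RMSSD, pNN50, the interquartile range MIRR, the median absolute
successive difference MDARR, and SDSD.  pNN50 counts successive
differences *strictly* greater than 50 ms and is normalized by the
number of successive differences (N - 1); quartiles use linear
interpolation; SDNN/SDSD use the sample (n-1) convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError
from .io import RRSeries

__all__ = ["TimeDomainFeatures", "time_domain_features"]

NN50_THRESHOLD_MS = 50.0


@dataclass
class TimeDomainFeatures:
    meanNN: float
    SDNN: float
    RMSSD: float
    pNN50: float
    MIRR: float
    MDARR: float
    SDSD: float

    def as_dict(self) -> dict[str, float]:
        return {
            "meanNN": self.meanNN,
            "SDNN": self.SDNN,
            "RMSSD": self.RMSSD,
            "pNN50": self.pNN50,
            "MIRR": self.MIRR,
            "MDARR": self.MDARR,
            "SDSD": self.SDSD,
        }


def time_domain_features(rr: RRSeries) -> TimeDomainFeatures:
    """Compute the seven time-domain indexes of an NN series (ms)."""
    x = rr.intervals
    if x.size < 3:
        raise InsufficientDataError(f"need >= 3 intervals, got {x.size}")
    d = np.diff(x)
    q1, q3 = np.percentile(x, [25, 75], method="linear")
    nn50 = int(np.sum(np.abs(d) > NN50_THRESHOLD_MS))
    return TimeDomainFeatures(
        meanNN=float(x.mean()),
        SDNN=float(x.std(ddof=1)),
        RMSSD=float(np.sqrt(np.mean(d**2))),
        pNN50=nn50 / d.size,
        MIRR=float(q3 - q1),
        MDARR=float(np.median(np.abs(d))),
        SDSD=float(d.std(ddof=1)),
    )
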