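"""Packaged reference data.

``RME``: failure intervals of thirty pieces of repairable mechanical
equipment, a standard complete benchmark dataset in reliability
analysis.

``TABLE4``: three IAT-II progressively censored samples drawn from the
RME data under different removal plans and thresholds.  The random
selection of withdrawn units behind these samples is not recorded
anywhere, so the observed samples ship verbatim and are never
regenerated.
"""

from __future__ import annotations

import numpy as np

from .censoring import CensoringScheme, IATIIPCSSample, classify_sample, parse_removals

__all__ = ["RME", "rme_data", "table4_sample", "TABLE4_SPECS"]

RME = (
    0.11, 0.30, 0.40, 0.45, 0.59, 0.63, 0.70, 0.71, 0.74, 0.77,
    0.94, 1.06, 1.17, 1.23, 1.23, 1.24, 1.43, 1.46, 1.49, 1.74,
    1.82, 1.86, 1.97, 2.23, 2.37, 2.46, 2.63, 3.46, 4.36, 4.73,
)

# (removal plan shorthand, T1, T2, observed times)
TABLE4_SPECS: dict[str, dict] = {
    "A": {
        "R": "4*2,0*10,4*2", "T1": 1.25, "T2": 2.25,
        "times": (0.30, 0.45, 0.59, 0.70, 0.77, 0.94, 1.06, 1.17,
                  1.43, 1.74, 1.82, 1.86, 2.23),
    },
    "B": {
        "R": "0*6,2*8", "T1": 1.5, "T2": 2.5,
        "times": (0.11, 0.40, 0.59, 0.74, 0.94, 1.06, 1.23, 1.49,
                  1.74, 1.82, 1.97, 2.23, 2.37, 2.46),
    },
    "C": {
        "R": "2*4,0*6,2*4", "T1": 1.0, "T2": 2.0,
        "times": (0.11, 0.30, 0.40, 0.59, 0.74, 0.94, 1.06, 1.23,
                  1.49, 1.74, 1.82, 1.97),
    },
}


def rme_data() -> np.ndarray:
    """The 30 RME failure intervals, sorted ascending."""
    return np.array(RME, dtype=float)


def table4_sample(name: str) -> IATIIPCSSample:
    """One of the packaged censored samples ('A', 'B' or 'C'), classified."""
    key = name.strip().upper().removeprefix("TABLE4")
    if key not in TABLE4_SPECS:
        raise KeyError(f"unknown sample {name!r}; expected one of A, B, C")
    spec = TABLE4_SPECS[key]
    scheme = CensoringScheme(n=30, m=14, R=parse_removals(spec["R"], 14),
                             T1=spec["T1"], T2=spec["T2"])
    return classify_sample(np.asarray(spec["times"]), scheme)
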