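"""Kinetic curve container and the not-detected (ND) sentinel.

A kinetic microplate read is a per-well time series of absorbance at a
single wavelength (414 nm for the ABTS radical cation).  Quantities that a
reduction cannot produce for a given curve — a half-max time on a curve
that never drops below half of its peak, a lag time on a flat well — are
*not detected* (ND), a first-class missing value distinct from an error.
ND propagates through percent inhibition and dose-response assembly as
missing, never as zero.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ND", "is_nd", "format_nd", "parse_nd", "KineticCurve", "WELL_RE", "well_index"]

#: Not-detected sentinel. IEEE NaN so it propagates through arithmetic.
ND: float = math.nan

#: Valid 96-well coordinate: rows A-H, columns 1-12 (no zero padding).
WELL_RE = re.compile(r"^[A-H](1[0-2]|[1-9])$")


def is_nd(x) -> bool:
    """True for the ND sentinel (NaN or None)."""
    return x is None or (isinstance(x, float) and math.isnan(x))


def format_nd(x, fmt: str = "{:.6g}") -> str:
    return "ND" if is_nd(x) else fmt.format(x)


def parse_nd(s: str) -> float:
    s = s.strip()
    return ND if s.upper() in {"ND", "NA", "NAN", ""} else float(s)


def well_index(well_id: str) -> int:
    """Row-major index 0..95 of a well coordinate (A1 -> 0, H12 -> 95)."""
    w = well_id.strip().upper()
    if not WELL_RE.match(w):
        raise ValueError(f"invalid 96-well coordinate: {well_id!r}")
    return (ord(w[0]) - ord("A")) * 12 + int(w[1:]) - 1


@dataclass
class KineticCurve:
    """One well's absorbance time course.

    Parameters
    ----------
    well_id
        Plate coordinate, A1-H12 (normalised to uppercase).
    times
        Acquisition times in minutes, strictly increasing, >= 2 points,
        first point >= 0.
    od
        Absorbance (optical density) at 414 nm, one value per time point.
    temperature_c
        Incubation temperature, metadata only.
    """

    well_id: str
    times: np.ndarray
    od: np.ndarray
    temperature_c: float = 37.0
    _skip_validation: bool = field(default=False, repr=False)

    def __post_init__(self):
        self.well_id = self.well_id.strip().upper()
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self._skip_validation:
            return
        if not WELL_RE.match(self.well_id):
            raise ValueError(f"invalid 96-well coordinate: {self.well_id!r}")
        if self.times.ndim != 1 or self.od.ndim != 1:
            raise ValueError("times and od must be one-dimensional")
        if len(self.times) != len(self.od):
            raise ValueError(
                f"well {self.well_id}: {len(self.times)} times but {len(self.od)} OD readings"
            )
        if len(self.times) < 2:
            raise ValueError(f"well {self.well_id}: need >= 2 readings")
        if self.times[0] < 0:
            raise ValueError(f"well {self.well_id}: negative start time {self.times[0]}")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError(f"well {self.well_id}: times not strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def window(self, t_min: float, t_max: float) -> "KineticCurve":
        """Restrict to readings with t_min <= t <= t_max (copy)."""
        m = (self.times >= t_min) & (self.times <= t_max)
        return KineticCurve(
            self.well_id, self.times[m], self.od[m], self.temperature_c, _skip_validation=True
        )
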