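"""Cell-abundance arithmetic for flow cytometry and FISH microscopy.

Flow-cytometric density converts an event count into cells per milliliter:

    N = n * 1000 / (q * t)

with ``n`` events counted, ``q`` the flow rate in microliters per minute and
``t`` the acquisition time in minutes; the factor 1000 converts microliters
to milliliters.  (Written inline the formula is ambiguous between
``(n*1000)/(q*t)`` and ``((n*1000)/q)*t``; only the former has units of
cells per volume, so that reading is implemented.)

FISH absolute density is the product of the hybridized fraction of
DAPI-stained objects and the DAPI direct count; counts below 500 measured
cells trigger a low-count warning rather than an error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

MIN_CELLS_MEASURED = 500


@dataclass
class FlowAcquisition:
    """One cytometer acquisition: events, flow rate (uL/min), time (min)."""

    n: int
    q: float
    t: float

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("event count cannot be negative")
        if self.q <= 0:
            raise ValueError("flow rate must be positive")
        if self.t <= 0:
            raise ValueError("acquisition time must be positive")


@dataclass
class FishCount:
    """FISH relative abundance paired with a DAPI direct count."""

    fraction_hybridized: float
    dapi_density: float
    n_cells_measured: int
    lengths: list[float] = field(default_factory=list)
    widths: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_hybridized <= 1.0:
            raise ValueError("fraction_hybridized must be in [0, 1]")
        if self.dapi_density < 0:
            raise ValueError("DAPI density cannot be negative")

    @property
    def low_count(self) -> bool:
        return self.n_cells_measured < MIN_CELLS_MEASURED


def flow_density(acq: FlowAcquisition) -> float:
    """Cells per mL from a flow-cytometer acquisition: n * 1000 / (q * t)."""
    return acq.n * 1000.0 / (acq.q * acq.t)


def fish_density(count: FishCount) -> float:
    """Absolute hybridized-cell density: fraction * DAPI direct count."""
    if count.low_count:
        warnings.warn(
            f"only {count.n_cells_measured} cells measured "
            f"(< {MIN_CELLS_MEASURED}); density estimate may be unstable",
            stacklevel=2,
        )
    return count.fraction_hybridized * count.dapi_density


def dimension_stats(
    lengths: Sequence[float], widths: Sequence[float]
) -> dict[str, tuple[float, float]]:
    """Mean +/- sample standard deviation (n-1) of cell dimensions, in um."""
    out: dict[str, tuple[float, float]] = {}
    for name, values in (("length", lengths), ("width", widths)):
        if len(values) < 2:
            raise ValueError(f"need at least 2 {name} measurements")
        n = len(values)
        mean = sum(values) / n
        var = sum((v - mean) ** 2 for v in values) / (n - 1)
        out[name] = (mean, math.sqrt(var))
    return out
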