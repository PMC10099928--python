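"""Secondary physiological endpoints: barrier integrity and cytotoxicity.

Transepithelial electrical resistance (TEER) readings from a voltohmmeter
are in ohms for the whole insert; multiplying by the insert membrane area
(0.6 cm^2 for the standard insert) gives the area-normalized resistance in
ohm*cm^2 that tissue-integrity results are reported in.

The adenylate-kinase (AK) release assay reports cytotoxicity as a
luminescence difference: dRLU = L_P - L_A, the reading from the treated
condition (cytochalasin B + EGF present) minus the untreated one.  A
negative difference is physically possible (reader noise at low release)
and is kept, with a warning, so replicate averaging stays unbiased.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import InvalidMeasurementError

__all__ = [
    "DEFAULT_INSERT_AREA_CM2",
    "TeerResult",
    "AkResult",
    "teer_total",
    "delta_rlu",
]

#: Membrane area of the standard 12/24-well tissue-culture insert.
DEFAULT_INSERT_AREA_CM2 = 0.6


@dataclass(frozen=True)
class TeerResult:
    reading_ohm: float
    area_cm2: float
    resistance_total: float  # ohm * cm^2


@dataclass(frozen=True)
class AkResult:
    l_present: float
    l_absent: float
    delta_rlu: float


def teer_total(
    reading_ohm: float, area_cm2: float = DEFAULT_INSERT_AREA_CM2
) -> TeerResult:
    """Area-normalized resistance: voltohmmeter reading x insert area."""
    if reading_ohm < 0:
        raise InvalidMeasurementError(
            f"negative TEER reading: {reading_ohm} ohm"
        )
    if area_cm2 <= 0:
        raise InvalidMeasurementError(f"insert area must be > 0: {area_cm2}")
    return TeerResult(reading_ohm, area_cm2, reading_ohm * area_cm2)


def delta_rlu(l_present: float, l_absent: float) -> AkResult:
    """AK-release cytotoxicity delta, L_P - L_A (may be negative)."""
    if l_present < 0 or l_absent < 0:
        raise InvalidMeasurementError("luminescence readings must be >= 0")
    d = l_present - l_absent
    if d < 0:
        warnings.warn(
            f"negative dRLU ({d:g}): treated luminescence below untreated",
            stacklevel=2,
        )
    return AkResult(l_present, l_absent, d)
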