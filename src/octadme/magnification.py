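"""Ocular magnification correction from axial length.

Lateral image scale on the retina is proportional to ``q = 0.01306 * (AL -
1.82)`` (modified Bennett relation; AL in mm).  A device calibrates its
nominal scan width for an assumed axial length, so the corrected lateral
scale for a subject eye is the nominal scale times
``(AL_subject - 1.82) / (AL_assumed - 1.82)``.  Areas scale by the square of
that factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

BENNETT_OFFSET_MM = 1.82
#: q (mm of retina per degree) = BENNETT_Q_PER_MM * (AL - BENNETT_OFFSET_MM)
BENNETT_Q_PER_MM = 0.01306

#: Device default used when no per-device assumption is supplied.
DEFAULT_ASSUMED_AXIAL_LENGTH_MM = 23.95


@dataclass(frozen=True)
class MagnificationModel:
    assumed_axial_length_mm: float = DEFAULT_ASSUMED_AXIAL_LENGTH_MM
    subject_axial_length_mm: float = DEFAULT_ASSUMED_AXIAL_LENGTH_MM
    #: Optional hook for a three-parameter variant taking
    #: (axial_length_mm, refraction_D, keratometry_mm) -> relative ocular
    #: magnification; when set it replaces the axial-length-only ratio.
    custom_factor: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        for al in (self.assumed_axial_length_mm, self.subject_axial_length_mm):
            if al <= 2.0:
                raise ValueError("axial lengths must exceed 2 mm")
        if self.assumed_axial_length_mm - BENNETT_OFFSET_MM <= 0:
            raise ValueError("assumed axial length yields nonpositive denominator")

    def factor(self) -> float:
        """Lateral-scale correction factor (1.0 when subject == assumed)."""
        if self.custom_factor is not None:
            return self.custom_factor(self.subject_axial_length_mm)
        return (self.subject_axial_length_mm - BENNETT_OFFSET_MM) / (
            self.assumed_axial_length_mm - BENNETT_OFFSET_MM
        )


def magnification_factor(mm: MagnificationModel) -> float:
    return mm.factor()
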