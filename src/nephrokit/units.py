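"""Explicit length/volume unit tagging.

All internal geometry is carried in micrometres; cortex volumes arrive from
tomography in cm^3 (or mm^3) and must be tagged explicitly — there is no
silent unit inference anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Volume", "UnitError", "MM_TO_UM", "CM_TO_UM"]

MM_TO_UM = 1.0e3
CM_TO_UM = 1.0e4

_VOLUME_TO_UM3 = {
    "um3": 1.0,
    "mm3": MM_TO_UM**3,
    "cm3": CM_TO_UM**3,
}


class UnitError(ValueError):
    """Raised when a quantity carries an unknown or mismatched unit tag."""


@dataclass(frozen=True)
class Volume:
    """A volume with an explicit unit tag (``um3``, ``mm3`` or ``cm3``)."""

    value: float
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in _VOLUME_TO_UM3:
            raise UnitError(
                f"unknown volume unit {self.unit!r}; expected one of "
                f"{sorted(_VOLUME_TO_UM3)}"
            )
        if self.value < 0:
            raise ValueError(f"volume must be non-negative, got {self.value}")

    def to_um3(self) -> float:
        return self.value * _VOLUME_TO_UM3[self.unit]

    def to(self, unit: str) -> "Volume":
        if unit not in _VOLUME_TO_UM3:
            raise UnitError(f"unknown volume unit {unit!r}")
        return Volume(self.to_um3() / _VOLUME_TO_UM3[unit], unit)
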