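"""Ocular magnification correction from axial length.

The physical size on the retina subtended by one image pixel depends on the
eye's optics.  A widely used approximation ties the retinal scale to the
axial length (AL) through the distance between the eye's second principal
point and the retina: the scale factor

    q = linear_coefficient * (AL - offset)    [mm per degree]

with the classic constants ``0.01306`` and ``1.82`` mm.  Lateral (transverse)
dimensions measured on a fundus or OCT image acquired under a nominal
reference AL are rescaled by the ratio of the q factors of the actual and
reference eyes.  Axial OCT dimensions are optically calibrated by the
instrument and are *not* AL-corrected here.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "EyeBiometry",
    "MagnificationModel",
    "bennett_q",
    "scale_factor",
    "DEFAULT_LINEAR_COEFFICIENT",
    "DEFAULT_OFFSET_MM",
    "DEFAULT_REFERENCE_AL_MM",
]

DEFAULT_LINEAR_COEFFICIENT = 0.01306  # mm per degree per mm of (AL - offset)
DEFAULT_OFFSET_MM = 1.82  # distance from second principal point proxy, mm
DEFAULT_REFERENCE_AL_MM = 24.00  # nominal AL assumed by instrument scaling

_AL_RANGE = (15.0, 40.0)
_SE_RANGE = (-30.0, 15.0)


@dataclass(frozen=True)
class EyeBiometry:
    """Per-eye biometry: axial length (mm), spherical equivalent (D), IOP (mmHg)."""

    axial_length: float
    spherical_equivalent: float = 0.0
    iop: float | None = None

    def __post_init__(self) -> None:
        if not (_AL_RANGE[0] < self.axial_length < _AL_RANGE[1]):
            raise ValueError(
                f"axial_length={self.axial_length} mm outside plausible range {_AL_RANGE}"
            )
        if not (_SE_RANGE[0] < self.spherical_equivalent < _SE_RANGE[1]):
            raise ValueError(
                f"spherical_equivalent={self.spherical_equivalent} D outside range {_SE_RANGE}"
            )


@dataclass(frozen=True)
class MagnificationModel:
    """AL-based retinal scale: ``q_factor = linear_coefficient * (AL - offset)``."""

    q_factor: float
    reference_axial_length: float
    linear_coefficient: float = DEFAULT_LINEAR_COEFFICIENT
    offset: float = DEFAULT_OFFSET_MM

    def __post_init__(self) -> None:
        if self.q_factor <= 0:
            raise ValueError("q_factor must be positive")


def bennett_q(
    biometry: EyeBiometry,
    linear_coefficient: float = DEFAULT_LINEAR_COEFFICIENT,
    offset_mm: float = DEFAULT_OFFSET_MM,
    reference_al_mm: float = DEFAULT_REFERENCE_AL_MM,
) -> MagnificationModel:
    """Retinal scale factor q (mm/degree) for an eye of given axial length."""
    q = linear_coefficient * (biometry.axial_length - offset_mm)
    if q <= 0:
        raise ValueError(
            f"axial_length={biometry.axial_length} does not exceed the model offset {offset_mm}"
        )
    return MagnificationModel(
        q_factor=q,
        reference_axial_length=reference_al_mm,
        linear_coefficient=linear_coefficient,
        offset=offset_mm,
    )


def scale_factor(
    biometry: EyeBiometry,
    reference_al: float = DEFAULT_REFERENCE_AL_MM,
    offset_mm: float = DEFAULT_OFFSET_MM,
) -> float:
    """Dimensionless lateral rescaling (AL - offset) / (reference AL - offset).

    Multiply the nominal physical-size-per-pixel by this ratio to obtain the
    true retinal size per pixel in the measured eye.  Strictly increasing in
    AL; exactly 1 when ``AL == reference_al``.
    """
    denom = reference_al - offset_mm
    if denom <= 0:
        raise ZeroDivisionError(
            f"reference_al={reference_al} must exceed the model offset {offset_mm}"
        )
    num = biometry.axial_length - offset_mm
    if num <= 0:
        raise ValueError("axial_length must exceed the model offset")
    return num / denom
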