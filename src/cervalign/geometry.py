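"""Cobb-angle geometry for cervical sagittal alignment.

Coordinates follow the raster convention of pixel-space annotations:
``x`` increases rightward, ``y`` increases downward.  "Clockwise positive"
is evaluated in this frame, so an endplate whose posterior end sits lower
than its anterior end has a positive slope.

The headline quantity is the C2-C7 Cobb angle: the angle of the C7
inferior endplate minus the angle of the C2 inferior endplate, both
measured against the horizontal.  Negative values indicate lordosis
(the normal posteriorly concave neck curve), positive values kyphosis.

The canonical image orientation is patient-facing-left, i.e. the anterior
endplate corner has the smaller ``x``.  Images of patients facing right
should be mirrored first (see :meth:`LandmarkSet.mirrored`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterator, Optional, Tuple

__all__ = [
    "Point2D",
    "LandmarkSet",
    "AngleMeasurement",
    "LANDMARK_LABELS",
    "wrap_angle",
    "endplate_slope",
    "c2c7_angle",
    "measure_from_landmarks",
    "range_of_motion",
]

#: Canonical landmark order: anterior/posterior corners of the C2 and C7
#: inferior endplates.  This order is fixed across heatmap channels,
#: annotation labels and model outputs.
LANDMARK_LABELS = ("C2A", "C2P", "C7A", "C7P")


def wrap_angle(angle: float) -> float:
    """Wrap an angle in degrees into the half-open interval (-180, 180].

    Ties at the branch cut resolve to +180.
    """
    wrapped = (angle + 180.0) % 360.0 - 180.0
    if wrapped == -180.0:
        wrapped = 180.0
    return wrapped


@dataclass(frozen=True)
class Point2D:
    """A pixel-space point (x rightward, y downward)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite coordinate: ({self.x}, {self.y})")

    def __iter__(self) -> Iterator[float]:
        yield self.x
        yield self.y


@dataclass(frozen=True)
class LandmarkSet:
    """The four endplate landmarks of a lateral cervical radiograph.

    Anterior and posterior corners of the C2 and C7 inferior endplates.
    Each endplate must be defined by two distinct points.
    """

    c2_anterior: Point2D
    c2_posterior: Point2D
    c7_anterior: Point2D
    c7_posterior: Point2D

    def __post_init__(self) -> None:
        if self.c2_anterior == self.c2_posterior:
            raise ValueError("degenerate C2 endplate: anterior == posterior")
        if self.c7_anterior == self.c7_posterior:
            raise ValueError("degenerate C7 endplate: anterior == posterior")

    def as_tuple(self) -> Tuple[Point2D, Point2D, Point2D, Point2D]:
        """Points in canonical :data:`LANDMARK_LABELS` order."""
        return (self.c2_anterior, self.c2_posterior, self.c7_anterior, self.c7_posterior)

    def mirrored(self, width: float) -> "LandmarkSet":
        """Mirror the landmarks horizontally about an image of ``width`` pixels.

        Converts a patient-facing-right radiograph into the canonical
        patient-facing-left frame (x -> width - 1 - x).
        """
        flip = lambda p: Point2D(width - 1.0 - p.x, p.y)  # noqa: E731
        return LandmarkSet(*(flip(p) for p in self.as_tuple()))


@dataclass(frozen=True)
class AngleMeasurement:
    """Slopes and Cobb angle for one radiograph, in degrees.

    ``c2c7_angle == c7_slope - c2_slope`` (wrapped); negative = lordosis.
    ``confidence`` is the min-of-peaks heatmap score in [0, 1], or ``None``
    when the measurement did not come from a model prediction.
    """

    c2_slope: float
    c7_slope: float
    c2c7_angle: float
    confidence: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("c2_slope", "c7_slope", "c2c7_angle"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"non-finite {name}: {v}")
            if not (-180.0 < v <= 180.0):
                raise ValueError(f"{name}={v} outside (-180, 180]")
        residual = wrap_angle(self.c7_slope - self.c2_slope) - self.c2c7_angle
        if abs(residual) > 1e-9:
            raise ValueError(
                f"angle identity violated: c7-c2 = "
                f"{wrap_angle(self.c7_slope - self.c2_slope)} vs {self.c2c7_angle}"
            )
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    def with_confidence(self, confidence: Optional[float]) -> "AngleMeasurement":
        return replace(self, confidence=confidence)


def endplate_slope(anterior: Point2D, posterior: Point2D) -> float:
    """Angle (degrees) of an endplate against the horizontal, clockwise positive.

    With y increasing downward, a clockwise-rotated endplate (posterior end
    lower than anterior) yields a positive angle.  Result in (-180, 180].

    Raises
    ------
    ValueError
        If the two points coincide (a degenerate endplate) or any
        coordinate is non-finite.
    """
    if not isinstance(anterior, Point2D):
        anterior = Point2D(*anterior)
    if not isinstance(posterior, Point2D):
        posterior = Point2D(*posterior)
    dx = posterior.x - anterior.x
    dy = posterior.y - anterior.y
    if dx == 0.0 and dy == 0.0:
        raise ValueError("degenerate endplate: anterior and posterior coincide")
    return wrap_angle(math.degrees(math.atan2(dy, dx)))


def c2c7_angle(c2_slope: float, c7_slope: float) -> float:
    """C2-C7 Cobb angle: C7 slope minus C2 slope, wrapped into (-180, 180]."""
    if not (math.isfinite(c2_slope) and math.isfinite(c7_slope)):
        raise ValueError("slopes must be finite")
    return wrap_angle(c7_slope - c2_slope)


def measure_from_landmarks(landmarks: LandmarkSet) -> AngleMeasurement:
    """Measure both endplate slopes and the C2-C7 angle from landmarks.

    The returned measurement carries no confidence score (confidence is a
    property of model predictions, not of geometry).
    """
    s2 = endplate_slope(landmarks.c2_anterior, landmarks.c2_posterior)
    s7 = endplate_slope(landmarks.c7_anterior, landmarks.c7_posterior)
    return AngleMeasurement(c2_slope=s2, c7_slope=s7, c2c7_angle=c2c7_angle(s2, s7))


def range_of_motion(
    neutral: float, flexion: float, extension: float
) -> Tuple[float, float]:
    """Flexional and extensional range of motion for one patient.

    With kyphosis positive, flexion increases the angle and extension
    decreases it, so::

        flexional_rom   = flexion - neutral
        extensional_rom = neutral - extension

    Both are positive for normal motion.  Returns ``(flexional_rom,
    extensional_rom)`` in degrees.
    """
    return (flexion - neutral, neutral - extension)
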