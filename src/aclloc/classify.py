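"""Femoral / middle / tibial side classification of a localized rupture point.

The rupture point is projected perpendicularly onto the line connecting the
femoral and tibial footprint centers; the line is divided into three equal
parts, and the third containing the foot of the perpendicular gives the side
class.  With a ~38 mm ligament each third spans ~12 mm.

Conventions (the source method leaves both unstated, so they are fixed here
deterministically): projections falling outside the segment are clamped to
[0, 1] rather than rejected, and exact boundary ties (t = 1/3 or 2/3) go to
the more femoral class.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

SIDES = ("femoral", "middle", "tibial")

__all__ = ["AclAxis", "SideClass", "project_fraction", "classify_side", "classify_case", "SIDES"]


@dataclass(frozen=True)
class AclAxis:
    """The femoral-to-tibial footprint line."""

    femoral_center: np.ndarray
    tibial_center: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "femoral_center", np.asarray(self.femoral_center, dtype=float))
        object.__setattr__(self, "tibial_center", np.asarray(self.tibial_center, dtype=float))
        if self.length <= 0:
            raise ValueError("footprint centers coincide: zero-length axis")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.tibial_center - self.femoral_center))

    @property
    def unit(self) -> np.ndarray:
        return (self.tibial_center - self.femoral_center) / self.length


@dataclass(frozen=True)
class SideClass:
    """A side assignment plus the projection fraction that produced it."""

    value: str
    t: float

    def __post_init__(self):
        if self.value not in SIDES:
            raise ValueError(f"unknown side {self.value!r}")
        if not 0.0 <= self.t <= 1.0:
            raise ValueError("t must lie in [0, 1]")
        if self.value != _side_of(self.t):
            raise ValueError(f"side {self.value!r} inconsistent with t={self.t}")


def project_fraction(point, axis: AclAxis) -> float:
    """Fraction t in [0, 1] of the perpendicular foot along the femoral->tibial axis.

    t = <point - femoral, u> / length, clamped to [0, 1]; off-axis components
    are ignored (perpendicular projection).
    """
    point = np.asarray(point, dtype=float)
    t = float(np.dot(point - axis.femoral_center, axis.unit) / axis.length)
    return min(1.0, max(0.0, t))


def _side_of(t: float) -> str:
    if t <= 1.0 / 3.0:
        return "femoral"
    if t <= 2.0 / 3.0:
        return "middle"
    return "tibial"


def classify_side(t: float) -> SideClass:
    """Thirds rule: femoral if t <= 1/3, middle if 1/3 < t <= 2/3, else tibial."""
    if not 0.0 <= t <= 1.0:
        raise ValueError("t must lie in [0, 1]")
    return SideClass(value=_side_of(t), t=t)


def classify_case(result, axis: AclAxis) -> SideClass:
    """Classify a localization result (or bare point) against a footprint axis."""
    point = getattr(result, "point", result)
    return classify_side(project_fraction(point, axis))


def write_classes(rows, path) -> None:
    """Write classification results TSV: case id, projection fraction, side."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["case_id", "t", "side"])
        for case_id, side in rows:
            w.writerow([case_id, f"{side.t:.6f}", side.value])
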