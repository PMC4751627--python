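"""Geometric measurement between structural units.

Distances are Euclidean, in nanometers (the coordinate unit of the
structure files).  Angles are measured at a vertex unit between the arms to
two other units, in degrees within [0, 180].  Values are carried at full
floating precision; the reporting convention is 3 decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import Unit
from .selection import Selection
from .errors import SelectionError

__all__ = ["distance", "angle", "measure_selection", "Measurement"]


def distance(a: Unit, b: Unit) -> float:
    """Euclidean distance between two units' positions, nm."""
    return float(np.linalg.norm(np.subtract(a.position, b.position)))


def angle(a: Unit, vertex: Unit, c: Unit) -> float:
    """Angle at `vertex` between the arms to `a` and `c`, in degrees.

    The cosine is clamped to [-1, 1] so nearly collinear arms cannot
    produce NaN.  A zero-length arm (a unit coincident with the vertex)
    is degenerate and raises, naming the unit.
    """
    u = np.subtract(a.position, vertex.position)
    v = np.subtract(c.position, vertex.position)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0:
        raise SelectionError(f"degenerate angle: unit {a.label()} coincides with the vertex")
    if nv == 0.0:
        raise SelectionError(f"degenerate angle: unit {c.label()} coincides with the vertex")
    cos = float(np.dot(u, v) / (nu * nv))
    cos = max(-1.0, min(1.0, cos))
    return math.degrees(math.acos(cos))


@dataclass(frozen=True)
class Measurement:
    """One measurement: which units, what was measured, the value."""

    kind: str  # "distance" | "angle"
    unit_labels: tuple[str, ...]
    value: float
    unit_of_measure: str  # "nm" | "deg"

    def tsv_row(self) -> str:
        return "\t".join(
            [self.kind, ";".join(self.unit_labels), f"{self.value:.3f}", self.unit_of_measure]
        )

    def __str__(self) -> str:
        return f"{self.kind}({', '.join(self.unit_labels)}) = {self.value:.3f} {self.unit_of_measure}"


def measure_selection(selection: Selection, kind: str) -> list[Measurement]:
    """Measure a selection: exactly 2 units for a distance, exactly 3 for
    an angle (in index order; the middle unit is the vertex)."""
    units = selection.units
    if kind == "distance":
        if len(units) != 2:
            raise SelectionError(
                f"distance needs exactly 2 selected units, got {len(units)}"
            )
        value, uom = distance(units[0], units[1]), "nm"
    elif kind == "angle":
        if len(units) != 3:
            raise SelectionError(
                f"angle needs exactly 3 selected units, got {len(units)}"
            )
        value, uom = angle(units[0], units[1], units[2]), "deg"
    else:
        raise SelectionError(f"unknown measurement kind {kind!r} (distance|angle)")
    return [Measurement(kind, tuple(u.label() for u in units), value, uom)]
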