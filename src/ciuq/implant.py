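"""Electrode array geometry and virtual insertion.

The array has 12 contacts labeled E1 (apical tip) to E12 (base), spanning a
23.1 mm active range behind a 1.0 mm tip.  Insertion depth is measured from
the round window along the duct spiral; a full insertion therefore needs at
least 24.1 mm, and a requested depth deeper than the duct allows is clamped
to the deepest anatomically possible insertion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ImplantConfig
from .errors import IncompleteInsertionError
from .geometry import CochlearShape

__all__ = ["ElectrodeArray", "Insertion", "insert_array", "max_insertion_depth"]


@dataclass(frozen=True)
class ElectrodeArray:
    """12-contact lateral-wall array; E1 is the apical tip contact."""

    n_contacts: int = 12
    active_range_mm: float = 23.1
    tip_mm: float = 1.0

    def __post_init__(self):
        if min(self.n_contacts, self.active_range_mm, self.tip_mm) <= 0:
            raise ValueError("array dimensions must be positive")

    @property
    def spacing_mm(self) -> float:
        return self.active_range_mm / (self.n_contacts - 1)

    @property
    def min_insertion_mm(self) -> float:
        return self.active_range_mm + self.tip_mm

    @property
    def labels(self) -> list[str]:
        return [f"E{k}" for k in range(1, self.n_contacts + 1)]

    @classmethod
    def from_config(cls, cfg: ImplantConfig) -> "ElectrodeArray":
        return cls(cfg.n_contacts, cfg.active_range_mm, cfg.tip_mm)


@dataclass
class Insertion:
    """Placed array: achieved depth and per-contact duct-arc positions."""

    array: ElectrodeArray
    requested_mm: float
    achieved_mm: float
    contact_arc_mm: np.ndarray   # (n_contacts,) duct arc of E1..E12, mm
    contact_theta: np.ndarray    # (n_contacts,) spiral angle, rad
    contact_xyz: np.ndarray      # (n_contacts, 3) positions on the duct spiral, mm
    clamped: bool = field(default=False)

    def contact_index(self, label: str) -> int:
        labels = self.array.labels
        if label not in labels:
            raise KeyError(f"unknown contact {label!r}; expected one of {labels}")
        return labels.index(label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contact": self.array.labels,
                "arc_mm": self.contact_arc_mm,
                "x_mm": self.contact_xyz[:, 0],
                "y_mm": self.contact_xyz[:, 1],
                "z_mm": self.contact_xyz[:, 2],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def max_insertion_depth(shape: CochlearShape) -> float:
    """Deepest insertion the cochlear duct allows: the duct arc length, mm."""
    return shape.duct_length


def insert_array(
    shape: CochlearShape, ea: ElectrodeArray, requested_mm: float
) -> Insertion:
    """Virtually insert the array to ``requested_mm`` (round-window depth).

    The achieved depth is ``min(requested, duct length)``; contact Ek sits
    at duct arc ``achieved - tip - (k-1) * spacing``.  Raises
    :class:`IncompleteInsertionError` below the 24.1 mm full-insertion
    minimum (an extra-cochlear contact would remain).
    """
    if requested_mm < ea.min_insertion_mm:
        raise IncompleteInsertionError(
            f"requested depth {requested_mm:.2f} mm < minimum full insertion "
            f"{ea.min_insertion_mm:.2f} mm (active range + tip)"
        )
    deepest = max_insertion_depth(shape)
    achieved = min(requested_mm, deepest)
    if achieved < ea.min_insertion_mm:
        raise IncompleteInsertionError(
            f"duct allows only {deepest:.2f} mm, below the full-insertion minimum"
        )
    k = np.arange(ea.n_contacts)
    arcs = achieved - ea.tip_mm - k * ea.spacing_mm
    theta = shape.arc_to_theta(arcs, "duct")
    return Insertion(
        array=ea,
        requested_mm=requested_mm,
        achieved_mm=achieved,
        contact_arc_mm=arcs,
        contact_theta=theta,
        contact_xyz=shape.point_at_theta(theta, "duct"),
        clamped=achieved < requested_mm,
    )
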