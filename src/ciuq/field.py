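"""Extracellular potential at the fiber bundles (monopolar stimulation).

The head-volume conduction problem is reduced to a point current source in
an infinite homogeneous medium of resistivity ``rho``:

    V_j = rho * I / (4 pi d_j),

with ``d_j`` the 3D distance from the active contact to bundle ``j``,
floored at a small minimum to guard the singularity.  The potential is
linear in both the current and the resistivity, which preserves the
qualitative behavior that matters for outcome scoring: higher resistivity
widens the activated region and degrades selectivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import FieldConfig
from .errors import DomainError
from .geometry import FiberSet
from .implant import Insertion

__all__ = ["StimulusPulse", "PotentialField", "potential_at_fibers", "min_distance_floor"]


@dataclass(frozen=True)
class StimulusPulse:
    """Biphasic cathodic-first rectangular pulse."""

    phase_us: float = 100.0
    amplitude_ua: float = 350.0

    def __post_init__(self):
        if self.phase_us <= 0 or self.amplitude_ua <= 0:
            raise DomainError("pulse phase width and amplitude must be positive")


@dataclass
class PotentialField:
    """Per-bundle potential magnitudes for one active contact."""

    contact: str
    potentials_v: np.ndarray   # (n_bundles,), all positive and finite
    resistivity_ohm_m: float
    amplitude_ua: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bundle": np.arange(len(self.potentials_v)), "potential_v": self.potentials_v}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def min_distance_floor(d_mm, floor_mm: float = 0.1):
    """Floor a contact-to-bundle distance to avoid the point-source singularity."""
    return np.maximum(d_mm, floor_mm)


def potential_at_fibers(
    fibers: FiberSet,
    insertion: Insertion,
    contact: str,
    amplitude_ua: float,
    resistivity_ohm_m: float,
    cfg: FieldConfig | None = None,
) -> PotentialField:
    """Point-source potential magnitude at every bundle for one contact."""
    if amplitude_ua <= 0:
        raise DomainError("amplitude must be positive")
    if resistivity_ohm_m <= 0:
        raise DomainError("resistivity must be positive")
    cfg = cfg or FieldConfig()
    pos = insertion.contact_xyz[insertion.contact_index(contact)]
    d_mm = np.linalg.norm(fibers.xyz - pos, axis=1)
    d_m = min_distance_floor(d_mm, cfg.distance_floor_mm) * 1e-3
    v = resistivity_ohm_m * amplitude_ua * 1e-6 / (4.0 * np.pi * d_m)
    return PotentialField(
        contact=contact,
        potentials_v=v,
        resistivity_ohm_m=resistivity_ohm_m,
        amplitude_ua=amplitude_ua,
    )
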