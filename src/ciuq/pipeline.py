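"""End-to-end patient evaluation context.

Bundles the deterministic chain geometry -> insertion -> field ->
activation -> maps for one virtual patient, so scoring and level fitting
can reuse the same objects without re-deriving them.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .activation import activate_threshold
from .config import Config, default_config
from .field import potential_at_fibers
from .geometry import CochlearShape, FiberSet, ShapeWeights, build_cochlea, place_fibers
from .implant import ElectrodeArray, Insertion, insert_array
from .scoring import ActivationMap, ScoreSet, TargetMap, build_target_map, score_patient_maps

__all__ = ["PatientContext", "make_context"]


@dataclass
class PatientContext:
    """Everything needed to stimulate and score one virtual patient."""

    shape: CochlearShape
    fibers: FiberSet
    insertion: Insertion
    resistivity_ohm_m: float
    config: Config

    @cached_property
    def target(self) -> TargetMap:
        return build_target_map(self.fibers, self.insertion, self.config.scoring)

    def activation_column(self, contact: str, amplitude_ua: float) -> np.ndarray:
        """Boolean spike column for one contact at a given amplitude."""
        field = potential_at_fibers(
            self.fibers,
            self.insertion,
            contact,
            amplitude_ua,
            self.resistivity_ohm_m,
            self.config.field_model,
        )
        return activate_threshold(field, self.config.activation.v_threshold).spikes

    def activation_map(self, amplitude_ua: float | None = None) -> ActivationMap:
        amp = amplitude_ua or self.config.activation.pulse_amplitude_ua
        cols = [self.activation_column(c, amp) for c in self.insertion.array.labels]
        return ActivationMap(
            matrix=np.stack(cols, axis=1),
            contacts=list(self.insertion.array.labels),
            provenance={
                "amplitude_ua": amp,
                "resistivity_ohm_m": self.resistivity_ohm_m,
                "weights": list(self.shape.weights.as_array()),
                "achieved_depth_mm": self.insertion.achieved_mm,
            },
        )

    def score(self, amplitude_ua: float | None = None) -> ScoreSet:
        return score_patient_maps(self.activation_map(amplitude_ua), self.target)


def make_context(
    weights: ShapeWeights | tuple,
    requested_depth_mm: float,
    resistivity_ohm_m: float,
    cfg: Config | None = None,
) -> PatientContext:
    """Build the full deterministic context for one patient."""
    cfg = cfg or default_config()
    shape = build_cochlea(weights, cfg.geometry)
    fibers = place_fibers(shape, cfg=cfg.geometry)
    ea = ElectrodeArray.from_config(cfg.implant)
    insertion = insert_array(shape, ea, requested_depth_mm)
    return PatientContext(
        shape=shape,
        fibers=fibers,
        insertion=insertion,
        resistivity_ohm_m=resistivity_ohm_m,
        config=cfg,
    )
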