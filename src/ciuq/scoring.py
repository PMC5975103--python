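"""Outcome scoring: activation vs target maps and the derived measures.

An *activation map* records which of the fiber bundles (rows, ordered base
to apex) spike when each contact (columns E1..E12) delivers the default
stimulus.  A *target map* encodes the tonotopically ideal response per
contact: positive weights (a Gaussian peaking at the contact's place,
0.1 at the band edge) inside the 3 mm acceptable band, a constant negative
penalty outside.  Comparing the two yields

* a per-contact *local performance score* on the near-field half turn
  (frequency selectivity),
* a per-contact *cross-turn score* on the remaining bundles (unintended
  activation about half a turn away),
* global *specificity* (true-negative rate — the headline performance
  measure) and *sensitivity* over all map cells, and
* a categorical *mismatch map* (TP/TN/FP/FN per cell).

Both local scores are mapped to percent: 100 is the ideal activation
profile, 50 corresponds to no stimulation at all, 0 to the inverse profile.
A column with no positive weights (the usual cross-turn case, where any
activation is spurious) maps [worst, none] onto [0, 100] instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import Config, ScoringConfig
from .errors import DomainError
from .field import potential_at_fibers
from .activation import activate_threshold
from .geometry import FiberSet
from .implant import Insertion

__all__ = [
    "ActivationMap",
    "TargetMap",
    "ScoreSet",
    "build_activation_map",
    "build_target_map",
    "split_map",
    "electrode_score",
    "global_scores",
    "mismatch_map",
    "score_patient_maps",
    "MISMATCH_CODES",
]

#: cell categories of the mismatch map
MISMATCH_CODES = {"TN": 0, "TP": 1, "FP": 2, "FN": 3}


@dataclass
class ActivationMap:
    """Boolean bundle-by-contact spike matrix (rows base->apex, cols E1..E12)."""

    matrix: np.ndarray            # (n_bundles, n_contacts) bool
    contacts: list[str]
    provenance: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix.astype(int), columns=self.contacts)
        df.insert(0, "bundle", np.arange(self.matrix.shape[0]))
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ActivationMap":
        df = pd.read_csv(path)
        contacts = [c for c in df.columns if c != "bundle"]
        return cls(matrix=df[contacts].to_numpy(dtype=bool), contacts=contacts)


@dataclass
class TargetMap:
    """Weighted ideal-excitation template aligned with an ActivationMap."""

    weights: np.ndarray           # (n_bundles, n_contacts) float
    contacts: list[str]
    contact_arc_mm: np.ndarray    # (n_contacts,) lamina-projected contact place
    contact_theta: np.ndarray     # (n_contacts,) spiral angle of each contact
    fiber_arc_mm: np.ndarray      # (n_bundles,)
    fiber_theta: np.ndarray       # (n_bundles,)
    band_halfwidth_mm: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.weights, columns=self.contacts)
        df.insert(0, "bundle", np.arange(self.weights.shape[0]))
        return df


def build_activation_map(
    fibers: FiberSet,
    insertion: Insertion,
    amplitude_ua: float,
    resistivity_ohm_m: float,
    cfg: Config,
    provenance: dict | None = None,
) -> ActivationMap:
    """Run the field + threshold-activation pipeline for every contact."""
    cols = []
    for label in insertion.array.labels:
        field = potential_at_fibers(
            fibers, insertion, label, amplitude_ua, resistivity_ohm_m, cfg.field_model
        )
        cols.append(activate_threshold(field, cfg.activation.v_threshold).spikes)
    return ActivationMap(
        matrix=np.stack(cols, axis=1),
        contacts=list(insertion.array.labels),
        provenance=provenance,
    )


def build_target_map(
    fibers: FiberSet, insertion: Insertion, cfg: ScoringConfig | None = None
) -> TargetMap:
    """Ideal-excitation template from the tonotopic place of each contact.

    Each contact's target is centered at its own lamina-projected arc
    position (place-matched); in-band weights follow a Gaussian whose value
    at the band edge is ``band_edge_weight``; out-of-band cells carry the
    constant penalty ``-out_of_band_penalty``.
    """
    cfg = cfg or ScoringConfig()
    hw = cfg.band_halfwidth_mm
    sigma = hw / np.sqrt(2.0 * np.log(1.0 / cfg.band_edge_weight))
    # project each contact radially onto the lamina spiral (same angle)
    theta_e = insertion.contact_theta
    s_e = np.interp(theta_e, fibers.theta, fibers.arc_mm)
    ds = fibers.arc_mm[:, None] - s_e[None, :]
    in_band = np.abs(ds) <= hw
    w = np.where(
        in_band,
        np.exp(-(ds**2) / (2.0 * sigma**2)),
        -cfg.out_of_band_penalty,
    )
    return TargetMap(
        weights=w,
        contacts=list(insertion.array.labels),
        contact_arc_mm=s_e,
        contact_theta=theta_e,
        fiber_arc_mm=fibers.arc_mm,
        fiber_theta=fibers.theta,
        band_halfwidth_mm=hw,
    )


def split_map(
    amap: ActivationMap, target: TargetMap, contact: str
) -> tuple[np.ndarray, np.ndarray]:
    """Near-field / cross-turn bundle masks for one contact.

    Near field is the half turn centered on the contact (bundles within
    ±pi/2 of its spiral angle); cross-turn is everything else.  The masks
    partition the column.
    """
    e = target.contacts.index(contact)
    near = np.abs(target.fiber_theta - target.contact_theta[e]) <= np.pi / 2.0
    return near, ~near


def electrode_score(active: np.ndarray, weights: np.ndarray) -> float:
    """Map a weighted activation sum onto a 0–100 score.

    50 is no stimulation, 100 the ideal profile (all positive-weight
    bundles and nothing else), 0 the inverse profile.  For a column with no
    positive weights the attainable range [worst, none] maps to [0, 100].
    Returns NaN for an all-zero weight column (score undefined).
    """
    active = np.asarray(active, dtype=bool)
    weights = np.asarray(weights, dtype=float)
    if active.shape != weights.shape:
        raise DomainError("activation and weight columns differ in length")
    raw = float(weights[active].sum())
    pos = float(weights[weights > 0].sum())
    neg = float(weights[weights < 0].sum())
    if pos == 0.0 and neg == 0.0:
        return float("nan")
    if pos == 0.0:
        return 100.0 * (1.0 - raw / neg)
    if neg == 0.0:
        return 50.0 + 50.0 * raw / pos
    if raw >= 0.0:
        return 50.0 + 50.0 * raw / pos
    return 50.0 + 50.0 * raw / abs(neg)


def global_scores(amap: ActivationMap, target: TargetMap) -> tuple[float, float]:
    """(specificity, sensitivity) over all map cells.

    Positive-weight cells are "should fire"; specificity = TN/(TN+FP) is
    the global performance measure, sensitivity = TP/(TP+FN).
    """
    should = target.weights > 0
    if not should.any():
        raise DomainError("degenerate target map: no positive-weight cells")
    act = amap.matrix
    tp = np.count_nonzero(act & should)
    fn = np.count_nonzero(~act & should)
    fp = np.count_nonzero(act & ~should)
    tn = np.count_nonzero(~act & ~should)
    return tn / (tn + fp), tp / (tp + fn)


def mismatch_map(amap: ActivationMap, target: TargetMap) -> np.ndarray:
    """Categorical comparison per cell, coded by :data:`MISMATCH_CODES`."""
    should = target.weights > 0
    act = amap.matrix
    out = np.full(act.shape, MISMATCH_CODES["TN"], dtype=np.int8)
    out[act & should] = MISMATCH_CODES["TP"]
    out[act & ~should] = MISMATCH_CODES["FP"]
    out[~act & should] = MISMATCH_CODES["FN"]
    return out


@dataclass
class ScoreSet:
    """All outcome measures for one patient."""

    contacts: list[str]
    local: np.ndarray        # (n_contacts,) percent
    cross_turn: np.ndarray   # (n_contacts,) percent
    specificity: float
    sensitivity: float

    def to_dict(self) -> dict:
        d = {"specificity": self.specificity, "sensitivity": self.sensitivity}
        for i, c in enumerate(self.contacts):
            d[f"local_{c}"] = float(self.local[i])
            d[f"cross_{c}"] = float(self.cross_turn[i])
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"contact": self.contacts, "local_score": self.local, "cross_turn_score": self.cross_turn}
        )


def score_patient_maps(amap: ActivationMap, target: TargetMap) -> ScoreSet:
    """Local, cross-turn and global measures from one activation/target pair."""
    n_c = len(amap.contacts)
    local = np.empty(n_c)
    cross = np.empty(n_c)
    for e, label in enumerate(amap.contacts):
        near, far = split_map(amap, target, label)
        local[e] = electrode_score(amap.matrix[near, e], target.weights[near, e])
        cross[e] = electrode_score(amap.matrix[far, e], target.weights[far, e])
    spec, sens = global_scores(amap, target)
    return ScoreSet(
        contacts=list(amap.contacts),
        local=local,
        cross_turn=cross,
        specificity=spec,
        sensitivity=sens,
    )
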