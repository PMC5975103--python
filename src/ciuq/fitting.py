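"""Post-implantation stimulus-level fitting (T- and C-levels).

The T-level of a contact is the smallest amplitude producing a first neural
response inside the contact's 3 mm target band; the C-level is the
amplitude that best trades maximal in-band recruitment against cross-turn
and out-of-band activation.  Levels are searched on a coarse amplitude grid
and the T-level is refined to 1 uA by bisection, which is exact for the
monotone threshold backend.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import FittingConfig
from .errors import DomainError
from .pipeline import PatientContext

__all__ = ["LevelResult", "find_t_level", "find_c_level", "fit_levels", "default_grid"]


@dataclass
class LevelResult:
    """Fitted per-contact stimulation levels, uA."""

    contacts: list[str]
    t_level_ua: np.ndarray
    c_level_ua: np.ndarray
    objective_at_c: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"contact": self.contacts, "T_uA": self.t_level_ua, "C_uA": self.c_level_ua}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def default_grid(cfg: FittingConfig | None = None) -> np.ndarray:
    cfg = cfg or FittingConfig()
    return np.arange(cfg.grid_min_ua, cfg.grid_max_ua + cfg.grid_step_ua, cfg.grid_step_ua)


def _in_band_mask(ctx: PatientContext, contact: str) -> np.ndarray:
    e = ctx.target.contacts.index(contact)
    return np.abs(ctx.target.fiber_arc_mm - ctx.target.contact_arc_mm[e]) <= ctx.target.band_halfwidth_mm


def _check_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise DomainError("empty amplitude grid")
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise DomainError("amplitude grid must be positive and strictly ascending")
    return grid


def find_t_level(
    ctx: PatientContext,
    contact: str,
    grid: np.ndarray | None = None,
    refine_ua: float | None = None,
) -> float | None:
    """Smallest amplitude with at least one in-band spike; None if unreachable.

    Scans the grid for the first in-band response, then bisects between the
    bracketing grid points down to ``refine_ua`` resolution.
    """
    grid = _check_grid(default_grid(ctx.config.fitting) if grid is None else grid)
    refine = refine_ua or ctx.config.fitting.refine_ua
    band = _in_band_mask(ctx, contact)

    def responds(amp: float) -> bool:
        return bool(ctx.activation_column(contact, amp)[band].any())

    hit = next((i for i, amp in enumerate(grid) if responds(amp)), None)
    if hit is None:
        return None
    lo = 0.0 if hit == 0 else float(grid[hit - 1])
    hi = float(grid[hit])
    while hi - lo > refine:
        mid = 0.5 * (lo + hi)
        if responds(mid):
            hi = mid
        else:
            lo = mid
    return hi


def _column_objective(
    ctx: PatientContext, contact: str, amp: float, lam: float
) -> tuple[float, float]:
    """(sensitivity + specificity - lam * cross-turn fraction, cross fraction)."""
    e = ctx.target.contacts.index(contact)
    active = ctx.activation_column(contact, amp)
    should = ctx.target.weights[:, e] > 0
    tp = np.count_nonzero(active & should)
    fn = np.count_nonzero(~active & should)
    fp = np.count_nonzero(active & ~should)
    tn = np.count_nonzero(~active & ~should)
    sens = tp / (tp + fn) if (tp + fn) else 0.0
    spec = tn / (tn + fp) if (tn + fp) else 0.0
    _, far = split_map_masks(ctx, contact)
    cross_frac = float(active[far].mean()) if far.any() else 0.0
    return sens + spec - lam * cross_frac, cross_frac


def split_map_masks(ctx: PatientContext, contact: str) -> tuple[np.ndarray, np.ndarray]:
    e = ctx.target.contacts.index(contact)
    near = np.abs(ctx.target.fiber_theta - ctx.target.contact_theta[e]) <= np.pi / 2.0
    return near, ~near


def find_c_level(
    ctx: PatientContext,
    contact: str,
    grid: np.ndarray | None = None,
    lam: float | None = None,
) -> tuple[float | None, float]:
    """Amplitude maximizing column sensitivity + specificity - lam * cross-turn.

    Constrained to amplitudes at or above the T-level; ties break toward
    the lowest amplitude.  Returns (C-level, objective); (None, nan) when
    the T-level itself is undefined.
    """
    grid = _check_grid(default_grid(ctx.config.fitting) if grid is None else grid)
    lam = ctx.config.fitting.cross_turn_lambda if lam is None else lam
    if lam < 0:
        raise DomainError("cross-turn penalty weight must be nonnegative")
    t = find_t_level(ctx, contact, grid)
    if t is None:
        return None, float("nan")
    candidates = grid[grid >= t]
    if candidates.size == 0:
        candidates = np.array([t])
    best_amp, best_obj = None, -np.inf
    for amp in candidates:
        obj, _ = _column_objective(ctx, contact, float(amp), lam)
        if obj > best_obj + 1e-12:
            best_amp, best_obj = float(amp), obj
    return best_amp, best_obj


def fit_levels(
    ctx: PatientContext,
    grid: np.ndarray | None = None,
    lam: float | None = None,
) -> LevelResult:
    """T- and C-levels for every contact of the inserted array."""
    labels = ctx.insertion.array.labels
    t = np.full(len(labels), np.nan)
    c = np.full(len(labels), np.nan)
    obj = np.full(len(labels), np.nan)
    for i, label in enumerate(labels):
        ti = find_t_level(ctx, label, grid)
        if ti is None:
            continue
        t[i] = ti
        ci, oi = find_c_level(ctx, label, grid, lam)
        c[i] = ci if ci is not None else np.nan
        obj[i] = oi
    return LevelResult(contacts=list(labels), t_level_ua=t, c_level_ua=c, objective_at_c=obj)
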