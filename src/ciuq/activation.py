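"""Fiber-bundle spike decisions for a given potential field.

Two backends decide which bundles fire.  The default *threshold* backend
declares a spike wherever the local extracellular potential magnitude
reaches a calibrated voltage; it is exact for the linear point-source field
and fast enough for population studies.  The optional *hh* backend
integrates a single-compartment Hodgkin–Huxley membrane per bundle, driven
by the biphasic cathodic-first pulse scaled by the local potential, with
rate constants Q10-accelerated to human temperature; a spike is a membrane
depolarization beyond a fixed criterion within the observation window.
Either way a bundle's response is a single all-or-none spike.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ActivationConfig, default_config
from .errors import BackendError, DomainError
from .field import PotentialField, StimulusPulse
from .geometry import FiberSet

__all__ = [
    "ActivationVector",
    "HHParams",
    "activate_threshold",
    "activate_hh",
    "hh_current_threshold",
    "activated_arc_span",
]


@dataclass
class ActivationVector:
    """Boolean spike indicator per bundle, with provenance."""

    spikes: np.ndarray          # (n_bundles,) bool
    backend: str
    contact: str
    amplitude_ua: float

    def __len__(self) -> int:
        return len(self.spikes)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"bundle": np.arange(len(self.spikes)), "spike": self.spikes.astype(int)}).to_csv(
            path, index=False
        )


def activate_threshold(
    field: PotentialField, v_threshold: float
) -> ActivationVector:
    """Bundle j spikes iff V_j >= v_threshold.

    Monotone in stimulation amplitude: since the field is linear in the
    current, raising the amplitude can only grow the activated set.
    """
    if v_threshold <= 0:
        raise DomainError("activation threshold must be positive")
    return ActivationVector(
        spikes=field.potentials_v >= v_threshold,
        backend="threshold",
        contact=field.contact,
        amplitude_ua=field.amplitude_ua,
    )


# ---------------------------------------------------------------------------
# Single-compartment Hodgkin–Huxley backend


@dataclass(frozen=True)
class HHParams:
    """Classic HH membrane constants (rest-relative voltages, mV; mS/cm^2)."""

    c_m: float = 1.0      # uF/cm^2
    g_na: float = 120.0
    g_k: float = 36.0
    g_l: float = 0.3
    e_na: float = 115.0
    e_k: float = -12.0
    e_l: float = 10.6
    q10: float = 3.0
    t_ref_c: float = 6.3  # temperature the rate constants were fitted at


def _safe_exprel_ratio(u: np.ndarray) -> np.ndarray:
    """u / (exp(u/10) - 1), continuous through u = 0."""
    u = np.asarray(u, dtype=float)
    small = np.abs(u) < 1e-7
    den = np.where(small, 1.0, np.expm1(np.where(small, 1.0, u) / 10.0))
    return np.where(small, 10.0 - u / 2.0, u / den)


def _rates(v: np.ndarray):
    a_m = 0.1 * _safe_exprel_ratio(25.0 - v)
    b_m = 4.0 * np.exp(-v / 18.0)
    a_h = 0.07 * np.exp(-v / 20.0)
    b_h = 1.0 / (np.exp((30.0 - v) / 10.0) + 1.0)
    a_n = 0.01 * _safe_exprel_ratio(10.0 - v)
    b_n = 0.125 * np.exp(-v / 80.0)
    return a_m, b_m, a_h, b_h, a_n, b_n


def _integrate_hh(
    drive_ua_cm2: np.ndarray, pulse: StimulusPulse, cfg: ActivationConfig, p: HHParams
) -> np.ndarray:
    """Integrate one HH compartment per bundle; returns peak depolarization (mV).

    The extracellular coupling injects ``+drive`` during the cathodic phase
    (depolarizing for nearby tissue) and ``-drive`` during the anodic phase.
    Exponential-Euler gating, forward-Euler voltage, fixed step.
    """
    phi = p.q10 ** ((cfg.hh_temperature_c - p.t_ref_c) / 10.0)
    dt = cfg.hh_dt_us * 1e-3  # ms
    n_steps = int(round(cfg.hh_window_ms / dt))
    phase_steps = int(round(pulse.phase_us * 1e-3 / dt))

    v = np.zeros_like(drive_ua_cm2)
    a_m, b_m, a_h, b_h, a_n, b_n = _rates(v)
    m = a_m / (a_m + b_m)
    h = a_h / (a_h + b_h)
    n = a_n / (a_n + b_n)
    peak = np.zeros_like(v)

    for step in range(n_steps):
        if step < phase_steps:
            i_stim = drive_ua_cm2
        elif step < 2 * phase_steps:
            i_stim = -drive_ua_cm2
        else:
            i_stim = 0.0
        a_m, b_m, a_h, b_h, a_n, b_n = _rates(v)
        for gate, a, b in ((0, a_m, b_m), (1, a_h, b_h), (2, a_n, b_n)):
            tot = phi * (a + b)
            inf = a / (a + b)
            decay = np.exp(-dt * tot)
            if gate == 0:
                m = inf + (m - inf) * decay
            elif gate == 1:
                h = inf + (h - inf) * decay
            else:
                n = inf + (n - inf) * decay
        i_ion = (
            p.g_na * m**3 * h * (v - p.e_na)
            + p.g_k * n**4 * (v - p.e_k)
            + p.g_l * (v - p.e_l)
        )
        v = v + dt * (i_stim - i_ion) / p.c_m
        np.maximum(peak, v, out=peak)
    if not np.all(np.isfinite(v)):
        bad = int(np.flatnonzero(~np.isfinite(v))[0])
        raise BackendError(f"HH integration diverged at bundle {bad}")
    return peak


def activate_hh(
    field: PotentialField,
    pulse: StimulusPulse | None = None,
    hh_params: HHParams | None = None,
    cfg: ActivationConfig | None = None,
) -> ActivationVector:
    """Spike decision by single-compartment HH integration per bundle.

    The drive current is ``hh_drive_gain * V_j`` (uA/cm^2), following the
    biphasic waveform; a bundle spikes if its membrane depolarizes past
    ``hh_spike_mv`` within the window.  A single spike is counted per pulse.
    """
    cfg = cfg or default_config().activation
    pulse = pulse or StimulusPulse(cfg.pulse_phase_us, field.amplitude_ua)
    p = hh_params or HHParams()
    drive = cfg.hh_drive_gain * field.potentials_v
    peak = _integrate_hh(drive, pulse, cfg, p)
    return ActivationVector(
        spikes=peak >= cfg.hh_spike_mv,
        backend="hh",
        contact=field.contact,
        amplitude_ua=field.amplitude_ua,
    )


def hh_current_threshold(
    pulse: StimulusPulse | None = None,
    cfg: ActivationConfig | None = None,
    hh_params: HHParams | None = None,
    tol_ua_cm2: float = 0.05,
) -> float:
    """Smallest drive current (uA/cm^2) that elicits an HH spike, by bisection."""
    cfg = cfg or default_config().activation
    pulse = pulse or StimulusPulse(cfg.pulse_phase_us, cfg.pulse_amplitude_ua)
    p = hh_params or HHParams()

    def spikes(i_drive: float) -> bool:
        peak = _integrate_hh(np.array([i_drive]), pulse, cfg, p)
        return bool(peak[0] >= cfg.hh_spike_mv)

    lo, hi = 0.0, 50.0
    while not spikes(hi):
        hi *= 2.0
        if hi > 1e6:
            raise BackendError("no HH spike found at any drive level")
    while hi - lo > tol_ua_cm2:
        mid = 0.5 * (lo + hi)
        if spikes(mid):
            hi = mid
        else:
            lo = mid
    return hi


def activated_arc_span(fibers: FiberSet, activation: ActivationVector) -> float:
    """Arc extent (mm) covered by the activated bundles; 0 if none fire."""
    s = fibers.arc_mm[activation.spikes]
    return float(s.max() - s.min()) if s.size else 0.0
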