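"""Parametric cochlear geometry, fiber placement and tonotopy.

The cochlea is modeled as a logarithmic spiral rising along the modiolar
axis,

    r(theta) = a * exp(-b * theta),   z(theta) = p * theta / (2 pi),

with ``theta`` in ``[0, 2 pi * turns]`` measured from the basal end (round
window).  Three shape weights, in standard-deviation units of a virtual
population, deform the mean shape:

* ``w1`` — overall size: scales every length (spiral radius and pitch).
* ``w2`` — spiral radius/tightness: scales the basal radius ``a`` while the
  radial decay ``b`` is re-solved so the lamina arc length is preserved, so
  this mode changes how tightly the cochlea coils, not how long it is.
* ``w3`` — rotation/height: scales the vertical pitch ``p``.

Two concentric spirals are carried: the *lamina* spiral, on which the
auditory-nerve-fiber bundles sit, and the *duct* spiral, radially outside it
at a lateral-wall offset that tapers from base to apex (the scala narrows
apically), on which the electrode contacts ride.  Arc length along either
spiral is the package-wide coordinate; the gains and base constants are
calibrated once so the mean-shape lamina length is 25.3 mm and the
population SD of lamina length is about 1.1 mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

from .config import GeometryConfig, default_config
from .errors import DomainError, InvalidShapeError

__all__ = [
    "ShapeWeights",
    "CochlearShape",
    "FiberSet",
    "build_cochlea",
    "arc_to_point",
    "tonotopic_frequency",
    "place_fibers",
]

Spiral = Literal["lamina", "duct"]

_N_GRID = 2049  # dense theta grid for the arc-length splines


@dataclass(frozen=True)
class ShapeWeights:
    """Mode weights of the virtual-population shape model, in SD units."""

    w1: float = 0.0
    w2: float = 0.0
    w3: float = 0.0
    max_abs: float = 3.0

    def __post_init__(self):
        for name in ("w1", "w2", "w3"):
            v = getattr(self, name)
            if not np.isfinite(v) or abs(v) > self.max_abs:
                raise InvalidShapeError(
                    f"{name}={v} outside the plausible range |w| <= {self.max_abs}"
                )

    def as_array(self) -> np.ndarray:
        return np.array([self.w1, self.w2, self.w3])


def _planar_length_factor(b: float, theta_max: float) -> float:
    """Arc length of the flat spiral r = e^{-b theta} per unit basal radius."""
    return np.sqrt(1.0 + b * b) * (1.0 - np.exp(-b * theta_max)) / b


class _ArcMap:
    """Monotone arc-length <-> angle map for one spiral, spline-backed."""

    def __init__(self, radius_fn, dradius_fn, pitch_per_rad: float, theta_max: float):
        self.radius_fn = radius_fn
        self.dradius_fn = dradius_fn
        self.pitch_per_rad = pitch_per_rad
        self.theta_max = theta_max
        theta = np.linspace(0.0, theta_max, _N_GRID)
        self._speed = CubicSpline(theta, self.speed(theta))
        self._arc = self._speed.antiderivative()
        self._theta_grid = theta
        self._arc_grid = self._arc(theta)
        self.length = float(self._arc_grid[-1])

    def speed(self, theta):
        r = self.radius_fn(theta)
        dr = self.dradius_fn(theta)
        return np.sqrt(dr * dr + r * r + self.pitch_per_rad**2)

    def arc(self, theta):
        return self._arc(theta)

    def theta(self, s):
        """Invert s(theta); interpolation start plus two Newton steps."""
        s = np.asarray(s, dtype=float)
        t = np.interp(s, self._arc_grid, self._theta_grid)
        for _ in range(2):
            t = t - (self._arc(t) - s) / self._speed(t)
            t = np.clip(t, 0.0, self.theta_max)
        return t

    def point(self, theta, z_per_rad: float):
        theta = np.asarray(theta, dtype=float)
        r = self.radius_fn(theta)
        return np.stack(
            [r * np.cos(theta), r * np.sin(theta), z_per_rad * theta], axis=-1
        )


@dataclass
class CochlearShape:
    """A concrete cochlea: calibrated spiral constants plus arc-length maps."""

    weights: ShapeWeights
    scale: float            # overall size factor (mode 1)
    basal_radius: float     # a, mm (after modes 1 and 2)
    radial_decay: float     # b, 1/rad (after mode 2)
    pitch: float            # mm per turn (after modes 1 and 3)
    theta_max: float        # rad, fixed angular extent
    duct_offset_base: float  # mm, lateral-wall offset at theta=0
    duct_offset_apex: float  # mm, at theta=theta_max

    def __post_init__(self):
        a, b = self.basal_radius, self.radial_decay
        p_rad = self.pitch / (2.0 * np.pi)
        c0 = self.duct_offset_base
        c1 = (self.duct_offset_apex - self.duct_offset_base) / self.theta_max
        self._maps = {
            "lamina": _ArcMap(
                lambda t: a * np.exp(-b * t),
                lambda t: -a * b * np.exp(-b * t),
                p_rad,
                self.theta_max,
            ),
            "duct": _ArcMap(
                lambda t: a * np.exp(-b * t) + c0 + c1 * t,
                lambda t: -a * b * np.exp(-b * t) + c1,
                p_rad,
                self.theta_max,
            ),
        }
        if self.lamina_length <= 0:
            raise InvalidShapeError("degenerate shape: nonpositive lamina length")

    @property
    def lamina_length(self) -> float:
        """Arc length of the osseous spiral lamina, mm (the size measure)."""
        return self._maps["lamina"].length

    @property
    def duct_length(self) -> float:
        """Arc length of the cochlear-duct spiral, mm (insertion bound)."""
        return self._maps["duct"].length

    def length(self, spiral: Spiral) -> float:
        return self._maps[spiral].length

    def arc_to_theta(self, s, spiral: Spiral = "lamina"):
        s_arr = np.asarray(s, dtype=float)
        L = self._maps[spiral].length
        if np.any(s_arr < -1e-9) or np.any(s_arr > L + 1e-9):
            raise DomainError(f"arc position outside [0, {L:.3f}] mm on {spiral} spiral")
        return self._maps[spiral].theta(np.clip(s_arr, 0.0, L))

    def theta_to_arc(self, theta, spiral: Spiral = "lamina"):
        return self._maps[spiral].arc(theta)

    def point_at_theta(self, theta, spiral: Spiral = "lamina"):
        return self._maps[spiral].point(theta, self.pitch / (2.0 * np.pi))

    def arc_to_point(self, s, spiral: Spiral = "lamina"):
        return self.point_at_theta(self.arc_to_theta(s, spiral), spiral)

    def descriptor(self) -> dict:
        """JSON-serializable summary of the shape."""
        return {
            "weights": list(self.weights.as_array()),
            "scale": self.scale,
            "basal_radius_mm": self.basal_radius,
            "radial_decay": self.radial_decay,
            "pitch_mm_per_turn": self.pitch,
            "theta_max_rad": self.theta_max,
            "lamina_length_mm": self.lamina_length,
            "duct_length_mm": self.duct_length,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.descriptor(), indent=2))


def build_cochlea(weights: ShapeWeights, cfg: GeometryConfig | None = None) -> CochlearShape:
    """Build a cochlea from shape weights using the calibrated spiral model.

    Deterministic.  Mode 2 deforms radius and decay jointly at constant
    lamina length; modes 1 and 3 scale size and pitch.
    """
    cfg = cfg or default_config().geometry
    if not isinstance(weights, ShapeWeights):
        weights = ShapeWeights(*weights, max_abs=cfg.max_abs_weight)
    theta_max = 2.0 * np.pi * cfg.turns
    scale = 1.0 + cfg.w1_gain * weights.w1
    if scale <= 0:
        raise InvalidShapeError("mode-1 weight collapses the shape")

    a0, b0 = cfg.basal_radius_mm, cfg.radial_decay
    a2 = a0 * (1.0 + cfg.w2_gain * weights.w2)
    target = a0 * _planar_length_factor(b0, theta_max)
    if weights.w2 == 0.0:
        b2 = b0
    else:
        b2 = brentq(
            lambda b: a2 * _planar_length_factor(b, theta_max) - target, 1e-3, 2.0
        )
    pitch = scale * cfg.pitch_mm_per_turn * (1.0 + cfg.w3_gain * weights.w3)
    return CochlearShape(
        weights=weights,
        scale=scale,
        basal_radius=scale * a2,
        radial_decay=b2,
        pitch=pitch,
        theta_max=theta_max,
        duct_offset_base=scale * cfg.duct_offset_base_mm,
        duct_offset_apex=scale * cfg.duct_offset_apex_mm,
    )


def arc_to_point(shape: CochlearShape, s, spiral: Spiral = "lamina"):
    """3D position (mm) at arc position ``s`` (mm from the round window)."""
    return shape.arc_to_point(s, spiral)


def tonotopic_frequency(x, cfg: GeometryConfig | None = None):
    """Greenwood place-frequency map.

    ``x`` is the fractional distance from the apex in [0, 1]; returns the
    characteristic frequency in Hz, F = A (10^(a x) - k), increasing from
    ~20 Hz at the apex to ~20 kHz at the base.
    """
    cfg = cfg or default_config().geometry
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0) or np.any(x_arr > 1):
        raise DomainError("fractional distance from apex must lie in [0, 1]")
    out = cfg.greenwood_A * (10.0 ** (cfg.greenwood_a * x_arr) - cfg.greenwood_k)
    return out if np.ndim(x) else float(out)


@dataclass
class FiberSet:
    """Tonotopically mapped nerve-fiber bundles on the lamina spiral."""

    arc_mm: np.ndarray          # (n,) strictly increasing, mm from round window
    theta: np.ndarray           # (n,) spiral angle of each bundle, rad
    xyz: np.ndarray             # (n, 3) positions, mm
    frequency_hz: np.ndarray    # (n,) strictly decreasing base -> apex
    band_halfwidth_mm: np.ndarray  # (n,) half of the inter-bundle spacing
    fibers_per_bundle: int
    lamina_length: float

    def __len__(self) -> int:
        return len(self.arc_mm)

    @property
    def n_bundles(self) -> int:
        return len(self.arc_mm)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bundle": np.arange(self.n_bundles),
                "arc_mm": self.arc_mm,
                "x_mm": self.xyz[:, 0],
                "y_mm": self.xyz[:, 1],
                "z_mm": self.xyz[:, 2],
                "frequency_hz": self.frequency_hz,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def place_fibers(
    shape: CochlearShape,
    n_bundles: int | None = None,
    total_fibers: int | None = None,
    cfg: GeometryConfig | None = None,
) -> FiberSet:
    """Place fiber bundles uniformly in arc length along the lamina spiral.

    ``n`` bundles sit at s = i L / (n + 1), i = 1..n (uniform interior
    placement), each representing ``round(total_fibers / n)`` fibers and
    carrying the Greenwood frequency of its place.
    """
    cfg = cfg or default_config().geometry
    n = cfg.n_bundles if n_bundles is None else int(n_bundles)
    total = cfg.total_fibers if total_fibers is None else int(total_fibers)
    if n < 2:
        raise DomainError("need at least 2 fiber bundles")
    L = shape.lamina_length
    s = L * np.arange(1, n + 1) / (n + 1)
    theta = shape.arc_to_theta(s, "lamina")
    return FiberSet(
        arc_mm=s,
        theta=theta,
        xyz=shape.point_at_theta(theta, "lamina"),
        frequency_hz=tonotopic_frequency(1.0 - s / L, cfg),
        band_halfwidth_mm=np.full(n, L / (2.0 * (n + 1))),
        fibers_per_bundle=int(round(total / n)),
        lamina_length=L,
    )
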