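"""Uncertainty propagation: Monte Carlo and the Probabilistic Collocation
Method (PCM).

PCM is non-intrusive polynomial chaos: each normally distributed input is
standardized to a random basis xi = (omega - mu) / sigma, the deterministic
model is evaluated at the (n+1)^p tensor product of probabilists'
Gauss–Hermite abscissae (the roots of the degree-(n+1) Hermite polynomial),
and a Lagrange surrogate interpolates those nodal values.  Moments follow
from the quadrature weights k_i:

    mean     = sum_i  f_i * k_i
    variance = sum_i (f_i - mean)^2 * k_i

with tensor weights the products of the one-dimensional ones.  The
quadrature integrates polynomials up to degree 2(n+1)-1 exactly against the
normal density, so low orders already capture smooth responses.  Truncated
distributions are not representable in this Hermite basis and are restricted
to Monte Carlo, which handles them by rejection sampling.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import roots_hermitenorm

from .errors import DomainError

__all__ = [
    "UncertainParameter",
    "CollocationPlan",
    "SurrogateModel",
    "UQResult",
    "hermite_collocation",
    "tensor_plan",
    "pcm_moments",
    "propagate_pcm",
    "run_mc",
]

ModelFn = Callable[[np.ndarray], Mapping[str, float] | float]


@dataclass(frozen=True)
class UncertainParameter:
    """Normally distributed input, optionally truncated at ±bound sigma."""

    name: str
    mean: float
    sd: float
    truncation_sd: float | None = None
    units: str = ""

    def __post_init__(self):
        if self.sd <= 0:
            raise DomainError(f"{self.name}: sd must be positive")
        if self.truncation_sd is not None and self.truncation_sd <= 0:
            raise DomainError(f"{self.name}: truncation bound must be positive")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw n values; truncation by rejection (re-sample until inside)."""
        x = rng.normal(self.mean, self.sd, size=n)
        if self.truncation_sd is not None:
            bound = self.truncation_sd * self.sd
            bad = np.abs(x - self.mean) > bound
            while bad.any():
                x[bad] = rng.normal(self.mean, self.sd, size=int(bad.sum()))
                bad = np.abs(x - self.mean) > bound
        return x


def hermite_collocation(
    param: UncertainParameter, npoints: int
) -> tuple[np.ndarray, np.ndarray]:
    """1-D collocation nodes and weights for one normal parameter.

    Nodes are mu + sigma * (probabilists' Gauss–Hermite abscissae); weights
    are normalized to sum to one, so they integrate polynomials of degree
    <= 2 npoints - 1 exactly against N(mu, sigma^2).
    """
    if npoints < 1:
        raise DomainError("need at least one collocation point")
    if param.truncation_sd is not None:
        raise DomainError(
            f"{param.name}: truncated parameters are not supported by PCM; use Monte Carlo"
        )
    if npoints == 1:
        return np.array([param.mean]), np.array([1.0])
    xi, w = roots_hermitenorm(npoints)
    order = np.argsort(xi)
    xi, w = xi[order], w[order]
    return param.mean + param.sd * xi, w / w.sum()


@dataclass
class CollocationPlan:
    """Tensor-product collocation grid over p parameters at order n."""

    params: list[UncertainParameter]
    order: int
    nodes_1d: list[np.ndarray]
    weights_1d: list[np.ndarray]
    tensor_nodes: np.ndarray    # ((n+1)^p, p)
    tensor_weights: np.ndarray  # ((n+1)^p,), sums to 1

    @property
    def n_nodes(self) -> int:
        return self.tensor_nodes.shape[0]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "order": self.order,
                    "params": [p.name for p in self.params],
                    "tensor_nodes": self.tensor_nodes.tolist(),
                    "tensor_weights": self.tensor_weights.tolist(),
                },
                indent=2,
            )
        )


def tensor_plan(params: Sequence[UncertainParameter], order: int) -> CollocationPlan:
    """Full tensor grid: (order+1) nodes per dimension, product weights."""
    if not params:
        raise DomainError("need at least one uncertain parameter")
    if order < 1:
        raise DomainError("polynomial order must be >= 1")
    npoints = order + 1
    nodes_1d, weights_1d = zip(*(hermite_collocation(p, npoints) for p in params))
    tensor_nodes = np.array(list(itertools.product(*nodes_1d)))
    tensor_weights = np.array(
        [np.prod(combo) for combo in itertools.product(*weights_1d)]
    )
    return CollocationPlan(
        params=list(params),
        order=order,
        nodes_1d=list(nodes_1d),
        weights_1d=list(weights_1d),
        tensor_nodes=tensor_nodes,
        tensor_weights=tensor_weights,
    )


def pcm_moments(values: np.ndarray, plan: CollocationPlan) -> tuple[float, float]:
    """Weighted mean and variance of nodal model values on a plan."""
    values = np.asarray(values, dtype=float)
    if values.shape != (plan.n_nodes,):
        raise DomainError(
            f"expected {plan.n_nodes} nodal values, got shape {values.shape}"
        )
    mean = float(np.dot(plan.tensor_weights, values))
    var = float(np.dot(plan.tensor_weights, (values - mean) ** 2))
    return mean, var


class SurrogateModel:
    """Lagrange-interpolated response surface over the random basis xi."""

    def __init__(self, plan: CollocationPlan, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (plan.n_nodes,):
            raise DomainError("one nodal value per tensor node required")
        self.plan = plan
        npoints = plan.order + 1
        p = len(plan.params)
        self._values = values.reshape((npoints,) * p)
        # standardized 1-D node locations per dimension
        self._xi_nodes = [
            (plan.nodes_1d[d] - plan.params[d].mean) / plan.params[d].sd
            for d in range(p)
        ]

    @staticmethod
    def _lagrange_basis(nodes: np.ndarray, x: float) -> np.ndarray:
        basis = np.empty(len(nodes))
        for i, xi in enumerate(nodes):
            others = np.delete(nodes, i)
            basis[i] = np.prod((x - others) / (xi - others))
        return basis

    def __call__(self, point: Sequence[float]) -> float:
        point = np.asarray(point, dtype=float)
        p = len(self.plan.params)
        if point.shape != (p,):
            raise DomainError(f"expected a point of dimension {p}")
        out = self._values
        for d in range(p):
            xi = (point[d] - self.plan.params[d].mean) / self.plan.params[d].sd
            if abs(xi) > 4.0:
                warnings.warn(
                    f"surrogate evaluated {abs(xi):.1f} sigma from the mean "
                    f"of {self.plan.params[d].name}; extrapolation",
                    stacklevel=2,
                )
            basis = self._lagrange_basis(self._xi_nodes[d], xi)
            out = np.tensordot(basis, out, axes=(0, 0))
        return float(out)


@dataclass
class UQResult:
    """Propagated mean/variance per output quantity."""

    method: str                       # "mc" | "pcm"
    n_runs: int
    outputs: dict[str, tuple[float, float]]   # name -> (mean, variance)
    seed: int | None = None
    order: int | None = None
    n_failures: int = 0
    samples: pd.DataFrame | None = field(default=None, repr=False)

    def mean(self, name: str) -> float:
        return self.outputs[name][0]

    def variance(self, name: str) -> float:
        return self.outputs[name][1]

    def sd(self, name: str) -> float:
        return float(np.sqrt(self.outputs[name][1]))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "method": self.method,
                    "n_runs": self.n_runs,
                    "seed": self.seed,
                    "order": self.order,
                    "n_failures": self.n_failures,
                    "outputs": {
                        k: {"mean": m, "variance": v}
                        for k, (m, v) in self.outputs.items()
                    },
                },
                indent=2,
            )
        )


def _as_output_dict(result: Mapping[str, float] | float) -> dict[str, float]:
    if isinstance(result, Mapping):
        return {k: float(v) for k, v in result.items()}
    return {"value": float(result)}


def propagate_pcm(
    model: ModelFn, params: Sequence[UncertainParameter], order: int
) -> tuple[UQResult, dict[str, SurrogateModel]]:
    """Evaluate the model on the tensor grid; return moments and surrogates."""
    plan = tensor_plan(params, order)
    rows = [_as_output_dict(model(node)) for node in plan.tensor_nodes]
    names = list(rows[0])
    outputs = {}
    surrogates = {}
    for name in names:
        vals = np.array([r[name] for r in rows])
        outputs[name] = pcm_moments(vals, plan)
        surrogates[name] = SurrogateModel(plan, vals)
    result = UQResult(
        method="pcm", n_runs=plan.n_nodes, outputs=outputs, order=order
    )
    return result, surrogates


def run_mc(
    model: ModelFn,
    params: Sequence[UncertainParameter],
    n_runs: int,
    seed: int,
) -> UQResult:
    """Monte Carlo propagation with per-run reproducible substreams.

    Run ``i`` draws its inputs from ``SeedSequence((seed, i))``, so results
    are bit-identical for a given seed regardless of execution order and
    the sample set is extensible without reshuffling.  Failed model runs
    are recorded, excluded and counted.  Variance uses the n-1 denominator.
    """
    if n_runs < 2:
        raise DomainError("Monte Carlo needs at least 2 runs")
    records: list[dict[str, float]] = []
    draws = np.empty((n_runs, len(params)))
    n_fail = 0
    for i in range(n_runs):
        rng = np.random.default_rng(np.random.SeedSequence((seed, i)))
        point = np.array([p.sample(rng, 1)[0] for p in params])
        draws[i] = point
        try:
            out = _as_output_dict(model(point))
        except Exception:
            n_fail += 1
            continue
        out = dict(out)
        for j, p in enumerate(params):
            out[f"input_{p.name}"] = point[j]
        records.append(out)
    if not records:
        raise DomainError("all Monte Carlo runs failed")
    df = pd.DataFrame.from_records(records)
    out_cols = [c for c in df.columns if not c.startswith("input_")]
    outputs = {
        c: (float(df[c].mean()), float(df[c].var(ddof=1))) for c in out_cols
    }
    return UQResult(
        method="mc",
        n_runs=len(records),
        outputs=outputs,
        seed=seed,
        n_failures=n_fail,
        samples=df,
    )
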