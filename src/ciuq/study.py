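"""Study orchestration: virtual populations and patient-specific UQ.

Two desk-scale experiments mirror the framework's use:

* a virtual-population Monte Carlo study — patients drawn from the shape,
  insertion-depth and resistivity distributions, evaluated independently
  and aggregated into histograms, per-electrode tables and scatter tables;
* a patient-specific study on the mean-shape cochlea with two uncertain
  inputs (insertion depth, bone resistivity), propagated both by Monte
  Carlo and by probabilistic collocation for cross-validation of moments.

Reproducibility contract: every patient or MC run derives its own RNG
substream from (seed, index), so results are bit-identical for a given
seed regardless of execution order or worker count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .config import Config, config_hash, default_config
from .errors import DomainError
from .fitting import LevelResult, fit_levels
from .geometry import ShapeWeights, build_cochlea
from .pipeline import PatientContext, make_context
from .scoring import ScoreSet
from .uq import UncertainParameter, UQResult, propagate_pcm, run_mc

__all__ = [
    "VirtualPatient",
    "StudyResult",
    "generate_population",
    "evaluate_patient",
    "run_population",
    "run_patient_specific",
    "fit_patient_levels",
    "aggregate",
]

log = logging.getLogger("ciuq")

GROUP_LABELS = ("group1_mean", "group2_minus_sd", "group3_plus_sd")


@dataclass(frozen=True)
class VirtualPatient:
    """One sampled patient: anatomy weights, insertion depth, resistivity."""

    patient_id: int
    w1: float
    w2: float
    w3: float
    insertion_mm: float
    resistivity_ohm_m: float
    group: str = ""

    @property
    def weights(self) -> ShapeWeights:
        return ShapeWeights(self.w1, self.w2, self.w3)


def _truncated_normal(rng: np.random.Generator, bound: float, size: int) -> np.ndarray:
    x = rng.normal(size=size)
    bad = np.abs(x) > bound
    while bad.any():
        x[bad] = rng.normal(size=int(bad.sum()))
        bad = np.abs(x) > bound
    return x


def generate_population(
    n: int,
    seed: int,
    resistivity_scheme: str = "three-group",
    cfg: Config | None = None,
) -> list[VirtualPatient]:
    """Sample a virtual population, deterministic per seed.

    Shape weights ~ N(0,1) truncated at ±3 per mode; requested insertion
    depth ~ N(27, 1) mm, floored at the 24.1 mm full-insertion minimum.
    Resistivity schemes: ``three-group`` fixes rho at the mean for the
    first half of the population and at mean -/+ one group SD for the two
    remaining quarters; ``full-normal`` draws rho ~ N(65.0, 21.6)
    (re-sampling nonpositive draws).
    """
    if n < 1:
        raise DomainError("population size must be >= 1")
    cfg = cfg or default_config()
    u = cfg.uq
    if resistivity_scheme not in ("three-group", "full-normal"):
        raise DomainError(f"unknown resistivity scheme {resistivity_scheme!r}")
    quarter = n // 4
    patients = []
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence((seed, i)))
        w = _truncated_normal(rng, u.weight_truncation_sd, 3)
        depth = max(
            rng.normal(u.insertion_mean_mm, u.insertion_sd_population_mm),
            cfg.implant.min_insertion_mm,
        )
        if resistivity_scheme == "three-group":
            if i < n - 2 * quarter:
                rho, group = u.resistivity_mean_ohm_m, GROUP_LABELS[0]
            elif i < n - quarter:
                rho = u.resistivity_mean_ohm_m - u.resistivity_sd_group_ohm_m
                group = GROUP_LABELS[1]
            else:
                rho = u.resistivity_mean_ohm_m + u.resistivity_sd_group_ohm_m
                group = GROUP_LABELS[2]
        else:
            rho = rng.normal(u.resistivity_mean_ohm_m, u.resistivity_sd_full_ohm_m)
            while rho <= 0:
                rho = rng.normal(u.resistivity_mean_ohm_m, u.resistivity_sd_full_ohm_m)
            group = "full_normal"
        patients.append(
            VirtualPatient(
                patient_id=i,
                w1=float(w[0]),
                w2=float(w[1]),
                w3=float(w[2]),
                insertion_mm=float(depth),
                resistivity_ohm_m=float(rho),
                group=group,
            )
        )
    log.info("generated population n=%d seed=%d scheme=%s", n, seed, resistivity_scheme)
    return patients


def patients_to_frame(patients: list[VirtualPatient]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in patients])


def patients_from_frame(df: pd.DataFrame) -> list[VirtualPatient]:
    return [
        VirtualPatient(
            patient_id=int(r["patient_id"]),
            w1=float(r["w1"]),
            w2=float(r["w2"]),
            w3=float(r["w3"]),
            insertion_mm=float(r["insertion_mm"]),
            resistivity_ohm_m=float(r["resistivity_ohm_m"]),
            group=str(r.get("group", "")),
        )
        for r in df.to_dict("records")
    ]


def patient_context(patient: VirtualPatient, cfg: Config | None = None) -> PatientContext:
    return make_context(
        patient.weights, patient.insertion_mm, patient.resistivity_ohm_m, cfg
    )


def evaluate_patient(patient: VirtualPatient, cfg: Config | None = None) -> ScoreSet:
    """Full pipeline (geometry -> insertion -> field -> activation -> scores).

    Pure function of (patient, config).
    """
    try:
        return patient_context(patient, cfg).score()
    except Exception as exc:
        raise type(exc)(f"patient {patient.patient_id}: {exc}") from exc


def _evaluate_row(patient: VirtualPatient, cfg: Config) -> dict:
    ctx = patient_context(patient, cfg)
    row = {
        "patient_id": patient.patient_id,
        "group": patient.group,
        "w1": patient.w1,
        "w2": patient.w2,
        "w3": patient.w3,
        "resistivity_ohm_m": patient.resistivity_ohm_m,
        "requested_mm": patient.insertion_mm,
        "achieved_mm": ctx.insertion.achieved_mm,
        "lamina_length_mm": ctx.shape.lamina_length,
    }
    row.update(ctx.score().to_dict())
    return row


def run_population(
    patients: list[VirtualPatient], cfg: Config | None = None, n_jobs: int = 1
) -> pd.DataFrame:
    """Evaluate every patient; one row per patient, order-independent.

    Evaluations are independent, so any worker count yields identical
    results; rows are sorted by patient id.
    """
    cfg = cfg or default_config()
    log.info("running population n=%d config=%s", len(patients), config_hash(cfg))
    if n_jobs == 1:
        rows = [_evaluate_row(p, cfg) for p in patients]
    else:
        rows = Parallel(n_jobs=n_jobs)(delayed(_evaluate_row)(p, cfg) for p in patients)
    return pd.DataFrame(rows).sort_values("patient_id").reset_index(drop=True)


def _patient_specific_model(cfg: Config):
    """Outcome model of the two uncertain inputs (depth, resistivity)."""

    def model(point: np.ndarray) -> dict:
        depth = max(float(point[0]), cfg.implant.min_insertion_mm)
        rho = float(point[1])
        ctx = make_context(ShapeWeights(0, 0, 0), depth, rho, cfg)
        return ctx.score().to_dict()

    return model


def patient_specific_params(cfg: Config | None = None) -> list[UncertainParameter]:
    cfg = cfg or default_config()
    u = cfg.uq
    return [
        UncertainParameter(
            "insertion_depth", u.insertion_mean_mm, u.insertion_sd_patient_mm, units="mm"
        ),
        UncertainParameter(
            "bone_resistivity",
            u.resistivity_mean_ohm_m,
            u.resistivity_sd_group_ohm_m,
            units="Ohm·m",
        ),
    ]


def run_patient_specific(
    method: str,
    order: int | None = None,
    n_mc: int | None = None,
    seed: int = 0,
    cfg: Config | None = None,
) -> UQResult:
    """Propagate the two patient-specific uncertainties through the pipeline.

    ``method='pcm'`` runs (order+1)^2 pipeline evaluations on the tensor
    collocation grid; ``method='mc'`` runs ``n_mc`` seeded Monte Carlo
    draws.  Outcome quantities: global specificity and sensitivity plus the
    twelve local and twelve cross-turn scores.
    """
    cfg = cfg or default_config()
    params = patient_specific_params(cfg)
    model = _patient_specific_model(cfg)
    log.info(
        "patient-specific %s order=%s n_mc=%s seed=%d config=%s",
        method, order, n_mc, seed, config_hash(cfg),
    )
    if method == "pcm":
        result, _ = propagate_pcm(model, params, order or cfg.uq.pcm_default_order)
        return result
    if method == "mc":
        return run_mc(model, params, n_mc or cfg.uq.mc_default_n, seed)
    raise DomainError(f"unknown method {method!r}; expected 'mc' or 'pcm'")


def fit_patient_levels(
    patient: VirtualPatient, cfg: Config | None = None
) -> LevelResult:
    """T/C levels for one patient (layout mirrors a per-contact level table)."""
    return fit_levels(patient_context(patient, cfg))


@dataclass
class StudyResult:
    """Aggregated population outcomes."""

    per_patient: pd.DataFrame
    specificity_hist: pd.DataFrame     # per group: bin edges and counts
    per_electrode: pd.DataFrame        # per group x contact: mean/SD of both scores
    length_scatter: pd.DataFrame       # lamina length vs global scores

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.per_patient.to_csv(outdir / "per_patient.csv", index=False)
        self.specificity_hist.to_csv(outdir / "specificity_hist.csv", index=False)
        self.per_electrode.to_csv(outdir / "per_electrode.csv", index=False)
        self.length_scatter.to_csv(outdir / "length_scatter.csv", index=False)


def aggregate(per_patient: pd.DataFrame, bin_width: float = 0.05) -> StudyResult:
    """Histograms, per-electrode mean/SD tables and scatter tables."""
    if len(per_patient) == 0:
        raise DomainError("no patient results to aggregate")
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    hist_rows = []
    for group, sub in per_patient.groupby("group"):
        counts, _ = np.histogram(sub["specificity"], bins=edges)
        for lo, hi, c in zip(edges[:-1], edges[1:], counts):
            hist_rows.append(
                {"group": group, "bin_lo": lo, "bin_hi": hi, "count": int(c)}
            )
    local_cols = [c for c in per_patient.columns if c.startswith("local_")]
    cross_cols = [c for c in per_patient.columns if c.startswith("cross_")]
    elec_rows = []
    for group, sub in per_patient.groupby("group"):
        for col in local_cols + cross_cols:
            kind, contact = col.split("_", 1)
            elec_rows.append(
                {
                    "group": group,
                    "contact": contact,
                    "score": "local" if kind == "local" else "cross_turn",
                    "mean": float(sub[col].mean()),
                    "sd": float(sub[col].std(ddof=1)) if len(sub) > 1 else float("nan"),
                    "n": len(sub),
                }
            )
    scatter = per_patient[
        ["patient_id", "group", "lamina_length_mm", "specificity", "sensitivity"]
    ].copy()
    return StudyResult(
        per_patient=per_patient,
        specificity_hist=pd.DataFrame(hist_rows),
        per_electrode=pd.DataFrame(elec_rows),
        length_scatter=scatter,
    )
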