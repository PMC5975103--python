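# Methods

This note records the models behind `ciuq`, their assumptions, the
parameters that matter, and the choices made where the design was open.

## Cochlear geometry

The cochlea is a logarithmic spiral in a right-handed mm frame with the
modiolar axis as z:

    r(θ) = a·e^(−bθ),   z(θ) = p·θ/2π,   θ ∈ [0, 2π·2.75].

Arc length along a spiral is the package-wide coordinate, measured in mm
from the round window (base) and increasing apically. Two concentric
spirals are carried: the **lamina** spiral (fiber bundles) and the **duct**
spiral (electrode contacts), the latter at a lateral-wall offset that
tapers linearly from 0.6 mm at the base to 0.2 mm at the apex. The taper
reflects the apical narrowing of the scala tympani and is what gives
apical contacts their lower stimulation thresholds; a constant offset would
make every contact equidistant from the nerve and flatten the T-level
profile, which is not what implanted patients show.

Three shape weights (SD units of a virtual population, truncated at ±3 to
exclude implausible anatomy) deform the mean shape:

| mode | meaning | implementation |
|------|---------|----------------|
| w1 | overall size | scales every length by `1 + g1·w1` |
| w2 | spiral radius / tightness | scales `a`; `b` re-solved so planar arc length is unchanged |
| w3 | height / rotation | scales the pitch `p` |

Making mode 2 length-preserving is a deliberate choice: it decouples
"how tightly the cochlea coils" from "how long it is", so the population SD
of lamina length is carried by mode 1 alone and can be calibrated exactly.

**Calibration** (`scripts/calibrate.py`, frozen into
`src/ciuq/data/default_config.yaml`): the basal radius solves
L(0,0,0) = 25.3 mm; the mode-1 gain solves SD(L) = 1.1 mm over a large
truncated-normal sample; the activation threshold voltage solves
"3 mm activated arc span at the default stimulus (E6, 350 µA, 65 Ω·m)";
the HH drive gain maps that voltage onto the HH rheobase. Calibrated
values: a = 3.419 mm, g1 = 0.0436, V_th = 1.041 V, gain = 225.7
(µA/cm²)/V. Defaults b = 0.12 rad⁻¹ and p = 1.0 mm/turn were chosen once
so the mean shape has plausible basal/apical radii and inter-turn 3D
distances of 1–2.5 mm, putting cross-turn stimulation at the edge of reach
of the calibrated activation radius — present at the apex, absent at the
base.

Arc-length maps use a cubic-spline antiderivative of the spiral speed on a
dense θ grid (2049 points, relative error ≪ 1e-6 against quadrature);
inversion uses interpolation plus two Newton steps.

## Fibers and tonotopy

334 bundles (≈90 fibers each) sit at s = iL/(n+1), i = 1..n, uniformly in
lamina arc length. Characteristic frequencies follow the Greenwood map
F(x) = 165.4·(10^(2.1x) − 0.88) Hz with x the fractional distance from the
apex: ≈20 Hz at the apex, ≈20.7 kHz at the base.

## Insertion

Contacts are uniformly spaced (23.1/11 = 2.1 mm) behind a 1 mm tip;
contact Ek sits at duct arc `achieved − 1.0 − (k−1)·2.1` mm. Requests below
24.1 mm (active range + tip) are rejected — a contact would remain outside
the cochlea — and requests beyond the duct's arc length are clamped to the
deepest anatomically possible insertion.

## Field and activation

The potential is a point source in an infinite homogeneous medium,
V = ρI/(4πd), distance floored at 0.1 mm. This keeps the two properties the
outcome measures depend on — monotone decay with distance, and linearity in
both current and resistivity (higher ρ ⇒ wider excitation ⇒ worse
selectivity) — while discarding tissue heterogeneity and the return-path
geometry; absolute potentials are not meaningful, only their scaling.

The default backend thresholds V at the calibrated V_th (exact and fast;
monotone in amplitude by linearity). The optional `hh` backend integrates a
single-compartment Hodgkin–Huxley membrane per bundle (classic constants,
rest-relative voltages; rates Q10 = 3 accelerated from 6.3 °C to 37 °C),
driven by ±gain·V_j during the cathodic/anodic phases of the 100 µs
biphasic pulse; a spike is a depolarization ≥ 40 mV above rest within a
1 ms window, counted at most once. Integration is fixed-step (1 µs,
exponential Euler for gates, forward Euler for voltage). Because the drive
is proportional to V_j, the HH spike decision is itself a threshold on V_j;
calibrating the gain to the HH rheobase therefore makes the two backends
agree by construction, which the tests verify on random patients.

## Scoring

The target map assigns, per contact, a Gaussian weight inside the 3 mm
acceptable band centered on the contact's lamina-projected place (value 1
at the center, 0.1 at the band edge) and a constant −0.25 outside. The
Gaussian-inside/constant-outside form, and the per-contact centering at
the contact's own tonotopic place, are design choices; only the sign
structure and the 3 mm bandwidth are fixed by the problem.

Per-contact scores map the weighted activation sum piecewise-linearly so
that 100 = ideal profile, 50 = no stimulation, 0 = inverse profile. Each
column is split at ±π/2 of spiral angle around the contact (half a turn)
into a near-field part (local performance score) and a cross-turn part. A
cross-turn column usually has no positive weights, so its attainable range
[worst, none] maps to [0, 100]; an all-zero weight column yields NaN
(undefined, flagged). Global specificity and sensitivity are confusion
rates over all 334×12 cells with positive-weight cells as "should fire";
the all-cells (rather than per-electrode-averaged) convention is a
documented choice.

## Level fitting

T-level: smallest amplitude with ≥1 in-band spike, grid-scanned
(10–1000 µA, 10 µA steps) and bisection-refined to 1 µA — exact under the
monotone threshold backend. C-level: the grid amplitude ≥ T maximizing
per-column `sensitivity + specificity − λ·(cross-turn activated fraction)`,
λ = 0.5 by default (the trade-off weight is not pinned down by the problem
and is exposed in config); ties break toward the lower amplitude.

## Uncertainty propagation

PCM uses probabilists' Gauss–Hermite nodes/weights (library Golub–Welsch),
shifted to μ + σξ and normalized to Σk = 1; multi-parameter grids are full
tensor products ((n+1)^p nodes, product weights); moments are the weighted
nodal mean and variance; the surrogate is a tensor-product Lagrange
interpolant over ξ = (ω−μ)/σ, exact at nodes and for polynomials of degree
≤ n, warning beyond ±4σ. Truncated normals are rejected by PCM (the
Hermite basis does not represent them) and handled in Monte Carlo by
rejection sampling. MC uses the n−1 variance denominator and derives each
run's RNG substream from (seed, run index), so results are bit-identical
per seed regardless of execution order or worker count, and sample sets
are extensible without reshuffling. The same substream rule generates
virtual populations.

Distributions: insertion depth N(27, 1) mm for populations and N(27, 0.5)
for the patient-specific study; shape weights N(0,1)³ truncated ±3; bone
resistivity N(65.0, 21.6) Ω·m for the `full-normal` scheme and σ = 4.5 Ω·m
for the three-group and patient-specific studies. Both resistivity spreads
are in config; 4.5 is the default for the group/patient-specific studies
because the 21.6 Ω·m spread dominates every other input and washes out
their effects (the preliminary-population behavior), which is exactly why
the grouped design exists.

## Problem sizes

All studies run at desk scale: population trend checks use 150–500
patients (≈2.4 ms per patient with the threshold backend), the
patient-specific comparison uses 9–49 PCM runs against 250 MC runs, and
the geometry-calibration check uses 500 sampled shapes. These sizes give
sampling errors well below the effect sizes being checked.

## What the generator does and does not emulate

The synthetic cochleae reproduce the population statistics that drive the
outcome measures (size distribution and its SD, coil tightness, inter-turn
proximity) but not real anatomical detail: no separate scalae, no
basilar-membrane mechanics, a fixed 2.75-turn angular extent, and a smooth
analytic lateral-wall offset. The field model ignores tissue
heterogeneity; the neuron model has no cable geometry, stochasticity or
refractoriness across pulses. Passing tests therefore demonstrate the
correctness of the pipeline's logic and the UQ machinery, and the
*direction* of the clinical trends (resistivity up ⇒ specificity down;
smaller cochleae ⇒ more cross-turn errors; apical contacts ⇒ lower
thresholds) — not quantitative agreement with measured patient outcomes,
whose absolute values depend on full head-model field solutions and
multi-compartment nerve models outside this package's scope.

## Numerical choices and degenerate inputs

Spline grids of 2049 points per spiral; Newton-refined arc inversion;
brentq for the three calibration solves and the length-preserving `b`
re-solve (bracket [1e-3, 2] rad⁻¹); point-source distance floor 0.1 mm;
HH step 1 µs; T-level bisection tolerance 1 µA; C-level tie-break toward
lower amplitude; undefined scores (no in-band response, all-zero weight
columns) propagate as NaN/None rather than raising, and degenerate target
maps (no positive cells anywhere) raise.
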