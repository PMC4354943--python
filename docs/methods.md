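# Methods

This note records the models, parameter choices and numerical decisions
behind the package, in the order the pipeline runs them.

## Designs and coded units

All fitting happens in coded units: each factor's low/mid/high setting
maps affinely to −1/0/+1 (`actual = mid + coded·(high−low)/2`), which
keeps the model matrix well conditioned and makes standardized effects
comparable across factors. The Plackett-Burman construction is the
canonical 12-run cyclic one (generator row `+ + − + + + − − − + −`
rotated through 11 rows, plus the all-minus row); any orthogonal 12-run
PB would serve, and orthogonality (XᵀX = 12·I in exact integer
arithmetic) is asserted by test rather than assumed. The Box-Behnken
design takes, for every pair of factors, the four (±1, ±1) combinations
with the other factors at 0. Center points (all factors at mid) are
appended last; their position is irrelevant to OLS. Designs are emitted
in canonical order with an optional seeded shuffle — run-order
randomization is a physical-lab concern the simulation does not model.

## Response-surface fitting

Screening uses a main-effects model (a two-level PB design cannot
separate interactions or curvature; its aliasing makes pure quadratics
literally collinear, which the fitter reports as a singular fit naming
the aliased terms). Optimization uses the full quadratic, 10 terms for
3 factors, leaving 5 residual df on the 15-run design. Fitting is plain
OLS (statsmodels); center-point replicates contribute to residual error
but not to effect contrasts. No stepwise term pruning is done — the
full declared model is always reported. Effects exactly at the critical
t are counted *not* significant (strict inequality) so the decision is
deterministic under ties.

## Desirability profiling

Individual desirabilities are linear Derringer ramps; overall
desirability is the importance-weighted geometric mean (any fully
undesirable response vetoes the point). The optimizer is a multi-start
Nelder-Mead: a 5×5×5 grid of seeded, slightly jittered starting points,
each refined to 1e-6 in coded units, with the best result clipped to
the cube. A property test guarantees the reported optimum is never
worse than the best point of a 21³ brute-force grid.

Anchor choices: for the two peak areas the ramp runs from the predicted
minimum to the predicted maximum over the coded cube (the goal is
"maximize" with no natural absolute anchors); for the two tailing
factors the ramp runs from 1.0 (perfectly symmetric) to 2.0, the
pharmacopeial acceptance criterion. The *defect simulation* instead
applies the stricter specification limit of 1.5 on tailing. This split
is deliberate: a method can pass acceptance at the desirability optimum
and still carry a nonzero defect rate against the tighter in-house
limit, which is precisely the situation the surrogate-minimization
stage exists to repair.

## Monte Carlo defect rate

Each simulated run draws every factor from a normal centered on the
setpoint, truncated to the factor's low/high range by rejection, with
standard deviations taken from the robustness perturbations of the
validation protocol read as ±3σ: flow ±0.1 mL/min → σ = 0.033,
wavelength ±2 nm and organic ratio ±2 % v/v → σ = 0.667. Injection
volume, absent from that list, uses σ = 0.5 µL (typical autosampler
repeatability). Responses are predicted from the fitted quadratics plus
N(0, rmse) noise (on by default; the rmse is the model's own residual
error, the closest available stand-in for run-to-run assay noise). A
run is defective if *any* response violates a limit; DR = m/n with a
Clopper-Pearson 95% interval, and per-response rates are reported so
defects can be attributed (in the fixture configuration essentially all
defects come from STP tailing against its 1.5 limit). Setting every σ
to zero with noise off reduces the simulation to a deterministic spec
check, which the tests exploit.

Lower spec limits on the two peak areas are required configuration; the
fixture defaults (0.12 and 0.15 AU·min) were chosen once
against the generator's area range so that the limits bind only in the
genuinely poor corner of the cube (high flow, low volume) and the DR
surface stays graded rather than saturating at 0 or 1.

## Latin hypercube + Gaussian-process surrogate

The simulation experiment sweeps setpoints over the full coded cube
("factor space" scale 1.0) with a Latin hypercube — exactly one point
per equal-width stratum per factor, delegated to scipy's sampler — and
estimates DR at each point. Zero-defect points are floored at 0.5/runs
(the usual continuity correction) before taking log₁₀ so the log is
finite; the floor is recorded in the experiment bundle.

The surrogate is constant-mean kriging: amplitude × anisotropic RBF +
white-noise term, hyperparameters by restarted MLE on the normalized
response. The white-noise term's upper bound is generous (1e1) because
a Monte Carlo DR estimate carries binomial sampling noise that the
surrogate must absorb — with, say, 2,000 runs per point, the log₁₀ DR
noise near DR ≈ 0.01 is of order 0.1, far above any "numerical" nugget.
On noiseless data the MLE drives the noise term to its 1e-8 floor and
the GP interpolates to the corresponding tolerance (~1e-4 on the
normalized scale; exact reproduction to 1e-6 would need a nugget so
small it breaks fitting on real surfaces). Jackknife validation refits
the GP without each point in turn, holding the hyperparameters at the
full-data MLE (the standard fast leave-one-out for kriging), and
reports actual-vs-predicted pairs; on the fixture pipeline the
goodness-of-fit r² is ≈ 0.98. DR minimization is multi-start L-BFGS-B
on the predicted log₁₀ DR from a Latin hypercube of starts plus the
best training point; the winner is confirmed by a fresh full-size
simulation — the surrogate proposes, the simulator disposes.

The total simulation budget (points × runs per point) is configurable;
the pipeline default is 80 points × 2,000 runs, and the per-setpoint
confirmation runs use the full 15,000. Tests use smaller presets (25 ×
400) purely as their problem size.

## Synthetic chromatogram generator

Peaks are exponentially modified Gaussians (scipy's exponnorm), the
minimal standard shape with a controllable tail; a Gaussian is used
when τ ≈ 0. The generator encodes, as ground truth, the behaviour the
screening stage is expected to rediscover:

- **Area law**: area = response_factor · injected mass / flow, with
  mass = concentration × injection volume. Doubling flow halves the
  area; the tests assert the invariance of area·flow/mass to 1% across
  the factor grid.
- **Tailing**: τ = τ₀ + c_vol·(V − 10) + c_org·(φ − 60) + c_flow·(f − 0.6),
  with the lipophilic late-eluting drug carrying the larger organic
  coefficient (silanol interactions) and the early drug a flow term.
  Coefficients were placed using a numerically computed USP-tailing vs
  τ/σ map so that STP tailing reaches ≈ 1.4 at the area-maximizing
  corner (low flow, high volume) — close enough to the 1.5 limit that
  factor variation produces a defect rate of order 0.5–1%, dominated by
  that one response.
- **Retention** shrinks inversely with flow and linearly with organic
  fraction; peak width scales with retention (constant plate count).
- **Wavelength** modulates the response factor through a shallow
  quadratic peaking at 270 nm (≈0.1% within ±5 nm), so the factor is
  real but never significant — matching its role as a screened-out
  factor.
- **Noise**: additive white detector noise (0.002 AU) plus a 1%
  relative injected-mass variability (autosampler repeatability), which
  makes replicate peak areas scatter with ≈1% RSD.

What the generator does *not* emulate: gradient-shape retention
dynamics (the late-gradient organic factor is inert by construction),
detector saturation, baseline drift, or carry-over. Passing tests
therefore demonstrate that the statistical machinery recovers a known
truth of this structure — not that the truth models any particular
instrument.

Peak measurement details: integration windows extend 7σ before and
7σ + 9τ after each apex; when adjacent windows collide they are split
midway between the first peak's 5% tail extent and the second peak's 5%
front extent, which keeps both peaks measurable down to genuine
co-elution. The baseline is the lower of the two window-edge medians
(robust when one edge sits on a neighbouring peak's flank); a width
crossing within 5 samples of a window edge is flagged as a truncated
peak rather than silently measured. USP widths are taken at 5% height
(tailing) and 50% height (plates, resolution; base width = 1.699 ×
half-height width) with linear interpolation on the 0.002-min grid,
fine enough that grid error in area and width is below 0.1%.

S/N follows the height-over-2×noise-SD convention (configurable), so
LOD at S/N = 3 is 6·noise_SD/slope under a linear height calibration.

## Release kinetics

The four release laws are fitted by their conventional linearizations —
Q vs t, ln(1−Q) vs t, Q vs √t, log₁₀Q vs log₁₀t — because that is how
such tables are produced in the dissolution literature and how their r²
values are defined. Zero-order and Higuchi fits keep a free intercept
and report the slope as the rate constant. Log-based fits require the
fractional scale, exclude t = 0, and the power-law fit additionally
drops points beyond 60% release (its validity bound). Model selection
is argmax r² with ties going to the model with fewer parameters. The
generator for noisy profiles clips to [0, 1] and enforces monotonicity
with a running maximum so every synthetic profile is a valid cumulative
curve.

## Quantification

The extinction-coefficient identity ε = area·flow/(1000·l·moles) comes
from integrating Beer-Lambert over the eluting peak: Ab(t) = ε·l·c(t)
and ∫c(t)·(flow/1000) dt = moles, with area in AU·min, flow in mL/min
and the factor 1000 converting mL to L. The HPLC route can either
average per-level ε estimates or regress area on moles; the per-level
mean is what the analysis script reports. The UV route is the
zero-intercept slope of absorbance vs molar concentration divided by
path length. Encapsulation efficiency is
100 × measured/theoretical (% w/w).

## Pipeline and reproducibility

The pipeline carries forward the factors whose screening |t| exceeds
t_crit for any response, topping up (or trimming) to the Box-Behnken
factor count by the largest |t| across responses; factors left behind
are clamped at configured preferred levels (wavelength 270 nm, late
organic 95% in the fixture). Every stage derives its RNG stream from
the single config seed, so one (config, seed) pair reproduces the
entire report bundle byte for byte. The final setpoint is rounded
half-away-from-zero to practical instrument increments (0.1 mL/min,
1 µL, 1% v/v, 1 nm); a 1e-9 epsilon before the floor keeps exact halves
(e.g. 0.65 mL/min) rounding away from zero despite binary
representation.

## Known limitations

- The defect simulation propagates the *fitted quadratic* models, not
  the generator truth, so its DR is only as good as the response
  surface — faithful to how such simulators are used, but worth
  remembering when the optimum sits at a cube corner where a BB design
  extrapolates.
- The surrogate's argmin is weakly identified wherever the DR surface
  is flat at ≈0; any point in the zero-defect basin is an acceptable
  answer, and the confirmation simulation is the arbiter.
- Linearized kinetic fits weight points differently from nonlinear
  least squares; rate constants from the two approaches differ for
  noisy data.
- The generator's inert late-organic factor means gradient-program
  optimization beyond the initial organic ratio is out of scope.
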