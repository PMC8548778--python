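# Methods

## Model

Each region of each hemisphere is modelled independently by a 1–H–1
perceptron in which every neuron, including the output neuron, uses the
hyperbolic tangent:

    ŷ(x) = tanh( b_out + Σ_j w_j · tanh(b_j + h_j x) ),   j = 1..H.

The output activation forces |ŷ| < 1, which is why both the input (age,
years) and the target (regional mean thickness, mm) are min–max scaled to
[−1, 1] before training; the two affine scalers are stored with the model
and inverted exactly at prediction time. H = 0 is the minimal all-tanh
network, a single output neuron on an affine input, ŷ = tanh(b_out + v·x).

Every neuron carries a bias. A bias-free tanh network passes through the
origin and cannot represent the offset-dominated thickness curves, so
biases are structural here, not optional. Because targets are scaled with
the observed min/max, the two extreme samples sit exactly at ±1, which the
tanh output can only approach; this affects those two samples only and is
accepted.

Scaling is fitted per region (each network sees one region), and — during
hidden-size selection — on the training portion only, so the validation
fold never leaks into the scaler. Final models are refit on all subjects
with scalers from all subjects. Ages outside the fitted range extrapolate
the affine map; curve nodes that required extrapolation are flagged.

## Training

Training is two-stage per region.

**Simulated annealing** explores weight space globally. Temperature steps
linearly from 15 to 0.001 over 100 levels, 100 candidate moves per level
(10,000 evaluations). A candidate adds Gaussian noise with standard
deviation `perturb_scale · T / T_initial` to all weights jointly and is
accepted by the Metropolis rule exp(−ΔMSE/T); the best state ever visited
is returned. Initial weights are uniform on [−0.5, 0.5]. Candidates are
clipped to the box [−8, 8]: with inputs in [−1, 1], weights beyond a few
units only drive tanh deeper into saturation, so an unbounded walk — at
these temperatures the Metropolis filter accepts almost everything, since
scaled-MSE differences are far below the early temperatures — diffuses
into a flat, redundant region of the error surface and never returns.
The bound keeps the hot phase exploring the responsive part of weight
space; without it the annealer returns its starting point essentially
unchanged.

**Levenberg–Marquardt** then refines: solve (JᵀJ + λI)δ = −Jᵀr with the
analytic residual Jacobian, accept a step only if the MSE strictly
decreases (λ ÷ 10 on acceptance, × 10 on rejection, λ₀ = 10⁻³), stop at
1,000 iterations, at an MSE of 10⁻⁵, or when λ exceeds 10¹² (stalled).
The accepted-MSE sequence is monotone non-increasing by construction.

`train_region(..., n_restarts=k)` repeats the whole two-stage run k times
and keeps the lowest training MSE. The default is a single run; the
recovery experiments use k = 3 because multi-inflection targets leave the
optimizer a few percent of runs in a local optimum that misses one bump,
and the bad runs are cleanly identifiable by their training MSE.

## Hidden-size selection

Subjects are split 80/20 once (seeded, unstratified); the same split is
reused for every H so validation errors are comparable. H grows from 0 and
the search stops at the first H whose validation MSE fails to improve on
the previous one by more than 5% (relative); the previous H is returned,
and final models are refit on 100% of subjects at that H.

The 5% threshold is a deliberate choice. With a strict
"any decrease continues" rule, the decision between H and H+1 on data the
smaller model already fits is a near coin flip: the expected validation
penalty for two extra parameters is σ²Δp/n_train while the fluctuation of
the paired validation-MSE difference is ≈ 2σ²√(Δp/n_train)/√n_val, and the
ratio of the two is a constant ≈ 0.35 independent of n and σ for an 80/20
split — so the strict rule grows H spuriously in roughly a third of runs.
Requiring a material improvement makes the choice reproducible without
changing what the rule measures.

A structural limitation worth knowing: H = 1 networks are always monotone
in the input (a monotone composition), so for targets whose best monotone
approximation is already achieved at H = 0 — e.g. even, two-bump profiles —
the greedy search stops at 0 and never discovers the H ≥ 2 structure. This
is a property of the greedy rule itself; the recovery experiments therefore
set the capacity per archetype explicitly rather than relying on selection.

## Numerical differentiation

Derivative weights for a stencil of N integer offsets solve the N×N moment
system Σⱼ cⱼsⱼᵏ = d!·δ_{k,d}, k = 0..N−1. The system is a Vandermonde
matrix and badly conditioned in floating point at N = 7, so it is solved
in exact rational arithmetic (sympy), converted to floats at the end; the
rule is then exact for polynomials of degree ≤ N−1, which the tests assert
both in exact arithmetic and against an independently constructed
Lagrange-interpolation oracle. On a uniform grid, interior nodes use the
centered stencil [−3..3]; the first and last three nodes use shifted
stencils whose seven points all lie inside the data, retaining full order
at the boundaries.

The derivative is computed on the unscaled mm-versus-years curve, so bands
are in mm/year. Accuracy on model curves follows standard stencil theory,
error ≈ (h⁶/140)·f⁽⁷⁾: with a 1-year step it is below 10⁻⁶ mm/year for
transitions wider than ~15 years and degrades for very sharp fitted
transitions; the grid step is configurable where that matters.

The age at which a region changes fastest is reported from the interior of
the grid (outermost 3 nodes excluded on each side): at the support
boundary the model is extrapolation-fragile and the stencil fully
one-sided, so small fit wobble there can masquerade as the steepest change
even when the fitted curve is within tolerance everywhere.

## Color bands and clustering

The color scale is a diverging red–green–blue map, symmetric about zero:
derivative 0 maps to the neutral green exactly, gains toward blue, losses
toward red, with limits ±max|derivative| shared across all regions of a
hemisphere so its bands are mutually comparable.

Clustering of derivative profiles uses agglomerative linkage with
correlation distance and average linkage, cut at k = 6 — an automatic
replacement for what was originally a manual grouping, not a reproduction
of it. Cluster ids are renumbered by the age of the centroid's extreme
derivative, and regions are ordered same-cluster-contiguous. Correlation
distance is scale-free, which groups same-shaped regions of different
amplitude, but it is wobble-sensitive for near-flat profiles: regions with
essentially no derivative structure cluster reliably only when fit noise
is small relative to their (small) profile variation.

## Summary tables

Per age window (whole grid, ≥ 40, ≥ 60 years): extremes are the
argmin/argmax over regions of the model curve's mean; variability is the
curve's standard deviation over the window; linearity is the R² of a
least-squares line fitted to the curve over the window. The variability
and linearity metrics are this package's choices (the summary CSVs carry a
`metric` column naming them). Alongside, each region's network MSE against
the scaled data is reported next to the MSE of an ordinary least-squares
line fitted to the same scaled data.

## Synthetic cohort

The generator emulates a pooled cross-sectional sample: default 1,100
subjects, ages uniform on [5, 96] (wide enough to cover every archetype's
inflection), sex Bernoulli(½) (generated for schema fidelity but unused by
the age-only models), and a source tag from four study names. Each region
follows one of six archetypes built from sums of scaled tanh sigmoids plus
a linear drift — the same function family the networks fit, which keeps
parameter recovery well-posed:

* `change25/40/50/70`: baseline − amplitude·tanh((age−T)/6) − drift; the
  analytic derivative is most negative exactly at T.
* `multi`: two tanh-pair bumps peaking near ages 35 and 62 (weights 0.8
  and 0.6) on the same drift.
* `constant`: a near-linear decline with mild curvature (so the profile is
  not exactly degenerate for correlation-based clustering).

Per-region defaults derive from the bundled 4-subject reference table:
baseline = the region's mean thickness there; amplitude = 10% of baseline;
noise SD = 6% of baseline (≈ 0.15 mm for a typical 2.5 mm region — the
order of the between-study spread visible in the reference table).
Proportional scaling reflects that thicker cortex shows proportionally
larger lifespan change and scatter, and it keeps the scaled-unit noise
floor comparable across thin and thick regions. Observed thickness is the
template plus Gaussian noise truncated to a physiological band (1.0–4.5 mm
by default); truncation affects well under 1% of draws for the thinnest
regions at default noise. Archetype assignment of the 62 regions follows
the published per-region groupings where a region is named and fills the
remainder with the late-life-change shape.

What the generator does *not* emulate: scanner/site effects between the
four source studies, longitudinal within-subject correlation, non-uniform
age distributions, and non-Gaussian measurement error. Passing recovery
tests therefore demonstrate that the pipeline recovers smooth trajectories
from independent noisy cross-sectional samples — not that real pooled MRI
data meet those assumptions.

The reference table is shipped verbatim; its sex column is coded `U`
(unknown) because the source table does not report sex, and the cohort
reader accepts `M`, `F`, `U`.

## Problem sizes used by the acceptance script

The script fits the full 62-region default cohort (n = 1,100) at H = 2,
runs the recovery experiment on six representative regions (one per
archetype, noise 0.05 mm, capacity 3 or 5 hidden units, best of 3
restarts), two selection runs at n = 300, clustering of all 62 noise-free
template bands, the exact-stencil polynomial check, and the reference-table
statistics. Everything derives from `--seed`.

## Known limitations

* Selection cannot discover even-symmetric structure (see above).
* Derivative bands at the outermost grid nodes are kept for display but
  excluded from extreme-age statistics.
* The linear-baseline comparison fits the line in scaled units; its MSE is
  comparable to the network's MSE but not to mm².
* Networks with very sharp fitted transitions (< ~5-year width) can exceed
  the 1-year-grid stencil error quoted above.
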