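# corthick

Lifespan modelling of regional cortical thickness with small tanh neural
networks, and derivative "speed" bands that localize the ages at which each
brain region gains or loses thickness.

## The problem

Mean cortical thickness (mm), measured per anatomical region from
structural MRI, changes non-linearly across life: steep childhood thinning,
mid-life plateaus, abrupt late-life decline — and different regions follow
different shapes. Classical linear regressions of thickness on age miss
these transitions. `corthick` models each of 62 regions (31 Desikan-style
parcels per hemisphere) independently with a minimal adaptive model and
then asks *when* each region changes fastest.

## The method

For each region, a 1–H–1 multilayer perceptron with hyperbolic-tangent
activations maps age to thickness:

    ŷ(x) = tanh( b_out + Σ_{j=1..H} w_j · tanh(b_j + h_j x) )

with age and thickness both min–max scaled to [−1, 1]. Training is
two-stage: simulated annealing (linear cooling, T = 15 → 0.001 over 100
levels × 100 iterations, Metropolis acceptance on the MSE) finds initial
weights globally, then Levenberg–Marquardt (≤ 1,000 iterations, MSE goal
10⁻⁵) refines them. The hidden size H can be chosen per region on an 80/20
train/validation split, growing H from 0 until the validation MSE stops
improving materially.

The fitted curve is evaluated on a uniform age grid (default 5–96 years,
1-year step) and differentiated with 7-point finite-difference stencils
whose weights c₁..c₇ solve the exact moment system
Σⱼ cⱼ sⱼᵏ = d!·δ_{k,d} (solved in rational arithmetic; the rule is exact
for polynomials of degree ≤ 6). Near the ends of the grid the point of
interest shifts inside one-sided stencils so every node keeps full order.
The derivative (mm/year) is rendered as a diverging color band — blue for
thickness gain, green for no change, red for loss — and regions with
similar bands are grouped by agglomerative clustering (correlation
distance, average linkage, k = 6) so related regions sit together.
Summary tables report, per age window (whole life, ≥ 40, ≥ 60), the regions
with extreme mean thickness, extreme variability, and extreme linearity,
plus each region's network-vs-straight-line fit comparison.

A synthetic-cohort generator ships with the package: 1,100 subjects, ages
5–96, with every region following one of six smooth trajectory archetypes
(abrupt change near age 25/40/50/70, multiple inflections peaking near 35
and 62, or a near-constant decline) plus Gaussian noise. It makes every
downstream stage testable end to end, including recovery of known
generating curves. A 4-subject reference thickness table (one subject each
from the IXI, MMRR, NKI and OASIS studies) is bundled as
`src/corthick/data/table1_fixture.csv`.

## Worked example

```
corthick simulate --n-subjects 1100 --seed 1 --out cohort.csv
corthick fit --cohort cohort.csv --out models/ --seed 1
corthick bands --models models/ --out bands/ --k 6 --png
corthick summarize --models models/ --cohort cohort.csv --out summary/
corthick fdcoef --offsets -3,-2,-1,0,1,2,3 -d 1
```

The last command prints the classic 7-point centered first-derivative rule:

```
s=-3  c=     -1/60  (-0.0166666666667)
s=-2  c=      3/20  (+0.15)
s=-1  c=      -3/4  (-0.75)
s=+0  c=         0  (+0)
s=+1  c=       3/4  (+0.75)
s=+2  c=     -3/20  (-0.15)
s=+3  c=      1/60  (+0.0166666666667)
```

`fit` writes one JSON model per region plus `fit_report.csv` with each
region's training MSE in scaled units (typically ≈ 0.03–0.11 on the default
synthetic cohort; the larger values belong to multi-inflection regions that
a 2-unit hidden layer cannot fully express — refit those with `-H 5` or
`--select`). `bands/bands_left.csv` is a 31 × 92 matrix of derivatives in
mm/year, rows ordered so same-cluster regions are contiguous, and
`clusters.csv` assigns every region to one of the k clusters.
`summary/extremes.csv` names the thinnest/thickest region per age window —
on the bundled reference table the thinnest left-hemisphere region is the
pericalcarine (mean 1.508 mm over its four subjects).

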