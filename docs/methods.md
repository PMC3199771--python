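# Methods

## The analysis

The package operationalises a sister-species comparative design.  Each
well-supported cherry of the phylogeny is one phylogenetically independent
data point; its node age comes from the ultrametric timetree and its two
terminal branch lengths from the same topology *before* ultrametric
correction (substitutions/site), so the standardized tip contrast

    c = (x1 - x2) / sqrt(bl1 + bl2)

has, under Brownian motion with rate σ², variance σ² regardless of the pair's
age.  Species within a pair are ordered lexicographically; every headline
analysis uses either |c| or a through-origin regression of one contrast on
another, both of which are invariant to that ordering.

Support values are kept on the 0–100 posterior-probability scale; missing
supports count as 0, so an unsupported cherry can never pass the filter.  The
default threshold is 95.  Polytomies are rejected by default; an opt-in flag
resolves them deterministically in input child order with zero-length
branches.  A tree is called ultrametric when the root-to-tip spread is below
1e-6 of tree height — a tolerance chosen for trees whose heights are tens of
Ma with branch lengths printed to ≥ 9 significant digits.

### Range geometry

All geometry is planar, in meters (an equirectangular helper converts lon/lat
about the mean latitude; over a Madagascar-sized extent the distortion is a
few per mil).  Species with ≥ 3 non-collinear localities get their minimum
convex polygon; 1-locality species a disc, and 2-locality or collinear
species a *capsule* (the buffered segment through the points) so the range is
one connected polygon and the documented midpoint-centroid rule is exact.
Two radii are carried in parallel: RSA = 25 km and RSB = 17 m, a generous and
a quasi-zero assumption about unobserved range extent.  Centroids do not
depend on the radius (point, midpoint, or hull centroid), so a single
centroid-distance matrix serves both policies.

Buffer discs are approximated by 128-segment polygons; a 128-gon's area is
within 0.05% of the true disc, comfortably inside the 0.1% tolerance the
geometry tests assert.  Intersection areas below 1e-12 km² count as zero when
classifying pairs as allopatric (overlap 0) vs sympatric (overlap > 0).

### Statistics

* **Sign test.**  Each sister-pair overlap is compared against the median
  (configurable: mean) of all non-sister pairwise overlaps; ties are dropped.
  With k of n comparisons positive, the continuity-corrected normal statistic
  is Z = (|k − n/2| − 0.5)/(√n/2); the exact two-sided binomial p is used for
  n < 25.  The choice of a single reference value (rather than an unstated
  per-combination pairing) is a design decision; both the median and the mean
  are exposed.
* **Through-origin regressions** decompose the *uncentered* total sum of
  squares: R² = 1 − SS_res/Σy², F = MS_model/MS_residual on (p, n−p) df.
  This is the convention for contrast regressions, where the origin is forced
  by the method.  Coefficients and standard errors come from ordinary least
  squares (statsmodels); the ANOVA columns are computed explicitly.
  Sequential (type I) per-term sums of squares are attached for the factorial
  model (main effects age, centroid distance, climatic distance; all three
  pairwise products; the triple product; no intercept).
* **Quantile regression** minimises the pinball loss Σρ_τ(y − a − bx) as a
  linear program (HiGHS).  At a vertex solution the below-line fraction is
  within 2/n of τ; with degenerate data the solver's vertex choice decides
  ties, so the fit is documented as non-unique there.  statsmodels' IRLS
  QuantReg serves as an independent cross-check in the tests, never as the
  implementation.
* **KS normality** of pair ages uses the one-sample Kolmogorov–Smirnov test
  against a normal with the sample mean and SD.  Estimating the parameters
  makes the standard p conservative-approximate; a Lilliefors-corrected p is
  available via a flag.
* **Age–range correlation** defaults to Pearson on overlap percentages
  (Spearman and km² overlap switchable).

### Climatic niche

Climate variables are z-scored; eigenvalues are those of the correlation
matrix; components with eigenvalue > 1 (Kaiser, applied before rotation) are
retained and their loadings varimax-rotated (Kaiser-normalized rows,
tolerance 1e-8).  Rotation preserves per-variable communalities; rotated
factors are re-ordered by explained variance with a positive-loading-sum sign
convention so results are reproducible.  Species are compared by squared
Mahalanobis distance between mean score vectors, scaled by the pooled
within-species score covariance — the standard multi-group choice when each
species contributes several localities; single-locality species add no
degrees of freedom, and a rank-deficient pooled matrix falls back to identity
scaling (logged).  A plain-Euclidean option exists.

### Richness contrasts

Ancestral trait values are Felsenstein weighted averages computed
tips-to-root with the usual branch lengthening v' = v + v_l·v_r/(v_l+v_r).
At each internal node the daughters are oriented by reconstructed trait
value; RRD = ln(N_large/N_small) and the trait contrast
(x_large − x_small)/√(v'_l+v'_r) are therefore canonical under daughter
swaps.  Reconstructed ties are dropped (deterministic) rather than randomly
oriented.  Body size enters on log10 by default, being ratio-scale.  The
test is a through-origin regression of RRD on the trait contrast, reported
with the plain correlation r as a second view.

## The synthetic-data generator

The generator emulates the statistical structure the analyses assume, not
any real geography:

* **Tree** — crown birth–death simulation (birth 1.0, death 0.6 per unit
  time) stopped when 250 lineages are extant, extinct lineages pruned,
  node times rescaled to a 44 Ma crown age.  The present is drawn uniformly
  inside the waiting interval in which exactly n lineages exist, so the final
  split never sits at age zero.  With γ > 0 a Brownian trait (rate 0.5)
  evolves along lineages and modulates speciation as λ = λ₀e^{−γx},
  producing genuinely trait-dependent diversification for the RRD tests.
* **Body size** — Brownian log10-SVL, root 30 mm, rate 0.003 per Ma: tip SVL
  spans roughly 5–120 mm and is right-skewed on the raw scale.
* **Range size** — log10 area = −0.8 + 2.0·log10(SVL) + Brownian deviation
  (rate 0.02) + N(0, 0.3²) noise, giving a strong positive log–log body–range
  association and areas from well under 1 km² to a few thousand km².
* **Space** — centroids follow 2-D Brownian diffusion (100 km²/Ma per axis)
  clipped to a 1600 × 600 km rectangle; the true range is a disc of the drawn
  area around the centroid; localities (1 + Poisson(4) per species) are
  uniform inside the disc.  Young sisters therefore sit close together and
  overlap more often — the spatial signal the pipeline is supposed to find.
* **Climate** — 21 columns, each a random smooth field of (x, y) (linear
  gradients plus a sinusoid) with per-variable scale/offset and noise, so
  nearby species have similar climates.
* **Phylogram** — branch lengths in substitutions/site obtained by
  multiplying each time-branch by a lognormal rate (median 0.005 subs/site/Ma,
  log-SD 0.3), standing in for a Bayesian phylogram before ultrametric
  correction.

One seed expands into named substreams (tree/rates/traits/space/climate/
support) so a change in one component's draw count never shifts another's.
Defaults were chosen once so that the generated data show the qualitative
structure of the motivating radiation — about two-thirds of sister pairs
allopatric, heavily overlapping sympatric pairs, right-skewed sizes — and are
not tuned per test.  Constant-rate birth–death gives younger cherries (mean
pair age ~1.5–2.5 Ma) than a radiation with an early-burst slowdown would;
modelling rate slowdowns is out of scope, and no test depends on absolute
pair ages.

What passing tests on these data do *not* show: robustness to locality error
and sampling bias, to fragmented (non-disc) ranges, to coastline/habitat
truncation of MCPs, or to correlated climate measurement error — real-data
features the generator deliberately omits.

## Problem sizes in the validation suite

Geometry oracles use 100 random point sets and 50 polygon pairs with 10⁵
Monte-Carlo samples each; contrast calibration 2000 cherries; regression
recovery 200 replicates at 53 pairs; quantile-regression checks n = 2000
(coverage), n = 1000 (envelope) and 200 replicates per sign direction; the
richness-contrast null 500 simulated 64-tip trees and the trait-dependent
check 100 trees of 100 tips.  These sizes put the Monte-Carlo error of each
check well inside its stated tolerance.

## Known limitations

* The two-locality "capsule" geometry is one defensible reading of
  buffer-around-two-localities; two disjoint discs would give the same areas
  to within the corridor term but a disconnected range.
* The sign test against a single central reference value is one of several
  possible pairings of sister overlaps with the non-sister background.
* Mahalanobis distances inherit the PCA's assumption that a common
  within-species score covariance is meaningful across species.
* Quantile-regression fits are non-unique on degenerate (e.g. heavily tied)
  data; the LP vertex returned is deterministic for a fixed input.
* The pipeline treats the phylogeny as known; support values filter pairs
  but no uncertainty is propagated into the statistics.
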