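# sisterrange

Comparative analyses of how body size and geographic range size shape
speciation in species-level radiations — built for evolutionary biologists
working with a time-calibrated phylogeny, point locality records, and a
body-size table (the motivating system is an island frog radiation of ~250
species, most of them small-bodied microendemics).

## What it computes

Given a rooted bifurcating species tree (an ultrametric timetree plus the
same topology with pre-ultrametric branch lengths), localities `(species, x,
y)` and maximal male snout–vent length (SVL, mm):

* **Sister pairs.** Every cherry (internal node with two terminal daughters),
  filtered by node support (posterior probability, default > 95) and by an
  exclusion list; node ages read off the timetree.
* **Range polygons.** Minimum convex polygons (MCPs) for species with ≥ 3
  localities; buffer discs/capsules for 1–2-locality species under two
  policies, RSA (25 km radius) and RSB (17 m), carried through every analysis
  side by side.  Overlap is expressed as a percentage of the smaller range,
  `100·A(a∩b)/min(A(a),A(b))`; pairs with zero overlap are allopatric.
* **Sister-pair statistics.** Age–range correlation; a sign test of
  sister-pair overlap against the non-sister background,
  `Z = (|k − n/2| − 0.5)/(√n/2)`; one-sample Kolmogorov–Smirnov normality of
  pair ages.
* **Standardized tip contrasts** `(x₁ − x₂)/√(bl₁ + bl₂)` for SVL, RSA and
  RSB, regressed through the origin (uncentered R², the classic ANOVA
  columns), plus a factorial through-origin regression on age, centroid
  distance and climatic distance with all interaction terms.
* **Quantile regression** (pinball-loss linear program) of range size and
  |range contrast| on pair age: peripatric speciation predicts a flat or
  negative τ = 0.9 envelope, so a positive high-quantile slope rejects it.
* **Climatic niche covariate.** Varimax-rotated PCA of per-locality climate
  variables (Kaiser retention, eigenvalue > 1) and squared Mahalanobis
  distances `D²(s,t) = (m_s − m_t)ᵀS⁻¹(m_s − m_t)` between species mean
  scores with pooled within-species covariance.
* **Richness contrasts.** At every internal node, `RRD = ln(N_large/N_small)`
  with daughters oriented by the Felsenstein-reconstructed trait value,
  regressed through the origin on the standardized trait contrast — negative
  slope means small-trait clades diversify more.

A seeded synthetic-data generator (`sisterrange.synth`) produces complete
datasets with this structure — a birth–death timetree rescaled to a 44 Ma
crown, right-skewed SVL and range-size distributions, a positive log–log
body–range association, diffusing range centroids, localities and smooth
climate fields — so every stage runs and is validated without any download.

## Worked example

```python
import sisterrange as sr

ds = sr.generate_dataset(sr.SynthConfig(seed=42))
summary = sr.run_analysis(ds)
```

prints (see `examples/02_synthetic_radiation.py`):

```
tips: 250, crown age: 44.0 Ma, localities: 1279
sister pairs          : 86
mean pair age (Ma)    : 1.53
% allopatric (RSA)    : 66.3
sympatric mean overlap: 62.0%
sign test             : Z=5.20, p=2e-07
```

86 of the 250 species fall in well-supported sister pairs; two-thirds of the
pairs have non-overlapping ranges (allopatric), but the sympatric minority
overlaps heavily, and the positive sign-test Z says sister species overlap
more than random non-sister species — shared ancestry keeps ranges close.
The `examples/` directory holds one short script per capability (fixture
pipeline, synthetic radiation, range polygons, the peripatry quantile test,
richness contrasts).

A thin CLI wraps the same calls:

```sh
sisterrange fixture --out-dir toy/
sisterrange synth --seed 1 --n-tips 250 --out-dir data/
sisterrange run --config config.yaml
```

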