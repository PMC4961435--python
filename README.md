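# betadismantle

Distance-matrix analysis of **partitioned beta-diversity** for
presence/absence community data — built for questions like "is the spread
of non-native bark and ambrosia beetles across regions a gradual,
climate-filtered process or a jumpy, trade-driven one?", answered at the
scale of site-by-species incidence tables (e.g. species × US states).

## What it computes

For every pair of sites with `a` shared species and `b`, `c` exclusive
species, total compositional beta-diversity is the Jaccard dissimilarity
and decomposes additively into a **species-richness-difference** and a
**species-replacement** component:

    β_cc   = (b + c) / (a + b + c)
    β_rich = |b − c| / (a + b + c)
    β_-3   = 2·min(b, c) / (a + b + c)
    β_cc   = β_rich + β_-3         (exact, enforced to 1e−12)

Around this partition the package provides the full analysis chain:

* **Mantel correlograms** — spatial autocorrelation of each component
  across equal-width geographic distance classes (Sturges' rule or a fixed
  class count), permutation-tested with progressive Bonferroni correction
  (class *i* at α/*i*), reported in the similarity-positive sign convention
  (positive = within-class pairs more similar than chance);
* **NMDS** — non-metric multidimensional scaling of the Jaccard matrix
  (Kruskal stress-1, classical-scaling first start plus seeded restarts);
* **MRM** — multiple regression on distance matrices: OLS on unfolded
  upper triangles with standardized predictors, optional quadratic terms,
  and coefficient p-values from joint row/column permutation of the
  response (the site, not the pair, is the exchangeable unit);
* **hierarchical partitioning** — each predictor's independent vs joint
  share of explained R² over all 2^k submodels (independent shares sum
  exactly to the full-model R²);
* predictor matrix builders: great-circle (haversine) centroid distances,
  climate differences, Bray-Curtis forest-composition dissimilarity, and
  log-transformed import-value and forest-area differences;
* a **synthetic community generator** with known ground truth
  (environmental filtering, dispersal limitation around introduction
  sites, import-driven richness) for end-to-end validation.

## Worked example

```python
import numpy as np
from betadismantle import CommunityMatrix, beta_partition_matrix

cm = CommunityMatrix(
    site_ids=["ME", "NY", "GA"],
    species_ids=["X. germanus", "X. crassiusculus", "A. maiche", "H. ligniperda"],
    values=[[1, 0, 0, 1],
            [1, 1, 0, 1],
            [1, 1, 1, 0]],
)
part = beta_partition_matrix(cm)
print(np.round(part.beta_cc.d, 3))
print(part.mean_beta_rich, part.mean_beta_3)
```

prints

```
[[0.    0.333 0.75 ]
 [0.333 0.    0.5  ]
 [0.75  0.5   0.   ]]
0.194  0.333
```

ME–NY differ only in richness (β_rich = 1/3, β_-3 = 0: NY holds a strict
superset), while ME–GA and NY–GA pairs mix replacement into the total; on
average replacement (0.33) outweighs richness difference (0.19) in this
toy table.

The same analysis runs end-to-end from the shell. With the packaged
12-site synthetic fixture:

```
$ betadismantle run --config cfg.yaml --out report/
bark: n_sites=12 mean_beta_rich=0.3508 mean_beta_3=0.5333 nmds_stress=0.1750
ambrosia: n_sites=12 mean_beta_rich=0.2871 mean_beta_3=0.5202 nmds_stress=0.2141
```

where `cfg.yaml` is

```yaml
synthetic:
  preset: fixture
  seed: 1
n_perm: 199
seed: 1
```

`report/` then holds, per guild, the three β matrices, correlogram tables
for β_rich and β_-3, NMDS coordinates, MRM tables (rows DIST, TEMP, RAIN,
FOR, AREA, IMP plus retained quadratic terms, with coefficients,
permutation p and cumulative R²) and hierarchical-partitioning tables
(independent/joint contribution per predictor), plus `summary.csv` and a
`provenance.json` sufficient to re-run bit-identically.  `betadismantle
synth --preset paper-like --seed 1 --out ds/` writes a full 48-site
two-guild dataset as CSV.

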