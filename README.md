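# emtpath

Pathogenomic analysis of epithelial–mesenchymal transition (EMT) in
carcinomas, as a tested, reusable Python pipeline. The package is aimed at
computational-pathology and tumor-microenvironment researchers who want the
quantitative backbone of an H&E + multi-omics EMT workflow without the
surrounding platform machinery: every stage runs on plain tables and
matrices, and a synthetic-data module generates statistically faithful
inputs for development and validation.

## What it computes

* **Cell-interaction-graph pathomics** (`emtpath.cellgraph`): from nucleus
  centroids labelled tumor/immune/stroma (T/I/S), 4096-px patches are
  given a k = 5 nearest-neighbour graph with a 50-px edge cutoff and its
  minimum spanning tree. Edge-length distributions per interaction
  subnetwork (T-T, T-I, T-S, I-I, I-S, S-S) × edge group (ranks v1–v5,
  all, MST) × six moments give 252 patch features; four aggregation
  moments across patches yield the **1,008-dimensional WSI descriptor**
  (6 × 7 × 6 × 4).
* **Prognostic modeling** (`emtpath.prognosis`): univariate Cox screening
  (select at p ≤ 0.05), an L1-penalised Cox risk score with
  cross-validated penalty choice, median-cutoff risk stratification
  (HR with 95% CI, log-rank test), and PCA + K-means pathological
  subtyping oriented so subtype 1 is stromal-high.
* **EMT macrostates** (`emtpath.macrostates`): epithelial/mesenchymal
  module scores (EMT score = mesenchymal − epithelial) and a
  three-component Gaussian mixture over pseudotime whose weighted-density
  intersection points define the EMT-early / EMT-stable / EMT-late
  boundaries.
* **Trajectory projection** (`emtpath.projection`): bulk or cell-line
  profiles are embedded jointly with a single-cell reference (shared
  genes, log-normalisation, optional empirical-Bayes batch adjustment,
  PCA) and assigned the median pseudotime of their k = 50 nearest
  reference cells, plus a macrostate; KDE mode counting diagnoses k.
* **Spatial colocalization** (`emtpath.spatial`): concentric ring levels
  1–5 around seed spots on a spot lattice, per-ring expression means, and
  Mann-Kendall trend tests (exact p for short series) classifying targets
  as colocalized / excluded / flat; plus nearest-distance trends for
  single-cell-resolution data.
* **Signature reversal** (`emtpath.reversal`): CMap-style KS connectivity
  of perturbation profiles with a disease up/down signature
  (negative = reversal), median-proximity collapsing of multi-condition
  profiles, most-reversing-first drug ranking, and ssGSEA-style
  drug-target enrichment with a membership-permutation null.
* **Synthetic data** (`emtpath.synthetic`): seeded generators for every
  input above — clustered/uniform T/I/S point patterns, survival cohorts
  with log-linear hazards, mixture pseudotime populations with marker
  ramps, niche-gradient spot lattices, and perturbation libraries with
  planted reversers — each shipping its ground truth.

See `docs/methods.md` for the models, conventions and numerical choices.

## Worked example

Segment a simulated EMT pseudotime axis into macrostates:

```python
import numpy as np
from emtpath.synthetic import SimConfig, gen_pseudotime_population
from emtpath.macrostates import fit_macrostate_model, assign_states, emt_score

cfg = SimConfig(seed=42, n_cells=3000)      # mixture (1/3,0,.5) (1/3,5,.5) (1/3,10,.5)
expr, pt, gt = gen_pseudotime_population(cfg)

model = fit_macrostate_model(pt, seed=0)
states = assign_states(pt, model)
print("means:", np.round(model.means, 3))
print("boundaries: b1=%.3f  b2=%.3f" % model.boundaries)
print(emt_score(expr).groupby(states, observed=True).mean().round(3))
```

Output:

```
means: [5.000e-03 4.998e+00 9.998e+00]
boundaries: b1=2.567  b2=7.485
EMT-early    -1.245
EMT-stable   -0.453
EMT-late      0.347
```

The EM fit recovers the three generating components (means 0/5/10), the
density-intersection boundaries fall between them, state assignment
matches the generating component for every cell (accuracy 1.000 on this
draw), and the mean EMT score increases strictly across the three states —
the ordering that defines EMT progression.

The same flows are scriptable from the shell, e.g.

```bash
emtpath simulate pseudotime --seed 42 --out sim/
emtpath emt-states --pseudotime sim/pseudotime.csv --expr sim/expression --out states/
emtpath features --cells segmentations/ --dialect hovernet-json --out features.csv
```

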