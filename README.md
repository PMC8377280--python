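# surfcode

Robust sparse coding of surface morphometry patches with max-pooled
subject representations and balanced random-forest classification.

The pipeline operates on registered surface grids (canonical 150 × 100
parameterization with one-to-one vertex correspondence to a template):

1. **morphometry** — per-vertex 4-vector features: radial distance (vertex
   to cross-section centroid, deformation along the surface normal) plus
   the three-component log-Euclidean vectorization of the tangent-plane
   deformation tensor `S = (JᵀJ)^{1/2}`; random overlapping square patches
   are vectorized into a patch matrix (e.g. 10×10 patches → p = 400,
   504 per hemisphere → 1,008 per subject); surface area / enclosed volume
   summary measures.
2. **pascs_core** — correntropy-induced sparse coding: per-patch
   half-quadratic weights `h = exp(−‖Dz−x‖²/σ²)` downweight outlier
   patches; codes are updated by weighted soft-threshold coordinate
   descent (one full pass + a few support-restricted passes); dictionary
   atoms take diagonal-Hessian SGD steps and are projected onto the
   unit-norm ball. With σ → ∞ the method reduces to plain ℓ1 stochastic
   coordinate coding.
3. **aggregate_classify** — coordinate-wise max-pooling of a subject's
   patch codes into one m-vector; binary amyloid labels from a centiloid
   cutoff (≥ 37.1 positive); random-forest classification (library
   defaults) under repeated stratified 10-fold cross-validation with
   per-training-fold random undersampling; ACC / B-ACC / SEN / SPE / AUC
   with Student-t 95% intervals; external validation and grid search.
4. **io_formats** — CSV metadata tables, HDF5/text grid containers,
   model persistence, JSON-lines run logs.
5. **synthetic** — ground-truth-dictionary patch generators (k-sparse
   Laplace codes, Gaussian noise, whole-patch uniform outliers) and
   two-group surface cohorts with planted morphometric effects.

## CLI

```bash
surfcode simulate patches --p 20 --m-true 5 --n 500 --k 3 --seed 1 --out sim/
surfcode simulate cohort --n-pos 100 --n-neg 100 --seed 1 --out cohort/
surfcode fit --patches sim/patches.tsv --m 5 --lam 0.3 --sigma 3.6 \
    --epochs 50 --seed 1 --out model.h5
surfcode encode --patches sim/patches.tsv --model model.h5 --out codes.tsv
surfcode cv --cohort-dir cohort/ --patch-size 6 --m 100 --sigma 30 \
    --seed 1 --out metrics.csv
surfcode metrics --predictions preds.csv
```

Default hyperparameters follow the reference configuration (patch size
10×10, m = 1800, λ = 0.22, σ = 3.6); σ is a kernel *scale* and must match
the data — the synthetic cohorts use σ ≈ 30 for their patch norms.

## Layout

```
src/surfcode/        io_formats, morphometry, pascs_core,
                     aggregate_classify, synthetic, pipeline, cli
tests/               pytest suite (+ independent plain-SCC reference oracle)
scripts/acceptance.py
```
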