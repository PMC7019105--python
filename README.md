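# cellnorm

Normalization is the first serious modelling decision in a single-cell
RNA-seq analysis: raw counts confound biology with sequencing depth,
capture efficiency and amplification noise, and different correction
strategies can change what downstream clustering, classification or
differential-expression analysis sees.  `cellnorm` implements seven
normalization strategies for gene-by-cell count matrices — from a simple
library-size rescale to spike-in-calibrated hierarchical Bayesian
inference — together with a seeded negative-binomial simulator with full
ground truth and a benchmarking harness that scores each method by how
well K-nearest-neighbour classification recovers known cell conditions,
measured with Cohen's kappa.

It is aimed at methodologists and analysts who want to compare
normalization strategies on simulated or real data under one consistent
interface before committing to one.

## Methods

| method | spike-ins | core idea |
| --- | --- | --- |
| `simple` | no | Y = ln(X·c/colsum + 1), the library-size baseline |
| `samstrt` | yes | depth from spike-in totals; Poisson resampling to a common depth |
| `basics` | yes | hierarchical Poisson-Gamma model; MCMC over cell factors φ_j, capture ν_j, technical noise θ |
| `grm` | yes | per-cell gamma regression of log concentration on log FPKM; output is expected log concentration |
| `scran` | no | pool cells, robust pool-level factors, deconvolve per-cell size factors by least squares |
| `scnorm` | no | quantile regression of the count-depth relationship in K gene groups; K grown until all slope modes ≤ 0.1 |
| `linnorm` | no | per-cell linear models anchored on low-variance "stable" genes, strength c ∈ [0,1] |

Every method is a scikit-learn-style transformer (`fit`, `transform`,
`get_params`) over a `CountMatrix`, with one-shot functions
(`normalize_scran(cm)`, …) for scripting.  The mathematical details,
priors, tie-breaks and identifiability choices are in
[`docs/methods.md`](docs/methods.md).

## Worked example

Simulate a two-group data set (5-fold change in 100 of 1000 genes, 8
spike-in rows with capture noise θ = 0.3), normalize it two ways, and
compare classification quality:

```python
import numpy as np
from cellnorm import simulate_dataset, clean_counts, pca_embed, knn_classify_repeated
from cellnorm.normalize import normalize_scran, normalize_simple

cm, truth = simulate_dataset(n_genes=1000, n_cells_per_group=24,
                             fold_change=5.0, n_de=100, seed=1)
cm = clean_counts(cm)                      # <10 gene / <10000 cell filters

for name, nm in [("scran", normalize_scran(cm)),
                 ("simple", normalize_simple(cm))]:
    values = np.log1p(nm.values[~cm.is_spikein]) if nm.scale == "linear" \
        else nm.values[~cm.is_spikein]
    scores = pca_embed(values, 20)
    kappas = knn_classify_repeated(scores, cm.condition, k=5,
                                   n_repeats=100, seed=2)
    print(f"{name:>6s}: median kappa = {np.median(kappas):.3f}")
```

```
 scran: median kappa = 1.000
simple: median kappa = 1.000
```

A median kappa of 1.0 means every repeated stratified split classified
the held-out cells perfectly after normalization — at a 5-fold change
the two groups are cleanly separable once depth is removed.  Lower the
fold change or add capture noise and the methods start to separate; the
full benchmark (`cellnorm benchmark`) runs all seven plus the raw-count
baseline and reports the kappa distributions per method.

The same pipeline is available from the shell:

```sh
cellnorm simulate --n-genes 1000 --fold-change 5 --n-de 100 --seed 1 --out sim
cellnorm normalize --method scran --input sim_counts.tsv --out norm
cellnorm evaluate --input norm_scran.tsv --labels sim_labels.tsv --out eval
cellnorm benchmark --seed 1 --out bench
```

Every command writes a JSON manifest (inputs, parameters, seed,
versions) from which its outputs can be regenerated.

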