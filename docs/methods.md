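# Methods

`cellnorm` implements seven normalization methods for single-cell RNA-seq
count matrices, a negative-binomial simulator with ground-truth tracking,
and a benchmarking harness that scores normalized output by how well
K-nearest-neighbour classification recovers known cell conditions.  This
note records the models, the numerical choices, and what the synthetic
data does and does not capture.

## Data model and cleaning

Counts are genes x cells, non-negative integers.  Spike-in transcripts
(synthetic RNA added in equal amounts to every cell's lysate, e.g. the
ERCC panel) sit in the same matrix behind a boolean mask; their known
concentrations live in a separate reference table.

Cleaning drops genes with row total below 10 and then cells with column
total below 10,000 in a single pass (genes first, then cells over the
remaining genes).  Spike-in rows are exempt from the gene filter by
default so small panels (8 transcripts in the mouse-embryonic-style
configuration) survive.  A second application of the filter can remove
further rows — the pass is deliberately not iterated to a fixed point
unless `to_fixed_point=True` is set.

FPKM is `counts * 1e9 / (gene_length * column_total)`, with the cleaned
matrix's column totals as the per-cell "million mapped reads" denominator.

## The seven methods

**Simple** — `Y = ln(X * c / colsum + 1)` with scale factor `c = 10^4`.
The baseline every other method is compared against.

**SAMstrt-style spike-in depth** — each cell's depth factor is its
spike-in column total divided by the geometric mean of all spike-in
column totals (the geometric mean is the package's choice of reference;
any common reference cancels in comparisons).  `expected` mode divides
counts by the factor; `resample` mode (default, 20 seeded draws) averages
Poisson draws with that expectation, mimicking resampling every cell to a
common spike-in depth.

**BASiCS-style hierarchical Poisson-Gamma model** — biological counts are
Poisson with mean `phi_j nu_j mu_i rho_ij`, spike-ins Poisson with mean
`nu_j mu_i`; `nu_j ~ Gamma(1/theta, mean s)` carries capture noise and
`rho_ij ~ Gamma(1/delta_i, 1/delta_i)` biological noise.  `rho` is
marginalized analytically (Poisson-Gamma = negative binomial with size
`1/delta_i`), and the remaining parameters are sampled by
Metropolis-within-Gibbs with log-scale random walks, step sizes adapted
toward 44 % acceptance during burn-in only.  Priors: log-normal(0, 2^2)
on `mu_i` and `delta_i`, Gamma(1,1) on `s` and `theta`, flat on
`log phi` under the constraint `sum(phi) = n` (enforced each sweep by
rescaling `phi` and compensating `mu`, a move along the likelihood's flat
direction).  Two identifiability choices matter:

* the spike-in rates `mu_i` are fixed inputs — their known input amounts
  when available, else the empirical spike-in row means, which anchors
  the `nu` scale near one;
* the capture-efficiency constant `s` is a single scalar shared by all
  cells.  Spike-ins enter every cell in the same volume, so a common
  centre is the natural model; a free per-cell `s_j` under a vague prior
  can track its own `nu_j` exactly, collapsing `theta` to zero
  (a Neyman-Scott-type degeneracy) and leaving technical noise
  unidentified.

Point estimates are posterior medians of the thinned post-burn-in draws
(default 20,000 sweeps, 10,000 burn-in, thin 10).  The normalized output
is `Y = X / (phi_j nu_j)` for biological genes and `Y = X / nu_j` for
spike-ins — the model does not prescribe an output formula, so the
package removes exactly the cell-specific multiplicative terms.

**GRM (per-cell gamma regression)** — within each cell, the natural log
of the known spike-in concentration is modeled as
`Gamma(mean = sum_d beta_d X^d, shape = phi)` with `X = ln(FPKM)`.
For each candidate degree 1–4 the mean coefficients are fitted by IRLS
with weights `1/mu^2` (the Gamma score for the mean does not involve the
shape, so this is the MLE), the shape by profile MLE
(`log k - digamma(k) = mean(C/mu - log(C/mu) - 1)`, solved by Brent in
log space).  The degree with the smallest mean squared spike-in residual
wins; ties (to within 1e-9 relative) go to the smaller degree, so
noiseless calibrations select the simplest interpolant.  Spike-ins with
zero FPKM or with log-concentration <= 0 (the Gamma response must be
positive) are excluded from the fit.  Every biological gene's normalized
value is the fitted expected log concentration at its `ln(FPKM)`; zero
counts stay 0 and are flagged.  The method is strictly per-cell — no
information crosses cells — so it denoises rather than rescales.

**scran-style deconvolution** — cells are sorted by library size onto a
ring; sliding windows of sizes 21, 26, ..., up to min(101, n) form pools
with comparable depth (below 21 cells a single pool size of n/2 is used,
with a warning below 20 cells).  For each pool, the median over expressed
genes of (pool sum of `X/t`) / (all-cell mean of `X/t`) gives a robust
pool factor insensitive to a minority of DE genes; each pool contributes
the linear equation `sum_{j in pool} x_j = factor` in the per-cell
unknowns `x_j = theta_j / t_j`.  Low-weight rows (weight 1e-3) anchoring
every `x_j` at the mean per-cell pool factor make the stacked system full
rank; the anchor value is exact on noiseless data, so exact recovery is
preserved there at any weight.  Least squares solves the system; size
factors `x_j t_j` are rescaled to mean one and divide the counts.

**SCnorm-style quantile regression** — the count-depth relationship (the
slope of log nonzero expression on log sequencing depth) is 1 under a
pure depth effect and should be 0 after normalization.  Per-gene slopes
come from exact median (L1) regression solved as a linear program.  Genes
with a defined slope are split into K equal groups by slope quantiles
(the grouping rule is the package's choice; the quantity whose
heterogeneity drives K is the natural grouping variable).  Within each
group, a quantile-regression surface over tau in {0.05..0.95} and degree
in {1,2,3} is fitted to the pooled (log depth, log count) cloud —
down-sampled deterministically (sorted, evenly spaced) to 600 points for
the LP — and the (tau*, d*) minimizing the gap between the fitted
curve's median count-depth slope and the mode of the group's gene slopes
is kept.  The per-cell scale factor is
`SF_j = exp(fit(D_j)) / exp(quantile_{tau*}(group log expression))` and
`Y = X / SF` on nonzero entries (zeros stay zero).  Starting at K = 1,
the normalized matrix is re-checked in 10 equal-size expression pools;
if any pool's slope mode exceeds 0.1 in magnitude K is incremented, up
to K = 10 (a warning flags non-convergence).  Genes with fewer than 10
nonzero cells are excluded from fitting and ride along with the
expression-nearest group, flagged in the fit.  The slope mode is the
argmax of a Gaussian KDE (Silverman bandwidth, 512-point grid, ties to
the smaller value).  Sequencing depth defaults to column totals but can
be supplied explicitly — after normalization the totals are deliberately
flat, so re-checking an already-normalized matrix only makes sense
against the original depths.

**Linnorm-style stable-gene linear models** — counts are put on relative
scale `R = X / colsum`, a common pseudo-depth `lambda` (median column
total) defines `G = ln(lambda R)`, and "stable" genes (nonzero in every
cell, lowest 30 % variance of `G`) anchor one OLS fit per cell of the
across-cell mean expression on the cell's own `G`.  The regression is on
`G` (not raw counts) — the only dimensionally consistent reading of the
procedure.  A strength coefficient `c` (default 0.5) interpolates:
`a <- c(a-1)+1`, `b <- cb`, `Y = ln(exp(aG + b) + 1)` on nonzero entries.
At `c = 0` the output reduces exactly to simple normalization at scale
`lambda`; at `c = 1` each cell is fully mapped onto the stable-gene
consensus.

## The simulator

`simulate_dataset` emulates a two-group plate-style experiment: gene mean
rates log-normal(1.0, 1.5) (heavily right-skewed, matching deep
plate-based data where cells below 10,000 total counts are discarded),
gene overdispersions log-normal around 0.3, mean-one log-normal(0.3)
cell scaling factors, counts negative-binomial with variance
`m + phi m^2`.  1000 of 10,000 genes (configurable) receive a
multiplicative fold change (2 or 5 by convention) in the second of two
equal subgroups of 24 cells each.  Eight spike-in rows with
geometrically spaced concentrations are appended; their counts are
Poisson around `nu_j mu_i` where `nu_j ~ Gamma(1/theta, mean s_j)`
shares the cell's scaling factor (theta = 0.3 by default) and `mu_i` is
proportional to concentration, scaled so the median expected spike-in
count is ~50.  Gene lengths are drawn uniformly (0.5–5 kb biological,
0.25–2 kb spike-in) so FPKM-based methods can run.  All stages are
seeded; one global seed fans out to per-stage child seeds through a
SeedSequence counter so stages can be reproduced independently.

What the simulator does **not** emulate: zero inflation beyond what NB
sampling produces (droplet-style dropout), batch effects, more than two
groups, gene-gene correlation, and amplification-length biases.  Tests
passing on this generator therefore demonstrate correctness of the
methods' estimation machinery under their own assumptions, not
performance on the full messiness of real data.

## Evaluation harness

Normalized matrices are compared on downstream class recovery: spike-in
rows are excluded, linear-scale outputs are `ln(x+1)`-transformed (log
outputs pass through), cells are embedded with centered-SVD PCA (top 50
components, capped by rank; the largest-magnitude loading of each
component is made positive for sign stability), and a Euclidean KNN
(k = 5, majority vote, ties to the smallest class index) is scored by
Cohen's kappa over 100 stratified 70/30 train/test splits.  Kappa
corrects observed agreement for chance agreement from the confusion
matrix margins, which keeps the score meaningful under unequal group
sizes.  The k, split fraction and feature space are package defaults,
recorded in every report.  Raw counts always run as a baseline, and
methods that need spike-ins are skipped (with a logged reason) on
spike-in-free data.

DE screening is a per-gene two-sided rank-sum test with
Benjamini-Hochberg step-up adjustment at alpha = 0.05 (a per-gene
negative-binomial GLM Wald test is available for count-scale values).
Note the step-up adjusted p-values are monotone in the input ranks but
not exactly idempotent — re-adjusting an adjusted vector can raise tied
blocks; this matches statsmodels' reference implementation exactly.

The benchmark fits the Poisson-Gamma model on the 1000 highest-count
biological genes plus all spike-ins (4000 sweeps, 2000 burn-in) and
applies the per-cell factors to the full matrix; full-matrix MCMC at
10,000 genes adds nothing to the per-cell factors but an order of
magnitude of compute.  These desk-scale problem sizes (10,000 genes,
48 cells, 100 splits) are the package's defaults and are what
`scripts/acceptance.py` reports.

## Numerical notes and tie-breaks

* Quantile regression: exact LP (HiGHS) for problems up to 600 points
  and for all weighted problems; statsmodels IRLS above that (used only
  for large unweighted fits).  Degenerate LP optima resolve to the
  solver's reported vertex, which is deterministic for fixed inputs.
* KDE mode: first grid argmax, i.e. ties break toward the smaller slope.
* GRM degree selection: smallest degree within 1e-9 relative tolerance
  of the best score.
* NB sampling with `phi = 0` falls back to Poisson draws exactly.
* The MCMC floors `delta` and `theta` at 1e-6 to keep the NB size
  finite; `theta` estimates at the floor indicate a Poisson-limit fit.
* All stochastic components take explicit integer seeds; identical seeds
  give bit-identical matrices and reports.

## Known limitations

* The Poisson-Gamma sampler is a desk-scale reimplementation: single
  chain, median point estimates, no convergence diagnostics beyond
  acceptance rates and effective chain storage.  For production-grade
  inference on real data, longer chains and multiple starts are advised.
* GRM output lives in log-concentration units; it is not comparable in
  scale to the other methods and is evaluated only through
  scale-invariant downstream metrics.
* The SCnorm-style K loop can hit K = 10 without satisfying the 0.1
  slope-mode rule on pathological data; the fit is then returned with a
  warning flag rather than an error.
* Per-cell Linnorm slopes are attenuated when the stable genes span a
  narrow expression range (regression on a noisy regressor); with
  realistic multi-decade expression ranges the attenuation is small.
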