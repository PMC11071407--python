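# Methods

This note documents the statistical model, its defaults, the synthetic-data
generators, and the numerical choices made where the design was open.

## Data model and preprocessing

An `STArray` holds a nonnegative-integer genes x spots count matrix with
integer lattice coordinates, a tissue-section id, an MROI (morphological
region of interest) label per spot, and optionally a composition simplex
per spot over cell types. Invariants enforced at construction: coordinates
unique within a tissue, composition rows on the simplex to 1e-8, depth equal
to the column sum.

Quality control removes genes detected in fewer than 2% of spots and then
spots with fewer than 100 UMIs (both configurable; the order genes-then-spots
is fixed and logged). Tissue-section detection runs connected components on
the 4-neighbor lattice, discards sections with fewer than a minimum spot
count (5 or 10 are the defaults used for young/old arrays in the colon study
design this follows), drops spots under 800 UMIs, and finally drops spots
whose retained neighborhood no longer embeds in the cross pattern
[[0,1,0],[1,1,1],[0,1,0]]. The cross-pattern pass is applied once, not
iterated to a fixed point. When both the 800-UMI section filter and the
100-UMI dataset filter are in play their interaction order is not uniquely
determined; this package applies section detection first and logs it.

Size factors are `s = depth / median(depth)` over retained spots, so the
modeled rate `lambda` is depth-free and comparable across analyses.

Adjacency supports two lattices: cartesian (4 neighbors at unit L1 distance)
and hexagonal (6 neighbors, odd-row offset convention as used by commercial
hex arrays).

## Reference priors and markers

In compositional mode the top-level prior for gene *i* in cell type *m* is
`N(mu, sigma^2)` with `mu`/`sigma` the empirical mean/SD of
`log(1 + x)` over that type's cells, where `x` is depth-normalized to 10k
counts per cell; the same prior is replicated across MROIs (an override
exists since region-specific references are rare). The SD is floored at 0.1
so constant genes cannot produce degenerate priors; the `log(1+x)` transform
and pseudocount are config fields. Non-compositional mode uses `N(0, 2^2)`
everywhere regardless of the reference.

Markers are selected one-vs-rest per type with Welch t-tests on
`log(x + 1)` of depth-normalized, gene-wise unit-variance-scaled counts
(scaling divides by the SD without centering, preserving nonnegativity),
BH-adjusted within type, significance = adjusted p < 0.05 and log2 fold
change > 1. The panel size m is the minimum significant-marker count across
types; the top m per type by adjusted p are kept (ties broken by |log2 fc|
then gene id, for determinism) and the deduplicated union is returned.

## Deconvolution

The reference matrix (marker rows, preprocessed as above) is factored
V = W H by multiplicative-update NMF with Frobenius loss (500 iterations
max, relative-change tolerance 1e-5). W is seeded with marker probabilities
(1 - adjusted p, floored at 1e-6 so no entry is absorbing) and H with the
binary cell-to-type assignment; the zero off-type entries of H are absorbing
under multiplicative updates, which is intentional — topics stay identified
with cell types. Spot profiles map onto the fixed W by per-spot NNLS;
consensus type signatures Q are per-type medians of H.

Compositions P solve

    min_{P >= 0} ||H' - Q P||_F^2 + alpha ||L - S P||_F^2

by projected Adam (learning rate 0.01, 100,000 iterations, seeded random
start). The norms are squared Frobenius for smooth gradients. alpha = 0
reproduces per-spot NNLS; the exact stacked-NNLS solution of the same
objective is kept in the package as an independent cross-check. By default
P is renormalized per spot to a simplex (required downstream); all-zero
columns map to the uniform simplex and are flagged. Spots with an all-zero
morphology column are deconvolved without the morphology term.

## The hierarchical count model

Per gene (genes share no parameters and are fit independently):

* Families: Poisson, NB, ZIP, ZINB with mean `s * lambda`. The NB uses the
  (mean, dispersion) parameterization `var = m + m^2/phi`;
  `phi ~ half-normal(0, 5)` (the original description states no dispersion
  prior). Zero inflation is a per-observation mixture with gene-level weight
  `theta ~ Beta(1, 2)`: a gene-level Bernoulli gate would force all of a
  gene's counts to zero jointly, contradicting the mixture description, so
  the mixture reading is implemented.
* `log lambda = B + psi + eps` with `B = x' beta E` (compositional) or
  `x' beta` (non-compositional).
* Hierarchy: `beta_l1 ~ N(mu_l1, sigma_l1^2)` (empirical or flat priors as
  above), `beta_l1l2 ~ N(beta_l1, sigma_l2^2)`,
  `beta_l1l2l3 ~ N(beta_l1l2, sigma_l3^2)`, with
  `sigma_l2, sigma_l3 ~ half-normal(0,1)` per covariate group.
* CAR field per tissue: `psi ~ N(0, [tau K (I - alpha K^{-1} W)]^{-1})`,
  i.e. precision `tau (K - alpha W)`; `alpha ~ U(0,1)`,
  `tau ~ Inv-Gamma(1,1)`. The log determinant uses the eigenvalues of
  `K^{-1/2} W K^{-1/2}` (computed once per tissue), so each density
  evaluation is sparse. Spots with no neighbors are excluded from the field
  (psi = 0 there, logged) because `K^{-1}` is undefined for them. psi is
  sampled jointly with its hyperparameters in the centered parameterization;
  at the small per-tissue sizes targeted here this mixes adequately and
  avoids differentiating a Cholesky factor.
* Spot effects: `eps ~ N(0, sigma^2)`, `sigma ~ half-normal(0, 0.3)`.

Whether psi is estimated for every gene or only expressed genes is exposed
as the `use_spatial` switch; simulation studies here disable it because the
generators produce independent spots.

### Inference

Sampling is an in-package adaptive Hamiltonian Monte Carlo (`stweave.hmc`):
all chains move as one vectorized batch; leapfrog trajectory lengths are
jittered uniformly in [1, 16]; the step size is tuned by Nesterov dual
averaging toward 0.8 acceptance; warmup splits in half, with a diagonal mass
matrix estimated from the first phase's draws and the step size re-adapted
under it. Constrained parameters move on unconstrained scales (log for
sigma/tau/phi, logistic for alpha/theta) with Jacobians included. Defaults:
4 chains, 250 warmup, 250 sampling iterations. Convergence is flagged per
gene by split R-hat (threshold 1.05 on beta, via arviz) and the divergence
count; non-converged fits are returned but flagged. All randomness derives
from `(seed, gene index)` so fits are reproducible draw-for-draw.

Correctness evidence in the test suite: finite-difference gradient checks
across all families/levels/terms; exact-pmf agreement with independently
composed scipy distributions; analytic-target sampling checks; prior
recovery with no data; simulation-based calibration (90% intervals cover
the generating value in >= 85/100 replicates); and agreement of the
posterior mode with a direct numerical optimizer of an independently coded
reduced density.

## Differential expression

For a contrast `delta = beta_1 - beta_2`, the Bayes factor for the point
null is the Savage-Dickey ratio of prior to posterior density at zero. The
prior density is analytic for pure top-level contrasts (difference of
normals); for deeper levels it is estimated from 10,000 seeded Monte-Carlo
draws of the marginal hierarchy prior (the conditional-on-hyperparameter
variant is also implemented; marginal is the default). The posterior density
at zero is a Gaussian KDE with Silverman bandwidth over the pooled draws.
BFs are capped at 1e6 (and floored at 1e-6) with a flag; fold changes are
reported in log2 units while the internal scale is natural log. Set-vs-set
comparisons pool draws per side and use the matching equal-weight prior
mixture. The DE convention used throughout the analyses is BF > 2 with
|log2 fc| > 0.5; by the usual scale BF > 5 is "substantial".

## Simulators

`synth_reference` builds a cell-typed reference: a log-normal baseline mean
per gene (SD 1.0) shared across types, disjoint planted marker blocks
multiplied by a configurable fold change (default 8), per-cell counts from a
gamma-Poisson law (dispersion 2, depth 2,000) to emulate overdispersed
snRNA-seq. The planted noise-free mean profile is attached to the result;
DE truth labels a (gene, type pair) as differential when the planted fold
ratio is >= 2 (configurable). Because the truth is defined from the planted
profile, cluster simulations are driven by that same profile — the analogue
of deriving both the simulator input and the DE truth from one set of
cluster-average profiles.

Cluster-based regime: per spot, a composition is drawn flat-Dirichlet over
the region's member types ("uniformly random proportions" is not otherwise
specified); reads per type are the largest-remainder integer apportionment
of M * E (M = 1,000 by default), so spot totals equal M exactly — plain
rounding would break that invariant; reads are multinomial over the type's
column-normalized profile and pooled. Defaults follow the validation design
the model family was assessed under: 12 arrays x 2,000 spots, two regions
1:1 (the test suite and reproduction script scale these down and say so).
The recommended likelihood for this regime is Poisson, matching the
multinomial marginals; spots are independent, so the CAR term is suppressed.

Cell-based regime: 10 cells per spot partitioned uniformly at random over
the region's member types, drawn without replacement within type from
cell profiles depth-normalized to 1,000, summed, rounded half-to-even.
The NB family (no zero inflation) is the recommended fit here.

Observability corruption pools compositions into superclasses through the
binary map S, adds zero-mean Gaussian noise, clips at zero element-wise, and
renormalizes; vectors clipped to zero fall back to the uniform simplex and
are flagged. Optional lattice smoothing blends each spot with the mean of
its inclusive neighborhood (so weight 1 turns a 2-spot pair into its rounded
mean) and rounds.

## Multicellular programs

Cell types present in at least 5% of spots on average enter the analysis;
per type, the top 5% of genes by coefficient of variation of `exp(beta-bar)`
across conditions are kept (the CV is taken on the exponentiated scale with
an epsilon floor because log-scale means can sit near zero). Matrices are
standardized gene-wise across conditions. Sparse multi-CCA maximizes
`sum_{i<j} w_i' B_i B_j' w_j` under `||w||_2 <= 1`, `||w||_1 < c` by
alternating soft-thresholded power iterations; the problem is non-convex, so
a deterministic multi-start (per-matrix leading singular vectors plus every
pairwise cross-product singular pair) is used and the best objective kept.
Successive programs are found after deflating each matrix against its
earlier variates, making within-type bases orthogonal. When penalties are
not supplied they are chosen by a permutation approach (25 column
permutations, standardized real-vs-permuted objective gap over a small grid).

Member genes are those with |w| > 0.1, capped at 250 per program across all
types, signed into up/down sets. Programs must be internally coherent (mean
pairwise member correlation >= 0.3); latter programs are additionally
dropped when their members' mean absolute correlation with an earlier kept
program exceeds 0.05 (multi-CCA emits programs in a fixed order, so
redundancy is judged against earlier output; the first program has no
comparator and this is logged). Activity per condition is the weighted sum
of member-gene expression and is exactly linear in beta-bar. Enrichment is
a one-sided Fisher exact test per named gene set, BH-adjusted across sets;
collections are supplied as GMT files (no pathway database is bundled —
those are version-dependent).

## Composition and power analyses

Composition tests treat each tissue section as one independent sample: spot
simplexes are averaged per (section, MROI) — the mean is the pooling
statistic, with a median option — and each cell type is compared between
groups by a hand-written two-sided Welch t-test (kept independent of scipy
so the two implementations can cross-validate). BH correction is applied
across cell types within each (MROI, group pair) family; significance stars
follow the 0.05 / 1e-3 / 1e-4 steps. Gradient genes require BF > 2 and
|log2 fc| > 0.5 between crypt base and apex plus non-strict monotonicity
(tolerance 1e-6) of the posterior-mean rate across BASE, BASE&MID, MID,
APEX in the direction of the fold change.

The power analysis approximates each beta posterior by a normal from its
mean and SD and reports KLD(full || subsampled) — the information lost when
the subsampled posterior stands in for the full one; the direction matters
and is tested.

## Problem sizes used in the checks

The end-to-end validation experiments run at reduced scale chosen to keep
the whole suite interactive while leaving each check decisively powered:
DE agreement uses 200 genes over 2 arrays x 200 spots (measured 99%
agreement against planted truth at seed 1); rate recovery uses 100 genes on
one array (per-type Pearson r > 0.9 on log rates); calibration uses 100
single-gene replicates of 30 spots; the subsampling analysis uses 15 genes
over 1/2/4 arrays of 50 spots with 3 seeds. Scaling these up changes
runtimes, not conclusions.

## What the synthetic data does and does not show

The generators reproduce the count laws, composition structure, marker
architecture and design hierarchy that the model assumes — so passing tests
demonstrates correct inference under the stated generative assumptions,
including the known mild misspecification that multicellular spots mix
rates arithmetically while the compositional model mixes them
geometrically (visible as slight attenuation of contrasts, absorbed easily
at the fold changes tested). They do not emulate segment-level batch
effects, gene-gene correlation within cells, platform-specific dropout
curves, or histology misannotation beyond Gaussian composition noise;
conclusions about real tissue require the corresponding real inputs.

## Known limitations

* Inference is HMC-only; there is no variational or MAP-only fast path.
* Genes are fit serially in-process; the per-gene independence makes
  external parallelization trivial but none is built in.
* The CAR field is excluded for isolated spots rather than imputed.
* Savage-Dickey BFs degrade when the posterior places essentially no mass
  near zero (hence the cap-and-flag) and the KDE estimate is noisy below a
  few hundred draws (hence the 100-draw minimum).
* No multiple-testing correction is applied to Bayes factors, matching the
  convention of the analyses this package reproduces.
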