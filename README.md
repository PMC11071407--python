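# stweave

Cell-type-resolved hierarchical Bayesian modeling of spatial transcriptomics
(ST) arrays.

An ST spot measures the pooled transcriptome of every cell sitting on a
barcoded lattice position, so raw spot counts confound cell-type identity,
tissue context, biological covariates, sequencing depth, and local spatial
structure. `stweave` is for computational biologists who want to untangle
those layers: it deconvolves spots into cell-type proportions using a
single-cell/single-nucleus reference and histology-derived constraints, and
then models counts with a hierarchical Bayesian generalized linear model
whose posterior separates cell-type-specific expression per tissue region
from spatial autocorrelation and spot-level noise.

## The model

Counts `y[i,j,k]` of gene *i* at spot *k* of tissue section *j* follow a
Poisson, NB, ZIP or ZINB law with mean `s[j,k] * lambda[i,j,k]`, where `s`
is the spot's UMI depth normalized by the dataset median, and

```
log lambda[i,j,k] = B[i,j,k] + psi[i,j,k] + eps[i,j,k]
```

* `B = x' beta E` — the characteristic rate: a one-hot encoding `x` of the
  spot's morphological region (MROI) picks a row of the (MROI x cell type)
  rate matrix `beta`, which is averaged under the spot's composition simplex
  `E`. `beta` is hierarchical over up to three covariate levels
  (e.g. age / colon region / animal), with empirical priors from the
  reference at the top and half-normal(0,1) group scales below.
* `psi` — a conditional autoregressive (CAR) field per tissue with precision
  `tau (K - alpha W)` over the 4- or 6-neighbor lattice adjacency `W`
  (`alpha ~ U(0,1)`, `tau ~ Inv-Gamma(1,1)`).
* `eps ~ N(0, sigma^2)` — i.i.d. spot noise, `sigma ~ half-normal(0, 0.3)`.

Genes are fit independently by adaptive Hamiltonian Monte Carlo (4 chains x
250 warmup + 250 draws by default, split R-hat monitored). Differential
expression between any two conditions, regions or cell types is the
Savage-Dickey density ratio `BF = p(delta beta = 0) / p(delta beta = 0 | data)`.

Around the core model the package provides: marker-seeded NMF/NNLS
deconvolution with a morphology penalty (`deconvolution`), empirical priors
and balanced marker panels (`reference`), ground-truth cluster- and
cell-based ST simulators (`simulate`), multicellular-program discovery by
sparse multi-CCA (`mcp`), and composition/power analyses (`downstream`).

## Worked example

`examples/03_fit_and_de.py` simulates multicellular spots from a two-type
reference with planted differential expression, fits the compositional
Poisson model, and calls DE by Bayes factor:

```
fitted 40 genes; DE/non-DE label agreement with planted truth: 92.5%
11 genes called DE (BF > 2, |l2fc| > 0.5):
 gene        bf       lfc  called  truth
g0000 1000000.0  2.342203    True   True
g0001 1000000.0  2.441021    True   True
...
example gene g0000: BF 1000000.00, log2 fc +2.34 (DE)
```

The planted markers (8-fold between types, i.e. log2 fc near 2.3 after
profile normalization) are recovered decisively — their posterior places no
mass at a zero contrast, so the Bayes factor saturates at its reporting cap
of 1e6 — while flat genes stay below the BF > 2, |l2fc| > 0.5 thresholds.
Agreement rises to 99% at the larger simulation scale used by the
reproduction script below. The other scripts in `examples/` walk through
QC, deconvolution, the simulators, program discovery, and the composition
and power analyses, each printing a few annotated numbers.

## Layout

```
src/stweave/
  spatial.py        data model, QC, section detection, adjacency, size factors
  io.py             MTX/TSV/CSV readers and writers
  reference.py      empirical priors, balanced marker selection
  deconvolution.py  seeded NMF, NNLS mapping, morphology-constrained P
  likelihoods.py    Poisson/NB/ZIP/ZINB log-pmfs and gradients
  hmc.py            vectorized adaptive Hamiltonian Monte Carlo
  model.py          hierarchical model, CAR prior, fitting, prediction
  bayesfactor.py    Savage-Dickey DE, pooled set-vs-set contrasts
  simulate.py       synthetic reference, cluster/cell simulators, corruption
  mcp.py            sparse multi-CCA programs, filtering, activity, enrichment
  downstream.py     Welch composition tests, gradient genes, posterior KLD
  validation.py     end-to-end benchmark experiments
  cli.py            thin command-line wrapper (`stweave --help`)
```

See `docs/methods.md` for the full model description, parameter defaults,
numerical choices and known limitations.
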