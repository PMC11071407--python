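"""End-to-end validation experiments on simulated ground truth.

These are the package's own benchmark workflows: generate ST data with a
known generative state (planted differential expression, known compositions),
run the full inference path, and score the result against the generating
truth.  They power both the test-suite's integration checks and the
reproduction script.

The cluster-based protocol follows the validation design the model family
was introduced with: a Poisson likelihood (matching the multinomial
marginals of the generator), spots simulated independently so the spatial
CAR term is suppressed, true compositions supplied to the compositional
model, and differential expression called by Savage-Dickey Bayes factor
(BF > 2) together with |log2 fold change| > 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayesfactor import delta_prior_density_at_zero, savage_dickey_bf
from .downstream import posterior_kld
from .model import CovariateHierarchy, ModelConfig, PosteriorSamples, build_model, fit
from .reference import PriorMode, ReferencePriors
from .simulate import SimulationConfig, simulate_cluster_spots, synth_reference
from .spatial import STArray, SizeFactors


def _flat_compositional_priors(gene_ids, celltypes, mroi="region0"):
    shape = (len(gene_ids), 1, len(celltypes))
    return ReferencePriors(
        mu=np.zeros(shape), sigma=np.full(shape, 2.0), gene_ids=list(gene_ids),
        mrois=[mroi], celltypes=list(celltypes), mode=PriorMode.compositional,
    )


def _fit_cluster_sim(data: STArray, seed: int, chains=4, warmup=250, samples=250) -> PosteriorSamples:
    priors = _flat_compositional_priors(data.gene_ids, data.celltypes, mroi=str(data.mroi[0]))
    tissues = sorted(set(data.tissue_id))
    hierarchy = CovariateHierarchy(tissues=tissues, l1=["all"] * len(tissues))
    cfg = ModelConfig(
        family="poisson", compositional=True, n_levels=1,
        chains=chains, warmup=warmup, samples=samples, seed=seed,
        use_spatial=False, use_spot_effects=False,  # spots are simulated independently
    )
    sf = SizeFactors(data.depth / np.median(data.depth))
    return fit(build_model(cfg, hierarchy, priors), data, sf)


@dataclass
class DEAgreementResult:
    agreement_pct: float
    n_genes: int
    calls: pd.DataFrame          # gene, bf, lfc, called, truth
    posterior: PosteriorSamples


def de_agreement_experiment(
    seed: int,
    n_genes: int = 200,
    markers_per_type: int = 10,
    n_arrays: int = 2,
    spots_per_array: int = 200,
    reads_per_spot: int = 1000,
    bf_threshold: float = 2.0,
    lfc_threshold: float = 0.5,
    chains: int = 4,
    warmup: int = 250,
    samples: int = 250,
) -> DEAgreementResult:
    """Agreement between planted and model-called DE on cluster-based data.

    A two-type synthetic reference with planted marker blocks defines the
    ground truth; multicellular spots are simulated per the multinomial
    cluster protocol with one MROI and true compositions; the compositional
    Poisson model is fitted per gene; DE between the two cell types is
    called by Savage-Dickey BF and log2 fold change; the returned score is
    the percentage of genes whose DE/non-DE label matches the planted truth.
    """
    ref, de_truth = synth_reference(n_genes, 2, markers_per_type, seed=seed)
    profiles = ref.planted_mean / ref.planted_mean.sum(axis=0, keepdims=True)
    sim = simulate_cluster_spots(
        profiles,
        SimulationConfig(
            n_arrays=n_arrays, spots_per_array=spots_per_array,
            reads_per_spot=reads_per_spot, regions={"region0": [0, 1]}, seed=seed,
        ),
        gene_ids=list(ref.gene_ids), celltypes=[str(t) for t in ref.types],
        de_truth=de_truth,
    )
    post = _fit_cluster_sim(sim.data, seed=seed, chains=chains, warmup=warmup, samples=samples)
    prior0 = delta_prior_density_at_zero((0.0, 2.0), (0.0, 2.0))
    truth = de_truth.set_index("gene")["is_de"]
    rows = []
    n_match = 0
    for gene, gp in zip(post.genes, post.gene_posteriors):
        b = gp.params["b1"]
        delta = (b[..., 0, 0, 0] - b[..., 0, 0, 1]).ravel()
        res = savage_dickey_bf(prior0, delta)
        called = bool(res.bf > bf_threshold and abs(res.lfc) > lfc_threshold)
        rows.append((gene, res.bf, res.lfc, called, bool(truth[gene])))
        n_match += called == bool(truth[gene])
    calls = pd.DataFrame(rows, columns=["gene", "bf", "lfc", "called", "truth"])
    return DEAgreementResult(
        agreement_pct=100.0 * n_match / len(post.genes),
        n_genes=len(post.genes), calls=calls, posterior=post,
    )


@dataclass
class RateRecoveryResult:
    pearson_r: dict              # cell type -> r between posterior-mean and true log rate
    min_r: float


def rate_recovery_experiment(
    seed: int,
    n_genes: int = 100,
    spots_per_array: int = 200,
    reads_per_spot: int = 1000,
) -> RateRecoveryResult:
    """Correlation between recovered cell-type rates and generating profiles.

    Fits the compositional Poisson model to one simulated array with true
    compositions and correlates the posterior-mean log rate per cell type
    against the log of the generating profile (which scales as reads *
    profile, the expected counts at unit size factor).
    """
    ref, de_truth = synth_reference(n_genes, 2, max(n_genes // 20, 2), seed=seed)
    profiles = ref.planted_mean / ref.planted_mean.sum(axis=0, keepdims=True)
    sim = simulate_cluster_spots(
        profiles,
        SimulationConfig(n_arrays=1, spots_per_array=spots_per_array,
                         reads_per_spot=reads_per_spot, regions={"region0": [0, 1]}, seed=seed),
        gene_ids=list(ref.gene_ids), celltypes=[str(t) for t in ref.types], de_truth=de_truth,
    )
    post = _fit_cluster_sim(sim.data, seed=seed)
    beta_mean = post.beta_mean("b1")[:, 0, 0, :]   # genes x types
    true_log_rate = np.log(reads_per_spot * profiles)
    rs = {}
    for c, t in enumerate(post.celltypes):
        rs[t] = float(np.corrcoef(beta_mean[:, c], true_log_rate[:, c])[0, 1])
    return RateRecoveryResult(pearson_r=rs, min_r=min(rs.values()))


def subsample_kld_experiment(
    seed: int,
    n_genes: int = 15,
    spots_per_array: int = 50,
    arrays_full: int = 4,
    arrays_sub: tuple = (1, 2),
) -> list:
    """Median posterior KLD of subsampled fits against the full-design fit.

    Simulates ``arrays_full`` arrays (stand-ins for animals), fits the model
    on the full set and on truncated subsets, approximates each beta
    posterior by a normal, and reports the median KLD(full || sub) per
    subset size.  More arrays should mean less information lost.
    """
    ref, de_truth = synth_reference(n_genes, 2, max(n_genes // 5, 1), seed=seed)
    profiles = ref.planted_mean / ref.planted_mean.sum(axis=0, keepdims=True)
    sim = simulate_cluster_spots(
        profiles,
        SimulationConfig(n_arrays=arrays_full, spots_per_array=spots_per_array,
                         reads_per_spot=1000, regions={"region0": [0, 1]}, seed=seed),
        gene_ids=list(ref.gene_ids), celltypes=[str(t) for t in ref.types], de_truth=de_truth,
    )
    data = sim.data

    def fit_first(n_arr):
        mask = np.isin(data.tissue_id, [f"array{j}" for j in range(n_arr)])
        sub = data.subset_spots(mask)
        return _fit_cluster_sim(sub, seed=seed)

    def summarize(post):
        mean = post.beta_mean("b1").reshape(len(post.genes), -1)
        sd = np.stack([gp.params["b1"].std(axis=(0, 1)) for gp in post.gene_posteriors])
        return mean, sd.reshape(len(post.genes), -1)

    full_mean, full_sd = summarize(fit_first(arrays_full))
    medians = []
    for n_arr in arrays_sub:
        sub_mean, sub_sd = summarize(fit_first(n_arr))
        klds = []
        for c in range(full_mean.shape[1]):
            klds.extend(
                posterior_kld(full_mean[:, c], full_sd[:, c], sub_mean[:, c], sub_sd[:, c]).table.kld
            )
        medians.append(float(np.median(klds)))
    return medians
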