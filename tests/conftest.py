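import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_reference():
    """Synthetic 2-type reference with planted marker blocks, seeded."""
    from stweave.simulate import synth_reference

    return synth_reference(n_genes=60, n_types=2, markers_per_type=10, seed=7)


@pytest.fixture
def flat_compositional_priors():
    """N(0, 2^2) priors for a 1-MROI, 2-type compositional model."""
    from stweave.reference import PriorMode, ReferencePriors

    def make(n_genes, gene_ids=None, celltypes=("type0", "type1"), mroi="region0"):
        shape = (n_genes, 1, len(celltypes))
        return ReferencePriors(
            mu=np.zeros(shape), sigma=np.full(shape, 2.0),
            gene_ids=list(gene_ids) if gene_ids is not None else [f"g{i:04d}" for i in range(n_genes)],
            mrois=[mroi], celltypes=list(celltypes), mode=PriorMode.compositional,
        )

    return make
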