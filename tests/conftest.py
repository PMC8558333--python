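import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_map():
    """A compact 3-chromosome frame for fast unit tests."""
    from ffnmap.simulate import build_genome_map

    return build_genome_map(3, 60_000_000, 1_000_000, seed=7)


@pytest.fixture(scope="session")
def f2_population(small_map):
    """A large F2 with the locus at the distal end of chr03."""
    from ffnmap.simulate import QtlModel, simulate_cross

    qtl = QtlModel(chromosome="chr03", position_bp=58_000_000)
    return qtl, simulate_cross(small_map, qtl, "F2", 10_000, seed=99)


def _null_mlm_replicate(rng, n=200, m=50):
    from ffnmap import association as assoc

    p = rng.uniform(0.05, 0.5, m)
    gmat = pd.DataFrame(
        rng.binomial(2, p, size=(n, m)), columns=[f"v{j}" for j in range(m)]
    )
    y = rng.normal(size=n)
    gmat = assoc.filter_maf(gmat)
    kin = assoc.kinship_matrix(gmat)
    return assoc.mlm_association(gmat, y, K=kin)["p_value"].to_numpy()


@pytest.fixture(scope="session")
def null_mlm_pvalues():
    """P-values from 1,000 null association replicates (n=200, 50 variants).

    Phenotypes are independent of the genotypes, kinship is estimated from
    the same 50 variants, as in a self-contained candidate-gene panel.
    """
    rng = np.random.default_rng(11)
    return [_null_mlm_replicate(rng) for _ in range(1000)]
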