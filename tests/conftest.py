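import numpy as np
import pandas as pd
import pytest

from exoburden import CausalGene, GenotypeMatrix, SimulationConfig, simulate_cohort


def make_genotypes(
    dosage,
    gq=None,
    dp=None,
    ab=None,
    chroms=None,
    is_male=None,
):
    """Small GenotypeMatrix builder with clean default metadata."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_s, n_v = dosage.shape
    if gq is None:
        gq = np.full((n_s, n_v), 60, dtype=np.int16)
    if dp is None:
        dp = np.full((n_s, n_v), 30, dtype=np.int16)
    if ab is None:
        ab = np.where(dosage == 2, 0.99, np.where(dosage == 1, 0.5, 0.01)).astype(
            np.float32
        )
    if chroms is None:
        chroms = ["1"] * n_v
    variants = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.arange(1, n_v + 1) * 100,
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeMatrix(
        dosage=dosage,
        gq=np.asarray(gq, dtype=np.int16),
        dp=np.asarray(dp, dtype=np.int16),
        ab=np.asarray(ab, dtype=np.float32),
        samples=np.array([f"S{i}" for i in range(n_s)]),
        is_male=np.zeros(n_s, dtype=bool) if is_male is None else np.asarray(is_male),
        variants=variants,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 2,000-sample cohort with one planted autosomal M3 effect."""
    cfg = SimulationConfig(
        n_samples=2000,
        n_genes=8,
        variants_per_gene=10,
        causal_genes=(CausalGene("GENE0002", 1.0, "M3"),),
        causal_carrier_freq=0.02,
        seed=7,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def x_cohort():
    """A cohort with an X-linked planted gene for hemizygote handling."""
    cfg = SimulationConfig(
        n_samples=3000,
        n_genes=6,
        variants_per_gene=10,
        causal_genes=(CausalGene("GENE0001", 1.66, "M3"),),
        causal_carrier_freq=0.02,
        x_linked_genes=("GENE0001",),
        seed=11,
    )
    return simulate_cohort(cfg)
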