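import numpy as np
import pandas as pd
import pytest

from bayesct.qc import MISSING, GenotypeMatrix
from bayesct.simulate import SimulationConfig, simulate_population

SMALL_GENOME = [("1", 40), ("2", 30), ("3", 20), ("X", 10)]


@pytest.fixture(scope="session")
def null_cohort():
    """No genetic signal: h2 = 0, no QTL."""
    config = SimulationConfig(
        n_sires=50,
        offspring_per_sire=4,
        n_snps=1_000,
        chromosomes=SMALL_GENOME,
        h2_liability=0.0,
        seed=42,
    )
    return simulate_population(config)


@pytest.fixture(scope="session")
def qtl_cohort():
    """One planted QTL window (1:10) with 10% of liability variance."""
    config = SimulationConfig(
        n_sires=80,
        offspring_per_sire=5,
        n_snps=2_000,
        chromosomes=SMALL_GENOME,
        qtl_spec=[("1", 10, 0.10)],
        h2_liability=0.24,
        seed=7,
    )
    return simulate_population(config)


def toy_genotypes(calls: np.ndarray) -> GenotypeMatrix:
    calls = np.asarray(calls, dtype=np.int8)
    return GenotypeMatrix(
        animal_ids=np.array([f"A{i}" for i in range(calls.shape[0])]),
        snp_ids=np.array([f"S{j}" for j in range(calls.shape[1])]),
        calls=calls,
    )


def toy_map(genotypes: GenotypeMatrix, chrom="1", spacing=100_000) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp": genotypes.snp_ids,
            "chrom": chrom,
            "pos": np.arange(1, genotypes.n_snps + 1) * spacing,
        }
    )
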