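import numpy as np
import pandas as pd
import pytest

from heatomics import (
    CountMatrix,
    ExpressionMatrix,
    SimulationConfig,
    simulate_counts,
    simulate_metabolites,
)


@pytest.fixture(scope="session")
def default_sim():
    """Default-scale simulated count matrix with planted classes."""
    config = SimulationConfig(rng_seed=11)
    cm, truth = simulate_counts(config)
    return config, cm, truth


@pytest.fixture(scope="session")
def strong_sim():
    """High-mean, low-dispersion simulation giving near-deterministic DE calls."""
    config = SimulationConfig(
        n_genes=1000,
        baseline_log_mean=6.9,
        baseline_log_sd=0.3,
        dispersion=0.01,
        effect_size_log2fc=3.0,
        planted={
            "common_up": 40,
            "common_down": 40,
            "unique_susceptible_up": 40,
            "unique_susceptible_down": 40,
        },
        rng_seed=5,
    )
    cm, truth = simulate_counts(config)
    return config, cm, truth


@pytest.fixture(scope="session")
def met_sim():
    """Simulated metabolite table with planted differential metabolites."""
    config = SimulationConfig(n_metabolites=300, rng_seed=21)
    mm, truth = simulate_metabolites(config)
    return config, mm, truth


def make_count_matrix(counts: np.ndarray, lengths=None, conditions=None) -> CountMatrix:
    """Hand-built CountMatrix over one genotype for unit tests."""
    n_genes, n_samples = counts.shape
    genes = [f"g{i}" for i in range(n_genes)]
    sample_ids = [f"s{j}" for j in range(n_samples)]
    if conditions is None:
        conditions = ["CK"] * (n_samples // 2) + ["HS"] * (n_samples - n_samples // 2)
    samples = pd.DataFrame(
        {
            "genotype": ["tolerant"] * n_samples,
            "condition": conditions,
            "replicate": list(range(1, n_samples + 1)),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    if lengths is None:
        lengths = np.full(n_genes, 1000)
    return CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=sample_ids),
        samples=samples,
        gene_lengths=pd.Series(lengths, index=genes),
    )


def make_expression(fpkm: np.ndarray, genotypes, conditions, replicates=None) -> ExpressionMatrix:
    """Hand-built ExpressionMatrix for screen/cluster/network unit tests."""
    n_genes, n_samples = fpkm.shape
    genes = [f"g{i}" for i in range(n_genes)]
    sample_ids = [f"s{j}" for j in range(n_samples)]
    if replicates is None:
        replicates = list(range(1, n_samples + 1))
    samples = pd.DataFrame(
        {"genotype": genotypes, "condition": conditions, "replicate": replicates},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ExpressionMatrix(
        fpkm=pd.DataFrame(fpkm, index=genes, columns=sample_ids), samples=samples
    )
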