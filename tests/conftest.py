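import numpy as np
import pandas as pd
import pytest

from semifieldgp import (
    GenotypeMatrix,
    SimulationConfig,
    build_layout,
    compute_grm,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def toy_layout():
    """1 bed, 1 unit, 30 real rows, padded for both structures."""
    return build_layout(beds=1, units_per_bed=1, rows_per_unit=30,
                        k_neighbors=5, d_max=2.75)


@pytest.fixture(scope="session")
def toy_geno():
    rng = np.random.default_rng(11)
    p = rng.uniform(0.1, 0.5, 80)
    dosage = 2.0 * (rng.random((12, 80)) < p)
    return GenotypeMatrix(
        pd.DataFrame(dosage,
                     index=[f"L{i:02d}" for i in range(12)],
                     columns=[f"S{j:03d}" for j in range(80)])
    )


@pytest.fixture(scope="session")
def toy_grm(toy_geno):
    return compute_grm(toy_geno)


@pytest.fixture(scope="session")
def small_experiment():
    """A small but complete synthetic experiment (fast to fit)."""
    cfg = SimulationConfig(seed=42, n_lines=30, n_snps=600,
                           rows_per_unit=40, units_per_bed=2, beds=2)
    return simulate_experiment(cfg)
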