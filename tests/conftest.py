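import numpy as np
import pandas as pd
import pytest

import panelpop as pp


@pytest.fixture(scope="session")
def small_panel() -> pp.GenotypeMatrix:
    """Three differentiated subpopulations, two subgenomes, 30% dropout."""
    cfg = pp.SimulationConfig(
        subpop_sizes={"WE": 60, "WA": 50, "SP": 50},
        n_snps={"A": 600, "C": 900},
        target_fst=0.2,
        f_is=0.8,
        call_rate=0.7,
        seed=42,
    )
    return pp.simulate_genotypes(cfg)


@pytest.fixture(scope="session")
def complete_panel() -> pp.GenotypeMatrix:
    """Fully observed panel (no missingness) for PCA/oracle comparisons."""
    cfg = pp.SimulationConfig(
        subpop_sizes={"WE": 50, "WA": 40, "SP": 40},
        n_snps={"A": 500, "C": 700},
        target_fst=0.2,
        f_is=0.8,
        call_rate=1.0,
        seed=7,
    )
    return pp.simulate_genotypes(cfg)


def make_matrix(dosages, chroms=None, positions=None, subpops=None) -> pp.GenotypeMatrix:
    """Hand-build a GenotypeMatrix from a dosage array."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, s = dosages.shape
    if chroms is None:
        chroms = ["A01"] * s
    if positions is None:
        positions = np.arange(1, s + 1) * 1000
    if subpops is None:
        subpops = ["P1"] * n
    snps = pd.DataFrame(
        {"chrom": chroms, "pos": positions},
        index=[f"{c}_{p}" for c, p in zip(chroms, positions)],
    )
    samples = pd.DataFrame(
        {"subpop": subpops}, index=[f"s{i}" for i in range(n)]
    )
    return pp.GenotypeMatrix(dosages, samples, snps, validate=False)
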