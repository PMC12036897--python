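import numpy as np
import pandas as pd
import pytest

from coinv import CrossConfig, GenotypeMatrix, simulate_f2_cross


@pytest.fixture
def toy_matrix() -> GenotypeMatrix:
    """Four individuals, three loci; locus C is monomorphic RR."""
    data = pd.DataFrame(
        {
            "Inv_A": ["RR", "RI", "II", "RI"],
            "Inv_B": ["RI", "RR", "RI", "II"],
            "Inv_C": ["RR", "RR", "RR", "RR"],
        },
        index=["p1", "p2", "p3", "p4"],
        dtype=object,
    )
    return GenotypeMatrix(data, cross_id="toy")


@pytest.fixture
def toy_meta() -> pd.Series:
    return pd.Series(
        {"Inv_A": "chr1", "Inv_B": "chr2", "Inv_C": "chr3"}, name="chromosome"
    )


@pytest.fixture(scope="session")
def mendelian_cross() -> GenotypeMatrix:
    """A large cross with no selection (pure 1:2:1 segregation)."""
    loci = [(f"Inv_{i + 1}", f"chr{i % 8 + 1}", True) for i in range(12)]
    cfg = CrossConfig(cross_id="null", n_individuals=400, loci=loci, seed=11)
    m, _ = simulate_f2_cross(cfg)
    return m


@pytest.fixture(scope="session")
def repulsion_cross() -> GenotypeMatrix:
    """Two unlinked loci with a planted (II, II) incompatibility (s = 0.2)."""
    loci = [("Inv_1", "chr1", True), ("Inv_2", "chr2", True)]
    s = [1.0] * 9
    s[8] = 0.2
    cfg = CrossConfig(
        cross_id="rep",
        n_individuals=400,
        loci=loci,
        pair_survival={("Inv_1", "Inv_2"): tuple(s)},
        seed=7,
    )
    m, _ = simulate_f2_cross(cfg)
    return m
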