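import numpy as np
import pandas as pd
import pytest

import sbayesr as sb


@pytest.fixture(scope="session")
def small_panel():
    """A 300 x 60 blockwise-LD panel (3 blocks of 20 SNPs, rho = 0.8)."""
    return sb.simulate_genotypes(n=300, p=60, block_size=20, rho=0.8, seed=42)


@pytest.fixture(scope="session")
def small_trait(small_panel):
    """Sparse trait on the small panel: 6 causal SNPs, h2 = 0.5."""
    arch = sb.ArchitectureSpec(mode="bayesr-mixture", counts=(2, 2, 2),
                               weights=(0.01, 0.1, 1.0))
    beta, causal, labels = sb.simulate_effects(small_panel.p, arch, seed=43)
    y = sb.simulate_phenotype(small_panel, beta, 0.5, seed=44)
    return {"beta": beta, "causal": causal, "labels": labels, "y": y}


@pytest.fixture()
def toy_sumstats():
    """Hand-built summary dataset with known values."""
    df = pd.DataFrame(
        {
            "snp_id": ["rs1", "rs2", "rs3", "rs4"],
            "A1": ["A", "G", "C", "A"],
            "A2": ["G", "A", "T", "T"],
            "freq": [0.3, 0.5, 0.12, 0.4],
            "b": [0.1, -0.05, 0.0, 0.02],
            "se": [0.05, 0.04, 0.05, 0.03],
            "p": [0.04, 0.2, 1.0, 0.5],
            "n": [1000.0, 1000.0, 1000.0, 1000.0],
        }
    )
    return sb.SummaryDataset(df)


def make_sumstats(n_snps, rng):
    """Random but valid summary records for property-style tests."""
    bases = np.array(["A", "C", "G", "T"])
    a1 = rng.choice(bases, n_snps)
    a2 = np.array([rng.choice([b for b in bases if b != x]) for x in a1])
    df = pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(n_snps)],
            "A1": a1,
            "A2": a2,
            "freq": rng.uniform(0.01, 0.99, n_snps),
            "b": rng.normal(0, 0.05, n_snps),
            "se": rng.uniform(0.01, 0.1, n_snps),
            "p": rng.uniform(1e-8, 1.0, n_snps),
            "n": rng.integers(500, 1500, n_snps).astype(float),
        }
    )
    return sb.SummaryDataset(df)
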