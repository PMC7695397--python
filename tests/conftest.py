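import numpy as np
import pytest

import mrkit


@pytest.fixture(scope="session")
def toy_dataset():
    """Deterministic 20-SNP, 3-exposure fixture with theta=(0.5, -0.2, 0)."""
    return mrkit.make_toy_fixture()


@pytest.fixture(scope="session")
def toy_univariable(toy_dataset):
    """Harmonized single-exposure view of the toy fixture (exposure 1)."""
    exposures, outcome, truth = toy_dataset
    ds = mrkit.harmonize(exposures[0], outcome)
    return ds, truth


def random_table(rng: np.random.Generator, n: int = 10, trait_id: str = "trait",
                 with_missing: bool = False) -> mrkit.SummaryStatsTable:
    """A valid random summary-statistics table for property tests."""
    pairs = [("A", "G"), ("T", "C"), ("A", "T"), ("C", "G"), ("G", "A"), ("C", "T")]
    records = []
    for j in range(n):
        ea, oa = pairs[rng.integers(len(pairs))]
        beta = float(rng.normal(0, 0.1))
        se = float(rng.uniform(0.005, 0.05))
        records.append(
            mrkit.GwasRecord(
                snp_id=f"rs{j}",
                effect_allele=ea,
                other_allele=oa,
                beta=beta,
                se=se,
                pval=float(min(1.0, max(1e-300, 2 * np.exp(-abs(beta) / se)))),
                eaf=None if (with_missing and rng.random() < 0.2)
                else float(rng.uniform(0.05, 0.95)),
                n=None if (with_missing and rng.random() < 0.2)
                else int(rng.integers(1000, 500000)),
            )
        )
    return mrkit.SummaryStatsTable(trait_id, "continuous", records)
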