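import numpy as np
import pytest

from cowas import (
    GenotypePanel,
    PairSpec,
    SimConfig,
    TrainConfig,
    VariantInfo,
    simulate_dataset,
)
from cowas.preprocess import adjust_pair, map_pqtls


def make_panel(dosages, ids=None, chrom="1", pos_start=100, samples=None):
    """Small hand-built genotype panel for unit tests."""
    dosages = np.asarray(dosages, dtype=float)
    n, p = dosages.shape
    ids = ids or [f"rs{j}" for j in range(p)]
    pairs = [("A", "G"), ("T", "C"), ("A", "C"), ("T", "G")]
    variants = [
        VariantInfo(ids[j], chrom, pos_start + j * 10, *pairs[j % 4]) for j in range(p)
    ]
    samples = samples or [f"s{i}" for i in range(n)]
    return GenotypePanel(samples, variants, dosages)


@pytest.fixture(scope="session")
def small_dataset():
    """One simulated pair at modest size, shared across read-only tests."""
    return simulate_dataset(SimConfig(n1=600, n2=2000, seed=11))


@pytest.fixture(scope="session")
def trained_pair(small_dataset):
    """Adjusted expression, pQTL scans, and a trained WeightSet for the pair."""
    from cowas.train import train_and_evaluate_pair

    ds = small_dataset
    a, b, subset = adjust_pair(ds.expression, ds.covariates, ds.pair)
    panel = ds.panel1.subset(samples=subset)
    qtl_a = map_pqtls(panel, a, ds.pair.protein_a)
    qtl_b = map_pqtls(panel, b, ds.pair.protein_b)
    ws = train_and_evaluate_pair(panel, ds.pair, a, b, qtl_a, qtl_b, TrainConfig(seed=5))
    return ds, panel, a, b, qtl_a, qtl_b, ws
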