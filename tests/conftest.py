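import numpy as np
import pandas as pd
import pytest

import spongelnc as sl


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic two-species bundle, fixed seed."""
    return sl.simulate_bundle(sl.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def normalized_celltype(bundle):
    matrix = sl.filter_samples(bundle.counts_celltype_a, bundle.meta_celltype_a)
    return sl.normalize_median_of_ratios(matrix)


@pytest.fixture(scope="session")
def published_example():
    return sl.load_published_example()


@pytest.fixture
def tiny_matrix():
    """3 genes x 3 samples with column j = 2 x column i structure."""
    counts = pd.DataFrame(
        [[10, 20, 10], [20, 40, 20], [30, 60, 30]],
        index=["g1", "g2", "g3"], columns=["s1", "s2", "s3"])
    biotype = pd.Series(["coding", "coding", "lncRNA"], index=counts.index)
    return sl.ExpressionMatrix(counts, biotype)


def make_matrix(counts, genes=None, samples=None, biotype=None):
    genes = genes or [f"g{i}" for i in range(len(counts))]
    samples = samples or [f"s{j}" for j in range(len(counts[0]))]
    df = pd.DataFrame(counts, index=genes, columns=samples)
    bt = pd.Series(biotype or ["coding"] * len(genes), index=genes)
    return sl.ExpressionMatrix(df, bt)


def make_meta(samples, groups, total_reads=None):
    total = total_reads if total_reads is not None else [2_000_000] * len(samples)
    return pd.DataFrame({"group": groups, "total_reads": total},
                        index=pd.Index(samples, name="sample"))
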