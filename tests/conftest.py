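import numpy as np
import pandas as pd
import pytest

import sfrgsn as sf


@pytest.fixture
def tiny_matrix():
    """2 genes x 2 samples with known values."""
    data = pd.DataFrame([[10.0, 0.0], [5.0, 7.0]],
                        index=["gA", "gB"], columns=["s1", "s2"])
    return sf.ExpressionMatrix(data)


@pytest.fixture
def small_dataset():
    """Small synthetic world with two disease groups and one planted edge each."""
    spec = sf.SimulationSpec(
        n_genes=30,
        groups=[("Normal", 15), ("A", 15), ("B", 15)],
        planted_edges=[(("g00", "g01"), "A", 0.8), (("g02", "g03"), "B", 0.8)],
        base_corr=0.1,
        ppi_density=0.08,
        seed=7,
    )
    return sf.generate_dataset(spec)


@pytest.fixture
def reference_world():
    """A matrix + labels + reference network over a handful of PPI pairs."""
    rng = np.random.default_rng(11)
    genes = [f"g{k}" for k in range(10)]
    samples = [f"n{k}" for k in range(8)] + [f"d{k}" for k in range(4)]
    data = pd.DataFrame(rng.normal(size=(10, 12)), index=genes, columns=samples)
    m = sf.ExpressionMatrix(data, unit="normalized")
    labels = sf.GroupLabels(
        {s: ("Normal" if s.startswith("n") else "D") for s in samples}, "Normal")
    pairs = {(genes[i], genes[j]) for i in range(10) for j in range(i + 1, 10)}
    ref = sf.build_reference_network(m, labels, pairs)
    return m, labels, ref
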