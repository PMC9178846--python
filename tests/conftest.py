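import numpy as np
import pandas as pd
import pytest

import heterosiskit as hk


@pytest.fixture(scope="session")
def small_triplet():
    """A 300-gene single-timepoint triplet simulation with planted truth."""
    cfg = hk.SimulationConfig(n_genes=300, timepoints=("T1",), seed=1)
    counts, sheet, truth = hk.simulate_triplet_counts(cfg)
    return counts, sheet, truth


@pytest.fixture(scope="session")
def strong_signal_run():
    """Strong-signal simulation pushed through DE + classification.

    5,000 genes, 5 replicates, 4-fold effects, dispersion 0.01, per-sample
    depth ~1e6 (5,000 genes x baseline mean 200).
    """
    cfg = hk.SimulationConfig(
        n_genes=5000,
        n_replicates=5,
        dispersion=0.01,
        baseline_mean=200.0,
        effect_fold=4.0,
        timepoints=("T1",),
        seed=7,
    )
    counts, sheet, truth = hk.simulate_triplet_counts(cfg)
    results = hk.run_cross_contrasts(counts, sheet, "SIM", "T1")
    calls = hk.encode_calls(results["HvsF"], results["HvsM"], results["FvsM"])
    assignments = hk.classify_table(calls)
    return counts, sheet, truth, results, assignments


def planted_block_expression(
    block_sizes=(50, 50), n_samples=20, within_cor=0.9, seed=0
):
    """Samples x genes matrix of correlated gene blocks (factor model)."""
    rng = np.random.default_rng(seed)
    w = np.sqrt(within_cor)
    blocks, labels = [], []
    for b, size in enumerate(block_sizes):
        f = rng.standard_normal(n_samples)
        blocks.append(
            w * f[:, None] + np.sqrt(1 - w**2) * rng.standard_normal((n_samples, size))
        )
        labels += [b] * size
    X = np.concatenate(blocks, axis=1)
    genes = [f"g{i:04d}" for i in range(X.shape[1])]
    return pd.DataFrame(X, columns=genes), np.array(labels)
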