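import numpy as np
import pytest

from gdesce import RunConfig, SyntheticConfig, generate, run_pipeline


@pytest.fixture
def tiny_counts():
    """3 cells x 2 genes with batch and truth labels."""
    from gdesce import CountMatrix

    return CountMatrix(
        np.array([[1, 3], [2, 0], [5, 4]]),
        cell_ids=["c1", "c2", "c3"],
        gene_ids=["g1", "g2"],
        batch=np.array(["a", "a", "b"]),
        truth=np.array(["t1", "t2", "t1"]),
    )


@pytest.fixture(scope="session")
def recovery_runs():
    """Full-pipeline runs on the default synthetic data, seeds 0-4.

    Shared between the parameter-recovery, batch-mixing and
    entropy-sharpening checks so the expensive runs happen once.
    """
    runs = []
    for seed in range(5):
        counts, _ = generate(SyntheticConfig(seed=seed))
        runs.append(run_pipeline(counts, RunConfig(seed=seed)))
    return runs
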