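import numpy as np
import pandas as pd
import pytest

from mir200sig import (
    AnalysisConfig,
    ExpressionMatrix,
    SampleAnnotations,
    SimulationParams,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_params():
    """Down-scaled cohort: fast but preserving the default structure."""
    return SimulationParams(
        n_samples=60, n_genes=600, n_program_genes=120, n_secondary_genes=40,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_params):
    return simulate_cohort(small_params)


@pytest.fixture(scope="session")
def noise_free_cohort():
    """No expression/anchor noise, no secondary program: exact convex mixtures."""
    return simulate_cohort(
        SimulationParams(
            n_samples=40, n_genes=400, n_program_genes=100, n_secondary_genes=0,
            noise_sd=0.0, anchor_noise_sd=0.0, seed=11,
        )
    )


@pytest.fixture(scope="session")
def scaled_config():
    """AnalysisConfig scaled to the small synthetic cohorts."""
    return AnalysisConfig(
        n_extreme=10, n_de_genes=200, n_variable_genes=200, n_centroid_genes=80,
        seed=7, gsea_permutations=200,
    )


@pytest.fixture()
def tiny_matrix():
    """3 genes x 4 samples, handy for exact arithmetic checks."""
    df = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [5.0, 5.0, 5.0, 5.0]],
        index=["GA", "GB", "GC"],
        columns=["S1", "S2", "S3", "S4"],
    )
    return ExpressionMatrix(df, "logCPM")


def make_annotations(n, anchor=None, seed=0, **extra):
    """Minimal valid annotation table for n samples."""
    rng = np.random.default_rng(seed)
    ids = [f"S{i + 1:03d}" for i in range(n)]
    df = pd.DataFrame(
        {
            "anchor_value": anchor if anchor is not None else rng.uniform(0, 1, n),
            "dfs_time": rng.uniform(1, 60, n),
            "dfs_event": rng.integers(0, 2, n),
        },
        index=pd.Index(ids, name="sample_id"),
    )
    for k, v in extra.items():
        df[k] = v
    return SampleAnnotations(df)
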