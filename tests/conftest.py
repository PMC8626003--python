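import numpy as np
import pandas as pd
import pytest

from tximage import ExpressionMatrix, SyntheticSpec, generate_dataset


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """2 genes x 3 samples with simple integer counts."""
    return ExpressionMatrix(["gA", "gB"], ["s1", "s2", "s3"], [[1, 2, 3], [4, 5, 6]])


@pytest.fixture
def toy_annotation() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chromosome": ["1", "22", "X", "MT"],
            "biotype": ["protein_coding", "lincRNA", "protein_coding", "pseudogene"],
            "excluded": [False, False, False, False],
        },
        index=pd.Index(["gA", "gB", "gC", "gD"], name="gene_id"),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Fast continuous-valued cohort for pipeline-level tests (no count noise)."""
    spec = SyntheticSpec(
        n_case=40, n_control=12, n_genes=60, n_signal_genes=6, n_modules=2,
        frac_low_count=0.1, frac_non_autosomal=0.1, frac_non_coding=0.1,
        mode="gaussian", seed=11,
    )
    return generate_dataset(spec)


def random_expression(n_genes: int, n_samples: int, seed: int) -> ExpressionMatrix:
    rng = np.random.default_rng(seed)
    vals = rng.gamma(2.0, 20.0, size=(n_genes, n_samples))
    return ExpressionMatrix(
        [f"g{i}" for i in range(n_genes)], [f"s{j}" for j in range(n_samples)], vals
    )
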