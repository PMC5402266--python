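import numpy as np
import pandas as pd
import pytest

from tsnetwork.synthdata import (
    ExpressionGenConfig,
    VariantGenConfig,
    generate_expression,
    write_fixture_bundle,
)


@pytest.fixture()
def toy_expression() -> pd.DataFrame:
    """3 genes x 4 samples, two tissues with two replicates each."""
    return pd.DataFrame(
        {
            "heart_r1": [10.0, 1.0, 4.0],
            "heart_r2": [12.0, 1.0, 4.0],
            "brain_r1": [1.0, 9.0, 4.0],
            "brain_r2": [3.0, 11.0, 4.0],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )


@pytest.fixture()
def toy_samples() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": ["heart_r1", "heart_r2", "brain_r1", "brain_r2"],
            "tissue": ["heart", "heart", "brain", "brain"],
        }
    )


@pytest.fixture(scope="session")
def small_bundle_config() -> ExpressionGenConfig:
    """Down-scaled bundle: fast, still 4 planted modules in 10 target tissues."""
    return ExpressionGenConfig(
        module_sizes=(30, 10, 8, 6),
        n_background_genes=400,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_bundle_config):
    matrix, annotation, manifest = generate_expression(small_bundle_config)
    return matrix, annotation, manifest


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory, small_bundle_config):
    outdir = tmp_path_factory.mktemp("bundle")
    paths = write_fixture_bundle(
        outdir, small_bundle_config, VariantGenConfig(seed=11)
    )
    return paths


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
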