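import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from glycoindex.io import ExpressionDataset
from glycoindex.simulate import SimulationConfig, generate_expression_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_dataset(values, genes=None, samples=None, groups=None, regions=None,
                 ages=None, sexes=None, dataset_id="test"):
    """Build a small ExpressionDataset from an array and optional metadata."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes or [f"G{i:03d}" for i in range(n_genes)]
    samples = samples or [f"s{i:03d}" for i in range(n_samples)]
    groups = groups or ["control"] * (n_samples // 2) + ["case"] * (n_samples - n_samples // 2)
    regions = regions or ["FC"] * n_samples
    ages = ages if ages is not None else np.linspace(60, 90, n_samples)
    sexes = sexes or [("F" if i % 2 == 0 else "M") for i in range(n_samples)]
    meta = pd.DataFrame(
        {"group": groups, "region": regions, "age": ages, "sex": sexes},
        index=pd.Index(samples, name="sample_id"),
    )
    return ExpressionDataset(
        dataset_id=dataset_id,
        values=pd.DataFrame(values, index=genes, columns=samples),
        metadata=meta,
    )


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_genes=300, n_per_group=12, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_expression_dataset(small_config, "FC")


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The default fixture bundle (full study conditions), built once."""
    from glycoindex.simulate import make_fixture_bundle

    out = tmp_path_factory.mktemp("bundle")
    cfg = SimulationConfig(seed=11)
    paths = make_fixture_bundle(cfg, out)
    return cfg, paths
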