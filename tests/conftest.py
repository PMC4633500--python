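import numpy as np
import pytest

from palmirna.pipeline import PipelineConfig, make_fixtures, run_pipeline
from palmirna.published import REFERENCE_MATURE_MIRNAS

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def reference_set() -> dict[str, str]:
    return dict(REFERENCE_MATURE_MIRNAS)


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """Default synthetic bundle: genome with 10 planted MIR loci, 5 ncRNA
    loci, four libraries of unequal depth, planted fold changes."""
    root = tmp_path_factory.mktemp("bundle")
    config_path, genome, truth = make_fixtures(root, seed=FIXTURE_SEED)
    return config_path, genome, truth


@pytest.fixture(scope="session")
def pipeline_result(fixture_bundle):
    config_path, genome, truth = fixture_bundle
    config = PipelineConfig.from_yaml(config_path)
    result = run_pipeline(config)
    return config, genome, truth, result


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
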