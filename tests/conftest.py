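import numpy as np
import pytest

from laryngofuse.synthetic import DatasetManifest, GeneratorConfig, generate_dataset


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory) -> tuple[GeneratorConfig, DatasetManifest]:
    """Small materialized dataset shared by I/O-level tests."""
    cfg = GeneratorConfig(patch_side=32, per_class_count=6, noise_fraction=0.05, seed=7)
    out = tmp_path_factory.mktemp("tiny_data")
    manifest = generate_dataset(cfg, out)
    return cfg, manifest
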