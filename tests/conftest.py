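import pytest

from graintrn.simulate import SimConfig, simulate_all, write_dataset


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(n_triads=30, n_tfs=8, targets_per_tf=6, n_causal_tfs=3,
                     n_accessions=60, seed=11)


@pytest.fixture(scope="session")
def small_ds(small_cfg):
    return simulate_all(small_cfg)


@pytest.fixture(scope="session")
def dataset_dir(small_ds, tmp_path_factory):
    return write_dataset(small_ds, tmp_path_factory.mktemp("dataset"))
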