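import pytest

from tfcoop import SyntheticConfig, generate, score_files


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """The default synthetic dataset: 20 TFs, 3 planted pairs, seed 1."""
    return generate(SyntheticConfig(seed=1), tmp_path_factory.mktemp("synth-default"))


@pytest.fixture(scope="session")
def default_results(default_dataset):
    cfg = default_dataset.config
    return score_files(
        default_dataset.regulation_path,
        default_dataset.tfbs_path,
        default_dataset.nucleosome_path,
        total_genes=cfg.n_genes,
    )
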