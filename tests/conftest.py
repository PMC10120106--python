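import pytest

from endopan.simulate import SimConfig


@pytest.fixture
def small_config():
    """Desk-scale configuration keeping every simulator fast in tests."""
    return SimConfig(
        seed=11,
        n_taxa_pool=80,
        depth_per_sample=4000,
        n_clusters=300,
        n_go_genes=400,
        study_size=60,
        n_gene_trees=60,
        n_scaffolds_per_sample=30,
    )
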