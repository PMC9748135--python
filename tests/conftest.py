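import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_fit():
    """A small trained pipeline shared by marker / downstream tests."""
    from multidec import SimConfig, TrainConfig, fit, simulate

    out = simulate(SimConfig(n_cells=300, n_groups=4, n_genes=150,
                             n_second_features=15, marker_genes_per_group=10,
                             de_fraction=0.1, seed=42))
    tc = TrainConfig(K=4, pretrain_epochs=40, pretrain_recon_only_epochs=20,
                     max_cluster_epochs=15, seed=42)
    fr = fit(out.dataset, k=4, data_type="cite", train_config=tc,
             n_hvg=None, seed=42)
    return out, fr
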