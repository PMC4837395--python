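import pytest

from chemosig.simulate import SimulationConfig, simulate_dataset


def small_config(**overrides) -> SimulationConfig:
    """A scaled-down simulated study that keeps the default effect sizes."""
    base = dict(
        n_genes=40,
        n_mirnas=12,
        cpgs_min=8,
        cpgs_max=16,
        n_double=5,
        n_bg_de_genes=5,
        n_regulator_mirnas=6,
        n_bg_de_mirnas=2,
        n_meth_mirnas=3,
        n_neutral_true_pairs=10,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_ds():
    return simulate_dataset(small_config(), seed=7)
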