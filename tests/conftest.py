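import numpy as np
import pytest

from twinmethyl.synthetic_data import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def tiny_study():
    """Small but complete synthetic study shared by read-only tests."""
    cfg = SimulationConfig(
        n_pairs_per_sex=6,
        n_chromosomes=2,
        chrom_length_bp=200_000,
        n_planted_dmrs=5,
        dmr_span_windows=(1, 3),
        n_latent_modules=2,
        module_size_windows=20,
        n_genes=40,
        fraction_discordant_pa=1.0,
        fraction_discordant_walkability=0.5,
        fraction_discordant_bmi=0.5,
        seed=123,
    )
    return simulate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
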