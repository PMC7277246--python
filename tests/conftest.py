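import numpy as np
import pytest

from viscomp.design import DesignSpec, generate_design
from viscomp.rating import RatingConfig, rate_comparisons
from viscomp.simulate import ObserverModel, sample_latent, simulate_comparisons


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def run_recovery_study(
    n_items: int,
    comparisons_per_item: int,
    noise_sd: float,
    seed: int,
    lapse_rate: float = 0.0,
    score_sd: float = 5.5,
):
    """Latent world -> simulated comparisons -> rated table; returns all three."""
    world = sample_latent(n_items, 25.0, score_sd, seed=seed)
    spec = DesignSpec(
        n_items=n_items,
        n_comparisons=comparisons_per_item * n_items // 2,
        n_observers=5,
        seed=seed + 1,
        item_ids=world.items(),
    )
    records = simulate_comparisons(
        world, spec, ObserverModel(noise_sd=noise_sd, lapse_rate=lapse_rate), seed=seed + 2
    )
    table = rate_comparisons(records, RatingConfig(shuffle_seed=seed + 3))
    return world, records, table
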