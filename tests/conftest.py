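import numpy as np
import pytest

from promcat import (
    CatConfig,
    ItemBank,
    ItemParameters,
    SimulationSpec,
    calibrate_score_anchors,
    generate_bank,
    simulate_responses,
)


@pytest.fixture
def dich_item():
    return ItemParameters("d1", (0.0,))


@pytest.fixture
def cat_config():
    return CatConfig()


@pytest.fixture
def small_bank():
    """Anchored 4-item bank with mixed category counts."""
    items = (
        ItemParameters("a", (-1.0, 0.0, 1.0)),
        ItemParameters("b", (0.5,)),
        ItemParameters("c", (-0.5, 0.5)),
        ItemParameters("d", (-1.5, -0.5, 0.5, 1.5)),
    )
    return calibrate_score_anchors(ItemBank("demo", items))


def random_item(rng, item_id="x", max_steps=4):
    m = int(rng.integers(1, max_steps + 1))
    return ItemParameters(item_id, tuple(np.sort(rng.normal(0.0, 1.2, size=m))))


def random_bank(rng, n_items=5, scale_id="rand"):
    items = tuple(random_item(rng, f"{scale_id}_{k}") for k in range(n_items))
    return ItemBank(scale_id, items)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def face_sim():
    """One simulated 9-item scale (complete, n=200) shared across tests."""
    spec = SimulationSpec(n_persons=200, seed=99)
    bank = calibrate_score_anchors(generate_bank(spec, 0))
    responses, truth = simulate_responses(bank, spec, 0)
    return bank, responses, truth
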