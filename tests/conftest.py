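import numpy as np
import pytest

from culturesim.state import CONFORMITY, EMPTY_CULTURE, PopulationState


def make_state(culture, alive=None, preference=None, next_culture_id=None, timestep=0):
    """Build a PopulationState from nested lists; -1 entries are empty sites."""
    culture = np.asarray(culture, dtype=np.int64)
    if alive is None:
        alive = culture != EMPTY_CULTURE
    else:
        alive = np.asarray(alive, dtype=bool)
    if preference is None:
        preference = np.full(culture.shape, CONFORMITY, dtype=np.int8)
    else:
        preference = np.asarray(preference, dtype=np.int8)
    if next_culture_id is None:
        next_culture_id = int(culture.max()) + 1 if (culture != EMPTY_CULTURE).any() else 0
    return PopulationState(
        alive=alive,
        culture=culture,
        preference=preference,
        next_culture_id=next_culture_id,
        timestep=timestep,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
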