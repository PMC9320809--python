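import pytest

from courtship_select import default_config, simulate_panel
from courtship_select.io import EthogramTrial


@pytest.fixture
def trial_factory():
    def make(states, trial_id="T1", male="A", female="X", interval=10.0):
        return EthogramTrial(
            trial_id=trial_id,
            states=list(states),
            male_strain=male,
            female_strain=female,
            interval_s=interval,
        )

    return make


@pytest.fixture(scope="session")
def small_panel():
    """A 6-strain × 2-context panel, 4 trials per pair, fixed seed."""
    cfg = default_config(seed=11, n_strains=6, trials_per_pair=4)
    return simulate_panel(cfg)
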