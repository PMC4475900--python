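import numpy as np
import pytest

from jpca.simulate import (
    default_rotational_spec,
    generate_latents,
    render_population,
    make_rotational_trialset,
    make_expansion_trialset,
)


@pytest.fixture(scope="session")
def rotational_latents():
    """Noiseless two-plane (2.5 Hz, 1 Hz) latent trajectories, 8 conditions."""
    spec = default_rotational_spec(seed=5)
    return generate_latents(spec, 8)


@pytest.fixture(scope="session")
def rotational_trials():
    """Study-conditions rotational TrialSet (8 cond, 40 electrodes, 100 trials)."""
    return make_rotational_trialset(seed=3)


@pytest.fixture(scope="session")
def expansion_trials():
    """Matched non-rotational (pure expansion/contraction) TrialSet."""
    return make_expansion_trialset(seed=3)


@pytest.fixture(scope="session")
def small_trials():
    """A fast, small TrialSet for plumbing tests."""
    spec = default_rotational_spec(seed=9)
    latents = generate_latents(spec, 4)
    return render_population(
        latents, n_electrodes=12, baseline_hz=20.0, gain_hz=10.0,
        trials_per_condition=15, pre_epoch_ms=100.0, seed=10,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
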