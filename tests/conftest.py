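import numpy as np
import pytest

from stndecide.ddm.params import DDMEffect, DDMParams
from stndecide.synth import generate_recording_dataset, simulate_ddm_trials


@pytest.fixture(scope="session")
def true_params():
    """Base decision-model parameters used across recovery harnesses."""
    return DDMParams(
        a=1.1, b_collapse=1.5, b_t=0.35, k=6.0, me=0.0, z=0.0,
        t0_contra=0.32, t0_ipsi=0.30,
    )


@pytest.fixture(scope="session")
def dk_effect(true_params):
    """Pure drift-scale stimulation effect, |d_k| = 0.5 k."""
    return DDMEffect(d_k=-0.5 * true_params.k)


@pytest.fixture(scope="session")
def small_session(true_params):
    """600-trial null session (30 per signed-coherence x stimulation cell)."""
    return simulate_ddm_trials(true_params, None, n_per_cond=30, seed=101)


@pytest.fixture(scope="session")
def small_effect_session(true_params, dk_effect):
    return simulate_ddm_trials(true_params, dk_effect, n_per_cond=30, seed=102)


@pytest.fixture(scope="session")
def small_recording():
    """15 neurons per cluster with the generator's default conditions."""
    spikes, trials, templates = generate_recording_dataset(15, seed=42)
    return spikes, trials, templates


@pytest.fixture(scope="session")
def recording_vectors(small_recording):
    from stndecide.cluster import build_activity_vectors
    from stndecide.cluster.vectors import vector_matrix

    spikes, trials, templates = small_recording
    vec = build_activity_vectors(spikes, trials)
    truth = {t.neuron_id: t.true_cluster for t in templates}
    y = np.array([truth[n] for n in vec.index])
    return vector_matrix(vec), y, vec
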