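import numpy as np
import pytest

from isfcnet import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_config():
    """Tiny two-group design with one planted edge difference."""
    mixing = sim.planted_pair_mixing(6, 3, r_a=0.7, r_b=0.2)
    return sim.SimConfig(
        n_subjects_per_group=4,
        n_nodes=6,
        n_timepoints=120,
        n_conditions=3,
        n_block_reps=5,
        stim_mixing={"control": mixing["a"], "cp": mixing["b"]},
        seed=11,
    )


@pytest.fixture
def quiet_artifacts():
    return sim.ArtifactParams(drift_amp=0.0, spike_rate=0.0, osc_amp=0.0)


def brute_force_isfc(data, symmetrize=True):
    """Independent double-loop leave-one-out ISFC oracle (z-values)."""
    S, N, T = data.shape
    clip = 1.0 - 1e-7
    out = np.empty((S, N, N))
    for s in range(S):
        others = np.mean([data[q] for q in range(S) if q != s], axis=0)
        for i in range(N):
            for j in range(N):
                r = np.corrcoef(data[s, i], others[j])[0, 1]
                out[s, i, j] = np.arctanh(np.clip(r, -clip, clip))
        if symmetrize:
            out[s] = 0.5 * (out[s] + out[s].T)
    return out
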