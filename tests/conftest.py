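import numpy as np
import pytest

import cycleseg as cs


@pytest.fixture(scope="session")
def templates():
    return cs.make_default_templates(seed=0)


@pytest.fixture(scope="session")
def clean_walk():
    """Five identical 1 s walk cycles at 200 Hz, no jitter, no noise."""
    tpl = cs.make_default_templates(seed=0)
    spec = cs.SequenceSpec(
        segments=[cs.SegmentSpec("walk", n_cycles=5, cycle_duration_s=1.0)]
    )
    rec, truth = cs.gen_recording(
        spec, tpl, sampling_rate=200.0, seed=0, subject_id="clean"
    )
    return rec, truth


@pytest.fixture(scope="session")
def small_pool():
    """Two lightly jittered subjects with walk and run bouts plus rest."""
    recs, truths = cs.gen_subject_pool(
        2, walk_cycles=8, run_cycles=8, rest_s=2.0, seed=42
    )
    return recs, truths


def random_circular_hmm(rng, n_states, n_features=1, name="x"):
    """Small random circular GMM-HMM for oracle comparisons."""
    self_probs = rng.uniform(0.3, 0.9, size=n_states)
    emissions = []
    for _ in range(n_states):
        k = int(rng.integers(1, 3))
        w = rng.uniform(0.2, 1.0, size=k)
        emissions.append(
            cs.GaussianMixtureDiag(
                w / w.sum(),
                rng.normal(0.0, 3.0, size=(k, n_features)),
                rng.uniform(0.2, 1.5, size=(k, n_features)),
            )
        )
    from cycleseg.hmm_core import circular_log_transitions

    return cs.ClassHMM(name, n_states, circular_log_transitions(self_probs), emissions)
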