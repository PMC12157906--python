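import numpy as np
import pytest

from hedlm import (
    Candidate,
    FeatureVector,
    SEGMENT_FEATURE_NAMES,
    featurize_trace,
    generate_dataset,
)
from hedlm.synth import SyntheticSpec


def make_fv(instance_id, values, label=None, user_id="u"):
    return FeatureVector(
        user_id=user_id, instance_id=instance_id, values=np.asarray(values, float), label=label
    )


def fv_with_segments(instance_id, label=None, user_id="u", **seg_overrides):
    """30-dim vector with all features 0.4 except named overrides.

    Overrides use keys like ``rms2=0.7`` meaning feature 'rms' in segment 2.
    """
    vals = np.full(30, 0.4)
    for key, value in seg_overrides.items():
        name, seg = key[:-1], int(key[-1])
        vals[(seg - 1) * 10 + SEGMENT_FEATURE_NAMES.index(name)] = value
    return make_fv(instance_id, vals, label=label, user_id=user_id)


@pytest.fixture(scope="session")
def small_synth_features():
    """Featurized 2-user synthetic dataset (overlap 0.5, seed 11)."""
    spec = SyntheticSpec(n_users=2, instances_per_user=16, overlap=0.5, seed=11)
    traces = generate_dataset(spec)
    by_user = {}
    for tr in traces:
        by_user.setdefault(tr.user_id, []).append(featurize_trace(tr))
    return by_user
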