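import numpy as np
import pytest

from deepjdd import FeatureBatch


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def random_batch_pair(rng, ns, nt, d=2, n_classes=2):
    """A (source, target) FeatureBatch pair with simplex soft labels."""

    def soft(n):
        raw = rng.random((n, n_classes)) + 1e-3
        return raw / raw.sum(axis=1, keepdims=True)

    src = FeatureBatch(features=rng.standard_normal((ns, d)),
                       soft_labels=soft(ns))
    tgt = FeatureBatch(features=rng.standard_normal((nt, d)),
                       soft_labels=soft(nt))
    return src, tgt
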