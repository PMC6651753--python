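import numpy as np
import pytest

import gridlime as gl


@pytest.fixture(scope="session")
def class1_patch():
    """Canonical positive synthetic patch (seed 0) with its annotation."""
    return gl.generate_patch(1, gl.SynthParams(seed=0))


@pytest.fixture(scope="session")
def class0_patch():
    return gl.generate_patch(0, gl.SynthParams(seed=0))


@pytest.fixture()
def grid9():
    return gl.squaregrid_segments(96, 96, 9)


@pytest.fixture()
def constant_classifier():
    """Classifier ignoring its input: always (0.3, 0.7)."""

    def predict(batch):
        return np.tile([0.3, 0.7], (batch.shape[0], 1))

    return gl.ClassifierAdapter(predict_fn=predict, n_classes=2)
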