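import numpy as np
import pytest

from catrace.model import AcquisitionMeta, NormalizedTrace


def make_trace(values, frame_rate=100.0, mode="dff"):
    """Wrap raw dF/F values in a NormalizedTrace with unit baseline."""
    values = np.asarray(values, dtype=float)
    return NormalizedTrace(
        meta=AcquisitionMeta(frame_rate=frame_rate),
        values=values,
        baseline=np.ones_like(values),
        mode=mode,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
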