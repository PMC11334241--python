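import numpy as np
import pytest

from siamquality.model import ModelConfig, SiamQualityNet
from siamquality.preprocess import LabeledSegment
from siamquality.simulate import ArtifactSchedule, make_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """Two 10-minute synthetic patients at 240 Hz with default artifacts."""
    return make_corpus(2, 10, 240.0, seed=42)


@pytest.fixture(scope="session")
def tiny_model():
    return SiamQualityNet(ModelConfig(encoder_variant="tiny_1d"), seed=0)


def random_segments(rng, n, n_patients=3, t_max=1200.0):
    """Toy labelled segments with random times and artifact fractions."""
    segs = []
    for i in range(n):
        pid = f"p{rng.integers(n_patients)}"
        segs.append(LabeledSegment(
            samples=np.zeros(4), y=float(rng.uniform()),
            t=float(rng.uniform(0, t_max)), patient_id=pid,
            segment_id=f"s{i:03d}"))
    return segs
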