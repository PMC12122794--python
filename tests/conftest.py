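import numpy as np
import pytest

from impact.features import build_subject_features
from impact.model import ModelConfig
from impact.synthetic import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Strongly separable 12-subject cohort for overfitting/shape tests."""
    cfg = SynthConfig(n_per_class=6, T=60, R=8, delta=5.0,
                      event_windows=((10, 20), (35, 20)),
                      affected_rois=(1, 2, 3), seed=42)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_features(tiny_cohort):
    return [
        build_subject_features(s.roi, subject_id=s.subject_id, label=s.label,
                               n_ica=3, window_width=20, stride=10, seed=0)
        for s in tiny_cohort.subjects
    ]


@pytest.fixture(scope="session")
def tiny_model_config():
    return ModelConfig(hidden_dim=16, n_heads=2, n_layers=1, dropout=0.0,
                       ffn_expansion=2, classifier_width=8, roi_dim=8,
                       ica_dim=3, conn_dim=28, max_rel_offset=8, seed=0)
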