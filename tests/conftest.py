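import numpy as np
import pytest

from eggsense.classify import RfConfig
from eggsense.features import FeatureConfig
from eggsense.io import SegmentPlan
from eggsense.pipeline import PipelineConfig, build_feature_table, run_all
from eggsense.preprocess import segment_and_label, select_channel
from eggsense.synth import SynthConfig, generate_cohort

COHORT_SEED = 1234


@pytest.fixture(scope="session")
def cohort_bundle():
    """Full 17-subject pipeline bundle at the five standard SNR targets
    (statistics included, classifier run separately where needed)."""
    cfg = PipelineConfig(seed=COHORT_SEED, skip_classifier=True)
    return run_all(cfg)


@pytest.fixture(scope="session")
def original_table(cohort_bundle):
    return cohort_bundle["original_table"]


@pytest.fixture(scope="session")
def small_segments():
    """Fast 3-subject cohort of filtered, labelled segments."""
    cfg = SynthConfig(n_channels=1, seed=7)
    records, _ = generate_cohort(cfg, 3, seed=7)
    plan = SegmentPlan.default(cfg.duration_s)
    segs = []
    for r in records:
        segs.extend(segment_and_label(r, plan, select_channel(r)))
    return segs


@pytest.fixture(scope="session")
def small_table(small_segments):
    return build_feature_table(small_segments, FeatureConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
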