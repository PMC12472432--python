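import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from swaylab.classify import GridSpec, run_repeated_splits
from swaylab.features import build_feature_table
from swaylab.io_formats import Condition, CopTrial, Group, SubjectRecord
from swaylab.simulate import SimConfig, generate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_trial(rng, n=150, fs=10.0, condition=Condition.EO, scale=1.0):
    """A plausible random sway trajectory (smoothed random walk)."""
    ap = np.cumsum(rng.normal(0, 0.4, n)) * scale
    ml = np.cumsum(rng.normal(0, 0.25, n)) * scale
    return CopTrial(condition=condition, fs=fs, ap=ap, ml=ml)


def make_record(rng, subject_id="S001", group=Group.HOA, n=150, fs=10.0):
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        trials={
            Condition.EO: make_trial(rng, n, fs, Condition.EO),
            Condition.EC: make_trial(rng, n, fs, Condition.EC),
        },
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_cohort():
    """The default separated synthetic cohort (37 HOA + 26 PD, seed 0)."""
    return generate_cohort(SimConfig.default(seed=0))


@pytest.fixture(scope="session")
def default_table(default_cohort):
    records, _ = default_cohort
    return build_feature_table(records)


@pytest.fixture(scope="session")
def small_table():
    """A small separated cohort for fast harness tests."""
    cfg = SimConfig.default(seed=7)
    cfg.n_hoa, cfg.n_pd = 10, 8
    records, _ = generate_cohort(cfg)
    return build_feature_table(records)


@pytest.fixture(scope="session")
def recovery_run(default_table):
    """15-split repeated evaluation on the default cohort (reduced grids)."""
    return run_repeated_splits(
        default_table, GridSpec.small(), n_splits=15, use_smote=False
    )
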