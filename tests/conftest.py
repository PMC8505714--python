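import numpy as np
import pytest

from mrcpdecode.pipeline import PipelineConfig, process_subject
from mrcpdecode.synthetic import (
    BehaviorModel,
    ExperimentConfig,
    NoiseAndArtifactModel,
    generate_templates,
    simulate_subject,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cfg():
    """One session, 10 trials per condition (60 trials)."""
    return ExperimentConfig(n_sessions=1)


@pytest.fixture(scope="session")
def quiet_noise():
    """No artifacts, mild background — for ground-truth-exact checks."""
    return NoiseAndArtifactModel(
        background_rms_uv=5.0,
        line_amp_uv=0.0,
        blink_rate_per_min=0.0,
        burst_prob_per_trial=0.0,
    )


@pytest.fixture(scope="session")
def sim_small(small_cfg):
    """One default-noise synthetic subject, 60 trials."""
    templates = generate_templates(small_cfg, effect_scale=1.0)
    return simulate_subject(
        small_cfg, templates, BehaviorModel(), NoiseAndArtifactModel(), seed=7
    )


@pytest.fixture(scope="session")
def sim_quiet(small_cfg, quiet_noise):
    """Artifact-free subject where every trial survives screening."""
    templates = generate_templates(small_cfg, effect_scale=1.0)
    return simulate_subject(small_cfg, templates, BehaviorModel(slow_prob=0.0),
                            quiet_noise, seed=11)


@pytest.fixture(scope="session")
def processed_subject():
    """A fully preprocessed 2-session subject (100 Hz epochs with flags)."""
    cfg = PipelineConfig(n_subjects=1, experiment=dict(n_sessions=2))
    epochs, summary, rejection, ica_frame, sim = process_subject(cfg, 42, "S1")
    return dict(epochs=epochs, summary=summary, rejection=rejection,
                ica=ica_frame, sim=sim)
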