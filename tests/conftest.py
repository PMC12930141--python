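"""Shared fixtures: small and full synthetic studies, analysis results."""

import pytest
from hypothesis import HealthCheck, settings

from gazelang.pipeline import StudyConfig, run_all
from gazelang.synthetic import SynthConfig, generate_study, generate_worked_fixture

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def worked():
    return generate_worked_fixture()


@pytest.fixture(scope="session")
def small_bundle():
    """A fast 3-language study (36 trials) for unit-level checks."""
    return generate_study(
        SynthConfig(seed=5, n_participants_per_language=3, n_scenes=4)
    )


@pytest.fixture(scope="session")
def default_bundle():
    """The full default study: 3 languages x 8 participants x 12 scenes,
    semantic coupling at its default strength."""
    return generate_study(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def default_result(default_bundle):
    return run_all(StudyConfig(seed=1), bundle=default_bundle)


@pytest.fixture(scope="session")
def null_result():
    """Independent-channel study: no gaze-message, no gaze-structure coupling."""
    bundle = generate_study(SynthConfig(seed=3, g_sem=0.0, g_syn_before=0.0))
    return run_all(StudyConfig(seed=3), bundle=bundle)


@pytest.fixture(scope="session")
def planning_syntax_result():
    """Study with a planted planning-phase syntactic coupling."""
    bundle = generate_study(SynthConfig(seed=2, g_sem=0.5, g_syn_before=0.7))
    return run_all(StudyConfig(seed=2), bundle=bundle)
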