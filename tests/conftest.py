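import pytest

from painpanel.episodes import Episode, PainObservation, impute_baseline
from painpanel.model import ModelSpec, PainPanelModel
from painpanel.simulate import CohortConfig, generate_cohort


def make_episode(times_scores, arm="entonox", eid="e1", **kwargs):
    return Episode(
        episode_id=eid,
        arm=arm,
        observations=tuple(PainObservation(t, s) for t, s in times_scores),
        **kwargs,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic two-arm cohort, pure model draws (no selection)."""
    config = CohortConfig(n_per_arm=150, seed=42, baseline_enforcement="none")
    return [impute_baseline(ep) for ep in generate_cohort(config)], config


@pytest.fixture(scope="session")
def fitted_results(small_cohort):
    """One fitted two-arm model shared across inference tests."""
    episodes, _ = small_cohort
    return PainPanelModel(episodes, ModelSpec()).fit()
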