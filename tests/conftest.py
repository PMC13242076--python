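import pytest

from toxconcord import SyntheticTrialConfig, generate_cohort


@pytest.fixture(scope="session")
def clean_config():
    """A cohort with every discordance mechanism switched off."""
    return SyntheticTrialConfig(
        n_per_arm=60,
        underreport_prob=0.0,
        overestimate_prob=0.0,
        item_noise=0.0,
        missing_item_prob=0.0,
        missing_visit_prob=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def clean_cohort(clean_config):
    return generate_cohort(clean_config)


@pytest.fixture(scope="session")
def noisy_config():
    return SyntheticTrialConfig(n_per_arm=200, seed=5)


@pytest.fixture(scope="session")
def noisy_cohort(noisy_config):
    return generate_cohort(noisy_config)
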