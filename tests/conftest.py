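import pytest

from chronosurvey import GeneratorConfig, generate, score_bundle


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig.from_yaml(GeneratorConfig.default_path())


@pytest.fixture(scope="session")
def small_survey(default_config):
    """A modest synthetic bundle shared across tests (n=1200, seed 7)."""
    import dataclasses

    cfg = dataclasses.replace(default_config, n_subjects=1200, seed=7)
    return generate(cfg)


@pytest.fixture(scope="session")
def small_scored(small_survey):
    return score_bundle(small_survey)
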