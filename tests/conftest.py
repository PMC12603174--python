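import numpy as np
import pytest

import bmcea


@pytest.fixture(scope="session")
def base_model():
    """The shipped default parameter set, assembled and ready to run."""
    return bmcea.default_model()


@pytest.fixture(scope="session")
def base_run(base_model):
    return base_model.run()


@pytest.fixture(scope="session")
def trial_cohort():
    """One trial-sized synthetic cohort (201/202 patients, default truth)."""
    return bmcea.simulate(bmcea.GeneratorConfig(seed=20230))


@pytest.fixture(scope="session")
def transition_datasets(trial_cohort):
    return bmcea.to_transition_datasets(trial_cohort)


@pytest.fixture(scope="session")
def model_selections(transition_datasets):
    """Six-family fits ranked per (arm, transition) on the trial cohort."""
    selections = {}
    for (tp, arm), data in transition_datasets.items():
        fits = []
        for fam in bmcea.FAMILY_ORDER:
            try:
                fits.append(bmcea.fit_mle(data, fam))
            except bmcea.survival.SurvivalError:
                continue
        selections[(arm, tp)] = bmcea.select_model(fits)
    return selections


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
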