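import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from tppbayes.models import ModelSpec
from tppbayes.sampling import SamplerSettings, sample_posterior
from tppbayes.simulate import Design, SimulationTruth, simulate_protein


def make_truth(scenario="null_sigmoid", a=600.0, tm=50.0, p=0.05, sigma=0.05,
               tm_shift=0.0, bump=None, design=None, pid="PX"):
    """Hand-built ground truth for one protein (deterministic, no rng)."""
    design = design or Design()
    T = np.asarray(design.temperatures)
    b = a / tm
    params = {c: {"a": a, "b": b, "p": p, "sigma": sigma} for c in design.conditions}
    templates = {c: np.zeros(T.size) for c in design.conditions}
    if tm_shift:
        params[design.conditions[1]]["b"] = a / (tm + tm_shift)
    if bump is not None:
        amp, center, width = bump
        tmpl = amp * np.exp(-((T - center) ** 2) / (2.0 * width**2))
        for c in design.conditions:
            templates[c] = tmpl.copy()
    affected = bool(tm_shift)
    return SimulationTruth(pid, scenario, affected, params, templates, tm_shift)


@pytest.fixture(scope="session")
def design():
    return Design()


@pytest.fixture(scope="session")
def null_protein(design):
    return simulate_protein(make_truth(pid="null1"), design, seed=11)


@pytest.fixture(scope="session")
def biphasic_protein(design):
    truth = make_truth(scenario="biphasic", bump=(0.25, 50.0, 3.0), sigma=0.04,
                       pid="biph1")
    return simulate_protein(truth, design, seed=12)


@pytest.fixture(scope="session")
def lean_settings():
    return SamplerSettings(n_walkers=48, n_warmup=150, n_draws=200, seed=21)


@pytest.fixture(scope="session")
def sigmoid_m0_fit(null_protein, lean_settings):
    return sample_posterior(ModelSpec("sigmoid", "M0"), null_protein, lean_settings)


@pytest.fixture(scope="session")
def sigmoid_m1_fit(null_protein, lean_settings):
    return sample_posterior(ModelSpec("sigmoid", "M1"), null_protein, lean_settings)


@pytest.fixture(scope="session")
def semi_m0_fit(null_protein, lean_settings):
    return sample_posterior(ModelSpec("semiparametric", "M0"), null_protein,
                            lean_settings)


@pytest.fixture(scope="session")
def semi_m1_biphasic_fit(biphasic_protein, lean_settings):
    return sample_posterior(ModelSpec("semiparametric", "M1"), biphasic_protein,
                            lean_settings)
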