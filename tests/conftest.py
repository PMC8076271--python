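import numpy as np
import pytest

from amylir.fixtures import load_fixture
from amylir.spectra import baseline_correct, normalize_amide_one, second_derivative
from amylir.synthetic import simulate_class_spectrum


@pytest.fixture(scope="session")
def reference_set():
    return load_fixture("reference_set")


@pytest.fixture(scope="session")
def test_set():
    return load_fixture("test_set")


@pytest.fixture(scope="session")
def predictor_calls_test():
    return load_fixture("predictor_calls_test")


@pytest.fixture(scope="session")
def predictor_calls_reference():
    return load_fixture("predictor_calls_reference")


def make_panel(n_per_class: int = 20, seed: int = 7, noise_sd: float = 0.01):
    """Seeded synthetic DII panel: n positive (fibril/oligomer) + n non-amyloid."""
    rng = np.random.default_rng(seed)
    panel, labels = [], []
    for k in range(n_per_class):
        pos_cls = "fibril" if k % 2 == 0 else "oligomer"
        for cls, label in [(pos_cls, "amyloid"), ("non_amyloid", "non_amyloid")]:
            spec = simulate_class_spectrum(cls, seed=int(rng.integers(2**31)), noise_sd=noise_sd)
            panel.append(second_derivative(normalize_amide_one(baseline_correct(spec))))
            labels.append(label)
    return panel, labels


@pytest.fixture(scope="session")
def dii_panel_40():
    """The standard 40-spectrum panel (20 amyloid-positive, 20 non-amyloid)."""
    return make_panel(n_per_class=20, seed=7)
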