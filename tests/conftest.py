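import numpy as np
import pytest

import leafcos as lc
from leafcos.synthdata import (
    ChamberEmissionModel,
    NoiseModel,
    apply_emission_correction,
    generate_experiment_suite,
)


@pytest.fixture(scope="session")
def chamber():
    """Reference cuvette: pressure 103100 Pa, AF 0.35 mmol s-1, 9 cm2 leaf."""
    return lc.ChamberConfig()


@pytest.fixture(scope="session")
def posterior_leaf():
    """Leaf at the study's posterior-mean physiology (linear Gamma variant)."""
    return lc.default_truth()


@pytest.fixture(scope="session")
def clean_suite():
    """Noise-free, emission-free two-experiment campaign with one shared
    truth (no plant-to-plant jitter): the exact forward model on 48 points."""
    data, truth = generate_experiment_suite(
        seed=1, noise=NoiseModel.off(), emission=ChamberEmissionModel.off(),
        jitter_plants=False)
    return data, truth


@pytest.fixture(scope="session")
def noisy_suite():
    """Campaign at the study noise level with chamber emission, corrected
    for the emission as an observational preprocessing step."""
    em = ChamberEmissionModel()
    data, truth = generate_experiment_suite(seed=42, emission=em)
    return apply_emission_correction(data, em), truth


@pytest.fixture(scope="session")
def small_dataset():
    """Cheap 12-point single-plant dataset for optimizer-heavy tests."""
    em = ChamberEmissionModel()
    data, truth = generate_experiment_suite(
        seed=7, emission=em, n_gsw=2, n_temp=2)
    return apply_emission_correction(data, em), truth


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    data, _ = small_dataset
    model = lc.CuvetteInversion(data)
    return model, model.fit()


def closure_residuals(cfg, profile, g_b, g_s, mesophyll_term):
    """Mass-balance residuals of the three chained layer equations,
    relative to the largest flux term."""
    p = profile
    terms = np.array([
        cfg.q * (np.asarray(p.x_in) - p.x_a),
        g_b * (p.x_a - p.x_b),
        g_s * (p.x_b - p.x_i) - np.asarray(p.e_h2o) * (p.x_b + p.x_i) / 2.0,
        mesophyll_term,
    ])
    scale = np.maximum(np.max(np.abs(terms), axis=0), 1e-12)
    return (terms - terms[0]) / scale
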