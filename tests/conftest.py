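"""Shared fixtures: small synthetic screens reused across test modules."""

import warnings

import pandas as pd
import pytest

import orgaprofiler as op
from orgaprofiler import synthetic_data as sd
from orgaprofiler.features import filter_and_center_features, fit_pca_transform

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def clinical_screen():
    """Three lines screened with a 6-drug dilution-series library.

    clin_001/002 share a MoA (pure shape shift), clin_003 has its own MoA,
    clin_004 is lethal at the top dose.
    """
    lib = sd.clinical_library_spec(n_drugs=6, seed=0)
    plates = op.generate_plate_layout(
        ["D004T", "D013T", "D018T"], lib, controls_per_plate=16, seed=1
    )
    cfg = op.EffectConfig(
        n_per_well=30,
        drug_effects={
            "clin_001": sd.DrugEffect(moa="MEK", shift_sd=2.0),
            "clin_002": sd.DrugEffect(moa="MEK", shift_sd=2.0),
            "clin_003": sd.DrugEffect(moa="mTOR", shift_sd=2.0),
            "clin_004": sd.DrugEffect(lethality=0.8, shift_sd=1.0),
        },
    )
    fm, truth = op.simulate_feature_table(plates, cfg, seed=7)
    return plates, cfg, fm, truth


@pytest.fixture(scope="session")
def moa_screen():
    """One line, 15 single-concentration drugs in 3 orthogonal MoA groups."""
    drugs = {
        f"d{g}{i}": sd.DrugEffect(moa=f"G{g}", shift_sd=2.0)
        for g in range(3)
        for i in range(5)
    }
    lib = pd.DataFrame(
        {
            "drug": list(drugs),
            "target": [e.moa for e in drugs.values()],
            "concentrations": [(7.5e-6,)] * len(drugs),
        }
    )
    plates = op.generate_plate_layout(["D004T"], lib, controls_per_plate=20, seed=0)
    cfg = op.EffectConfig(n_per_well=120, drug_effects=drugs, baseline_death=0.0)
    fm, truth = op.simulate_feature_table(plates, cfg, seed=5)
    filtered = filter_and_center_features(fm)
    _, scores = fit_pca_transform(filtered, n_components=25)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        profiles = [
            op.fit_drug_effect_profile(scores, fm.meta, d, "D004T", seed=1)
            for d in drugs
        ]
    return profiles, truth


@pytest.fixture(scope="session")
def separable_screen():
    """Controls drawn from fully separated live/dead clusters (no label noise)."""
    lib = sd.clinical_library_spec(n_drugs=4, seed=0)
    plates = op.generate_plate_layout(
        ["D004T", "D013T"], lib, controls_per_plate=16, seed=1
    )
    cfg = op.EffectConfig(n_per_well=40, baseline_death=0.0, control_lethality=1.0)
    fm, truth = op.simulate_feature_table(plates, cfg, seed=3)
    return fm, truth


@pytest.fixture(scope="session")
def dose_screen():
    """One line with a drug killing 30% at top dose; 200 organoids per well."""
    lib = sd.clinical_library_spec(n_drugs=2, seed=0)
    plate = op.generate_plate_layout(["D004T"], lib, controls_per_plate=16, seed=2)[0]
    cfg = op.EffectConfig(
        n_per_well=200,
        baseline_death=0.0,
        drug_effects={"clin_001": sd.DrugEffect(lethality=0.30)},
    )
    fm, truth = op.simulate_feature_table(plate, cfg, seed=4)
    model = op.train_live_dead_classifier(fm, "D004T", seed=0)
    return fm, truth, model


@pytest.fixture(scope="session")
def multiview_noisy():
    views, truth = op.simulate_multiview(noise_sd=0.3, seed=11)
    return views, truth


def solid_field(seed=2, **overrides):
    defaults = dict(
        n_organoids=10, noise_sd=2.0, psf_sigma=1.0, mode="solid",
        radius_range=(11.0, 18.0), shape=(200, 200),
    )
    defaults.update(overrides)
    params = op.ImageSimParams(**defaults)
    return op.simulate_image_stacks(None, params, seed=seed)[0]
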