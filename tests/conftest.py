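import numpy as np
import pytest

import ftirscreen as fs


@pytest.fixture(scope="session")
def small_grid():
    return fs.default_grid(2000.0, 800.0, 121)


@pytest.fixture(scope="session")
def small_cohort():
    """A 16-patient triplicate cohort on the full default grid."""
    cfg = fs.CohortConfig(n_patients=16, seed=11)
    return fs.generate_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_ga():
    return fs.GAConfig(population_size=10, generations=3, k_min=3, k_max=8, seed=0)


@pytest.fixture(scope="session")
def small_ensemble(small_cohort, tiny_ga):
    """A six-model ensemble trained on the small cohort (all patients)."""
    return fs.train_ensemble(
        small_cohort, fs.PreprocConfig(), tiny_ga, fs.McConfig(n_models=6, seed=3)
    )


def make_prediction(pid, fracs, theta=0.5):
    """Hand-built PatientPrediction from replicate vote fractions."""
    from ftirscreen.consensus_predict import consensus_call

    fracs = np.asarray(fracs, dtype=float)
    calls, patient_call = consensus_call(fracs, theta)
    votes = [
        fs.ReplicateVote(f"{pid}.r{i}", float(f), "positive" if c else "negative")
        for i, (f, c) in enumerate(zip(fracs, calls))
    ]
    return fs.PatientPrediction(pid, votes, float(fracs.mean()), patient_call, theta)
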