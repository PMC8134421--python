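import numpy as np
import pandas as pd
import pytest

from asepred import CohortSimConfig, FeatureSimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """200-locus cohort with strong ASE effects, fixed seed."""
    cfg = CohortSimConfig(
        n_loci=200, n_individuals_per_locus=20, ase_fraction=0.15,
        depth_distribution={"kind": "negative_binomial", "mean": 60, "dispersion": 5},
        pi_ase_distribution={"kind": "mirrored_uniform", "low": 0.7, "high": 0.95},
        rho=0.02, seed=3)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def labelled_features():
    """Planted-signal encoded matrix + labels for classifier tests."""
    from asepred import impute_and_encode, simulate_feature_matrix

    rng = np.random.default_rng(7)
    n = 1200
    y = pd.Series(rng.random(n) < 0.3, index=[f"L{i:05d}" for i in range(n)])
    cfg = FeatureSimConfig(n_features_numeric=8, n_features_categorical=2,
                           effect_vector=(2.0, 1.5, 0, 0, 0, 0, 0, 0, 1.0, 0),
                           missing_rate=0.02, seed=11)
    matrix = impute_and_encode(simulate_feature_matrix(y, cfg))
    return matrix, y.astype(int)
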