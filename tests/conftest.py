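import numpy as np
import pandas as pd
import pytest

import haiforest as hf


@pytest.fixture(scope="session")
def default_cohort():
    """Default four-generation synthetic cohort, seed 1."""
    gens, exposures, effects = hf.default_doetinchem_like_config()
    waves, outcome, truth = hf.simulate_cohort(gens, exposures, effects, seed=1)
    return {
        "generations": gens,
        "exposures": exposures,
        "effects": effects,
        "waves": waves,
        "outcome": outcome,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def default_features(default_cohort):
    """Feature matrix + age-adjusted HAI outcome for the default cohort."""
    fm = hf.build_feature_matrix(
        default_cohort["waves"], hf.descriptors_for(default_cohort["exposures"])
    )
    scored = hf.score_cohort(default_cohort["outcome"])
    y = scored.set_index("participant_id").loc[fm.data.index, "age_adjusted"].to_numpy()
    return {"fm": fm, "scored": scored, "y": y}


def toy_regression(n=300, p=10, signal=(0,), coef=2.0, noise=1.0, seed=0):
    """Gaussian features; outcome linear in the `signal` columns plus noise."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, p)), columns=[f"f{j:02d}" for j in range(p)]
    )
    y = np.zeros(n)
    for j in signal:
        y = y + coef * X.iloc[:, j].to_numpy()
    y = y + rng.normal(scale=noise, size=n)
    return X, y
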