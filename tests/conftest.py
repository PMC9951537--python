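import numpy as np
import pytest

import predaot as p

#: One-candidate grid with a modest forest; keeps model-training tests fast.
TINY_GRID = {"n_estimators": [50], "max_depth": [None], "max_features": ["sqrt"]}


@pytest.fixture(scope="session")
def small_records():
    """400 synthetic compounds, default study-like conditions."""
    return p.generate_fixture(p.FixtureSpec(n_compounds=400, noise_sd=0.2, seed=11))


@pytest.fixture(scope="session")
def trained_cascade(small_records):
    """A cascade trained on 80% of small_records, plus its held-out test split."""
    train_ids, test_ids = p.split_dataset(small_records, 0.8, seed=13)
    train = [r for r in small_records if r.compound_id in train_ids]
    test = [r for r in small_records if r.compound_id in test_ids]
    model = p.train_cascade(train, classifier_grid=TINY_GRID, regressor_grid=TINY_GRID, seed=17)
    return model, train, test
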