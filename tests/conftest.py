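"""Shared fixtures: phantom datasets, extractor, fitted detector, retina model.

Expensive session-scoped fixtures (the trained 1-D U-Net, the fitted
MahaAD detector) are built once and shared; all randomness is seeded so
the suite is reproducible run to run.
"""

import numpy as np
import pytest

import octood as o


@pytest.fixture(scope="session")
def phantom_params():
    return o.PhantomParams()


@pytest.fixture(scope="session")
def clean_train(phantom_params):
    """Clean in-distribution training set (334 M-scans, the study's count)."""
    mscans, ilm = o.generate_mscans(334, phantom_params, seed=101)
    return mscans, ilm


@pytest.fixture(scope="session")
def clean_test(phantom_params):
    """Held-out clean M-scans with annotations."""
    mscans, ilm = o.generate_mscans(300, phantom_params, seed=202)
    return mscans, ilm


@pytest.fixture(scope="session")
def extractor():
    return o.make_test_extractor(0)


@pytest.fixture(scope="session")
def mahaad_detector(extractor, clean_train):
    """MahaAD fitted on the clean training set with the seeded pyramid."""
    return o.MahaADDetector(extractor=extractor).fit(clean_train[0])


@pytest.fixture(scope="session")
def retina_model(phantom_params):
    """1-D U-Net trained at reduced scale: 500 train / 100 val M-scans."""
    train_m, train_i = o.generate_mscans(500, phantom_params, seed=11)
    val_m, val_i = o.generate_mscans(100, phantom_params, seed=12)
    model = o.IlmHeatmapRegressor(
        base_channels=8, max_epochs=30, patience=8, seed=0
    )
    model.fit(train_m, train_i, X_val=val_m, y_val=val_i)
    return model


@pytest.fixture(scope="session")
def retina_val(phantom_params):
    mscans, ilm = o.generate_mscans(100, phantom_params, seed=12)
    return mscans, ilm


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
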