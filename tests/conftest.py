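import numpy as np
import pytest

import prostadiff as pf


@pytest.fixture(scope="session")
def scheme():
    """The bundled 10-row VERDICT-style scheme (5 DW + 5 matched b=0)."""
    return pf.verdict_scheme()


@pytest.fixture(scope="session")
def small_dki_estimator(scheme):
    """A quickly trained DKI regressor shared by fitting-level tests."""
    ds = pf.generate_training_set("DKI", scheme, n=4000, snr=35, seed=11)
    return pf.train_fitter(ds, pf.FitterConfig(seed=12))
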