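import numpy as np
import pytest

import crtwald as cw


@pytest.fixture(scope="session")
def small_trial():
    """One modest seeded trial with an interior variance estimate."""
    sc = cw.TrialScenario(K=12, nbar=30, cv=0.3, icc=0.05, seed=7)
    return cw.simulate_trial(sc, np.random.default_rng(7))


@pytest.fixture(scope="session")
def small_fit(small_trial):
    fit = cw.fit_glmm(small_trial)
    assert fit.converged
    return fit


@pytest.fixture(scope="session")
def converged_fits():
    """A batch of seeded converged fits spanning boundary and interior."""
    sc = cw.TrialScenario(K=10, nbar=40, cv=0.5, icc=0.05, seed=0)
    fits = []
    for seed in range(30):
        data = cw.simulate_trial(sc, np.random.default_rng(1000 + seed))
        fit = cw.fit_glmm(data)
        if fit.converged:
            fits.append(fit)
    assert len(fits) >= 20
    return fits
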