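import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from whaletrack import calibrate as cal
from whaletrack import deadreckon as dr
from whaletrack import simulate as sim
from whaletrack import ssm


@pytest.fixture(scope="session")
def gps_model():
    return cal.reference_gps_error_model()


@pytest.fixture(scope="session")
def vis_model():
    return cal.reference_visual_error_model()


@pytest.fixture(scope="session")
def small_dataset():
    """A 2-h synthetic deployment with both GPS and visual fixes."""
    return sim.simulate_dataset(sim.SimConfig(duration=7200), seed=42)


@pytest.fixture(scope="session")
def small_fit(small_dataset, gps_model, vis_model):
    """A converged short MCMC fit of the small deployment."""
    ds = small_dataset
    fixes = ssm.align_fix_times(ds.fixes)
    v = ds.truth.dr_velocity()
    times = np.unique(fixes.t)
    d, delta = dr.segment_displacements(v, times)
    cfg = ssm.McmcConfig(iterations=6000, burn_in=2000, thin=4, seed=11)
    post = ssm.fit_mcmc(fixes, d, delta, gps_model, vis_model, config=cfg)
    return ds, fixes, v, post
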