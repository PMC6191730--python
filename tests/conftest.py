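import numpy as np
import pytest

from refluxscint.cohort import CohortConfig, generate_cohort
from refluxscint.kinetics import KineticsParams, simulate_kinetics
from refluxscint.protocol import AcquisitionProtocol
from refluxscint.render import render_frames
from refluxscint.tac import default_roi_set


@pytest.fixture(scope="session")
def protocol():
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def rois():
    return default_roi_set(64)


@pytest.fixture(scope="session")
def default_cohort():
    """The default 250-patient cohort at a fixed seed."""
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def refluxer_study(protocol):
    """A rendered study for a vigorous refluxer-aspirator."""
    params = KineticsParams(
        reflux_event_rate_upright=0.15,
        reflux_event_rate_supine=0.4,
        clearance_rate=0.05,
        aspiration_fraction=0.15,
    )
    series = simulate_kinetics(params, protocol, seed=11)
    upright, supine, delayed = render_frames(series, protocol, seed=12)
    return params, series, upright, supine, delayed


@pytest.fixture(scope="session")
def quiet_study(protocol):
    """A rendered study with no reflux and no retained residual."""
    params = KineticsParams(
        reflux_event_rate_upright=0.0,
        reflux_event_rate_supine=0.0,
        aspiration_fraction=0.0,
        residual_fraction=0.0,
    )
    series = simulate_kinetics(params, protocol, seed=21)
    upright, supine, delayed = render_frames(series, protocol, seed=22)
    return params, series, upright, supine, delayed
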