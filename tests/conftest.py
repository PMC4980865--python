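"""Shared fixtures: default simulation objects, built once per session."""

import pytest

from renofur import (
    KineticParams,
    FrameSchedule,
    make_phantom,
    render_frames,
    simulate_kinetics,
    extract_tacs,
)


@pytest.fixture(scope="session")
def default_params():
    return KineticParams()


@pytest.fixture(scope="session")
def ideal_bolus_params():
    """Default kinetics with an instantaneous bolus (no mixing ramp)."""
    return KineticParams(t_mix_s=0.0)


@pytest.fixture(scope="session")
def schedule():
    return FrameSchedule()


@pytest.fixture(scope="session")
def phantom():
    return make_phantom(128)


@pytest.fixture(scope="session")
def noiseless_stack(default_params, schedule, phantom):
    series = simulate_kinetics(default_params, schedule)
    return render_frames(series, phantom, default_params, noise="none")


@pytest.fixture(scope="session")
def noiseless_tacs(noiseless_stack, phantom):
    return extract_tacs(noiseless_stack, phantom.rois)
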