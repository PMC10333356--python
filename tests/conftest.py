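import numpy as np
import pytest

from pamloc.geometry import long_array, short_array
from pamloc.signals import make_chirp
from pamloc.simulate import Scenario, SourceSpec, render


@pytest.fixture(scope="session")
def long_arr():
    return long_array()


@pytest.fixture(scope="session")
def short_arr():
    return short_array()


@pytest.fixture(scope="session")
def chirp48k():
    return make_chirp(0.002, 48_000)


def render_chirp_scene(array, azimuth, range_m=200.0, depth=0.0,
                       onset=1.0, duration=3.0, source_level=156.0):
    """Render a single noiseless chirp scenario (shared test helper)."""
    scenario = Scenario(
        array=array,
        sources=(SourceSpec(make_chirp(0.002, 48_000), source_level,
                            (azimuth, range_m, depth), onset=onset),),
        duration=duration,
    )
    return render(scenario)


@pytest.fixture(scope="session")
def chirp_scene_factory():
    return render_chirp_scene
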