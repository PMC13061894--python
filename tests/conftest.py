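import numpy as np
import pytest

from gestaltfbm.geometry import GeometrySpec
from gestaltfbm.stimgen import StripSpec, render_strip


@pytest.fixture(scope="session")
def geometry():
    return GeometrySpec()


@pytest.fixture(scope="session")
def rendered_strips(geometry):
    """One rendered strip per cue (rendering is the slow part)."""
    return {cue: render_strip(StripSpec(cue=cue), geometry, seed=7)
            for cue in ("ambiguous", "symmetry", "closure", "convexity",
                        "all_cues")}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
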