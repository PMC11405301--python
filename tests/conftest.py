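import logging
import warnings

import numpy as np
import pytest

from seegviz.contacts import segment_contacts
from seegviz.phantom import PhantomSpec, make_ct_phantom, make_recording

logging.getLogger("seegviz").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def phantom_default():
    """Default two-electrode phantom with streaks (seed 1)."""
    spec = PhantomSpec(seed=1)
    ct, brain, truth = make_ct_phantom(spec)
    return spec, ct, brain, truth


@pytest.fixture(scope="session")
def phantom_clean():
    """Artifact-free, well-separated phantom: no streak bridges, no
    diffuse rays, wide-pitch (5 mm) electrodes.

    With nothing filling the upper-percentile quota the metal threshold
    falls into the tissue-noise tail; noise_sd 15 and the wide pitch keep
    neighbouring contact blobs from bridging at that threshold (a clean,
    low-artifact CT).
    """
    spec = PhantomSpec(
        seed=4, streak_count=0, artifact_rays=0, noise_sd=15.0,
        contact_spacing_mm=5.0,
    )
    ct, brain, truth = make_ct_phantom(spec)
    return spec, ct, brain, truth


@pytest.fixture(scope="session")
def segmented_default(phantom_default):
    _, ct, brain, _ = phantom_default
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return segment_contacts(ct, brain)


@pytest.fixture(scope="session")
def recording(tmp_path_factory, phantom_default):
    """EDF recording for the default phantom plus updated ground truth."""
    _, _, _, truth = phantom_default
    path = tmp_path_factory.mktemp("edf") / "rec.edf"
    path, truth = make_recording(truth, path, seed=1)
    return path, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20240903)
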