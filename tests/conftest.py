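import logging

import numpy as np
import pytest

from ctcpolyp import (
    CleansingConfig,
    PhantomConfig,
    TaggingSpec,
    electronic_cleanse,
    generate_phantom,
    segment_colon,
)

# the segmentation logs skipped slices etc.; keep test output quiet
logging.getLogger("ctcpolyp").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_phantom():
    """Default tagged phantom (seed 1): volume + truth."""
    return generate_phantom(PhantomConfig(seed=1))


@pytest.fixture(scope="session")
def untagged_phantom():
    """Same geometry without tagged fluid (no pool, no halo)."""
    return generate_phantom(
        PhantomConfig(seed=1, tagging=TaggingSpec(fill_fraction=0.0))
    )


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, untagged, polyp-free phantom for exact checks."""
    return generate_phantom(
        PhantomConfig(
            seed=1,
            noise_sd_hu=0.0,
            material_jitter_frac=0.0,
            tagging=TaggingSpec(fill_fraction=0.0),
            polyps=(),
            halo_amplitude_hu=0.0,
        )
    )


@pytest.fixture(scope="session")
def segmented(default_phantom):
    vol, _ = default_phantom
    return segment_colon(vol)


@pytest.fixture(scope="session")
def cleansed(default_phantom):
    vol, _ = default_phantom
    return electronic_cleanse(vol, cfg=CleansingConfig())


@pytest.fixture()
def disc_image():
    """Synthetic axial slice: air disc in soft tissue (sharp interface)."""
    yy, xx = np.mgrid[:64, :64]
    rho = np.hypot(yy - 32, xx - 32)
    img = np.where(rho <= 20, -1000.0, 54.0)
    return img
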