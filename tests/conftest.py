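import numpy as np
import pytest

import spheroscreen as ss


@pytest.fixture(scope="session")
def disk_truth():
    """Noiseless circular spheroid, radius 100 px, scale 1 um/px."""
    return ss.ImageTruth(center=(256.0, 256.0), semi_axes=(100.0, 100.0),
                         noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def disk_image(disk_truth):
    return ss.generate_spheroid_image(disk_truth)


@pytest.fixture(scope="session")
def disk_measurement(disk_image):
    return ss.segment_spheroid(disk_image)


@pytest.fixture(scope="session")
def rimless_disk():
    """Dark disk on a light background with sd-5 (uniform) noise — a clean
    two-class image for exercising the raw Yen threshold without rim
    effects.  Light-tailed noise keeps the histogram classes sharp-edged;
    Gaussian tails make any entropy threshold graze the majority class."""
    rng = np.random.default_rng(3)
    img = np.full((256, 256), 200.0)
    rr, cc = np.mgrid[0:256, 0:256]
    mask = (rr - 128) ** 2 + (cc - 128) ** 2 <= 60 ** 2
    img[mask] = 60.0
    half_width = 5.0 * np.sqrt(3.0)  # uniform noise with SD 5
    img = np.clip(np.rint(img + rng.uniform(-half_width, half_width, img.shape)),
                  0, 255).astype(np.uint8)
    return img, mask


@pytest.fixture(scope="session")
def mono_plate_truth():
    """The stated monophasic simulation world (logIC50 0.5, CV 10%, n=6 x 9)."""
    return ss.default_plate_truth("4pl", cv=10.0)


@pytest.fixture(scope="session")
def mono_readings(mono_plate_truth):
    return ss.simulate_plate(ss.with_seed(mono_plate_truth, 42))
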