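import numpy as np
import pytest
from scipy import ndimage

from srshisto import phantom, quantify
from srshisto.preproc import UnmixMatrix, unmix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_matrix():
    return UnmixMatrix()


def blobby_labels(h, w, n_classes, rng, sigma=4.0):
    """Random contiguous-region label map (smoothed-field argmax)."""
    fields = np.stack([ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma)
                       for _ in range(n_classes)])
    return fields.argmax(axis=0)


def separable_patches(n, size=64, seed0=0):
    """Phantom patches from the well-separated 4-class spec, as
    (unmixed-channel image, truth labels) training pairs."""
    out = []
    for s in range(n):
        spec = phantom.separable_phantom_spec(size, size, seed=seed0 + s)
        samp = phantom.generate(spec)
        img = quantify.maps_to_image(unmix(samp.frame))
        out.append((img, samp.truth_labels))
    return out


def cellular_patches(n, size=64, seed0=0):
    """Single-class high-grade patches with truth nuclei masks."""
    out = []
    for s in range(n):
        cs = [phantom.ClassSpec(5, 138.3, 170.0, 4.0, 198.0, 0.0049, 0.21)]
        spec = phantom.PhantomSpec(height=size, width=size, class_specs=cs,
                                   target_area_fractions=np.array([1.0]),
                                   seed=seed0 + s, region_smoothness=8)
        samp = phantom.generate(spec)
        img = quantify.maps_to_image(unmix(samp.frame))
        out.append((img, samp.truth_nuclei.astype(np.int64)))
    return out


@pytest.fixture(scope="session")
def small_phantom():
    """A 256x256 full-taxonomy phantom shared by read-only tests."""
    spec = phantom.PhantomSpec(height=256, width=256, seed=7,
                               region_smoothness=16.0)
    return phantom.generate(spec)
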