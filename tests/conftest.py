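import numpy as np
import pytest

import spikesight as ss


@pytest.fixture(scope="session")
def fixture_dataset(tmp_path_factory):
    """The standard synthetic study dataset: 50 images/class, 80/20 split."""
    root = tmp_path_factory.mktemp("fixture_ds")
    return ss.make_dataset(50, seed=0, out_dir=root)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A tiny dataset for plumbing tests (8 images/class)."""
    root = tmp_path_factory.mktemp("small_ds")
    return ss.make_dataset(8, seed=7, out_dir=root)


@pytest.fixture(scope="session")
def trained_model(fixture_dataset):
    """Pipeline trained under the study conditions (K=200, seed 0)."""
    return ss.train_pipeline(fixture_dataset, ss.Config({"codebook.k": 200}), seed=0)


@pytest.fixture(scope="session")
def blob_image():
    """128x128 black image with one bright Gaussian blob (sigma=4) at (64, 64)."""
    yy, xx = np.mgrid[0:128, 0:128].astype(float)
    return np.exp(-((yy - 64.0) ** 2 + (xx - 64.0) ** 2) / (2 * 4.0 ** 2))


@pytest.fixture(scope="session")
def textured_image():
    """A deterministic multi-blob texture rich in keypoints."""
    rng = np.random.default_rng(42)
    yy, xx = np.mgrid[0:128, 0:128].astype(float)
    img = np.zeros((128, 128))
    for _ in range(20):
        cy, cx = rng.uniform(16, 112, 2)
        s = rng.uniform(2.0, 6.0)
        img += rng.uniform(0.3, 1.0) * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s * s))
    return img / img.max()
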