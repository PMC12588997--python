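import numpy as np
import pytest

from leafchem.msio import empirical_line_calibrate
from leafchem.pipeline import recovery_dataset, recovery_experiment
from leafchem.synthgen import SceneSpec, generate_leaf_capture
from leafchem.texfeat import extract_all


@pytest.fixture(scope="session")
def lab_spec() -> SceneSpec:
    """Default laboratory-scale scene spec, fixed seed."""
    return SceneSpec(seed=11)


@pytest.fixture(scope="session")
def quiet_spec() -> SceneSpec:
    """Noise-free spec for deterministic reflectance checks."""
    return SceneSpec(seed=11, noise_sigma=0.0, illumination_jitter=0.0)


@pytest.fixture(scope="session")
def calibrated_leaf(lab_spec):
    """One calibrated single-leaf capture plus its ground truth."""
    capture, gt = generate_leaf_capture(lab_spec, (2.8, 2.2), leaf_id="fixture_leaf")
    return empirical_line_calibrate(capture, lab_spec.panel()), gt


@pytest.fixture(scope="session")
def leaf_features(calibrated_leaf):
    """The 480-entry feature vector of the fixture leaf."""
    capture, gt = calibrated_leaf
    return extract_all(capture, gt.mask)


@pytest.fixture(scope="session")
def recovery_results():
    """Held-out R^2 of the chemistry recovery experiment (n = 300 leaves).

    Expensive (about two minutes); shared by the estimator and acceptance
    tests.
    """
    table = recovery_dataset(seed=1, n_leaves=300)
    return recovery_experiment(seed=1, table=table)


def random_blob_mask(rng: np.random.Generator, shape=(48, 64)) -> np.ndarray:
    """A random filled-rectangle mask (non-empty)."""
    h, w = shape
    r0 = int(rng.integers(0, h - 8))
    c0 = int(rng.integers(0, w - 8))
    r1 = int(rng.integers(r0 + 4, min(h, r0 + 24)))
    c1 = int(rng.integers(c0 + 4, min(w, c0 + 24)))
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1, c0:c1] = True
    return mask
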