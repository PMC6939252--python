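import numpy as np
import pytest

import arcmorph as am


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ellipse_dataset():
    """Two-group ellipse-outline dataset with sliding semilandmarks."""
    tpl = am.make_template("ellipse_outline", 10)
    spec = am.SimulationSpec(
        tpl,
        [am.GroupSpec("A", 10), am.GroupSpec("B", 10, offset=0.05)],
        landmark_noise_sd=0.01,
        seed=42,
    )
    return am.simulate_landmarks(spec)


@pytest.fixture
def mandible_dataset():
    """Three-group toy-mandible dataset without semilandmarks."""
    tpl = am.make_template("toy_mandible")
    spec = am.SimulationSpec(
        tpl,
        [
            am.GroupSpec("palaeo_inuit", 12, offset=0.0),
            am.GroupSpec("inuit", 12, offset=0.06),
            am.GroupSpec("modern_greenland", 12, offset=0.04),
        ],
        landmark_noise_sd=0.015,
        seed=7,
    )
    return am.simulate_landmarks(spec)


def random_rigid(points: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random similarity transform (proper rotation + translation + scaling)."""
    m = points.shape[1]
    if m == 2:
        th = rng.uniform(0, 2 * np.pi)
        c, s = np.cos(th), np.sin(th)
        rot = np.array([[c, -s], [s, c]])
    else:
        q, r = np.linalg.qr(rng.normal(size=(m, m)))
        rot = q * np.sign(np.diag(r))
        if np.linalg.det(rot) < 0:
            rot[:, -1] *= -1
    return points @ rot.T * rng.uniform(0.3, 3.0) + rng.uniform(-10, 10, m)
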