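import numpy as np
import pytest

from oculid import EyeHexagon, SyntheticEyeSpec, render_frame
from oculid.config import PipelineConfig


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def clean_spec():
    """Noiseless up-gaze spec: rendering is its own ground truth."""
    return SyntheticEyeSpec(noise_sigma=0.0)


@pytest.fixture(scope="session")
def noisy_spec():
    return SyntheticEyeSpec(noise_sigma=0.03, seed=11)


@pytest.fixture(scope="session")
def clean_frame(clean_spec):
    return render_frame(clean_spec, 0.0)


@pytest.fixture(scope="session")
def noisy_frame(noisy_spec):
    return render_frame(noisy_spec, 0.0)


@pytest.fixture()
def right_hexagon(clean_frame):
    _, truth = clean_frame
    return EyeHexagon("right", truth.eyes[0].hexagon)


def brute_force_threshold(values: np.ndarray) -> float:
    """Independent oracle: exhaustive best single-threshold split.

    Scans all 255 gray-level candidates and returns the threshold
    maximizing the between-class variance (the optimum a two-cluster
    intensity partition should agree with on bimodal data).
    """
    v = np.asarray(values, dtype=float).ravel()
    best_t, best_score = 0.5, -1.0
    for thr in np.linspace(v.min(), v.max(), 255)[1:-1]:
        lo, hi = v[v < thr], v[v >= thr]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / v.size, hi.size / v.size
        score = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if score > best_score:
            best_score, best_t = score, thr
    return best_t
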