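import numpy as np
import pytest

from ridgekit.synthetic import SyntheticSpec, render_ridge_image, degrade


@pytest.fixture(scope="session")
def clean_truth():
    """Small noiseless capture with a smoothly varying orientation field."""
    spec = SyntheticSpec(
        width=480,
        height=320,
        ridge_period=8.0,
        orientation_model=("linear", -0.6, 0.6),
        noise_sd=0.0,
        brightness_error_amplitude=0.0,
        n_dislocations=10,
        seed=11,
    )
    return spec, render_ridge_image(spec)


@pytest.fixture(scope="session")
def degraded_capture():
    """Moderately degraded capture with its ground truth."""
    spec = SyntheticSpec(
        width=480,
        height=320,
        ridge_period=8.0,
        orientation_model=("linear", -0.6, 0.6),
        noise_sd=10.0,
        brightness_error_amplitude=20.0,
        n_dislocations=10,
        seed=11,
    )
    truth = render_ridge_image(spec)
    return spec, truth, degrade(truth, spec)


def block_true_orientation(dense: np.ndarray, bi: int, bj: int, W: int) -> float:
    """Doubled-angle mean of the dense truth over one block."""
    blk = dense[bi * W : (bi + 1) * W, bj * W : (bj + 1) * W]
    return 0.5 * np.arctan2(np.sin(2 * blk).mean(), np.cos(2 * blk).mean())


def angdiff(a: float, b: float) -> float:
    """Absolute angular difference modulo pi, in radians."""
    return abs((a - b + np.pi / 2) % np.pi - np.pi / 2)
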