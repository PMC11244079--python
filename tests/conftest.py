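import numpy as np
import pytest

from pipmorph.outline import Outline


def circle_outline(n: int = 360, radius: float = 1.0, centre=(0.0, 0.0)) -> Outline:
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return Outline(
        np.column_stack(
            [centre[0] + radius * np.cos(t), centre[1] + radius * np.sin(t)]
        )
    )


def ellipse_outline(a: float, b: float, n: int = 360) -> Outline:
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return Outline(np.column_stack([a * np.cos(t), b * np.sin(t)]))


def square_outline() -> Outline:
    return Outline(
        np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    )


def random_smooth_outline(rng, n_points: int = 360, n_harmonics: int = 6) -> Outline:
    """Random simple closed curve: perturbed circle in polar harmonics."""
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    r = np.ones_like(t)
    for k in range(2, n_harmonics + 2):
        amp = 0.25 / k
        r += amp * rng.uniform(-1, 1) * np.cos(k * t) + amp * rng.uniform(
            -1, 1
        ) * np.sin(k * t)
    return Outline(np.column_stack([r * np.cos(t), r * np.sin(t)]))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
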