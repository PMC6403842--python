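import numpy as np
import pytest

from loopex.configs import torus_knot_coords
from loopex.topology import ClosedCurve


def curve_from_param(fx, fy, fz, n):
    """Uniform arc-length polygon from a closed parametric curve."""
    tt = np.linspace(0, 2 * np.pi, 40 * n, endpoint=False)
    pts = np.stack([fx(tt), fy(tt), fz(tt)], axis=1)
    seg = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])[:-1]
    want = np.linspace(0, s[-1] + seg[-1], n, endpoint=False)
    idx = np.clip(np.searchsorted(s, want), 0, len(pts) - 1)
    return ClosedCurve(pts[idx])


@pytest.fixture(scope="session")
def trefoil():
    return torus_knot_coords(2, 3, 133)


@pytest.fixture(scope="session")
def figure_eight():
    """The standard parametric figure-eight knot (determinant 5)."""
    return curve_from_param(
        lambda t: (2 + np.cos(2 * t)) * np.cos(3 * t),
        lambda t: (2 + np.cos(2 * t)) * np.sin(3 * t),
        lambda t: np.sin(4 * t),
        150,
    )


@pytest.fixture(scope="session")
def t37():
    return torus_knot_coords(3, 7, 200)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_closed_walk(n, rng, scale=1.5):
    """A random closed polygon (drift-corrected random walk)."""
    steps = rng.standard_normal((n, 3))
    steps -= steps.mean(axis=0)
    return ClosedCurve(np.cumsum(steps, axis=0) * scale)
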