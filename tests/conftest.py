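import numpy as np
import pytest

from curveflow import ClosedCurve


def regular_ngon(n: int, radius: float = 1.0, ccw: bool = True) -> ClosedCurve:
    """Regular n-gon inscribed in a circle, counterclockwise by default."""
    theta = 2.0 * np.pi * np.arange(n) / n
    if not ccw:
        theta = -theta
    return ClosedCurve(radius * np.column_stack([np.cos(theta), np.sin(theta)]))


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def random_star_polygon(rng, n: int = 10) -> ClosedCurve:
    """Random star-shaped polygon (simple, counterclockwise)."""
    theta = np.sort(rng.uniform(0.0, 2.0 * np.pi, n))
    # enforce distinct angles so chords cannot degenerate
    theta += np.arange(n) * 1e-6
    r = rng.uniform(0.5, 1.5, n)
    return ClosedCurve(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))
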