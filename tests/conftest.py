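import numpy as np
import pytest

from congalines import CsrParams, SurfaceMap, ThomasParams, Window

#: fitted background parameters for the densest studied surface, reused as
#: realistic simulation conditions throughout the suite
H5_CSR = CsrParams(140.0)
H5_THOMAS = ThomasParams(kappa=18.0, mu=6.0, sigma=0.07263)


def rect_window(w=1.0, h=None) -> Window:
    h = w if h is None else h
    return Window(np.array([[0.0, 0.0], [w, 0.0], [w, h], [0.0, h]]))


@pytest.fixture
def unit_window() -> Window:
    return rect_window(1.0)


@pytest.fixture
def big_window() -> Window:
    """2 x 2 m rectangle, the standard simulation arena."""
    return rect_window(2.0)


@pytest.fixture
def l_window() -> Window:
    """A non-rectangular (L-shaped) window for geometry edge cases."""
    return Window(
        np.array([[0, 0], [2, 0], [2, 1], [1, 1], [1, 2], [0, 2]], dtype=float)
    )


def surface_on(window: Window, points) -> SurfaceMap:
    return SurfaceMap(points=np.asarray(points, dtype=float), window=window)


def brute_force_triples(pts: np.ndarray, r: float, theta_deg: float) -> set:
    """Exhaustive O(n^3) alignment enumeration, independent of the package.

    Enumerates every (i, j, k) with j as middle point via full broadcasting:
    both links <= r and non-zero, bearing change < theta, endpoints distinct.
    Triples are canonicalised with the smaller endpoint first.
    """
    pts = np.asarray(pts, dtype=float)
    n = len(pts)
    if n < 3:
        return set()
    diff = pts[None, :, :] - pts[:, None, :]
    d = np.hypot(diff[..., 0], diff[..., 1])
    b = np.degrees(np.arctan2(diff[..., 1], diff[..., 0])) % 360.0
    link = (d <= r) & (d > 0.0)
    # bearing(i -> j) vs bearing(j -> k), broadcast to (i, j, k)
    delta = np.abs(b[:, :, None] - b[None, :, :]) % 360.0
    delta = np.minimum(delta, 360.0 - delta)
    ok = link[:, :, None] & link[None, :, :] & (delta < theta_deg)
    ii, jj, kk = np.nonzero(ok)
    return {
        (min(i, k), j, max(i, k))
        for i, j, k in zip(ii, jj, kk)
        if i != k
    }
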