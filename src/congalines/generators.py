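"""Seeded point-process simulators and the synthetic conga-surface generator.

Two null backgrounds are supported: complete spatial randomness (homogeneous
Poisson, intensity ``lam`` in points per m^2) and the Thomas cluster process
(Poisson parents at intensity ``kappa``, each spawning Poisson(``mu``)
offspring displaced by an isotropic Gaussian with per-axis SD ``sigma``).
These emulate the densities and cluster scales typical of Avalonian
fossil-bearing surfaces (tens to low hundreds of specimens per m^2, cluster
SDs of a few tens of millimetres).

``generate_conga_surface`` plants near-collinear chains of 3-6 points on top
of a background, returning both the surface and a ground-truth record, so the
detection and inference stages can be exercised without the deposited maps.

All generators are reproducible: every routine takes a seed (or Generator)
and derives child streams deterministically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import stats
from shapely.geometry import Polygon

from .errors import InvalidParameterError, PlacementError
from .surfaces import SurfaceMap, Window

__all__ = [
    "CsrParams",
    "ThomasParams",
    "PlantedChain",
    "CongaTruth",
    "simulate_csr",
    "simulate_thomas",
    "generate_conga_surface",
    "uniform_in_window",
]

#: parent-intensity buffer around the window, in units of sigma, so clusters
#: seeded just outside still contribute offspring (truncation bias < 0.01%)
PARENT_BUFFER_SIGMAS = 4.0


@dataclass(frozen=True)
class CsrParams:
    """Homogeneous Poisson background: intensity ``lam`` in points m^-2."""

    lam: float

    def __post_init__(self):
        if not self.lam >= 0:
            raise InvalidParameterError(f"lam must be >= 0, got {self.lam}")

    @property
    def intensity(self) -> float:
        return self.lam


@dataclass(frozen=True)
class ThomasParams:
    """Thomas cluster background.

    kappa : parent intensity, m^-2
    mu    : mean offspring per parent (dimensionless)
    sigma : per-axis SD of the Gaussian offspring displacement, metres
    """

    kappa: float
    mu: float
    sigma: float

    def __post_init__(self):
        if not (self.kappa > 0 and self.mu > 0 and self.sigma > 0):
            raise InvalidParameterError(
                f"Thomas parameters must be positive, got "
                f"kappa={self.kappa}, mu={self.mu}, sigma={self.sigma}"
            )

    @property
    def intensity(self) -> float:
        """Mean point intensity kappa * mu, m^-2."""
        return self.kappa * self.mu


@dataclass(frozen=True)
class PlantedChain:
    """Ground truth for one planted chain."""

    anchor: tuple
    length: int
    spacings: tuple  # per-link spacing, metres
    azimuth_deg: float
    jitter_deg: float
    indices: tuple  # row indices into the surface point array
    points: np.ndarray

    @property
    def n_triples(self) -> int:
        """Consecutive three-point alignments contributed: length - 2."""
        return self.length - 2


@dataclass(frozen=True)
class CongaTruth:
    """Planted-chain record accompanying a synthetic surface."""

    chains: tuple
    background: object  # CsrParams | ThomasParams

    @property
    def n_planted_triples(self) -> int:
        return sum(c.n_triples for c in self.chains)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _uniform_in_polygon(poly, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points in a shapely polygon by rejection from its bbox."""
    if n == 0:
        return np.empty((0, 2))
    xmin, ymin, xmax, ymax = poly.bounds
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = max(2 * (n - filled), 16)
        x = rng.uniform(xmin, xmax, m)
        y = rng.uniform(ymin, ymax, m)
        ok = shapely.intersects_xy(poly, x, y)
        take = min(int(ok.sum()), n - filled)
        out[filled : filled + take, 0] = x[ok][:take]
        out[filled : filled + take, 1] = y[ok][:take]
        filled += take
    return out


def uniform_in_window(window: Window, n: int, rng) -> np.ndarray:
    """n points uniform on the window (holes excluded), by bbox rejection."""
    rng = _rng(rng)
    if n == 0:
        return np.empty((0, 2))
    xmin, ymin, xmax, ymax = window.bounds
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = max(2 * (n - filled), 16)
        x = rng.uniform(xmin, xmax, m)
        y = rng.uniform(ymin, ymax, m)
        ok = window.contains(x, y)
        take = min(int(ok.sum()), n - filled)
        out[filled : filled + take, 0] = x[ok][:take]
        out[filled : filled + take, 1] = y[ok][:take]
        filled += take
    return out


def simulate_csr(params: CsrParams, window: Window, seed) -> SurfaceMap:
    """Draw a CSR pattern: Poisson(lam * A) points uniform on the window."""
    rng = _rng(seed)
    n = rng.poisson(params.lam * window.area)
    pts = uniform_in_window(window, int(n), rng)
    return SurfaceMap(points=pts, window=window)


def simulate_thomas(params: ThomasParams, window: Window, seed) -> SurfaceMap:
    """Draw a Thomas cluster pattern on the window.

    Parents are Poisson on the window exterior dilated by 4 sigma (so edge
    clusters are not lost); each parent spawns Poisson(mu) offspring with
    isotropic Gaussian displacement. Offspring landing outside the window or
    in a hole are discarded; parents themselves are not part of the pattern.
    """
    rng = _rng(seed)
    buffered = Polygon(window.exterior).buffer(PARENT_BUFFER_SIGMAS * params.sigma)
    exp_parents = params.kappa * buffered.area
    exp_points = exp_parents * params.mu
    if exp_parents > max(1e4, 10.0 * exp_points):
        # sparse-offspring regime (kappa huge, mu tiny): enumerate only the
        # parents that produce at least one offspring — exactly equivalent
        p_prod = -math.expm1(-params.mu)
        n_parents = int(rng.poisson(exp_parents * p_prod))
        parents = _uniform_in_polygon(buffered, n_parents, rng)
        # zero-truncated Poisson(mu) via inverse cdf
        u = rng.uniform(math.exp(-params.mu), 1.0, n_parents)
        counts = stats.poisson.ppf(u, params.mu).astype(int)
    else:
        n_parents = int(rng.poisson(exp_parents))
        parents = _uniform_in_polygon(buffered, n_parents, rng)
        counts = rng.poisson(params.mu, n_parents)
    total = int(counts.sum())
    if total == 0:
        return SurfaceMap(points=np.empty((0, 2)), window=window)
    centres = np.repeat(parents, counts, axis=0)
    pts = centres + rng.normal(0.0, params.sigma, size=(total, 2))
    keep = window.contains(pts[:, 0], pts[:, 1])
    return SurfaceMap(points=pts[keep], window=window)


def _simulate_background(model, window: Window, seed) -> SurfaceMap:
    if isinstance(model, CsrParams):
        return simulate_csr(model, window, seed)
    if isinstance(model, ThomasParams):
        return simulate_thomas(model, window, seed)
    raise InvalidParameterError(f"unknown background model {model!r}")


def _place_chain(
    window: Window,
    length: int,
    spacing_dist,
    jitter_deg: float,
    rng: np.random.Generator,
    max_retries: int,
) -> tuple:
    """One chain wholly inside the window; resample anchor/azimuth on failure."""
    for _ in range(max_retries):
        anchor = uniform_in_window(window, 1, rng)[0]
        azimuth = rng.uniform(0.0, 360.0)
        spacings = np.array([spacing_dist(rng) for _ in range(length - 1)])
        bearings = azimuth + rng.uniform(-jitter_deg, jitter_deg, length - 1)
        steps = spacings[:, None] * np.column_stack(
            [np.cos(np.deg2rad(bearings)), np.sin(np.deg2rad(bearings))]
        )
        pts = anchor + np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
        if window.contains(pts[:, 0], pts[:, 1]).all():
            return pts, anchor, spacings, azimuth
    raise PlacementError(
        f"could not place a length-{length} chain after {max_retries} tries"
    )


def generate_conga_surface(
    background,
    window: Window,
    n_chains: int,
    seed,
    length_dist=(3, 4, 5, 6),
    spacing=0.012,
    jitter_deg: float = 5.0,
    max_retries: int = 1000,
) -> tuple:
    """Synthetic surface: background pattern plus planted conga chains.

    Parameters
    ----------
    background
        CsrParams or ThomasParams for the null background.
    n_chains
        Number of chains to plant.
    length_dist
        Chain lengths sampled uniformly from this tuple (default 3-6 points,
        the range of observed conga lines).
    spacing
        Inter-point spacing in metres: a scalar for fixed spacing or a
        (low, high) pair for uniform sampling per link.
    jitter_deg
        Each link bearing is the chain azimuth plus Uniform(-jitter, +jitter);
        consecutive-link bearing changes therefore never exceed 2 * jitter.

    Returns
    -------
    (SurfaceMap, CongaTruth)
        Background points first, then chain points in planting order; the
        truth record carries each chain's indices into the point array.
    """
    if n_chains < 0:
        raise InvalidParameterError("n_chains must be >= 0")
    if jitter_deg < 0:
        raise InvalidParameterError("jitter_deg must be >= 0")
    if np.isscalar(spacing):
        if spacing <= 0:
            raise InvalidParameterError("spacing must be positive")
        spacing_dist = lambda rng: float(spacing)  # noqa: E731
    else:
        lo, hi = spacing
        if not 0 < lo <= hi:
            raise InvalidParameterError("spacing band must satisfy 0 < lo <= hi")
        spacing_dist = lambda rng: float(rng.uniform(lo, hi))  # noqa: E731

    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    bg_seed, chain_seed = ss.spawn(2)
    bg = _simulate_background(background, window, np.random.default_rng(bg_seed))
    rng = np.random.default_rng(chain_seed)

    chain_pts, chains = [], []
    offset = bg.n
    for _ in range(n_chains):
        length = int(rng.choice(length_dist))
        pts, anchor, spacings, azimuth = _place_chain(
            window, length, spacing_dist, jitter_deg, rng, max_retries
        )
        chains.append(
            PlantedChain(
                anchor=(float(anchor[0]), float(anchor[1])),
                length=length,
                spacings=tuple(float(s) for s in spacings),
                azimuth_deg=float(azimuth % 360.0),
                jitter_deg=float(jitter_deg),
                indices=tuple(range(offset, offset + length)),
                points=pts,
            )
        )
        chain_pts.append(pts)
        offset += length

    all_pts = (
        np.vstack([bg.points] + chain_pts) if chain_pts else bg.points
    )
    surface = SurfaceMap(points=all_pts, window=window)
    return surface, CongaTruth(chains=tuple(chains), background=background)
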