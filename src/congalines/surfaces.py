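"""Geometry and data model for mapped fossil surfaces.

A mapped surface is a polygonal observation window (possibly with holes where
the rock is cracked or eroded), a set of specimen coordinates inside it, and
optional per-specimen marks (taxon, frond/stem dimensions, orientation).
Tectonic strain recorded by ovate holdfast discs can be estimated and removed
(retrodeformation) before any spatial statistics are computed.

Units are SI throughout: coordinates and lengths in metres, angles in degrees.

Boundary convention: a point exactly on the window exterior counts as inside
(closed exterior); a point exactly on a hole boundary also counts as inside
(open holes).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from shapely.geometry import Polygon

from .errors import (
    InsufficientDataError,
    InvalidMaskError,
    InvalidStrainError,
    InvalidWindowError,
)

__all__ = [
    "Window",
    "SurfaceMap",
    "StrainEstimate",
    "area",
    "estimate_strain",
    "retrodeform",
    "forward_stretch",
    "mask_holes",
]


def _as_ring(vertices) -> np.ndarray:
    ring = np.asarray(vertices, dtype=float)
    if ring.ndim != 2 or ring.shape[1] != 2 or ring.shape[0] < 3:
        raise InvalidWindowError(
            f"polygon ring needs >= 3 (x, y) vertices, got shape {ring.shape}"
        )
    return ring


@dataclass(frozen=True)
class Window:
    """Polygonal mapped region, possibly with holes (masked cracks/erosion).

    Parameters
    ----------
    exterior
        Ordered (n, 2) vertex array of the outer boundary, metres.
    holes
        Sequence of ordered vertex arrays, one per masked hole.
    """

    exterior: np.ndarray
    holes: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "exterior", _as_ring(self.exterior))
        object.__setattr__(
            self, "holes", tuple(_as_ring(h) for h in self.holes)
        )
        poly = Polygon(self.exterior, [h for h in self.holes])
        if not poly.is_valid:
            raise InvalidWindowError(
                f"invalid window polygon: {shapely.is_valid_reason(poly)}"
            )
        if poly.area <= 0:
            raise InvalidWindowError("window has zero area")
        object.__setattr__(self, "_polygon", poly)
        object.__setattr__(self, "_exterior_poly", Polygon(self.exterior))
        object.__setattr__(
            self, "_hole_polys", tuple(Polygon(h) for h in self.holes)
        )

    @property
    def polygon(self) -> Polygon:
        """Shapely polygon (exterior minus holes)."""
        return self._polygon

    @property
    def area(self) -> float:
        """Area in m^2: exterior minus holes."""
        return self._polygon.area

    @property
    def perimeter(self) -> float:
        """Length of the exterior boundary in metres."""
        return self._exterior_poly.exterior.length

    @property
    def bounds(self) -> tuple:
        """(xmin, ymin, xmax, ymax) of the exterior."""
        return self._exterior_poly.bounds

    @property
    def short_side(self) -> float:
        xmin, ymin, xmax, ymax = self.bounds
        return min(xmax - xmin, ymax - ymin)

    def contains(self, x, y) -> np.ndarray:
        """Vectorised membership test under the closed-exterior/open-holes rule."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        inside = shapely.intersects_xy(self._exterior_poly, x, y)
        for hp in self._hole_polys:
            inside &= ~shapely.contains_xy(hp, x, y)
        return inside

    def with_holes(self, extra_holes) -> "Window":
        """New window with additional holes subtracted."""
        hole_polys = [Polygon(_as_ring(h)) for h in extra_holes]
        for hp in hole_polys:
            if not self._exterior_poly.contains(hp):
                raise InvalidMaskError("mask hole not inside window exterior")
        geom = self._polygon
        for hp in hole_polys:
            geom = geom.difference(hp)
        if geom.geom_type != "Polygon":
            raise InvalidMaskError(
                f"masking split the window into a {geom.geom_type}"
            )
        ext = np.asarray(geom.exterior.coords)[:-1]
        holes = tuple(np.asarray(r.coords)[:-1] for r in geom.interiors)
        return Window(ext, holes)


def area(window: Window) -> float:
    """Window area in m^2 (exterior minus holes)."""
    return window.area


@dataclass(frozen=True)
class StrainEstimate:
    """Bulk tectonic strain: aspect ratio R >= 1 and stretch azimuth phi.

    ``phi_deg`` is the major-axis (stretch) direction, an orientation on
    [0, 180). ``phi_defined`` is False when R == 1, where the azimuth is
    meaningless.
    """

    R: float
    phi_deg: float
    phi_defined: bool = True

    def __post_init__(self):
        if not self.R >= 1.0:
            raise InvalidStrainError(f"aspect ratio R must be >= 1, got {self.R}")
        object.__setattr__(self, "phi_deg", float(self.phi_deg) % 180.0)


@dataclass(frozen=True)
class SurfaceMap:
    """Specimen point pattern on a mapped window, with optional marks and discs.

    ``points`` is (n, 2) in metres. ``marks`` is a dict of equal-length arrays
    (e.g. ``taxon``, ``orientation_deg``). ``discs`` is an (m, 5) array of
    fitted holdfast ellipses ``[cx, cy, a, b, azimuth_deg]`` with a >= b > 0,
    used for retrodeformation.
    """

    points: np.ndarray
    window: Window
    marks: dict = field(default_factory=dict)
    discs: np.ndarray | None = None

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "points", pts)
        if len(pts):
            ok = self.window.contains(pts[:, 0], pts[:, 1])
            if not ok.all():
                raise InvalidWindowError(
                    f"{(~ok).sum()} point(s) fall outside the window"
                )
        for name, arr in self.marks.items():
            if len(arr) != len(pts):
                raise ValueError(
                    f"mark {name!r} has length {len(arr)} != {len(pts)} points"
                )
        if self.discs is not None:
            discs = np.asarray(self.discs, dtype=float).reshape(-1, 5)
            if np.any(discs[:, 3] <= 0) or np.any(discs[:, 2] < discs[:, 3]):
                raise ValueError("disc semi-axes must satisfy a >= b > 0")
            object.__setattr__(self, "discs", discs)

    @property
    def n(self) -> int:
        return len(self.points)

    def __len__(self) -> int:
        return len(self.points)


def estimate_strain(discs) -> StrainEstimate:
    """Estimate bulk strain from ovate holdfast discs.

    R is the mean of the per-disc axis ratios a/b; the stretch azimuth is the
    circular mean (period 180 deg) of the major-axis azimuths, weighting each
    disc equally. Discs that were originally circular imply R = 1, in which
    case the azimuth is flagged undefined.
    """
    discs = np.asarray(discs, dtype=float).reshape(-1, 5)
    if len(discs) == 0:
        raise InsufficientDataError("strain estimation needs at least one disc")
    ratios = discs[:, 2] / discs[:, 3]
    R = float(np.mean(ratios))
    # orientation mean with period 180 deg: average the doubled angles
    ang2 = np.deg2rad(2.0 * discs[:, 4])
    s, c = np.sin(ang2).mean(), np.cos(ang2).mean()
    if np.hypot(s, c) < 1e-12 or np.allclose(ratios, 1.0):
        return StrainEstimate(max(R, 1.0), 0.0, phi_defined=False)
    phi = math.degrees(0.5 * math.atan2(s, c)) % 180.0
    return StrainEstimate(max(R, 1.0), phi)


def _strain_matrix(R: float, phi_deg: float, inverse: bool) -> np.ndarray:
    """Area-preserving pure-shear matrix: stretch sqrt(R) along phi.

    ``inverse=True`` gives the retrodeformation (compress along phi).
    """
    phi = math.radians(phi_deg)
    c, s = math.cos(phi), math.sin(phi)
    rot = np.array([[c, -s], [s, c]])
    sr = math.sqrt(R)
    scale = np.diag([1.0 / sr, sr] if inverse else [sr, 1.0 / sr])
    return rot @ scale @ rot.T


def _transform_ellipses(discs: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Map ellipses [cx, cy, a, b, az] through the linear map M (about origin)."""
    out = discs.copy()
    out[:, :2] = discs[:, :2] @ M.T
    for i, (a, b, az) in enumerate(discs[:, 2:5]):
        t = math.radians(az)
        Q = np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])
        # columns of M @ Q @ diag(a, b) span the image ellipse
        U, sv, _ = np.linalg.svd(M @ Q @ np.diag([a, b]))
        out[i, 2], out[i, 3] = sv[0], sv[1]
        out[i, 4] = math.degrees(math.atan2(U[1, 0], U[0, 0])) % 180.0
    return out


def _apply_linear(surface: SurfaceMap, M: np.ndarray) -> SurfaceMap:
    ext = surface.window.exterior @ M.T
    holes = tuple(h @ M.T for h in surface.window.holes)
    discs = (
        _transform_ellipses(surface.discs, M) if surface.discs is not None else None
    )
    return SurfaceMap(
        points=surface.points @ M.T,
        window=Window(ext, holes),
        marks=surface.marks,
        discs=discs,
    )


def retrodeform(surface: SurfaceMap, strain: StrainEstimate) -> SurfaceMap:
    """Remove tectonic strain by the area-preserving inverse pure shear.

    Coordinates are rotated so the stretch azimuth lies along +x, compressed
    by 1/sqrt(R) along it and expanded by sqrt(R) across it, then rotated
    back. Points, window vertices and disc ellipses all transform together;
    the window area (hence fitted intensity) is unchanged.
    """
    if not strain.R >= 1.0:
        raise InvalidStrainError(f"R must be >= 1, got {strain.R}")
    if strain.R == 1.0:
        return surface
    M = _strain_matrix(strain.R, strain.phi_deg, inverse=True)
    return _apply_linear(surface, M)


def forward_stretch(surface: SurfaceMap, strain: StrainEstimate) -> SurfaceMap:
    """Apply the tectonic stretch (the inverse of :func:`retrodeform`)."""
    if not strain.R >= 1.0:
        raise InvalidStrainError(f"R must be >= 1, got {strain.R}")
    if strain.R == 1.0:
        return surface
    M = _strain_matrix(strain.R, strain.phi_deg, inverse=False)
    return _apply_linear(surface, M)


def mask_holes(surface: SurfaceMap, hole_polygons) -> SurfaceMap:
    """Mask eroded patches: subtract hole polygons and drop covered points.

    Points strictly inside a hole are removed (open-holes convention); marks
    are filtered in step. Idempotent for a fixed hole set.
    """
    hole_polygons = list(hole_polygons)
    if not hole_polygons:
        return surface
    new_window = surface.window.with_holes(hole_polygons)
    keep = (
        new_window.contains(surface.points[:, 0], surface.points[:, 1])
        if len(surface.points)
        else np.zeros(0, dtype=bool)
    )
    marks = {k: np.asarray(v)[keep] for k, v in surface.marks.items()}
    return SurfaceMap(
        points=surface.points[keep],
        window=new_window,
        marks=marks,
        discs=surface.discs,
    )
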