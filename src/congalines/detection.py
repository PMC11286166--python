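"""Conga-line detection: three-point alignments and maximal chains.

A three-point alignment is an unordered triple (p1, p2, p3) with p2 in the
middle, both spacings at most r, and the bearing change between the two links
strictly less than theta. The triple count over a surface, as a function of
the search radius r, is the statistic compared against null-model
expectations.

Counting convention: triples are unordered — a chain traversed from either
end is the same geometric feature and is counted once. Overlapping triples
inside longer chains all count (a 4-point chain contributes 2), matching the
analytic expectation, which enumerates all consecutive triples. Distance
comparisons are inclusive (<= r), the angle comparison strict (< theta).

Neighbour search uses a k-d tree, so the cost is governed by the number of
near pairs rather than n^3; the output is identical to exhaustive
enumeration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import InvalidParameterError, UndefinedBearingError
from .surfaces import SurfaceMap

__all__ = [
    "AlignmentParams",
    "AlignmentResult",
    "bearing",
    "bearing_diff",
    "count_alignments",
    "assemble_chains",
]


@dataclass(frozen=True)
class AlignmentParams:
    """Search parameters: max spacing r (metres), max bearing change theta (deg)."""

    r: float
    theta_deg: float

    def __post_init__(self):
        if not self.r > 0:
            raise InvalidParameterError(f"r must be > 0, got {self.r}")
        if not 0 < self.theta_deg <= 180:
            raise InvalidParameterError(
                f"theta_deg must be in (0, 180], got {self.theta_deg}"
            )


@dataclass(frozen=True)
class AlignmentResult:
    """Detected alignments on one pattern at one (r, theta).

    triples : frozenset of (i, j, k) with j the middle point and i < k
    chains  : maximal chains (point-index tuples, length >= 3)
    chain_azimuths_deg : axis orientation of each chain (first-to-last
        bearing folded to [0, 180))
    """

    triples: frozenset
    chains: tuple
    chain_azimuths_deg: tuple
    params: AlignmentParams

    @property
    def count(self) -> int:
        """Number of three-point alignments."""
        return len(self.triples)


def bearing(p_a, p_b) -> float:
    """Bearing of p_b from p_a: degrees counterclockwise from +x, in [0, 360)."""
    dx = p_b[0] - p_a[0]
    dy = p_b[1] - p_a[1]
    if dx == 0.0 and dy == 0.0:
        raise UndefinedBearingError("bearing between coincident points")
    return math.degrees(math.atan2(dy, dx)) % 360.0


def bearing_diff(b: float, b_prime: float) -> float:
    """Minimal absolute circular difference of two bearings, in [0, 180]."""
    d = abs(b - b_prime) % 360.0
    return min(d, 360.0 - d)


def _points_of(pp) -> np.ndarray:
    if isinstance(pp, SurfaceMap):
        return pp.points
    return np.asarray(pp, dtype=float).reshape(-1, 2)


def count_alignments(pp, params: AlignmentParams) -> AlignmentResult:
    """Find every three-point alignment at (r, theta) and assemble chains.

    For each candidate middle point j, the two links point from p1 to j and
    from j to p3; the alignment condition |b' - b| < theta is equivalent to
    the two neighbours subtending an angle greater than 180 - theta at j.
    Coincident points never form a link (a link of zero length has no
    bearing), and p1 != p3.
    """
    pts = _points_of(pp)
    n = len(pts)
    if n < 3:
        return AlignmentResult(frozenset(), (), (), params)

    tree = cKDTree(pts)
    pairs = tree.query_pairs(params.r, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
        pairs = pairs[d > 0.0]  # coincident points cannot form a link

    # adjacency lists
    nbrs = [[] for _ in range(n)]
    for a, b in pairs:
        nbrs[a].append(b)
        nbrs[b].append(a)

    thresh = 180.0 - params.theta_deg
    triples = set()
    for j in range(n):
        nb = nbrs[j]
        m = len(nb)
        if m < 2:
            continue
        nb = np.array(nb)
        vec = pts[nb] - pts[j]
        ang = np.degrees(np.arctan2(vec[:, 1], vec[:, 0]))
        # pairwise separation angle between neighbour directions
        diff = np.abs(ang[:, None] - ang[None, :]) % 360.0
        diff = np.minimum(diff, 360.0 - diff)
        ii, kk = np.nonzero(np.triu(diff > thresh, k=1))
        for a, c in zip(nb[ii].tolist(), nb[kk].tolist()):
            if a != c:
                triples.add((min(a, c), j, max(a, c)))

    triples = frozenset(triples)
    chains = assemble_chains(triples)
    azimuths = tuple(
        bearing(pts[ch[0]], pts[ch[-1]]) % 180.0 for ch in chains
    )
    return AlignmentResult(triples, chains, azimuths, params)


def assemble_chains(triples) -> tuple:
    """Merge triples sharing a consecutive pair into maximal chains.

    (i, j, k) and (j, k, l) merge into (i, j, k, l). A chain is maximal when
    no triple extends it at either end; branching (two triples extending the
    same pair to different endpoints) yields separate chains sharing a
    prefix. Each geometric chain is reported once (reversals deduplicated).
    """
    if not triples:
        return ()
    directed = set()
    for i, j, k in triples:
        directed.add((i, j, k))
        directed.add((k, j, i))

    succ = {}
    pairs_with_pred = set()
    for a, b, c in directed:
        succ.setdefault((a, b), []).append(c)
        pairs_with_pred.add((b, c))
    for v in succ.values():
        v.sort()

    starts = [t for t in directed if (t[0], t[1]) not in pairs_with_pred]
    covered = set()
    chains = []

    def extend(path):
        tail = (path[-2], path[-1])
        exts = [
            c for c in succ.get(tail, ())
            if (tail[0], tail[1], c) in directed and c not in path
        ]
        if not exts:
            chains.append(tuple(path))
            return
        for c in exts:
            covered.add((tail[0], tail[1], c))
            extend(path + [c])

    for a, b, c in sorted(starts):
        covered.add((a, b, c))
        extend([a, b, c])
    # cycles (no triple without a predecessor) — cover leftovers
    for t in sorted(directed):
        if t not in covered:
            covered.add(t)
            extend(list(t))

    seen = set()
    out = []
    for ch in chains:
        key = min(ch, ch[::-1])
        if key not in seen:
            seen.add(key)
            out.append(tuple(key))
    return tuple(out)
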