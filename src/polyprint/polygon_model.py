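"""Per-minutia polygon descriptors.

Each validated minutia is represented by the set of all valid n-vertex
polygons whose vertices are neighboring minutiae. A polygon is encoded
as a fixed-length vector of n edge lengths (pixels) and n central angles
(degrees, subtended at the reference), canonically rotated so the
longest edge comes first — which makes the vector invariant to rotation
and translation of the whole print.

Angles are measured counter-clockwise from the positive x axis
(x = column, y = row); mirror reflections change descriptors, rigid
motions do not.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .minutiae import Minutia, MinutiaSet

_TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class ModelParams:
    """Polygon construction parameters: vertex count and radius search."""

    n: int = 5
    r_step: float = 5.0
    r_max: float = 120.0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("n must be >= 3")
        if not (0 < self.r_step <= self.r_max):
            raise ValueError("require 0 < r_step <= r_max")


@dataclass(frozen=True)
class Polygon:
    """n vertices ordered counter-clockwise by angle around the reference."""

    reference: Minutia
    vertices: tuple[Minutia, ...]


@dataclass(frozen=True)
class PolygonDescriptor:
    """Canonical (edges, angles) vector; edges[0] is the largest edge."""

    edges: tuple[float, ...]
    angles: tuple[float, ...]

    @property
    def vector(self) -> np.ndarray:
        return np.array(self.edges + self.angles, dtype=float)

    def __len__(self) -> int:
        return 2 * len(self.edges)


@dataclass
class MinutiaModel:
    """A minutia plus its polygon descriptors (none => unregistered)."""

    minutia: Minutia
    descriptors: list[PolygonDescriptor]

    @property
    def registered(self) -> bool:
        return bool(self.descriptors)

    def descriptor_matrix(self) -> np.ndarray:
        """(num_descriptors, 2n) stacked vectors, cached for matching."""
        cached = getattr(self, "_matrix", None)
        if cached is None or cached.shape[0] != len(self.descriptors):
            cached = np.stack([d.vector for d in self.descriptors])
            object.__setattr__(self, "_matrix", cached)
        return cached


@dataclass
class FingerprintModel:
    """All registered minutiae of one print."""

    registered: list[MinutiaModel]
    params: ModelParams
    meta: dict | None = None

    def __len__(self) -> int:
        return len(self.registered)


def _quadrant(dx: float, dy: float) -> int:
    """Axis-aligned quadrant index around the reference.

    0: +x/+y, 1: -x/+y, 2: -x/-y, 3: +x/-y; points exactly on an axis
    go to the lower-index adjacent quadrant.
    """
    if dy == 0:
        return 0 if dx > 0 else 1
    if dx == 0:
        return 0 if dy > 0 else 2
    if dx > 0:
        return 0 if dy > 0 else 3
    return 1 if dy > 0 else 2


def find_neighbors(
    ref: Minutia, s: MinutiaSet, p: ModelParams
) -> list[Minutia] | None:
    """Grow a circle around ``ref`` until enough well-spread neighbors appear.

    The radius increases in steps of ``r_step``. The first radius holding
    at least n+2 neighbors with every quadrant occupied wins. If ``r_max``
    is reached without that, the within-r_max set is accepted whenever it
    has at least n members (quadrant condition waived); otherwise None —
    the minutia stays unregistered.
    """
    others = [m for m in s if m.xy != ref.xy]
    if not others:
        return None
    d = np.array([math.hypot(m.x - ref.x, m.y - ref.y) for m in others])
    quad = np.array([_quadrant(m.x - ref.x, m.y - ref.y) for m in others])

    r = p.r_step
    while r <= p.r_max + 1e-9:
        within = d <= r
        if within.sum() >= p.n + 2 and len(set(quad[within].tolist())) == 4:
            return [m for m, w in zip(others, within) if w]
        r += p.r_step
    within = d <= p.r_max
    if within.sum() >= p.n:
        return [m for m, w in zip(others, within) if w]
    return None


def order_vertices(ref: Minutia, subset) -> Polygon | None:
    """Sort vertices counter-clockwise around ``ref``; None if invalid.

    For angularly sorted vertices the polygon is simple and strictly
    contains the reference iff every angular gap between consecutive
    vertices is below 180 degrees. Duplicate angles (two vertices seen
    from the reference along the same ray) are degenerate.
    """
    angles = []
    for v in subset:
        dx, dy = v.x - ref.x, v.y - ref.y
        if dx == 0 and dy == 0:
            return None
        angles.append(math.atan2(dy, dx) % _TWO_PI)
    order = sorted(range(len(subset)), key=lambda i: angles[i])
    sorted_angles = [angles[i] for i in order]
    for a, b in zip(sorted_angles, sorted_angles[1:]):
        if math.isclose(a, b, abs_tol=1e-12):
            return None
    gaps = [
        (sorted_angles[(i + 1) % len(order)] - sorted_angles[i]) % _TWO_PI
        for i in range(len(order))
    ]
    if max(gaps) >= math.pi:
        return None
    verts = tuple(subset[i] for i in order)
    return Polygon(reference=ref, vertices=verts)


def describe_polygon(poly: Polygon) -> PolygonDescriptor:
    """Edge lengths and central angles in canonical cyclic rotation.

    edges[i] is the distance between consecutive vertices, angles[i] the
    angle at the reference between the same vertex pair (degrees). The
    cycle is rotated so the largest edge leads; ties pick the
    lexicographically largest (edges, angles) rotation.
    """
    ref = poly.reference
    verts = poly.vertices
    k = len(verts)
    edges = []
    angs = []
    for i in range(k):
        a, b = verts[i], verts[(i + 1) % k]
        edges.append(math.hypot(b.x - a.x, b.y - a.y))
        ta = math.atan2(a.y - ref.y, a.x - ref.x)
        tb = math.atan2(b.y - ref.y, b.x - ref.x)
        angs.append(math.degrees((tb - ta) % _TWO_PI))

    best = None
    max_edge = max(edges)
    for r in range(k):
        if edges[r] == max_edge:
            cand = (
                tuple(edges[r:] + edges[:r]),
                tuple(angs[r:] + angs[:r]),
            )
            if best is None or cand > best:
                best = cand
    return PolygonDescriptor(edges=best[0], angles=best[1])


def build_model(s: MinutiaSet, p: ModelParams) -> FingerprintModel:
    """Represent every minutia by all valid n-gons over its neighbor set."""
    registered: list[MinutiaModel] = []
    for ref in s:
        neigh = find_neighbors(ref, s, p)
        if neigh is None or len(neigh) < p.n:
            continue
        descriptors = []
        for subset in combinations(neigh, p.n):
            poly = order_vertices(ref, subset)
            if poly is not None:
                descriptors.append(describe_polygon(poly))
        if descriptors:
            registered.append(MinutiaModel(minutia=ref, descriptors=descriptors))
    if not registered:
        warnings.warn("no minutia could be registered", stacklevel=2)
    return FingerprintModel(registered=registered, params=p)
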