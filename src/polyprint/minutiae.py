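"""Minutiae extraction via Crossing Numbers and three-stage validation.

A minutia is a ridge ending (termination) or a ridge fork (bifurcation)
found on a one-pixel-wide skeleton. Raw extractions are cleaned in three
steps: a minimum same-type distance ``delta``, a convex-hull region of
interest eroded inward by ``gamma`` pixels, and replacement of tight
minutiae clouds by their centroid.

Coordinate convention: 0-based, ``x`` = column index, ``y`` = row index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform
from shapely.geometry import Point, Polygon as ShapelyPolygon

TERMINATION = "termination"
BIFURCATION = "bifurcation"
AVERAGED = "averaged"

_TYPES = frozenset({TERMINATION, BIFURCATION, AVERAGED})

# Cyclic 8-neighborhood order: down the left column, across the bottom,
# up the right column, across the top — (row, col) offsets from center.
_CYCLE = [(-1, -1), (0, -1), (1, -1), (1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0)]


@dataclass(frozen=True)
class Minutia:
    """A labeled feature point: integer pixel at extraction, real after averaging."""

    x: float
    y: float
    mtype: str

    def __post_init__(self) -> None:
        if self.mtype not in _TYPES:
            raise ValueError(f"unknown minutia type {self.mtype!r}")

    @property
    def xy(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass
class MinutiaSet:
    """An ordered collection of minutiae with source-image dimensions."""

    minutiae: list[Minutia]
    width: int = 0
    height: int = 0
    provenance: str = "raw"

    def __len__(self) -> int:
        return len(self.minutiae)

    def __iter__(self):
        return iter(self.minutiae)

    def __getitem__(self, i: int) -> Minutia:
        return self.minutiae[i]

    def coords(self) -> np.ndarray:
        """(k, 2) array of (x, y) coordinates."""
        if not self.minutiae:
            return np.empty((0, 2), dtype=float)
        return np.array([(m.x, m.y) for m in self.minutiae], dtype=float)


@dataclass(frozen=True)
class ValidationParams:
    """Thresholds for the three validation stages, all in pixels."""

    delta: float = 10.0
    gamma: float = 10.0
    cloud_radius: float | None = None  # defaults to delta

    def __post_init__(self) -> None:
        if self.delta < 0 or self.gamma < 0:
            raise ValueError("delta and gamma must be >= 0")
        if self.cloud_radius is not None and self.cloud_radius < 0:
            raise ValueError("cloud_radius must be >= 0")

    @property
    def effective_cloud_radius(self) -> float:
        return self.delta if self.cloud_radius is None else self.cloud_radius


def crossing_number(neigh: np.ndarray) -> int:
    """Crossing number of the center pixel of a 3x3 binary neighborhood.

    Half the sum of absolute differences between consecutive neighbors
    in the cyclic 8-neighborhood order; equivalently the number of
    0-to-1 transitions around the ring. Value 1 marks a termination,
    2 a middle ridge point, 3 a bifurcation.
    """
    neigh = np.asarray(neigh)
    if neigh.shape != (3, 3):
        raise ValueError("neighborhood must be 3x3")
    ring = [int(bool(neigh[1 + dr, 1 + dc])) for dr, dc in _CYCLE]
    total = sum(abs(ring[i] - ring[(i + 1) % 8]) for i in range(8))
    return total // 2


def extract_minutiae(skel) -> MinutiaSet:
    """Extract raw minutiae from a unit-width skeleton.

    Every interior ridge pixel with crossing number 1 is emitted as a
    termination and 3 as a bifurcation; border pixels are excluded.
    Accepts a binary array or any object with a ``pixels`` attribute.
    """
    pixels = getattr(skel, "pixels", skel)
    img = np.asarray(pixels).astype(bool)
    h, w = img.shape
    padded = img.astype(np.int8)

    # transition count via shifted views over the interior
    ring = [padded[1 + dr : h - 1 + dr, 1 + dc : w - 1 + dc] for dr, dc in _CYCLE]
    cn = sum(np.abs(ring[i] - ring[(i + 1) % 8]) for i in range(8)) // 2

    interior = img[1:-1, 1:-1]
    out: list[Minutia] = []
    ys, xs = np.nonzero(interior)
    for r, c in zip(ys.tolist(), xs.tolist()):
        v = int(cn[r, c])
        if v == 1:
            out.append(Minutia(float(c + 1), float(r + 1), TERMINATION))
        elif v == 3:
            out.append(Minutia(float(c + 1), float(r + 1), BIFURCATION))
    return MinutiaSet(out, width=w, height=h, provenance="raw")


def filter_same_type_distance(s: MinutiaSet, delta: float) -> MinutiaSet:
    """Remove both members of every same-type pair closer than ``delta``."""
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if delta == 0 or len(s) < 2:
        return replace(s, minutiae=list(s.minutiae))
    coords = s.coords()
    dist = squareform(pdist(coords))
    drop = np.zeros(len(s), dtype=bool)
    for i in range(len(s)):
        for j in range(i + 1, len(s)):
            if s[i].mtype == s[j].mtype and dist[i, j] < delta:
                drop[i] = drop[j] = True
    kept = [m for m, d in zip(s.minutiae, drop) if not d]
    return replace(s, minutiae=kept)


def _cross(o, a, b) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def convex_hull(points) -> list[tuple[float, float]]:
    """Counter-clockwise convex hull by incremental insertion in sorted order.

    Points are added one at a time in lexicographic order while the lower
    and upper chains are maintained; collinear boundary points are not
    kept as vertices. Raises ``ValueError("degenerate hull")`` for fewer
    than 3 points or an all-collinear input.
    """
    pts = sorted({(float(p[0]), float(p[1])) for p in points})
    if len(pts) < 3:
        raise ValueError("degenerate hull")
    lower: list[tuple[float, float]] = []
    for p in pts:
        while len(lower) >= 2 and _cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list[tuple[float, float]] = []
    for p in reversed(pts):
        while len(upper) >= 2 and _cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = lower[:-1] + upper[:-1]
    if len(hull) < 3:
        raise ValueError("degenerate hull")
    return hull


def roi_filter(s: MinutiaSet, gamma: float) -> MinutiaSet:
    """Keep minutiae at least ``gamma`` pixels inside the convex hull.

    Equivalent to eroding the hull polygon by a disk of radius gamma and
    keeping the minutiae the eroded region still covers. With gamma = 0
    every minutia (hull vertices included) is kept.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    if gamma == 0:
        return replace(s, minutiae=list(s.minutiae))
    hull = convex_hull([m.xy for m in s])
    poly = ShapelyPolygon(hull)
    boundary = poly.exterior
    kept = [
        m
        for m in s
        if poly.covers(Point(m.x, m.y)) and boundary.distance(Point(m.x, m.y)) >= gamma
    ]
    if not kept:
        warnings.warn("ROI erosion removed every minutia", stacklevel=2)
    return replace(s, minutiae=kept)


def merge_clouds(s: MinutiaSet, cloud_radius: float) -> MinutiaSet:
    """Replace clusters of mutually close minutiae by their centroid.

    Connected components of the proximity graph (any pair closer than
    ``cloud_radius``, regardless of type) with two or more members
    collapse to a single ``averaged`` minutia at the component centroid.
    """
    if cloud_radius < 0:
        raise ValueError("cloud_radius must be >= 0")
    if cloud_radius == 0 or len(s) < 2:
        return replace(s, minutiae=list(s.minutiae))
    coords = s.coords()
    dist = squareform(pdist(coords))
    close = (dist < cloud_radius) & ~np.eye(len(s), dtype=bool)
    graph = coo_matrix(close)
    n_comp, labels = connected_components(graph, directed=False)

    # emit components ordered by their smallest member index
    first_idx = {}
    for i, lab in enumerate(labels):
        first_idx.setdefault(int(lab), i)
    out: list[Minutia] = []
    for lab in sorted(first_idx, key=first_idx.get):
        members = np.nonzero(labels == lab)[0]
        if len(members) == 1:
            out.append(s[int(members[0])])
        else:
            cx, cy = coords[members].mean(axis=0)
            out.append(Minutia(float(cx), float(cy), AVERAGED))
    return replace(s, minutiae=out)


def validate(s_raw: MinutiaSet, p: ValidationParams) -> MinutiaSet:
    """Apply the three validation stages in order: delta, ROI, clouds."""
    s = filter_same_type_distance(s_raw, p.delta)
    s = roi_filter(s, p.gamma)
    s = merge_clouds(s, p.effective_cloud_radius)
    s.provenance = "validated"
    return s
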