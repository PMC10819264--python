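"""Minutia and fingerprint matching.

Two minutiae match when their closest pair of polygon descriptors (by
plain Euclidean distance over the 2n-vector) survives an element-wise
error test: each slot passes if its relative error is within ``th_rel``
percent OR its absolute difference is within ``th_l`` pixels (edges) /
``th_a`` degrees (angles). Two fingerprints match when at least ``tmc``
minutiae can be put in one-to-one correspondence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .polygon_model import FingerprintModel, MinutiaModel, PolygonDescriptor


@dataclass(frozen=True)
class MatchParams:
    th_rel: float = 11.0  # relative error, percent
    th_l: float = 5.0  # absolute edge error, pixels
    th_a: float = 10.0  # absolute angle error, degrees
    tmc: float = 12  # minimum matched-minutiae count

    def __post_init__(self) -> None:
        if min(self.th_rel, self.th_l, self.th_a, self.tmc) < 0:
            raise ValueError("all match thresholds must be >= 0")


@dataclass(frozen=True)
class MinutiaMatch:
    index_a: int
    index_b: int
    poly_a: int
    poly_b: int
    distance: float
    validated: bool


@dataclass
class MatchResult:
    matches: list[MinutiaMatch]
    decision: bool
    params: MatchParams

    @property
    def matched_count(self) -> int:
        return len(self.matches)


def polygon_distance(d1: PolygonDescriptor, d2: PolygonDescriptor) -> float:
    """Euclidean norm of the element-wise descriptor difference (unweighted)."""
    if len(d1.edges) != len(d2.edges):
        raise ValueError("descriptor length mismatch")
    return float(np.linalg.norm(d1.vector - d2.vector))


def _relative_error(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    denom = np.maximum(a, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = 100.0 * np.abs(a - b) / denom
    return np.where(denom == 0, 0.0, rel)


def validate_pair(
    d1: PolygonDescriptor, d2: PolygonDescriptor, p: MatchParams
) -> bool:
    """Element-wise OR of relative and absolute error criteria on all slots."""
    if len(d1.edges) != len(d2.edges):
        raise ValueError("descriptor length mismatch")
    e1, e2 = np.array(d1.edges), np.array(d2.edges)
    a1, a2 = np.array(d1.angles), np.array(d2.angles)
    edges_ok = (_relative_error(e1, e2) <= p.th_rel) | (np.abs(e1 - e2) <= p.th_l)
    angles_ok = (_relative_error(a1, a2) <= p.th_rel) | (np.abs(a1 - a2) <= p.th_a)
    return bool(edges_ok.all() and angles_ok.all())


def match_minutia(
    ma: MinutiaModel, mb: MinutiaModel, p: MatchParams
) -> MinutiaMatch:
    """Best descriptor pair by Euclidean distance; only that pair is validated."""
    va = ma.descriptor_matrix()
    vb = mb.descriptor_matrix()
    if va.shape[1] != vb.shape[1]:
        raise ValueError("descriptor length mismatch")
    # squared distances between all descriptor pairs
    d2 = (
        (va**2).sum(axis=1)[:, None]
        + (vb**2).sum(axis=1)[None, :]
        - 2.0 * va @ vb.T
    )
    i, j = np.unravel_index(int(np.argmin(d2)), d2.shape)
    dist = polygon_distance(ma.descriptors[i], mb.descriptors[j])
    ok = validate_pair(ma.descriptors[i], mb.descriptors[j], p)
    return MinutiaMatch(-1, -1, int(i), int(j), dist, ok)


def match_fingerprints(
    a: FingerprintModel, b: FingerprintModel, p: MatchParams
) -> MatchResult:
    """Greedy one-to-one assignment of validated minutia matches.

    Candidates (validated best-polygon pairs over all registered minutia
    pairs) are consumed in ascending descriptor distance; decision is
    matched_count >= tmc.
    """
    if len(a) == 0 or len(b) == 0:
        warnings.warn("matching against an empty model", stacklevel=2)
        return MatchResult(matches=[], decision=False, params=p)
    candidates: list[MinutiaMatch] = []
    for ia, ma in enumerate(a.registered):
        for ib, mb in enumerate(b.registered):
            m = match_minutia(ma, mb, p)
            if m.validated:
                candidates.append(
                    MinutiaMatch(ia, ib, m.poly_a, m.poly_b, m.distance, True)
                )
    candidates.sort(key=lambda m: (m.distance, m.index_a, m.index_b))
    used_a: set[int] = set()
    used_b: set[int] = set()
    kept: list[MinutiaMatch] = []
    for m in candidates:
        if m.index_a in used_a or m.index_b in used_b:
            continue
        used_a.add(m.index_a)
        used_b.add(m.index_b)
        kept.append(m)
    return MatchResult(matches=kept, decision=len(kept) >= p.tmc, params=p)
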