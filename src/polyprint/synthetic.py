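"""Synthetic inputs: minutia point patterns, oriented ridge images, and
FVC-style genuine/impostor benchmarks.

Point sets are scattered with a minimum pairwise spacing so that
validation is a no-op on the unperturbed pattern; perturbation applies a
rigid transform (rotation about the image center, then translation)
followed by Gaussian jitter, random dropout and spurious insertions.
All randomness flows from an explicit seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .evaluation import GENUINE, IMPOSTOR, SweepCurve, confusion, metrics, sweep_tmc
from .matching import MatchParams, match_fingerprints
from .minutiae import (
    BIFURCATION,
    TERMINATION,
    Minutia,
    MinutiaSet,
    ValidationParams,
    validate,
)
from .polygon_model import ModelParams, build_model

MIN_SPACING = 20.0  # 2x the default same-type distance delta


@dataclass(frozen=True)
class SyntheticParams:
    k: int = 30
    extent: float = 300.0
    termination_fraction: float = 0.5
    jitter_sigma: float = 0.0
    drop_rate: float = 0.0
    spurious_rate: float = 0.0
    rotation: float = 0.0  # degrees, about the extent center
    translation: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("termination_fraction", "drop_rate", "spurious_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.k < 1 or self.extent <= 0 or self.jitter_sigma < 0:
            raise ValueError("invalid synthetic parameters")


@dataclass(frozen=True)
class BenchmarkSpec:
    num_fingers: int = 20
    impressions_per_finger: int = 2
    base: SyntheticParams = field(default_factory=SyntheticParams)
    # perturbation applied to every impression after the first
    jitter_sigma: float = 0.0
    drop_rate: float = 0.0
    spurious_rate: float = 0.0
    rotation: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.num_fingers < 2 or self.impressions_per_finger < 2:
            raise ValueError("need >= 2 fingers and >= 2 impressions")


def _scatter(rng: np.random.Generator, k: int, extent: float, margin: float) -> np.ndarray:
    """Uniform points with minimum pairwise spacing, by bounded rejection."""
    pts: list[tuple[float, float]] = []
    attempts = 0
    limit = 2000 * k
    while len(pts) < k:
        attempts += 1
        if attempts > limit:
            raise RuntimeError(
                f"could not place {k} points with spacing {MIN_SPACING} in extent {extent}"
            )
        x = rng.uniform(margin, extent - margin)
        y = rng.uniform(margin, extent - margin)
        if all((x - px) ** 2 + (y - py) ** 2 >= MIN_SPACING**2 for px, py in pts):
            pts.append((x, y))
    return np.array(pts)


def generate_minutia_set(p: SyntheticParams) -> MinutiaSet:
    """Scatter k labeled minutiae with spacing 2*delta (validation no-op)."""
    rng = np.random.default_rng(p.seed)
    margin = min(0.05 * p.extent, MIN_SPACING)
    pts = _scatter(rng, p.k, p.extent, margin)
    n_term = int(round(p.termination_fraction * p.k))
    out = []
    for idx, (x, y) in enumerate(pts):
        mtype = TERMINATION if idx < n_term else BIFURCATION
        out.append(Minutia(float(x), float(y), mtype))
    return MinutiaSet(out, width=int(p.extent), height=int(p.extent), provenance="raw")


def rigid_transform(
    coords: np.ndarray, rotation_deg: float, translation, center: float
) -> np.ndarray:
    """Rotate about (center, center) then translate; returns new (k, 2)."""
    th = math.radians(rotation_deg)
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    c = np.array([center, center])
    return (coords - c) @ rot.T + c + np.asarray(translation, dtype=float)


def perturb(s: MinutiaSet, p: SyntheticParams) -> MinutiaSet:
    """Rigid transform, then jitter, dropout and spurious insertions."""
    rng = np.random.default_rng(p.seed)
    coords = s.coords()
    if len(s):
        coords = rigid_transform(coords, p.rotation, p.translation, p.extent / 2.0)
        if p.jitter_sigma > 0:
            coords = coords + rng.normal(0.0, p.jitter_sigma, size=coords.shape)
    keep = rng.uniform(size=len(s)) >= p.drop_rate if len(s) else np.array([], bool)
    out = [
        Minutia(float(x), float(y), m.mtype)
        for (x, y), m, k in zip(coords, s.minutiae, keep)
        if k
    ]
    n_spur = int(round(p.spurious_rate * p.k))
    existing = [(m.x, m.y) for m in out]
    placed = 0
    attempts = 0
    while placed < n_spur and attempts < 2000 * max(n_spur, 1):
        attempts += 1
        x = rng.uniform(0, p.extent)
        y = rng.uniform(0, p.extent)
        if all((x - px) ** 2 + (y - py) ** 2 >= MIN_SPACING**2 for px, py in existing):
            mtype = TERMINATION if rng.uniform() < p.termination_fraction else BIFURCATION
            out.append(Minutia(float(x), float(y), mtype))
            existing.append((x, y))
            placed += 1
    return replace(s, minutiae=out)


def generate_ridge_image(
    orientation: float,
    wavelength: float,
    extent: int = 256,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Sinusoidal plane-wave ridge pattern with known ground truth.

    Ridges run along ``orientation`` degrees from the +x axis; intensity
    varies along the normal with the given wavelength. Returns the image
    and a metadata dict with the ground-truth orientation/frequency.
    """
    if not 3.0 <= wavelength <= 25.0:
        raise ValueError("wavelength must be in [3, 25] pixels")
    th = math.radians(orientation)
    ys, xs = np.mgrid[0:extent, 0:extent].astype(float)
    phase = 2.0 * np.pi / wavelength * (-xs * math.sin(th) + ys * math.cos(th))
    img = np.cos(phase)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    meta = {
        "orientation_deg": orientation % 180.0,
        "wavelength": wavelength,
        "frequency": 1.0 / wavelength,
        "noise_sigma": noise_sigma,
        "seed": seed,
    }
    return img, meta


def _impression_params(spec: BenchmarkSpec, finger: int, imp: int, seed: int) -> SyntheticParams:
    # deterministic per-impression sub-seed
    sub = seed * 1_000_003 + finger * 1009 + imp
    if imp == 0:
        return replace(spec.base, seed=sub, jitter_sigma=0.0, drop_rate=0.0,
                       spurious_rate=0.0, rotation=0.0, translation=(0.0, 0.0))
    return replace(
        spec.base,
        seed=sub,
        jitter_sigma=spec.jitter_sigma,
        drop_rate=spec.drop_rate,
        spurious_rate=spec.spurious_rate,
        rotation=spec.rotation,
        translation=spec.translation,
    )


def run_benchmark(
    spec: BenchmarkSpec,
    model_params: ModelParams | None = None,
    match_params: MatchParams | None = None,
    validation_params: ValidationParams | None = None,
    seed: int = 0,
) -> dict:
    """Full synthetic evaluation loop, fully seeded.

    Builds every impression (first one unperturbed, the rest perturbed),
    validates and models it, runs all genuine (same finger) and impostor
    (first impressions of different fingers) comparisons, and returns a
    JSON-serializable report with confusion metrics at the configured
    TMC plus the FMR/FNMR sweep and EER.
    """
    mp = model_params or ModelParams()
    qp = match_params or MatchParams()
    vp = validation_params or ValidationParams()

    models = {}
    for f in range(spec.num_fingers):
        base = generate_minutia_set(
            replace(spec.base, seed=seed * 7919 + f)
        )
        for imp in range(spec.impressions_per_finger):
            pparams = _impression_params(spec, f, imp, seed)
            s = perturb(base, pparams)
            s = validate(s, vp)
            models[(f, imp)] = build_model(s, mp)

    labels: list[str] = []
    counts: list[int] = []
    pairs: list[tuple] = []
    for f in range(spec.num_fingers):
        for i in range(spec.impressions_per_finger):
            for j in range(i + 1, spec.impressions_per_finger):
                res = match_fingerprints(models[(f, i)], models[(f, j)], qp)
                labels.append(GENUINE)
                counts.append(res.matched_count)
                pairs.append(((f, i), (f, j)))
    for f1 in range(spec.num_fingers):
        for f2 in range(f1 + 1, spec.num_fingers):
            res = match_fingerprints(models[(f1, 0)], models[(f2, 0)], qp)
            labels.append(IMPOSTOR)
            counts.append(res.matched_count)
            pairs.append(((f1, 0), (f2, 0)))

    decisions = [c >= qp.tmc for c in counts]
    conf = confusion(decisions, labels)
    rep = metrics(conf)
    genuine_counts = [c for c, lab in zip(counts, labels) if lab == GENUINE]
    impostor_counts = [c for c, lab in zip(counts, labels) if lab == IMPOSTOR]
    curve = sweep_tmc(genuine_counts, impostor_counts)
    return {
        "spec": {
            "num_fingers": spec.num_fingers,
            "impressions_per_finger": spec.impressions_per_finger,
            "jitter_sigma": spec.jitter_sigma,
            "drop_rate": spec.drop_rate,
            "spurious_rate": spec.spurious_rate,
            "rotation": spec.rotation,
            "translation": list(spec.translation),
            "seed": seed,
        },
        "counts": {
            "genuine": genuine_counts,
            "impostor": impostor_counts,
        },
        "confusion": {"tp": conf.tp, "fp": conf.fp, "tn": conf.tn, "fn": conf.fn},
        "metrics": {
            "precision": rep.precision,
            "recall": rep.recall,
            "f1": rep.f1,
            "fmr": rep.fmr,
            "fnmr": rep.fnmr,
        },
        "sweep": {
            "thresholds": curve.thresholds.tolist(),
            "fmr": curve.fmr.tolist(),
            "fnmr": curve.fnmr.tolist(),
            "eer": curve.eer,
            "eer_threshold": curve.eer_threshold,
        },
    }
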