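"""File formats and configuration.

Templates are plain text (one minutia per line: ``x y type`` with type
T/B/A and a ``# width height`` header); models are JSON; config is YAML
with validated defaults.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .minutiae import AVERAGED, BIFURCATION, TERMINATION, Minutia, MinutiaSet
from .polygon_model import (
    FingerprintModel,
    MinutiaModel,
    ModelParams,
    PolygonDescriptor,
)

_TYPE_CODE = {TERMINATION: "T", BIFURCATION: "B", AVERAGED: "A"}
_CODE_TYPE = {v: k for k, v in _TYPE_CODE.items()}


@dataclass
class Config:
    """All pipeline parameters with the tuned defaults."""

    block_size: int = 16
    smooth_sigma: float = 1.0
    variance_threshold: float = 0.1
    delta: float = 10.0
    gamma: float = 10.0
    cloud_radius: float | None = None
    n: int = 5
    r_step: float = 5.0
    r_max: float = 120.0
    th_rel: float = 11.0
    th_l: float = 5.0
    th_a: float = 10.0
    tmc: float = 12
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            ("block_size", self.block_size >= 4),
            ("smooth_sigma", self.smooth_sigma >= 0),
            ("variance_threshold", self.variance_threshold >= 0),
            ("delta", self.delta >= 0),
            ("gamma", self.gamma >= 0),
            ("cloud_radius", self.cloud_radius is None or self.cloud_radius >= 0),
            ("n", self.n >= 3),
            ("r_step", 0 < self.r_step <= self.r_max),
            ("th_rel", self.th_rel >= 0),
            ("th_l", self.th_l >= 0),
            ("th_a", self.th_a >= 0),
            ("tmc", self.tmc >= 0),
        ]
        for key, ok in checks:
            if not ok:
                raise ValueError(f"config value out of range: {key}")


def load_config(path) -> Config:
    """YAML config with defaults; unknown keys warn, bad values error."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must hold a mapping")
    known = {f.name for f in fields(Config)}
    unknown = set(raw) - known
    if unknown:
        warnings.warn(f"ignoring unknown config keys: {sorted(unknown)}", stacklevel=2)
    return Config(**{k: v for k, v in raw.items() if k in known})


def read_image(path) -> np.ndarray:
    """8-bit grayscale pixel grid from TIFF/PNG/BMP; RGB is luminance-converted."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"image not found: {p}")
    try:
        with Image.open(p) as im:
            if getattr(im, "n_frames", 1) > 1:
                raise ValueError(f"multi-page image not supported: {p}")
            return np.asarray(im.convert("L"), dtype=np.uint8)
    except FileNotFoundError:
        raise
    except ValueError:
        raise
    except Exception as exc:  # undecodable
        raise ValueError(f"cannot read image {p}: {exc}") from exc


def write_skeleton(path, skel) -> None:
    pixels = getattr(skel, "pixels", skel)
    Image.fromarray((np.asarray(pixels, bool) * 255).astype(np.uint8)).save(path)


def write_template(path, s: MinutiaSet) -> None:
    lines = [f"# {s.width} {s.height}"]
    for m in s:
        lines.append(f"{m.x:.6f} {m.y:.6f} {_TYPE_CODE[m.mtype]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_template(path) -> MinutiaSet:
    text = Path(path).read_text()
    width = height = 0
    minutiae: list[Minutia] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if len(parts) == 2:
                width, height = int(parts[0]), int(parts[1])
            continue
        parts = line.split()
        if len(parts) != 3 or parts[2] not in _CODE_TYPE:
            raise ValueError(f"malformed template line {lineno}: {line!r}")
        try:
            x, y = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise ValueError(f"malformed template line {lineno}: {line!r}") from exc
        minutiae.append(Minutia(x, y, _CODE_TYPE[parts[2]]))
    return MinutiaSet(minutiae, width=width, height=height, provenance="raw")


def template_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_model(path, model: FingerprintModel) -> None:
    doc = {
        "params": {
            "n": model.params.n,
            "r_step": model.params.r_step,
            "r_max": model.params.r_max,
        },
        "meta": model.meta or {},
        "minutiae": [
            {
                "x": mm.minutia.x,
                "y": mm.minutia.y,
                "type": _TYPE_CODE[mm.minutia.mtype],
                "descriptors": [
                    list(d.edges) + list(d.angles) for d in mm.descriptors
                ],
            }
            for mm in model.registered
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_model(path) -> FingerprintModel:
    doc = json.loads(Path(path).read_text())
    params = ModelParams(**doc["params"])
    registered = []
    for entry in doc["minutiae"]:
        vec_len = 2 * params.n
        descs = []
        for vec in entry["descriptors"]:
            if len(vec) != vec_len:
                raise ValueError("descriptor length does not match model n")
            descs.append(
                PolygonDescriptor(
                    edges=tuple(vec[: params.n]), angles=tuple(vec[params.n :])
                )
            )
        registered.append(
            MinutiaModel(
                minutia=Minutia(entry["x"], entry["y"], _CODE_TYPE[entry["type"]]),
                descriptors=descs,
            )
        )
    return FingerprintModel(registered=registered, params=params, meta=doc.get("meta"))
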