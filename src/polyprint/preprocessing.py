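"""Fingerprint enhancement: from a raw gray image to a ridge skeleton.

The pipeline is the classical one for ~500 dpi prints: variance-based
segmentation, mean/variance normalization, least-mean-square gradient
orientation estimation smoothed in the doubled-angle domain, ridge
frequency from the x-signature, oriented Gabor filtering, binarization
at zero, and Zhang-Suen thinning.

Conventions: 0-based coordinates, x = column, y = row; orientations are
ridge angles measured from the positive x axis in [0, pi).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve
from skimage.morphology import skeletonize as _sk_skeletonize

DEFAULT_BLOCK_SIZE = 16
MIN_WAVELENGTH = 3.0
MAX_WAVELENGTH = 25.0


@dataclass
class OrientationField:
    """Per-block ridge angle in radians, range [0, pi)."""

    theta: np.ndarray
    block_size: int


@dataclass
class FrequencyField:
    """Per-block ridge frequency (cycles/pixel) with a validity mask."""

    freq: np.ndarray
    valid: np.ndarray
    block_size: int


@dataclass
class SkeletonImage:
    """Binary unit-width ridge map restricted to the foreground mask."""

    pixels: np.ndarray
    mask: np.ndarray


def _as_float(img) -> np.ndarray:
    a = np.asarray(img, dtype=float)
    if a.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if a.shape[0] < 32 or a.shape[1] < 32:
        raise ValueError("image must be at least 32x32")
    if not np.all(np.isfinite(a)):
        raise ValueError("image contains non-finite values")
    return a


def _block_view(shape: tuple[int, int], block_size: int) -> tuple[int, int]:
    h, w = shape
    return (-(-h // block_size), -(-w // block_size))


def segment(img, block_size: int = DEFAULT_BLOCK_SIZE, variance_threshold: float = 0.1) -> np.ndarray:
    """Foreground mask: blocks of the variance-normalized image whose gray
    variance reaches ``variance_threshold``.
    """
    a = _as_float(img)
    if block_size < 4:
        raise ValueError("block_size must be >= 4")
    std = a.std()
    norm = (a - a.mean()) / std if std > 0 else a - a.mean()
    h, w = a.shape
    mask = np.zeros((h, w), dtype=bool)
    any_fg = False
    for r0 in range(0, h, block_size):
        for c0 in range(0, w, block_size):
            blk = norm[r0 : r0 + block_size, c0 : c0 + block_size]
            if blk.var() >= variance_threshold:
                mask[r0 : r0 + block_size, c0 : c0 + block_size] = True
                any_fg = True
    if not any_fg:
        raise ValueError("no fingerprint region found")
    return mask


def normalize(img, target_mean: float = 0.0, target_var: float = 1.0) -> np.ndarray:
    """Affine-on-deviation normalization to an exact global mean/variance."""
    if target_var <= 0:
        raise ValueError("target_var must be > 0")
    a = _as_float(img)
    var = a.var()
    if var == 0:
        raise ValueError("cannot normalize a constant image")
    return target_mean + (a - a.mean()) * np.sqrt(target_var / var)


def estimate_orientation(
    img, block_size: int = DEFAULT_BLOCK_SIZE, smooth_sigma: float = 1.0
) -> OrientationField:
    """Block-wise ridge orientation by the least-mean-square gradient method.

    The gradient covariance is accumulated per block; the doubled-angle
    components are smoothed with a Gaussian of ``smooth_sigma`` blocks
    before the angle is halved back, which fills flat blocks from their
    neighbors.
    """
    a = _as_float(img)
    gy, gx = np.gradient(a)
    gxx = gx * gx
    gyy = gy * gy
    gxy = gx * gy

    nbr, nbc = _block_view(a.shape, block_size)
    vxx = np.zeros((nbr, nbc))
    vyy = np.zeros((nbr, nbc))
    vxy = np.zeros((nbr, nbc))
    for br in range(nbr):
        for bc in range(nbc):
            sl = (
                slice(br * block_size, (br + 1) * block_size),
                slice(bc * block_size, (bc + 1) * block_size),
            )
            vxx[br, bc] = gxx[sl].sum()
            vyy[br, bc] = gyy[sl].sum()
            vxy[br, bc] = gxy[sl].sum()

    # doubled angle of the dominant gradient direction
    sin2 = 2.0 * vxy
    cos2 = vxx - vyy
    if smooth_sigma > 0:
        sin2 = ndimage.gaussian_filter(sin2, smooth_sigma)
        cos2 = ndimage.gaussian_filter(cos2, smooth_sigma)
    theta_grad = 0.5 * np.arctan2(sin2, cos2)
    theta = np.mod(theta_grad + np.pi / 2.0, np.pi)  # ridges run normal to the gradient
    return OrientationField(theta=theta, block_size=block_size)


def _block_centers(nb: int, block_size: int) -> np.ndarray:
    return np.arange(nb) * block_size + block_size / 2.0


def estimate_frequency(
    img, orient: OrientationField, window: int = 32
) -> FrequencyField:
    """Block ridge frequency from peak spacing of the oriented x-signature.

    For each block a profile of length ``window`` is sampled through the
    block center along the ridge normal; the mean spacing of its local
    maxima gives the wavelength. Blocks outside the plausible 3-25 px
    wavelength band are flagged invalid and filled from the nearest
    valid block.
    """
    a = _as_float(img)
    bs = orient.block_size
    nbr, nbc = orient.theta.shape
    freq = np.zeros((nbr, nbc))
    valid = np.zeros((nbr, nbc), dtype=bool)
    ts = np.arange(window) - (window - 1) / 2.0
    h, w = a.shape
    for br in range(nbr):
        for bc in range(nbc):
            th = orient.theta[br, bc]
            # normal to the ridge direction
            nx, ny = -np.sin(th), np.cos(th)
            cy = br * bs + bs / 2.0
            cx = bc * bs + bs / 2.0
            xs = cx + ts * nx
            ys = cy + ts * ny
            inside = (xs >= 0) & (xs <= w - 1) & (ys >= 0) & (ys <= h - 1)
            if inside.sum() < MIN_WAVELENGTH * 2:
                continue
            profile = ndimage.map_coordinates(
                a, np.vstack([ys[inside], xs[inside]]), order=1, mode="nearest"
            )
            peaks = _local_maxima(profile)
            if len(peaks) < 2:
                continue
            wavelength = float(np.mean(np.diff(peaks)))
            if MIN_WAVELENGTH <= wavelength <= MAX_WAVELENGTH:
                freq[br, bc] = 1.0 / wavelength
                valid[br, bc] = True
    if not valid.any():
        raise ValueError("no block yielded a plausible ridge frequency")
    if not valid.all():
        # fill invalid blocks from the nearest valid one
        _, (ir, ic) = ndimage.distance_transform_edt(~valid, return_indices=True)
        freq = freq[ir, ic]
    return FrequencyField(freq=freq, valid=valid, block_size=bs)


def _local_maxima(profile: np.ndarray) -> np.ndarray:
    p = np.asarray(profile)
    idx = np.nonzero((p[1:-1] > p[:-2]) & (p[1:-1] >= p[2:]))[0] + 1
    return idx


def _gabor_kernel(theta: float, freq: float) -> np.ndarray:
    """Zero-mean even Gabor kernel tuned to one orientation/frequency.

    sigma_x = sigma_y = 0.5 / freq, truncated at 3 sigma.
    """
    sigma = 0.5 / freq
    half = int(np.ceil(3.0 * sigma))
    ys, xs = np.mgrid[-half : half + 1, -half : half + 1]
    # rotate so the wave varies along the ridge normal
    xr = xs * np.cos(theta) + ys * np.sin(theta)
    yr = -xs * np.sin(theta) + ys * np.cos(theta)
    g = np.exp(-(xr**2 + yr**2) / (2.0 * sigma**2)) * np.cos(2.0 * np.pi * freq * yr)
    return g - g.mean()


def gabor_enhance(
    img,
    orient: OrientationField,
    freq: FrequencyField,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Filter each block with a Gabor kernel tuned to its local
    orientation/frequency; binarize the response at zero.

    Returns a binary uint8 image (ridge = 1) with background forced to 0.
    """
    a = _as_float(img)
    bs = orient.block_size
    nbr, nbc = orient.theta.shape
    h, w = a.shape
    out = np.zeros((h, w), dtype=np.uint8)
    if mask is None:
        mask = np.ones((h, w), dtype=bool)
    for br in range(nbr):
        for bc in range(nbc):
            r0, c0 = br * bs, bc * bs
            r1, c1 = min(r0 + bs, h), min(c0 + bs, w)
            if not mask[r0:r1, c0:c1].any():
                continue
            kern = _gabor_kernel(orient.theta[br, bc], freq.freq[br, bc])
            half = kern.shape[0] // 2
            pr0, pc0 = max(r0 - half, 0), max(c0 - half, 0)
            pr1, pc1 = min(r1 + half, h), min(c1 + half, w)
            patch = a[pr0:pr1, pc0:pc1]
            resp = fftconvolve(patch, kern, mode="same")
            blk = resp[r0 - pr0 : r0 - pr0 + (r1 - r0), c0 - pc0 : c0 - pc0 + (c1 - c0)]
            out[r0:r1, c0:c1] = (blk > 0).astype(np.uint8)
    out[~mask] = 0
    return out


def _has_2x2(img: np.ndarray) -> np.ndarray:
    return img[:-1, :-1] & img[1:, :-1] & img[:-1, 1:] & img[1:, 1:]


def _neighbors8(img: np.ndarray, r: int, c: int) -> list[int]:
    h, w = img.shape
    out = []
    for dr, dc in [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]:
        rr, cc = r + dr, c + dc
        out.append(int(img[rr, cc]) if 0 <= rr < h and 0 <= cc < w else 0)
    return out


def _is_simple(img: np.ndarray, r: int, c: int) -> bool:
    """Deletable without changing local 8-connectivity (one 0->1 run)."""
    nb = _neighbors8(img, r, c)
    transitions = sum(abs(nb[i] - nb[(i + 1) % 8]) for i in range(8)) // 2
    return transitions == 1 and sum(nb) > 1


def skeletonize(binary, mask: np.ndarray | None = None) -> SkeletonImage:
    """Zhang-Suen thinning to a unit-width skeleton.

    A deterministic cleanup pass removes redundant pixels of any
    remaining 2x2 all-ridge block so the unit-width invariant holds.
    """
    b = np.asarray(binary).astype(bool)
    if mask is not None:
        b = b & mask
    skel = _sk_skeletonize(b, method="zhang")
    skel = np.ascontiguousarray(skel)
    # enforce no 2x2 all-ridge block
    changed = True
    while changed:
        changed = False
        blocks = np.argwhere(_has_2x2(skel))
        for r, c in blocks:
            for rr, cc in ((r, c), (r, c + 1), (r + 1, c), (r + 1, c + 1)):
                if skel[rr, cc] and _is_simple(skel, rr, cc):
                    skel[rr, cc] = False
                    changed = True
                    break
            if changed:
                break
    return SkeletonImage(pixels=skel, mask=mask if mask is not None else np.ones_like(skel, bool))


def enhance_pipeline(
    img,
    block_size: int = DEFAULT_BLOCK_SIZE,
    variance_threshold: float = 0.1,
    smooth_sigma: float = 1.0,
) -> SkeletonImage:
    """Full enhancement chain: segment, normalize, orient, frequency,
    Gabor, thin."""
    mask = segment(img, block_size, variance_threshold)
    norm = normalize(img, 0.0, 1.0)
    orient = estimate_orientation(norm, block_size, smooth_sigma)
    freq = estimate_frequency(norm, orient)
    binary = gabor_enhance(norm, orient, freq, mask)
    return skeletonize(binary.astype(bool), mask)
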