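"""Single-beat phase portraits via time-delay embedding.

A beat is upsampled tenfold with Gaussian interpolation, min-max
normalized to [0, 1], embedded into 2D points (x(t), x(t + tau)), and
rasterized over an r x r grid that records only the presence or absence
of the trajectory in each cell.  The binary grid is block-replicated to
the network input size so portraits stay strictly binary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .preprocess import BeatSegment

UPSAMPLE_FACTOR = 10
KERNEL_SIGMA = 0.5   # in original sample periods
KERNEL_TRUNCATE = 4.0  # kernel support is +-KERNEL_TRUNCATE * sigma


@dataclass(frozen=True)
class PhasePortrait:
    """Binary occupancy grid of a delay-embedded beat plus its resized image."""

    grid: np.ndarray
    tau_ms: float
    partitions: int
    image: np.ndarray
    subject_id: str

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=np.uint8)
        image = np.asarray(self.image, dtype=np.uint8)
        if not np.isin(grid, (0, 1)).all() or not np.isin(image, (0, 1)).all():
            raise ValueError("portrait entries must be binary")
        if grid.max() == 0:
            raise ValueError("portrait must have at least one occupied cell")
        if image.shape[0] < grid.shape[0]:
            raise ValueError("image must be at least as large as the grid")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "image", image)


def normalize(samples: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]: (x - x_min) / (x_max - x_min)."""
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        raise ValueError("degenerate beat: constant signal cannot be normalized")
    return (x - lo) / (hi - lo)


def upsample_gaussian(samples: np.ndarray, factor: int) -> np.ndarray:
    """Upsample by Gaussian-kernel interpolation.

    Each output point at fractional position q (in original sample units)
    is a normalized Gaussian-weighted average of the samples within
    +-4 sigma of q, with sigma = 0.5 sample periods.  The ends are padded
    by linear extrapolation so the interpolator reproduces affine signals
    exactly; constant input maps to constant output.  Output length is
    factor*(N-1) + 1.
    """
    x = np.asarray(samples, dtype=float)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    n = x.size
    m = factor * (n - 1) + 1
    q = np.arange(m) / factor
    reach = int(np.ceil(KERNEL_TRUNCATE * KERNEL_SIGMA))
    left = x[0] - (x[1] - x[0]) * np.arange(reach, 0, -1)
    right = x[-1] + (x[-1] - x[-2]) * np.arange(1, reach + 2)
    padded = np.concatenate([left, x, right])
    base = np.floor(q).astype(int)
    offsets = np.arange(-reach, reach + 2)
    idx = base[:, None] + offsets[None, :]
    dist = idx - q[:, None]
    w = np.exp(-(dist**2) / (2 * KERNEL_SIGMA**2))
    w[np.abs(dist) > KERNEL_TRUNCATE * KERNEL_SIGMA] = 0.0
    vals = padded[idx + reach]
    return np.sum(w * vals, axis=1) / np.sum(w, axis=1)


def embed(samples: np.ndarray, tau_samples: int) -> np.ndarray:
    """Delay-embed into 2D points (x[i], x[i + tau]); returns (N - tau, 2)."""
    x = np.asarray(samples, dtype=float)
    if not 0 <= tau_samples < x.size:
        raise ValueError("tau_samples must lie in [0, len(samples))")
    if tau_samples == 0:
        return np.column_stack([x, x])
    return np.column_stack([x[:-tau_samples], x[tau_samples:]])


def rasterize(points: np.ndarray, partitions: int) -> np.ndarray:
    """Mark which cells of an r x r grid the trajectory visits.

    Column = min(floor(x*r), r-1); row 0 is the top of the image, so
    row = r-1 - min(floor(y*r), r-1).  Only the sample points themselves
    are marked; no line segments are drawn between consecutive points.
    """
    pts = np.asarray(points, dtype=float)
    r = int(partitions)
    if r < 2:
        raise ValueError("partitions must be >= 2")
    if pts.size and (pts.min() < 0 or pts.max() > 1):
        raise ValueError("coordinates must lie in [0, 1]")
    grid = np.zeros((r, r), dtype=np.uint8)
    if pts.size == 0:
        return grid
    col = np.minimum((pts[:, 0] * r).astype(int), r - 1)
    row = r - 1 - np.minimum((pts[:, 1] * r).astype(int), r - 1)
    grid[row, col] = 1
    return grid


def resize_portrait(grid: np.ndarray, out_pixels: int) -> np.ndarray:
    """Nearest-neighbour block replication to out_pixels x out_pixels.

    Each cell becomes a (p/r) x (p/r) block, so the image stays binary and
    the occupied fraction is preserved exactly.
    """
    grid = np.asarray(grid, dtype=np.uint8)
    r = grid.shape[0]
    p = int(out_pixels)
    if p < r:
        raise ValueError("out_pixels must be >= grid partitions")
    if p % r != 0:
        raise ValueError("out_pixels must be divisible by grid partitions")
    k = p // r
    return np.kron(grid, np.ones((k, k), dtype=np.uint8))


def tau_ms_to_samples(tau_ms: float, fs: float,
                      factor: int = UPSAMPLE_FACTOR) -> int:
    """Convert a delay in ms to samples at the upsampled rate."""
    return int(round(tau_ms * fs * factor / 1000.0))


def beat_to_portrait(beat: BeatSegment, tau_ms: float, partitions: int,
                     out_pixels: int, fs: float) -> PhasePortrait:
    """Full beat-to-portrait pipeline.

    Order: upsample x10 -> normalize -> embed -> rasterize -> resize.
    """
    up = upsample_gaussian(beat.samples, UPSAMPLE_FACTOR)
    norm = normalize(up)
    tau = tau_ms_to_samples(tau_ms, fs)
    pts = embed(norm, tau)
    grid = rasterize(pts, partitions)
    image = resize_portrait(grid, out_pixels)
    return PhasePortrait(grid=grid, tau_ms=tau_ms, partitions=partitions,
                         image=image, subject_id=beat.subject_id)


def count_holes(grid: np.ndarray) -> int:
    """Number of enclosed background regions (loops) in a binary portrait.

    Background is 4-connected; a hole is a background component that does
    not touch the image border.  Loops of the trajectory (QRS outer loop,
    T/P inner loops) appear as holes.
    """
    bg = np.asarray(grid) == 0
    labels, n = ndimage.label(bg, structure=np.array([[0, 1, 0],
                                                      [1, 1, 1],
                                                      [0, 1, 0]]))
    border = np.unique(np.concatenate([labels[0], labels[-1],
                                       labels[:, 0], labels[:, -1]]))
    return int(n - np.count_nonzero(border))
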