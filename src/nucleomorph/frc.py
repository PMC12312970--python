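"""Fourier-ring-correlation (FRC) resolution estimation for 2D micrographs.

FRC measures the spectral correlation between two images of the same field
over annular frequency rings; the spatial frequency where the curve first
drops below a threshold (the field's dominant convention is 1/7) defines
the image resolution.  When only a single acquisition is available, a
checkerboard split produces the two statistically independent half-images.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .core import VoxelGrid

#: fixed-threshold convention
ONE_SEVENTH = 1.0 / 7.0


@dataclass(frozen=True)
class FRCCurve:
    """Per-ring spectral correlation between two images.

    ``frequency`` is the ring-centre spatial frequency in cycles/pixel
    (strictly increasing, Nyquist = 0.5); ``correlation`` the real FRC per
    ring, clipped to [-1, 1]; ``n_per_ring`` the Fourier samples per ring.
    """

    frequency: np.ndarray
    correlation: np.ndarray
    n_per_ring: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.frequency) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(np.abs(self.correlation) > 1 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")


def checkerboard_split(img: VoxelGrid) -> Tuple[VoxelGrid, VoxelGrid]:
    """Split one image into two half-images on complementary checkerboards.

    Even-parity pixels (row+column even) go to image A, odd-parity pixels
    to image B; each set is reassembled on a half-resolution grid by taking
    alternate columns with a one-pixel shear on odd rows, halving the pixel
    count.  Column spacing doubles accordingly.  Deterministic.
    """
    data = np.asarray(img.data)
    if data.ndim != 2:
        raise ValueError("checkerboard split requires a 2D image")
    h, w = data.shape
    if h < 64 or w < 64:
        raise ValueError("image too small for a meaningful split (min 64x64)")
    w2 = w - (w % 2)
    rows = np.arange(h)[:, None]
    cols_a = 2 * np.arange(w2 // 2)[None, :] + (rows % 2)       # row+col even
    cols_b = 2 * np.arange(w2 // 2)[None, :] + ((rows + 1) % 2)  # row+col odd
    a = data[rows, cols_a]
    b = data[rows, cols_b]
    sy, sx = img.spacing
    spacing = (sy, 2 * sx)
    name = img.channel_name
    return (
        VoxelGrid(a, spacing, f"{name}/A" if name else "A"),
        VoxelGrid(b, spacing, f"{name}/B" if name else "B"),
    )


def _hann2d(shape: Tuple[int, int]) -> np.ndarray:
    wy = np.hanning(shape[0])
    wx = np.hanning(shape[1])
    return np.outer(wy, wx)


def frc_curve(
    imgA: VoxelGrid, imgB: VoxelGrid, ring_width: int = 1
) -> FRCCurve:
    """Fourier ring correlation between two equally shaped 2D images.

    Both images are mean-subtracted and Hann-apodized (suppressing edge
    artefacts that inflate high-frequency correlation), Fourier transformed,
    and correlated ring by ring:

        FRC(r) = Re Σᵣ F_A·conj(F_B) / sqrt(Σᵣ|F_A|² · Σᵣ|F_B|²)

    Rings are annuli of ``ring_width`` frequency bins of the smaller image
    dimension, covering (0, Nyquist].  FRC is symmetric in its arguments
    and invariant to global intensity scaling of either image.
    """
    a = np.asarray(imgA.data, dtype=np.float64)
    b = np.asarray(imgB.data, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("images must have the same shape")
    if a.ndim != 2:
        raise ValueError("FRC is defined for 2D images")
    if ring_width < 1:
        raise ValueError("ring_width must be >= 1")
    win = _hann2d(a.shape)
    FA = np.fft.fft2((a - a.mean()) * win)
    FB = np.fft.fft2((b - b.mean()) * win)
    fy = np.fft.fftfreq(a.shape[0])[:, None]
    fx = np.fft.fftfreq(a.shape[1])[None, :]
    freq = np.sqrt(fy**2 + fx**2)  # cycles/pixel
    n_half = min(a.shape) // 2
    df = 1.0 / min(a.shape)  # one frequency bin
    n_rings = max(1, n_half // ring_width)
    edges = df * ring_width * np.arange(n_rings + 1)
    ring = np.digitize(freq.ravel(), edges) - 1
    inside = (ring >= 0) & (ring < n_rings) & (freq.ravel() > 0)
    num = np.bincount(ring[inside], weights=(FA * np.conj(FB)).real.ravel()[inside],
                      minlength=n_rings)
    pa = np.bincount(ring[inside], weights=(np.abs(FA) ** 2).ravel()[inside],
                     minlength=n_rings)
    pb = np.bincount(ring[inside], weights=(np.abs(FB) ** 2).ravel()[inside],
                     minlength=n_rings)
    n_per = np.bincount(ring[inside], minlength=n_rings)
    populated = n_per > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(populated & (pa * pb > 0), num / np.sqrt(pa * pb), 0.0)
    corr = np.clip(corr, -1.0, 1.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return FRCCurve(
        frequency=centers[populated],
        correlation=corr[populated],
        n_per_ring=n_per[populated],
    )


def frc_resolution(
    curve: FRCCurve, threshold: float = ONE_SEVENTH, pixel_nm: float = 35.0
) -> Optional[float]:
    """Resolution in nm from the first threshold crossing of the FRC curve.

    The crossing frequency is located by linear interpolation between the
    adjacent rings; resolution = pixel size / crossing frequency.  Returns
    None ("not determined") when the curve never falls below the threshold.

    ``threshold`` defaults to the fixed-1/7 convention; pass e.g. a half-bit
    or 3σ curve value for other criteria.  ``pixel_nm`` is the physical
    pixel size of the images that produced the curve.
    """
    f, c = curve.frequency, curve.correlation
    below = np.flatnonzero(c < threshold)
    if below.size == 0:
        return None
    i = below[0]
    if i == 0:
        f_cross = f[0]
    else:
        f0, f1 = f[i - 1], f[i]
        c0, c1 = c[i - 1], c[i]
        t = (c0 - threshold) / (c0 - c1)
        f_cross = f0 + t * (f1 - f0)
    if f_cross <= 0:
        return None
    return float(pixel_nm / f_cross)
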