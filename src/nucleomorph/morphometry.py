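"""Per-nucleus morphometric measurements.

Four parameters characterize each segmented nucleus: volume V (µm³),
compactness V²/S³ (with the 36π-normalized variant that equals 1 for a
sphere), elongation r1/r2 from the best-fitted ellipsoid, and chromatin
density (total Hoechst intensity over volume, on a normalized scale where
a uniform unit-intensity nucleus measures 1).  An optional CDT1 marker
channel gates nuclei to the G1 cell-cycle phase.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.measure import marching_cubes, mesh_surface_area

from .core import LabelMask, NucleusMorphometry, PipelineConfig, VoxelGrid

#: solid-ellipsoid relation between semi-radius and central second moment
_MOMENT_FACTOR = 5.0


def measure_volume(mask_label: np.ndarray, spacing: Sequence[float]) -> float:
    """Volume in µm³: voxel count times the physical voxel volume.

    ``spacing`` is in nm per axis (z, y, x)."""
    mask_label = np.asarray(mask_label, dtype=bool)
    n = int(mask_label.sum())
    if n == 0:
        raise ValueError("empty label has no volume")
    voxel_um3 = float(np.prod(np.asarray(spacing) / 1000.0))
    return n * voxel_um3


def measure_surface(
    mask_label: np.ndarray,
    spacing: Sequence[float],
    smoothing_vox: float = 1.0,
) -> float:
    """Surface area in µm² of the 0.5-level iso-surface mesh of the label.

    Marching cubes runs with the physical spacing so anisotropic voxels are
    handled; the label is zero-padded so surfaces at the array border close.

    ``smoothing_vox`` is the sigma (voxels) of a Gaussian applied to the
    binary volume before meshing.  Meshing a raw binary overestimates the
    area of smooth shapes by ~9% through staircase facets; one voxel of
    smoothing removes that bias (< 1% error on voxelized ellipsoids at the
    acquisition spacing).  Smoothing rounds sharp edges, so set it to 0 for
    polyhedral test shapes.
    """
    mask_label = np.asarray(mask_label, dtype=bool)
    if not mask_label.any():
        raise ValueError("empty label has no surface")
    if min(mask_label.shape) < 2 or any(
        np.ptp(np.nonzero(mask_label)[ax]) < 1 for ax in range(mask_label.ndim)
    ):
        raise ValueError("label too small to mesh (< 2 voxels along an axis)")
    pad = max(2, int(np.ceil(3 * smoothing_vox)))
    padded = np.pad(mask_label, pad).astype(np.float64)
    if smoothing_vox > 0:
        padded = ndimage.gaussian_filter(padded, smoothing_vox)
    spacing_um = tuple(np.asarray(spacing, dtype=float) / 1000.0)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=spacing_um)
    return float(mesh_surface_area(verts, faces))


def compactness(V: float, S: float) -> Tuple[float, float]:
    """Compactness C = V²/S³ and its 36π-normalized variant.

    C is dimensionless and scale-invariant; 36π·V²/S³ equals 1 for a
    perfect sphere and is < 1 for any other shape.
    """
    if V <= 0 or S <= 0:
        raise ValueError("V and S must be > 0")
    C = V**2 / S**3
    return C, 36.0 * np.pi * C


def fit_ellipsoid(
    mask_label: np.ndarray, spacing: Sequence[float]
) -> Tuple[float, float, float, np.ndarray]:
    """Best-fitted ellipsoid semi-radii from second central moments.

    The covariance of the voxel coordinate cloud (in physical µm) is
    eigen-decomposed; for a solid ellipsoid the second central moment along
    a principal axis is r²/5, so semi-radii are √(5λ), sorted r1 ≥ r2 ≥ r3.

    Returns
    -------
    (r1, r2, r3, axes)
        Semi-radii in µm and the principal-axis matrix (rows are unit axes
        in (z, y, x) lab coordinates, matching the radii order).
    """
    coords = np.argwhere(np.asarray(mask_label, dtype=bool))
    if coords.shape[0] < 4:
        raise ValueError("need at least 4 voxels to fit an ellipsoid")
    spacing_um = np.asarray(spacing, dtype=float) / 1000.0
    pts = coords * spacing_um
    cov = np.cov(pts, rowvar=False, bias=True)
    if np.linalg.matrix_rank(cov, tol=1e-12) < pts.shape[1]:
        raise ValueError("degenerate (coplanar) label; cannot fit an ellipsoid")
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    radii = np.sqrt(_MOMENT_FACTOR * np.clip(eigvals, 0.0, None))
    r1, r2, r3 = radii
    return float(r1), float(r2), float(r3), eigvecs.T


def elongation(r1: float, r2: float) -> float:
    """Elongation E = r1/r2 of the two main radii; 1 for a sphere."""
    if r2 <= 0:
        raise ValueError("r2 must be > 0")
    if r1 < r2:
        raise ValueError("r1 must be >= r2")
    return r1 / r2


def chromatin_density(
    img: VoxelGrid, mask_label: np.ndarray, V: float
) -> float:
    """Chromatin density: total Hoechst intensity over nuclear volume.

    Intensities are rescaled to [0, 1] by the image bit-depth maximum and
    the total is normalized per voxel volume, so a nucleus of uniform unit
    intensity measures 1 regardless of acquisition settings.
    """
    if V <= 0:
        raise ValueError("V must be > 0")
    mask_label = np.asarray(mask_label, dtype=bool)
    if mask_label.shape != img.shape:
        raise ValueError("label does not lie within the image")
    total = float(np.asarray(img.data, dtype=np.float64)[mask_label].sum())
    total /= img.intensity_max()
    voxel_um3 = img.voxel_volume_um3()
    return total * voxel_um3 / V


def gate_g1(marker_img: VoxelGrid, mask_label: np.ndarray, threshold: float) -> bool:
    """G1 gate: mean CDT1 marker intensity over the label >= threshold.

    Marker intensities are rescaled by the bit-depth maximum before
    averaging; the boundary is inclusive (mean == threshold is positive).
    """
    mask_label = np.asarray(mask_label, dtype=bool)
    if mask_label.shape != marker_img.shape:
        raise ValueError("marker image is not aligned with the mask")
    if not mask_label.any():
        raise ValueError("empty label")
    mean = float(np.asarray(marker_img.data, dtype=np.float64)[mask_label].mean())
    mean /= marker_img.intensity_max()
    return mean >= threshold


def measure_nuclei(
    img: VoxelGrid,
    labels: LabelMask,
    marker: Optional[VoxelGrid] = None,
    config: Optional[PipelineConfig] = None,
) -> List[NucleusMorphometry]:
    """Measure every labelled nucleus in a stack.

    Parameters
    ----------
    img
        Hoechst (nuclear) channel.
    labels
        Instance mask aligned with ``img``.
    marker
        Optional CDT1 channel for G1 gating; when absent ``g1_positive``
        is left unset.
    config
        Pipeline configuration (elongation mode, G1 threshold).
    """
    config = config or PipelineConfig()
    labels.validate_against(img)
    records = []
    for lab in labels.ids:
        region = labels.labels == lab
        V = measure_volume(region, img.spacing)
        S = measure_surface(region, img.spacing)
        C, C_norm = compactness(V, S)
        r1, r2, r3, _ = fit_ellipsoid(region, img.spacing)
        denom = r2 if config.elongation_mode == "intermediate" else r3
        E = elongation(r1, denom)
        D = chromatin_density(img, region, V)
        g1 = (
            gate_g1(marker, region, config.g1_threshold)
            if marker is not None
            else None
        )
        records.append(
            NucleusMorphometry(
                label=int(lab), volume_um3=V, surface_um2=S,
                compactness=C, compactness_norm=C_norm,
                r1=r1, r2=r2, r3=r3, elongation=E,
                chromatin_density=D, g1_positive=g1,
            )
        )
    return records
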