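"""Core data contracts shared by every pipeline stage.

The raw-image contract is :class:`VoxelGrid` — a scalar intensity array
indexed ``(z, y, x)`` (or ``(y, x)`` for single-plane images) together with
the physical voxel spacing in nanometres.  Instance segmentations travel as
:class:`LabelMask` objects aligned voxel-for-voxel with their grid, and
per-nucleus measurements as :class:`NucleusMorphometry` records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Optional, Sequence, Tuple

import numpy as np
import yaml

#: Confocal acquisition spacing used as the fallback default, in nm (z, y, x).
DEFAULT_SPACING_NM: Tuple[float, float, float] = (150.0, 120.0, 120.0)


@dataclass(frozen=True)
class VoxelGrid:
    """A 3D (or 2D) scalar intensity image with physical voxel spacing.

    Parameters
    ----------
    data
        Intensity array indexed ``(z, y, x)`` — or ``(y, x)`` for 2D
        micrographs (as used by Fourier-ring-correlation analysis).
        Intensities must be finite and non-negative.
    spacing
        Physical size of one voxel along each axis of ``data``, in nm.
        Confocal stacks acquired for nuclear morphometry use
        ``(150, 120, 120)``.
    channel_name
        Free-text channel identifier, e.g. ``"Hoechst"`` or ``"CDT1"``.
    """

    data: np.ndarray
    spacing: Tuple[float, ...]
    channel_name: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        object.__setattr__(self, "data", data)
        if data.ndim not in (2, 3):
            raise ValueError(f"VoxelGrid must be 2D or 3D, got {data.ndim}D")
        spacing = tuple(float(s) for s in self.spacing)
        object.__setattr__(self, "spacing", spacing)
        if len(spacing) != data.ndim:
            raise ValueError(
                f"spacing has {len(spacing)} entries for a {data.ndim}D image"
            )
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing values must be > 0, got {spacing}")
        if not np.all(np.isfinite(data)):
            raise ValueError("intensities must be finite")
        if np.issubdtype(data.dtype, np.floating) and data.size and data.min() < 0:
            raise ValueError("intensities must be >= 0")

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def voxel_volume_um3(self) -> float:
        """Physical volume of one voxel in µm³ (3D grids only)."""
        if self.ndim != 3:
            raise ValueError("voxel volume is defined for 3D grids only")
        sz, sy, sx = self.spacing
        return (sz / 1000.0) * (sy / 1000.0) * (sx / 1000.0)

    def intensity_max(self) -> float:
        """Bit-depth maximum used to rescale intensities to [0, 1].

        Integer images use the dtype maximum (e.g. 65535 for 16-bit);
        floating-point images are assumed to already be on a [0, 1] scale.
        """
        if np.issubdtype(self.data.dtype, np.integer):
            return float(np.iinfo(self.data.dtype).max)
        return 1.0


@dataclass(frozen=True)
class LabelMask:
    """Integer instance labels aligned with a :class:`VoxelGrid`.

    ``0`` is reserved for background; instance ids are contiguous ``1..K``.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if labels.size and labels.min() < 0:
            raise ValueError("labels must be non-negative (0 = background)")
        object.__setattr__(self, "labels", labels)

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.labels.shape

    @property
    def ids(self) -> np.ndarray:
        """Sorted instance ids present in the mask (background excluded)."""
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_labels(self) -> int:
        return int(self.ids.size)

    def validate_against(self, grid: VoxelGrid) -> None:
        if self.labels.shape != grid.data.shape:
            raise ValueError(
                f"label shape {self.labels.shape} does not match "
                f"image shape {grid.data.shape}"
            )

    @staticmethod
    def from_array(labels: np.ndarray) -> "LabelMask":
        """Relabel to contiguous 1..K and wrap."""
        labels = np.asarray(labels)
        ids = np.unique(labels)
        ids = ids[ids > 0]
        out = np.zeros_like(labels, dtype=np.int32)
        for new, old in enumerate(ids, start=1):
            out[labels == old] = new
        return LabelMask(out)


@dataclass
class NucleusMorphometry:
    """Morphometric record for one segmented nucleus.

    Attributes
    ----------
    label
        Instance id in the :class:`LabelMask`.
    volume_um3
        Nuclear volume V (µm³): voxel count × physical voxel volume.
    surface_um2
        Surface area S (µm²) of the iso-surface mesh of the label.
    compactness
        Dimensionless V²/S³.
    compactness_norm
        36π·V²/S³ — equals 1 for a perfect sphere, < 1 otherwise.
    r1, r2, r3
        Semi-radii (µm) of the best-fitted ellipsoid, sorted r1 ≥ r2 ≥ r3.
    elongation
        r1/r2, the ratio of the two main radii; 1 for a sphere.
    chromatin_density
        Total nuclear-channel intensity over volume after the declared
        normalization (uniform unit-intensity nucleus ⇒ 1).
    g1_positive
        True if the nucleus passes the CDT1 G1-phase gate.
    """

    label: int
    volume_um3: float
    surface_um2: float
    compactness: float
    compactness_norm: float
    r1: float
    r2: float
    r3: float
    elongation: float
    chromatin_density: float
    g1_positive: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.volume_um3 <= 0:
            raise ValueError("volume must be > 0")
        if self.surface_um2 <= 0:
            raise ValueError("surface area must be > 0")
        if not (self.r1 >= self.r2 >= self.r3 > 0):
            raise ValueError("semi-radii must satisfy r1 >= r2 >= r3 > 0")
        if self.elongation < 1.0 - 1e-9:
            raise ValueError("elongation must be >= 1")
        if self.chromatin_density < 0:
            raise ValueError("chromatin density must be >= 0")


@dataclass
class PipelineConfig:
    """Tunable parameters for the segmentation/measurement pipeline.

    Defaults follow the acquisition and classifier settings of the study
    this pipeline reproduces; every field can be overridden from a YAML
    file via :meth:`from_yaml`.
    """

    #: Smoothing scales for the per-voxel feature bank, in x/y voxel units.
    feature_scales: Sequence[float] = (1.0, 2.0, 4.0, 8.0)
    #: Random-Forest tree count for voxel classification.
    n_trees: int = 200
    #: Worker threads for classifier fit/predict.
    n_threads: int = 8
    #: Probability threshold turning the nucleus-class map into a mask.
    p_threshold: float = 0.5
    #: Minimum distance-transform height (voxels) for a watershed seed.
    seed_threshold: float = 2.0
    #: Seeds closer than this (voxels, Euclidean) are merged — nuclei
    #: closer than 10 voxels are not separated.
    min_seed_separation: float = 10.0
    #: Drop segmented objects smaller than this many voxels (0 disables).
    min_object_size: int = 500
    #: Mean CDT1 intensity (normalized) at or above which a nucleus is G1.
    g1_threshold: float = 0.1
    #: Fallback voxel spacing in nm when image metadata is absent.
    default_spacing_nm: Tuple[float, float, float] = DEFAULT_SPACING_NM
    #: Elongation denominator: "intermediate" (r1/r2) or "smallest" (r1/r3).
    elongation_mode: str = "intermediate"
    #: Seed for every stochastic component (classifier training).
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("tree count must be >= 1")
        if self.min_seed_separation < 0:
            raise ValueError("min seed separation must be >= 0")
        if self.elongation_mode not in ("intermediate", "smallest"):
            raise ValueError("elongation_mode must be 'intermediate' or 'smallest'")
        self.feature_scales = tuple(float(s) for s in self.feature_scales)
        self.default_spacing_nm = tuple(float(s) for s in self.default_spacing_nm)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["feature_scales"] = list(self.feature_scales)
        payload["default_spacing_nm"] = list(self.default_spacing_nm)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
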