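"""TIFF/OME-TIFF and tabular readers/writers.

Voxel spacing is resolved in priority order: explicit ``spacing`` override,
OME ``PhysicalSize*`` metadata, ImageJ metadata, then (with a warning) the
configured acquisition default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile

from .core import DEFAULT_SPACING_NM, LabelMask, NucleusMorphometry, VoxelGrid

log = logging.getLogger(__name__)

_MORPHO_COLUMNS = [
    "label", "volume_um3", "surface_um2", "compactness", "compactness_norm",
    "r1", "r2", "r3", "elongation", "chromatin_density", "g1_positive",
]


def _spacing_from_ome(tif: tifffile.TiffFile) -> Optional[Tuple[float, ...]]:
    try:
        import xml.etree.ElementTree as ET

        root = ET.fromstring(tif.ome_metadata)
        ns = root.tag.split("}")[0] + "}" if "}" in root.tag else ""
        pixels = root.find(f".//{ns}Pixels")
        if pixels is None:
            return None
        unit_scale = {"nm": 1.0, "µm": 1000.0, "um": 1000.0, None: 1000.0}

        def axis(name: str) -> Optional[float]:
            v = pixels.get(f"PhysicalSize{name}")
            if v is None:
                return None
            u = pixels.get(f"PhysicalSize{name}Unit")
            return float(v) * unit_scale.get(u, 1000.0)

        z, y, x = axis("Z"), axis("Y"), axis("X")
        if y is None or x is None:
            return None
        return (z, y, x) if z is not None else (y, x)
    except Exception:  # pragma: no cover - defensive against malformed XML
        return None


def _spacing_from_imagej(tif: tifffile.TiffFile) -> Optional[Tuple[float, ...]]:
    meta = tif.imagej_metadata or {}
    page = tif.pages[0]
    try:
        xres = page.tags["XResolution"].value  # pixels per unit, rational
        yres = page.tags["YResolution"].value
    except KeyError:
        return None
    unit = meta.get("unit", "")
    scale = {"nm": 1.0, "um": 1000.0, "µm": 1000.0, "micron": 1000.0}.get(unit)
    if scale is None:
        return None
    sx = scale * xres[1] / xres[0]
    sy = scale * yres[1] / yres[0]
    if "spacing" in meta:
        return (float(meta["spacing"]) * scale, sy, sx)
    return (sy, sx)


def read_stack(
    path,
    channel: Optional[str | int] = None,
    spacing: Optional[Sequence[float]] = None,
    allow_default_spacing: bool = False,
) -> VoxelGrid:
    """Read one channel of a TIFF/OME-TIFF stack into a :class:`VoxelGrid`.

    Parameters
    ----------
    path
        TIFF or OME-TIFF file with resolvable axis order.
    channel
        Channel name (matched against OME channel names) or integer index.
        Required when the file holds more than one channel.
    spacing
        Per-axis voxel spacing override in nm (z, y, x), used when metadata
        is absent or wrong.
    allow_default_spacing
        If True and neither metadata nor an override provides spacing, fall
        back to the acquisition default (150, 120, 120) nm with a warning
        instead of raising.
    """
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes  # e.g. "ZYX", "CZYX", "ZCYX", "YX"
        axes = axes.replace("S", "C").replace("Q", "Z").replace("I", "Z")
        if "T" in axes:
            raise ValueError("time series are not supported")
        channel_names: List[str] = []
        if tif.ome_metadata:
            try:
                import xml.etree.ElementTree as ET

                root = ET.fromstring(tif.ome_metadata)
                ns = root.tag.split("}")[0] + "}" if "}" in root.tag else ""
                channel_names = [
                    c.get("Name") or "" for c in root.iter(f"{ns}Channel")
                ]
            except Exception:  # pragma: no cover
                pass
        meta_spacing = _spacing_from_ome(tif) if tif.ome_metadata else None
        if meta_spacing is None:
            meta_spacing = _spacing_from_imagej(tif)

    if "C" in axes:
        c_axis = axes.index("C")
        n_channels = data.shape[c_axis]
        if channel is None:
            if n_channels > 1:
                raise ValueError(
                    f"file has {n_channels} channels; a channel name or "
                    "index is required"
                )
            idx = 0
        elif isinstance(channel, int):
            idx = channel
        else:
            if channel not in channel_names:
                raise ValueError(
                    f"channel {channel!r} not found; available: {channel_names}"
                )
            idx = channel_names.index(channel)
        data = np.take(data, idx, axis=c_axis)
        axes = axes.replace("C", "")
    if set(axes) - {"Z", "Y", "X"}:
        raise ValueError(f"ambiguous or unsupported axis order {axes!r}")
    order = [axes.index(a) for a in ("Z", "Y", "X") if a in axes]
    data = np.transpose(data, order)

    resolved = tuple(spacing) if spacing is not None else meta_spacing
    if resolved is not None and len(resolved) != data.ndim:
        if len(resolved) == 3 and data.ndim == 2:
            resolved = resolved[-2:]
        elif len(resolved) == 2 and data.ndim == 3:
            raise ValueError("2-axis spacing given for a 3D stack")
    if resolved is None:
        if not allow_default_spacing:
            raise ValueError(
                f"{path}: no voxel-spacing metadata and no override; pass "
                "spacing=(z, y, x) in nm or set allow_default_spacing=True"
            )
        resolved = DEFAULT_SPACING_NM[-data.ndim :]
        warnings.warn(
            f"{path}: no spacing metadata; assuming acquisition default "
            f"{resolved} nm",
            stacklevel=2,
        )
    name = channel if isinstance(channel, str) else ""
    return VoxelGrid(data=data, spacing=resolved, channel_name=name)


def write_stack(path, grid: VoxelGrid) -> None:
    """Write a :class:`VoxelGrid` as OME-TIFF with physical voxel sizes."""
    axes = "ZYX" if grid.ndim == 3 else "YX"
    meta = {
        "axes": axes,
        "PhysicalSizeX": grid.spacing[-1] / 1000.0,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": grid.spacing[-2] / 1000.0,
        "PhysicalSizeYUnit": "µm",
    }
    if grid.ndim == 3:
        meta["PhysicalSizeZ"] = grid.spacing[0] / 1000.0
        meta["PhysicalSizeZUnit"] = "µm"
    if grid.channel_name:
        meta["Channel"] = {"Name": [grid.channel_name]}
    tifffile.imwrite(path, grid.data, metadata=meta, ome=True)


def write_labels(path, mask: LabelMask, spacing: Sequence[float]) -> None:
    """Write a label mask as OME-TIFF (int32), spacing in nm."""
    grid = VoxelGrid(mask.labels.astype(np.int32), tuple(spacing), "labels")
    write_stack(path, grid)


def read_labels(path) -> LabelMask:
    grid = read_stack(path, allow_default_spacing=True)
    return LabelMask(np.asarray(grid.data).astype(np.int32))


def write_morphometry_csv(records: List[NucleusMorphometry], path) -> None:
    """Write per-nucleus morphometry, one row per nucleus.

    Round-trips losslessly at better than 1e-6 relative precision.
    """
    if not records:
        raise ValueError("no morphometry records to write")
    df = pd.DataFrame([asdict(r) for r in records])[_MORPHO_COLUMNS]
    df.to_csv(path, index=False, float_format="%.9g")


def read_morphometry_csv(path) -> List[NucleusMorphometry]:
    df = pd.read_csv(path)
    missing = set(_MORPHO_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"morphometry CSV missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        g1 = d["g1_positive"]
        d["g1_positive"] = None if pd.isna(g1) else bool(g1)
        d["label"] = int(d["label"])
        records.append(NucleusMorphometry(**d))
    return records


def read_cq_csv(path) -> pd.DataFrame:
    """Read a qPCR Cq table with columns sample, group, gene, cq."""
    df = pd.read_csv(path)
    required = {"sample", "group", "gene", "cq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Cq table missing columns: {sorted(missing)}")
    return df


def read_plate_csv(path) -> pd.DataFrame:
    """Read a plate-array luminescence table: well, gene, group, luminescence."""
    df = pd.read_csv(path)
    required = {"gene", "group", "luminescence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    if (df["luminescence"] < 0).any():
        raise ValueError("luminescence values must be >= 0")
    return df
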