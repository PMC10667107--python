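"""Glial engulfment volumetrics.

Quantifies how much labeled neuronal material (e.g. GFP⁺ presynaptic inputs)
sits inside a glial cell, Imaris-surface style: the cell (Iba1⁺ microglia or
S100β⁺ astrocyte) is segmented from its marker channel, cargo voxels inside
the cell mask are summed, and

    percent engulfment  = 100 × engulfed cargo volume / cell volume
    input density       = total cargo volume / field-of-view volume
    normalized          = percent engulfment / input density

so that a cell sitting in a denser field of inputs is not credited for
engulfing more simply because more material is available.  Group values are
finally expressed relative to a reference group mean ("relative % engulfment").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

__all__ = [
    "Scene",
    "EngulfmentResult",
    "SegmentationParams",
    "segment_cell",
    "percent_engulfment",
    "input_density",
    "normalized_engulfment",
    "relative_percent",
    "analyze_scene",
]


@dataclass
class Scene:
    """One imaged glial cell: cell-marker and cargo channels plus a seed.

    Arrays are (z, y, x); ``voxel_size_um`` and the seed point are (x, y, z).
    """

    cell_channel: np.ndarray
    cargo_channel: np.ndarray
    voxel_size_um: np.ndarray
    seed_um: np.ndarray
    cell_type: Literal["microglia", "astrocyte"] = "microglia"
    scene_id: str = "scene0"
    animal_id: str = "animal0"

    def __post_init__(self) -> None:
        self.cell_channel = np.asarray(self.cell_channel, dtype=float)
        self.cargo_channel = np.asarray(self.cargo_channel, dtype=float)
        if self.cell_channel.shape != self.cargo_channel.shape:
            raise ValueError("cell and cargo channels must share a shape")
        self.voxel_size_um = np.asarray(self.voxel_size_um, dtype=float)
        if np.any(self.voxel_size_um <= 0):
            raise ValueError("voxel sizes must be > 0")
        self.seed_um = np.asarray(self.seed_um, dtype=float)
        nz, ny, nx = self.cell_channel.shape
        extent = np.array([nx, ny, nz]) * self.voxel_size_um
        if np.any(self.seed_um < 0) or np.any(self.seed_um >= extent):
            raise ValueError("seed point outside the field of view")

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size_um))

    @property
    def field_volume_um3(self) -> float:
        return float(self.cell_channel.size) * self.voxel_volume_um3

    def seed_index(self) -> tuple[int, int, int]:
        """Seed point as a (z, y, x) voxel index."""
        vx, vy, vz = self.voxel_size_um
        x, y, z = self.seed_um
        return (int(z / vz), int(y / vy), int(x / vx))


@dataclass
class SegmentationParams:
    """Thresholding settings for the cell and cargo channels."""

    method: Literal["otsu", "quantile", "fixed"] = "otsu"
    quantile: float = 0.99
    fixed_value: float | None = None


@dataclass
class EngulfmentResult:
    scene_id: str
    animal_id: str
    cell_type: str
    cell_volume_um3: float
    engulfed_volume_um3: float
    percent_engulfment: float
    input_density: float
    normalized_engulfment: float

    def __post_init__(self) -> None:
        assert 0.0 <= self.engulfed_volume_um3 <= self.cell_volume_um3 + 1e-9, (
            "engulfed volume exceeds cell volume"
        )
        assert 0.0 <= self.percent_engulfment <= 100.0 + 1e-9
        assert 0.0 <= self.input_density <= 1.0 + 1e-9


def _threshold(channel: np.ndarray, params: SegmentationParams) -> float:
    if params.method == "fixed":
        if params.fixed_value is None:
            raise ValueError("fixed thresholding requires fixed_value")
        return float(params.fixed_value)
    if params.method == "quantile":
        return float(np.quantile(channel, params.quantile))
    return float(threshold_otsu(channel))


def segment_cell(scene: Scene, params: SegmentationParams | None = None) -> np.ndarray:
    """Segment the seeded cell: the thresholded component containing the seed.

    Returns a boolean (z, y, x) mask.  Raises if the seed voxel falls below
    threshold (i.e. the seed is not on a cell).
    """
    params = params or SegmentationParams()
    thr = _threshold(scene.cell_channel, params)
    binary = scene.cell_channel > thr
    zi, yi, xi = scene.seed_index()
    if not binary[zi, yi, xi]:
        raise ValueError(
            f"seed point {tuple(scene.seed_um)} μm is below the cell threshold "
            f"({thr:.3g}); not inside a cell"
        )
    labels = cc_label(binary, connectivity=1)
    return labels == labels[zi, yi, xi]


def cargo_mask(scene: Scene, params: SegmentationParams | None = None) -> np.ndarray:
    """Threshold the cargo channel into a boolean mask."""
    params = params or SegmentationParams()
    if not np.any(scene.cargo_channel > 0):
        return np.zeros_like(scene.cargo_channel, dtype=bool)
    thr = _threshold(scene.cargo_channel, params)
    return scene.cargo_channel > thr


def percent_engulfment(
    cell_mask: np.ndarray, cargo: np.ndarray, voxel_volume_um3: float = 1.0
) -> float:
    """100 × engulfed cargo volume / cell volume.

    ``cargo`` may be a boolean mask or an intensity channel with a separate
    thresholding already applied.  Invariant to intensity rescaling that
    preserves the thresholded voxel set, since only voxel membership counts.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise ValueError("empty cell mask")
    cargo = np.asarray(cargo, dtype=bool)
    engulfed = int(np.count_nonzero(cargo & cell_mask))
    total = int(np.count_nonzero(cell_mask))
    return 100.0 * engulfed / total


def input_density(scene: Scene, params: SegmentationParams | None = None) -> float:
    """Total cargo⁺ volume / field-of-view volume (dimensionless fraction)."""
    cargo = cargo_mask(scene, params)
    return float(np.count_nonzero(cargo)) / cargo.size


def normalized_engulfment(percent: float, density: float) -> float:
    """Percent engulfment normalized by local input abundance.

    A cell in a field with twice the input density scores half as high for
    the same engulfed fraction.
    """
    if density <= 0:
        raise ValueError("input density must be > 0 for normalization")
    return percent / density


def relative_percent(
    group_values: Sequence[float], reference_group_values: Sequence[float]
) -> np.ndarray:
    """Group values × 100 / reference-group mean ("relative % engulfment")."""
    ref = np.asarray(reference_group_values, dtype=float)
    if ref.size == 0 or ref.mean() == 0:
        raise ValueError("reference group empty or zero-mean")
    return np.asarray(group_values, dtype=float) * 100.0 / ref.mean()


def analyze_scene(
    scene: Scene,
    cell_params: SegmentationParams | None = None,
    cargo_params: SegmentationParams | None = None,
) -> EngulfmentResult:
    """Full per-scene pipeline: segment, measure, normalize."""
    mask = segment_cell(scene, cell_params)
    cargo = cargo_mask(scene, cargo_params)
    voxvol = scene.voxel_volume_um3
    cell_volume = float(np.count_nonzero(mask)) * voxvol
    engulfed = float(np.count_nonzero(cargo & mask)) * voxvol
    pct = percent_engulfment(mask, cargo)
    dens = float(np.count_nonzero(cargo)) / cargo.size
    norm = normalized_engulfment(pct, dens) if dens > 0 else float("nan")
    return EngulfmentResult(
        scene_id=scene.scene_id,
        animal_id=scene.animal_id,
        cell_type=scene.cell_type,
        cell_volume_um3=cell_volume,
        engulfed_volume_um3=engulfed,
        percent_engulfment=pct,
        input_density=dens,
        normalized_engulfment=norm,
    )
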