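"""Core in-memory containers for the imaging arm of the pipeline.

An :class:`ImageStack` is the raw measured object: a multi-channel 3D
confocal stack of a single (tumor-)forebrain organoid, stored plane-major.
Downstream stages attach masks (:class:`SegmentationResult`) and reduce the
stack to compartment summaries (:class:`OrganoidMeasurement`): the tumor
marker summed over segmented tumor areas and the neuronal marker summed over
the whole organoid, across all confocal planes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

TUMOR = "tumor"
NEURONAL = "neuronal"


@dataclass
class ImageStack:
    """Multi-channel 3D image stack, shape (planes, height, width, channels)."""

    voxels: np.ndarray
    channel_names: Sequence[str] = (TUMOR, NEURONAL)
    voxel_size: tuple[float, float, float] | None = None  # (z, y, x), optional

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError(
                f"expected 4D (planes, height, width, channels), got shape {self.voxels.shape}"
            )
        if self.voxels.shape[3] != len(self.channel_names):
            raise ValueError("channel_names length does not match last axis")
        if not np.all(np.isfinite(self.voxels)) or self.voxels.min() < 0:
            raise ValueError("intensities must be finite and non-negative")

    @property
    def n_planes(self) -> int:
        return self.voxels.shape[0]

    @property
    def plane_shape(self) -> tuple[int, int]:
        return self.voxels.shape[1:3]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as a (planes, height, width) array."""
        try:
            idx = list(self.channel_names).index(name)
        except ValueError:
            raise KeyError(
                f"unknown channel {name!r}; available: {list(self.channel_names)}"
            ) from None
        return self.voxels[..., idx]


@dataclass
class SegmentationResult:
    """Boolean organoid and tumor-area masks for one stack.

    ``tumor_mask`` is always a subset of ``organoid_mask``; the thresholds
    actually applied are recorded in ``method``.
    """

    organoid_mask: np.ndarray
    tumor_mask: np.ndarray
    method: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.organoid_mask = np.asarray(self.organoid_mask, dtype=bool)
        self.tumor_mask = np.asarray(self.tumor_mask, dtype=bool)
        if self.organoid_mask.shape != self.tumor_mask.shape:
            raise ValueError("masks must have identical shapes")
        if np.any(self.tumor_mask & ~self.organoid_mask):
            raise ValueError("tumor_mask must be a subset of organoid_mask")


@dataclass
class OrganoidMeasurement:
    """Per-organoid compartment summaries.

    tumor_sum
        Tumor-channel brightness summed over tumor areas, all planes.
    neuronal_sum
        Neuronal-channel brightness summed over the whole organoid, all planes.
    tumor_area / tme_area
        Voxel counts of the tumor compartment and of the organoid minus
        tumor (the neuronal microenvironment).
    per_plane
        Dict of per-plane arrays for each of the four quantities; each sums
        (within floating tolerance) to the whole-stack value.
    """

    tumor_sum: float
    neuronal_sum: float
    tumor_area: int
    tme_area: int
    per_plane: dict[str, np.ndarray] = field(default_factory=dict)
    n_saturated: int = 0
    well_id: str | None = None

    def as_row(self) -> dict:
        return {
            "well_id": self.well_id,
            "tumor_sum": self.tumor_sum,
            "neuronal_sum": self.neuronal_sum,
            "tumor_area": self.tumor_area,
            "tme_area": self.tme_area,
            "n_saturated": self.n_saturated,
        }


@dataclass(frozen=True)
class AggregateStats:
    """Sample mean, SD (n-1 denominator) and SEM of a group of organoids.

    For n == 1 the SD is reported as 0.0 (and hence SEM 0.0): a single
    organoid carries no dispersion information and downstream error bars
    collapse rather than propagate NaN.
    """

    n: int
    mean: float
    sd: float
    sem: float
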