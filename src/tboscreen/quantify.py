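"""Segmentation and compartment-specific summed-brightness measurement.

The per-organoid readout of the screen is deliberately simple and robust:

* the organoid is segmented per plane by Otsu thresholding on the sum of
  all channels, followed by hole filling and retention of the largest
  connected component;
* tumor areas are segmented by a single Otsu threshold on the tumor channel
  restricted to organoid voxels (pooled over all planes), intersected with
  the organoid mask;
* the measurement is the *summed brightness*: tumor-channel intensity summed
  over tumor areas and neuronal-channel intensity summed over the whole
  organoid, across all confocal planes, plus the compartment areas
  (tumor voxels, and organoid-minus-tumor voxels for the tumor
  microenvironment).

Optional constant-background subtraction removes the autofluorescence
pedestal before summing; see :func:`estimate_background`.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .types import NEURONAL, TUMOR, AggregateStats, ImageStack, OrganoidMeasurement, SegmentationResult


def _plane_threshold(plane: np.ndarray, fixed: float | None) -> float | None:
    """Otsu threshold for one plane; None when the plane is degenerate."""
    if fixed is not None:
        return fixed
    if plane.max() <= 0 or np.ptp(plane) == 0:
        return None
    return float(threshold_otsu(plane))


def segment_organoid(
    stack: ImageStack,
    threshold: float | None = None,
    fill_holes: bool = True,
    largest_component_only: bool = True,
) -> np.ndarray:
    """Boolean organoid mask, one thresholded region per plane.

    Per-plane global Otsu on the sum of channels (or a fixed ``threshold``),
    then hole filling and largest connected component per plane. Empty
    planes are allowed; an all-zero stack yields an empty mask with a
    warning rather than an exception.
    """
    total = stack.voxels.sum(axis=-1)
    if total.max() <= 0:
        warnings.warn("all-zero stack: returning empty organoid mask", stacklevel=2)
        return np.zeros(total.shape, dtype=bool)
    mask = np.zeros(total.shape, dtype=bool)
    for k in range(total.shape[0]):
        thr = _plane_threshold(total[k], threshold)
        if thr is None:
            continue
        plane = total[k] > thr
        if fill_holes:
            plane = ndimage.binary_fill_holes(plane)
        if largest_component_only and plane.any():
            labels, n = ndimage.label(plane)
            if n > 1:
                sizes = np.bincount(labels.ravel())
                sizes[0] = 0
                plane = labels == sizes.argmax()
        mask[k] = plane
    return mask


def segment_tumor_areas(
    stack: ImageStack,
    organoid_mask: np.ndarray,
    threshold: float | None = None,
    tumor_channel: str = TUMOR,
) -> np.ndarray:
    """Boolean tumor-area mask, a subset of the organoid mask.

    A single Otsu threshold on the tumor channel pooled over all organoid
    voxels (3D, not per plane: individual planes may contain no tumor), or a
    fixed ``threshold`` from config. Degenerate input (no organoid voxels,
    or an effectively constant tumor channel) yields an empty mask.
    """
    ch = stack.channel(tumor_channel)
    inside = ch[organoid_mask]
    if inside.size == 0:
        return np.zeros_like(organoid_mask)
    if threshold is None:
        if np.ptp(inside) == 0 or inside.max() <= 0:
            return np.zeros_like(organoid_mask)
        threshold = float(threshold_otsu(inside))
    return (ch > threshold) & organoid_mask


def segment(
    stack: ImageStack,
    organoid_threshold: float | None = None,
    tumor_threshold: float | None = None,
    tumor_channel: str = TUMOR,
) -> SegmentationResult:
    """Full segmentation: organoid mask then tumor areas within it."""
    organoid = segment_organoid(stack, threshold=organoid_threshold)
    tumor = segment_tumor_areas(
        stack, organoid, threshold=tumor_threshold, tumor_channel=tumor_channel
    )
    return SegmentationResult(
        organoid_mask=organoid,
        tumor_mask=tumor,
        method={
            "organoid_threshold": organoid_threshold if organoid_threshold is not None else "otsu-per-plane",
            "tumor_threshold": tumor_threshold if tumor_threshold is not None else "otsu-3d-within-organoid",
        },
    )


def sum_brightness(stack: ImageStack, mask: np.ndarray, channel: str) -> tuple[np.ndarray, float]:
    """Per-plane and total summed brightness of ``channel`` within ``mask``.

    Exact arithmetic sum of masked voxel intensities (accumulated in
    float64); the per-plane values add up to the total.
    """
    if mask.shape != stack.voxels.shape[:3]:
        raise ValueError(f"mask shape {mask.shape} does not match stack {stack.voxels.shape[:3]}")
    ch = stack.channel(channel).astype(np.float64)
    per_plane = np.where(mask, ch, 0.0).sum(axis=(1, 2))
    return per_plane, float(per_plane.sum())


def estimate_background(
    stack: ImageStack,
    segmentation: SegmentationResult,
    channel: str,
    method: str = "compartment",
) -> float:
    """Constant per-voxel background estimate for one channel.

    ``compartment``
        Median intensity over the in-organoid voxels where the channel's
        specific signal is absent: organoid-minus-tumor voxels for the tumor
        channel, tumor voxels for the neuronal channel. This targets the
        in-organoid autofluorescence pedestal directly. For the neuronal
        channel the region is restricted to the most tumor-confident half of
        the mask (voxels at or above the mask's median tumor intensity):
        channel noise is independent, so the restriction does not bias the
        estimate, but it guards against dim false-positive mask voxels that
        still carry neuronal signal.
    ``outside``
        Median over out-of-organoid voxels. With dark, noise-clipped
        surroundings this is near zero and removes only camera offset.

    Falls back to ``outside`` when the complement compartment is empty.
    """
    ch = stack.channel(channel)
    if method == "outside":
        region = ~segmentation.organoid_mask
    elif method == "compartment":
        complement = segmentation.organoid_mask & ~segmentation.tumor_mask
        if channel == TUMOR:
            region = complement
        else:
            region = segmentation.tumor_mask
            if region.any() and complement.any():
                tum = stack.channel(TUMOR)
                in_mask = tum[region]
                rest = tum[complement]
                sigma = 1.4826 * np.median(np.abs(rest - np.median(rest)))
                contrast = float(np.median(in_mask) - np.median(rest))
                if contrast <= 3 * sigma:
                    # tumor mask has no real contrast (e.g. fully ablated
                    # tumor): it is a noise split, and its voxels still
                    # carry neuronal signal. Assume a shared pedestal and
                    # reuse the tumor channel's complement estimate.
                    return float(np.median(rest))
                region = region & (tum >= np.median(in_mask))
        if not region.any():
            region = ~segmentation.organoid_mask
    else:
        raise ValueError(f"unknown background method {method!r}")
    if not region.any():
        return 0.0
    return float(np.median(ch[region]))


def measure_organoid(
    stack: ImageStack,
    segmentation: SegmentationResult,
    tumor_channel: str = TUMOR,
    neuronal_channel: str = NEURONAL,
    background: str | float | None = None,
    saturation_level: float | None = None,
    well_id: str | None = None,
) -> OrganoidMeasurement:
    """Reduce one stack to its compartment summaries.

    ``background`` is ``None`` (off), a fixed per-voxel value, or an
    estimation method name for :func:`estimate_background`; when on, the
    estimated pedestal times the number of masked voxels is subtracted from
    each sum (floored at 0). Saturated voxels are never excluded, only
    counted when ``saturation_level`` is given.
    """
    if segmentation.organoid_mask.shape != stack.voxels.shape[:3]:
        raise ValueError("segmentation shape does not match stack")
    tum_pp, tum_total = sum_brightness(stack, segmentation.tumor_mask, tumor_channel)
    neu_pp, neu_total = sum_brightness(stack, segmentation.organoid_mask, neuronal_channel)
    tumor_area_pp = segmentation.tumor_mask.sum(axis=(1, 2))
    organoid_area_pp = segmentation.organoid_mask.sum(axis=(1, 2))

    if background is not None:
        if isinstance(background, (int, float)):
            b_t = b_n = float(background)
        else:
            b_t = estimate_background(stack, segmentation, tumor_channel, method=background)
            b_n = estimate_background(stack, segmentation, neuronal_channel, method=background)
        tum_pp = np.maximum(tum_pp - b_t * tumor_area_pp, 0.0)
        neu_pp = np.maximum(neu_pp - b_n * organoid_area_pp, 0.0)
        tum_total = float(tum_pp.sum())
        neu_total = float(neu_pp.sum())

    n_sat = 0
    if saturation_level is not None:
        n_sat = int((stack.voxels >= saturation_level).sum())

    return OrganoidMeasurement(
        tumor_sum=tum_total,
        neuronal_sum=neu_total,
        tumor_area=int(tumor_area_pp.sum()),
        tme_area=int((organoid_area_pp - tumor_area_pp).sum()),
        per_plane={
            "tumor_sum": tum_pp,
            "neuronal_sum": neu_pp,
            "tumor_area": tumor_area_pp,
            "tme_area": organoid_area_pp - tumor_area_pp,
        },
        n_saturated=n_sat,
        well_id=well_id,
    )


def measure_stacks(
    stacks: Iterable[tuple[str, ImageStack]],
    background: str | float | None = None,
    saturation_level: float | None = None,
) -> list[OrganoidMeasurement]:
    """Segment and measure a stream of (well_id, stack) pairs."""
    out = []
    for well_id, stack in stacks:
        seg = segment(stack)
        out.append(
            measure_organoid(
                stack, seg, background=background,
                saturation_level=saturation_level, well_id=well_id,
            )
        )
    return out


def aggregate_group(
    measurements: Iterable[OrganoidMeasurement] | Sequence[float], field: str | None = None
) -> AggregateStats:
    """Mean, SD (n-1 denominator) and SEM of one measurement field.

    Accepts either raw numbers or measurements plus a ``field`` name
    (``tumor_sum``, ``neuronal_sum``, ``tumor_area``, ``tme_area``).
    A single value has SD and SEM reported as 0 by policy.
    """
    if field is not None:
        values = np.array([getattr(m, field) for m in measurements], dtype=float)
    else:
        values = np.asarray(list(measurements), dtype=float)
    if values.size == 0:
        raise ValueError("cannot aggregate an empty group")
    n = int(values.size)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    return AggregateStats(n=n, mean=mean, sd=sd, sem=sd / np.sqrt(n))
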