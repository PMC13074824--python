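"""Signal-void artifact segmentation for metallic biopsy markers.

Metallic markers dephase nearby spins and carve a signal void into MR
magnitude images that is typically much larger than the marker itself.  The
void is segmented by a noise-referenced threshold rule: estimate the mean of
a no-signal region in or near the phantom, threshold the image at 125% of
that mean, and keep the contiguous sub-threshold region inside the phantom.
Extent is reported per imaging axis from the maximum number of mask voxels
along any line parallel to that axis, and volume from the voxel count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["ArtifactSegmentation", "segment_signal_void", "artifact_extent"]

logger = logging.getLogger(__name__)

#: The void threshold as a multiple of the noise-region mean.
THRESHOLD_FACTOR = 1.25


@dataclass
class ArtifactSegmentation:
    """Void mask with per-axis extents (mm), volume (mm^3) and the threshold used."""

    mask: np.ndarray
    extent_mm: tuple[float, float, float]
    volume_mm3: float
    threshold_used: float


def artifact_extent(
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    mode: str = "line_count",
) -> tuple[float, float, float]:
    """Per-axis extent of a mask in millimetres.

    ``line_count`` (default): for each axis, the maximum over all lines
    parallel to that axis of the number of mask voxels on the line, times
    the spacing.  ``bounding_box``: the bounding-box width instead (the
    looser reading of "maximum number of voxels along each axis").  An
    empty mask has zero extents.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return (0.0, 0.0, 0.0)
    extents = []
    for ax in range(3):
        if mode == "line_count":
            n = int(mask.sum(axis=ax).max())
        elif mode == "bounding_box":
            idx = np.nonzero(mask.any(axis=tuple(a for a in range(3) if a != ax)))[0]
            n = int(idx.max() - idx.min() + 1)
        else:
            raise ValueError(f"unknown extent mode {mode!r}")
        extents.append(n * spacing[ax] * 1e3)
    return tuple(extents)


def segment_signal_void(
    image: np.ndarray,
    noise_region: np.ndarray,
    phantom_mask: np.ndarray,
    spacing: tuple[float, float, float],
    connectivity: int = 1,
    seed_point: tuple[int, int, int] | None = None,
    extent_mode: str = "line_count",
) -> ArtifactSegmentation:
    """Segment the marker signal void by the 125%-of-noise-mean threshold rule.

    Candidate voxels satisfy ``image < 1.25 * mean(image over noise_region)``
    (strictly less than) and lie inside ``phantom_mask``.  The returned mask
    is the largest connected candidate component, or -- when ``seed_point``
    is given, for images with several voids -- the component containing the
    seed.  An empty candidate set yields an empty segmentation with volume 0
    (a valid result, logged).  The rule is invariant under positive scaling
    of the image, since the threshold scales with the noise mean.
    """
    image = np.asarray(image, dtype=float)
    noise_region = np.asarray(noise_region, dtype=bool)
    phantom_mask = np.asarray(phantom_mask, dtype=bool)
    if not noise_region.any():
        raise ValueError("noise region must be nonempty")
    if not phantom_mask.any():
        raise ValueError("phantom mask must be nonempty")

    threshold = THRESHOLD_FACTOR * float(image[noise_region].mean())
    candidates = (image < threshold) & phantom_mask
    if not candidates.any():
        logger.info("no sub-threshold voxels inside the phantom; empty segmentation")
        mask = np.zeros_like(candidates)
    else:
        structure = ndimage.generate_binary_structure(3, connectivity)
        labels, _ = ndimage.label(candidates, structure=structure)
        if seed_point is not None:
            lab = labels[tuple(seed_point)]
            if lab == 0:
                logger.info("seed point is not a candidate voxel; empty segmentation")
                mask = np.zeros_like(candidates)
            else:
                mask = labels == lab
        else:
            counts = np.bincount(labels.ravel())[1:]
            mask = labels == int(np.argmax(counts)) + 1

    volume_mm3 = float(mask.sum()) * float(np.prod(spacing)) * 1e9
    return ArtifactSegmentation(
        mask=mask,
        extent_mm=artifact_extent(mask, spacing, mode=extent_mode),
        volume_mm3=volume_mm3,
        threshold_used=threshold,
    )
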