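"""Skin-VOI construction from the attenuation map.

The body contour is traced on the in-vivo attenuation map (background
null outside the body) by thresholding; the skin VOI is the shell left
after eroding the contour inwards by ``n`` voxel layers (default 3,
nominally 9.375 mm at 3.125 mm in-plane spacing); the shell is then
partitioned into five regions (face, scalp, chest, abdomen, back) by
axis-aligned anatomical planes, with an automated exclusion rule
standing in for the manual removal of adjacent hot-organ uptake.

Erosion uses the 6-connected (face-adjacent) structuring element,
iterated, so "n voxels" means n surface layers regardless of the
anisotropic voxel size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import (
    Landmarks,
    Mask,
    Region,
    RegionLabelMap,
    SegmentationError,
    SubjectMeta,
    Volume,
)
from .quantification import suv_bw
from .volume_io import require_registered

log = logging.getLogger(__name__)

#: 6-connected (face-adjacent) structuring element.
_CROSS = ndimage.generate_binary_structure(3, 1)
#: 26-connected element used for body-component labeling.
_FULL = ndimage.generate_binary_structure(3, 3)

DEFAULT_ERODE_VOXELS = 3
DEFAULT_SPILLOVER_SUV = 2.5
DEFAULT_SPILLOVER_DILATE = 2


def shell_depth_mm(n_voxels: int, inplane_spacing_mm: float) -> float:
    """Nominal in-plane depth of an ``n``-layer shell, mm."""
    return n_voxels * inplane_spacing_mm


def body_contour_mask(pifa: Volume, threshold: float = 0.0) -> Mask:
    """Trace the body contour on the attenuation map by thresholding.

    Keeps the largest 26-connected component above ``threshold`` and
    fills internal holes in 3D (internal air would otherwise create
    spurious shells).
    """
    above = np.asarray(pifa.data) > threshold
    if not above.any():
        raise SegmentationError("no body found: threshold leaves an empty mask")
    labeled, n_comp = ndimage.label(above, structure=_FULL)
    if n_comp > 1:
        counts = np.bincount(labeled.ravel())[1:]
        keep = int(np.argmax(counts)) + 1
        log.warning("body contour: %d disjoint components; keeping largest (%d voxels)",
                    n_comp, counts[keep - 1])
        above = labeled == keep
    filled = ndimage.binary_fill_holes(above)
    return Mask.from_volume(pifa, filled, tag="body")


def erode_mask(mask: Mask, n_voxels: int) -> Mask:
    """Erode a mask by ``n`` iterations of the 6-connected element.

    ``n = 0`` is the identity; eroding to empty is legal.  Voxels
    outside the grid count as background, so a mask touching the grid
    border is eroded there too.
    """
    if n_voxels < 0:
        raise ValueError(f"n_voxels must be >= 0, got {n_voxels}")
    if n_voxels == 0:
        return mask.like(mask.data.copy(), tag="interior")
    eroded = ndimage.binary_erosion(mask.data, structure=_CROSS, iterations=n_voxels,
                                    border_value=0)
    return mask.like(eroded, tag="interior")


def skin_shell(body: Mask, n_voxels: int = DEFAULT_ERODE_VOXELS) -> Mask:
    """The skin VOI: body minus its ``n``-fold erosion.

    A body thinner than about ``2 n`` voxels erodes to an empty interior,
    leaving no surface shell to subtract — rejected as degenerate.
    """
    interior = erode_mask(body, n_voxels)
    if not interior.data.any():
        raise SegmentationError(
            f"skin shell is degenerate (empty interior): body is thinner "
            f"than {2 * n_voxels} voxels")
    shell = body.data & ~interior.data
    if not shell.any():
        raise SegmentationError("skin shell is empty")
    return body.like(shell, tag="shell")


@dataclass(frozen=True)
class SpilloverReport:
    """Voxels removed from the shell near hot interior sources."""

    removed_voxels: int
    n_sources: int
    source_sizes: tuple[int, ...] = ()

    @property
    def adjusted(self) -> bool:
        return self.removed_voxels > 0


def exclude_organ_spillover(
    shell: Mask,
    pet: Volume,
    interior: Mask,
    meta: SubjectMeta,
    suv_threshold: float = DEFAULT_SPILLOVER_SUV,
    dilate_voxels: int = DEFAULT_SPILLOVER_DILATE,
) -> tuple[Mask, SpilloverReport]:
    """Remove shell voxels adjacent to hot interior organs.

    Automated stand-in for the manual VOI review that keeps brain,
    salivary-gland, liver and urinary uptake out of the skin VOI:
    interior voxels whose SUV exceeds ``suv_threshold`` are dilated by
    ``dilate_voxels`` (6-connectivity) and subtracted from the shell.
    """
    require_registered(shell, pet)
    require_registered(interior, pet)
    suv = suv_bw(np.asarray(pet.data), meta.dose_bq, meta.weight_g)
    hot = interior.data & (suv > suv_threshold)
    if not hot.any():
        return shell.like(shell.data.copy(), tag="shell"), SpilloverReport(0, 0)
    _, n_sources = ndimage.label(hot, structure=_FULL)
    sizes = tuple(int(s) for s in
                  np.bincount(ndimage.label(hot, structure=_FULL)[0].ravel())[1:])
    zone = ndimage.binary_dilation(hot, structure=_CROSS, iterations=dilate_voxels) \
        if dilate_voxels > 0 else hot
    cleaned = shell.data & ~zone
    removed = int(shell.data.sum() - cleaned.sum())
    if not cleaned.any():
        raise SegmentationError("spillover exclusion removed the entire shell")
    return shell.like(cleaned, tag="shell"), SpilloverReport(removed, n_sources, sizes)


def classify_region_planes(
    shell_data: np.ndarray,
    coords: tuple[np.ndarray, np.ndarray, np.ndarray],
    landmarks: Landmarks,
) -> np.ndarray:
    """Label shell voxels by plane-side classification (vectorized).

    Head (cranial to the neck plane) splits at the coronal ear-canal
    plane into face (anterior, inclusive) and scalp; the trunk splits at
    the coronal mid-arm plane into back (posterior) and an anterior part
    split at the axial T12 plane into chest (cranial, inclusive) and
    abdomen.
    """
    _, cy, cz = coords
    head = cz > landmarks.neck.offset_mm
    anterior_head = cy >= landmarks.ear_canal.offset_mm
    anterior_trunk = cy >= landmarks.mid_arm.offset_mm
    chestward = cz >= landmarks.t12.offset_mm

    labels = np.zeros(shell_data.shape, dtype=np.int16)
    shell = shell_data.astype(bool)
    labels[shell & head & anterior_head] = int(Region.FACE)
    labels[shell & head & ~anterior_head] = int(Region.SCALP)
    labels[shell & ~head & ~anterior_trunk] = int(Region.BACK)
    labels[shell & ~head & anterior_trunk & chestward] = int(Region.CHEST)
    labels[shell & ~head & anterior_trunk & ~chestward] = int(Region.ABDOMEN)
    return labels


def partition_regions(shell: Mask, landmarks: Landmarks) -> RegionLabelMap:
    """Partition the skin shell into the five regions by landmark planes."""
    coords_1d = [shell.axis_coords(a) for a in range(3)]
    for name, plane in (("ear_canal", landmarks.ear_canal), ("mid_arm", landmarks.mid_arm),
                        ("t12", landmarks.t12), ("neck", landmarks.neck)):
        ax = plane.axis_index
        lo, hi = coords_1d[ax][0], coords_1d[ax][-1]
        if not (lo - shell.spacing[ax] <= plane.offset_mm <= hi + shell.spacing[ax]):
            raise SegmentationError(
                f"landmark plane {name!r} ({plane.axis}={plane.offset_mm} mm) "
                f"lies outside the volume extent [{lo}, {hi}] mm")
    cx, cy, cz = coords_1d
    coords = (cx[:, None, None], cy[None, :, None], cz[None, None, :])
    labels = classify_region_planes(shell.data, coords, landmarks)
    return RegionLabelMap(labels, shell.spacing, shell.origin)
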