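"""Electrode-contact segmentation from a brain-masked post-implant CT.

Metal voxels are isolated by masking and percentile thresholding, cleaned
with a small spherical median filter, resampled to the 1 mm isotropic
working space, and then reduced — by repeated grouping, directional 1-D
erosion, and representative replacement — until every physical contact is
represented by a canonical 3x3x3-voxel cube whose centre (the *midpoint*)
is the reported contact location.

The directional erosion scheme thins the bridges that CT streaking and
blur create between neighbouring contacts: a component wider than the
representative along z is eroded along x, wider along x is eroded along y,
and wider along y is eroded along x.  Because this rule set cannot shrink
every shape (no z-directional erosion is ever applied), a fallback erosion
along the widest oversized axis runs whenever a full pass removes nothing,
which guarantees termination.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import (
    FACE_STRUCTURE,
    VoxelGrid,
    erode_mask,
    grid_as_bool,
    resample_isotropic,
)

logger = logging.getLogger(__name__)

TEMPLATE_EDGE = 3  # representative contact is a 3 mm x 3 mm x 3 mm cube


@dataclass
class SegmentationParams:
    """Tunable parameters of the contact segmentation stage.

    Defaults are the pipeline's operating point for CT data with heavy
    metal artifacts: a high metal threshold, a small median filter, and an
    aggressive rethreshold after interpolation.
    """

    metal_percentile: float = 99.5
    median_kernel_radius_mm: float = 0.5
    rethreshold_percentile: float = 40.0
    mask_erosions: int = 3
    template_edge: int = TEMPLATE_EDGE

    def __post_init__(self) -> None:
        for p in (self.metal_percentile, self.rethreshold_percentile):
            if not 0 < p < 100:
                raise ValueError(f"percentile {p} outside (0, 100)")
        if self.median_kernel_radius_mm <= 0 or self.template_edge <= 0:
            raise ValueError("radius and template edge must be positive")
        if self.mask_erosions < 0:
            raise ValueError("mask_erosions must be >= 0")

    @property
    def template_volume(self) -> int:
        return self.template_edge ** 3

    @property
    def replace_below(self) -> int:
        # "smaller than half the size of the representative"
        return int(np.ceil(self.template_volume / 2))


@dataclass
class ContactComponent:
    """A face-connected set of metal voxels — the unit of the erosion loop."""

    voxels: np.ndarray  # (n, 3) 0-based indices
    forced_midpoint: np.ndarray | None = None  # set for clipped template cubes

    def __post_init__(self) -> None:
        self.voxels = np.atleast_2d(np.asarray(self.voxels, dtype=np.int64))
        if self.voxels.size == 0:
            raise ValueError("component must be non-empty")

    @property
    def size(self) -> int:
        return len(self.voxels)

    @property
    def extent(self) -> np.ndarray:
        """Per-axis bounding-box width in voxels."""
        return self.voxels.max(axis=0) - self.voxels.min(axis=0) + 1

    @property
    def midpoint(self) -> np.ndarray:
        """Centroid of the voxels, rounded to the nearest voxel index."""
        if self.forced_midpoint is not None:
            return np.asarray(self.forced_midpoint, dtype=np.int64)
        return np.round(self.voxels.mean(axis=0)).astype(np.int64)


@dataclass
class ContactSet:
    """Localized contacts on the 1 mm isotropic working grid."""

    contacts: list[ContactComponent]
    grid: VoxelGrid  # reference lattice (defines index -> mm)
    params: SegmentationParams = field(default_factory=SegmentationParams)

    def midpoints_vox(self) -> np.ndarray:
        if not self.contacts:
            return np.empty((0, 3), dtype=np.int64)
        return np.array([c.midpoint for c in self.contacts])

    def midpoints_mm(self) -> np.ndarray:
        if not self.contacts:
            return np.empty((0, 3))
        return np.atleast_2d(self.grid.index_to_world(self.midpoints_vox().astype(float)))

    def to_table(self) -> pd.DataFrame:
        vox = self.midpoints_vox()
        mm = self.midpoints_mm()
        return pd.DataFrame(
            {
                "contact_id": np.arange(1, len(self.contacts) + 1),
                "x_vox": vox[:, 0] if len(vox) else [],
                "y_vox": vox[:, 1] if len(vox) else [],
                "z_vox": vox[:, 2] if len(vox) else [],
                "x_mm": mm[:, 0] if len(mm) else [],
                "y_mm": mm[:, 1] if len(mm) else [],
                "z_mm": mm[:, 2] if len(mm) else [],
            }
        )

    def to_label_volume(self) -> VoxelGrid:
        """Integer label volume: each representative cube carries its id."""
        lab = np.zeros(self.grid.shape, dtype=np.int32)
        half = self.params.template_edge // 2
        for i, c in enumerate(self.contacts, start=1):
            lo = np.maximum(c.midpoint - half, 0)
            hi = np.minimum(c.midpoint + half + 1, self.grid.shape)
            lab[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = i
        return self.grid.with_data(lab)


def isolate_metal(
    ct: VoxelGrid, brain_mask: VoxelGrid, params: SegmentationParams | None = None
) -> VoxelGrid:
    """Keep only metal(-artifact) voxels inside the eroded brain mask.

    The brain mask is eroded ``params.mask_erosions`` times so skull
    remnants at the mask rim cannot pass the threshold, then voxels at or
    above the ``metal_percentile`` of the in-mask intensity distribution
    are retained.
    """
    params = params or SegmentationParams()
    if ct.shape != brain_mask.shape:
        raise ValueError("CT and brain mask must share the lattice")
    eroded = grid_as_bool(erode_mask(brain_mask, params.mask_erosions))
    if not eroded.any():
        raise ValueError("brain mask is empty after erosion")
    inside = ct.data[eroded]
    if np.ptp(inside) == 0:
        raise ValueError("constant image inside mask: threshold undefined")
    thr = np.percentile(inside, params.metal_percentile)
    out = (ct.data >= thr) & eroded
    return ct.with_data(out.astype(np.uint8))


def median_filter_sphere(
    mask: VoxelGrid, radius_mm: float = 0.5, spacing: np.ndarray | None = None
) -> VoxelGrid:
    """Median filter with a spherical kernel rendered in native voxels.

    The kernel contains every voxel whose centre lies within ``radius_mm``
    of the central voxel; at typical CT spacing this is a small cross.
    Removes isolated voxels and thin streaks while preserving solid blobs.
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    spacing = np.asarray(spacing if spacing is not None else mask.spacing)
    half = np.maximum(np.floor(radius_mm / spacing).astype(int), 0)
    grids = np.mgrid[
        -half[0] : half[0] + 1, -half[1] : half[1] + 1, -half[2] : half[2] + 1
    ]
    dist2 = sum((grids[i] * spacing[i]) ** 2 for i in range(3))
    footprint = dist2 <= radius_mm ** 2
    data = grid_as_bool(mask).astype(np.uint8)
    out = ndimage.median_filter(data, footprint=footprint, mode="constant", cval=0)
    return mask.with_data(out.astype(np.uint8))


def rethreshold_after_resample(
    mask_grid: VoxelGrid, params: SegmentationParams | None = None
) -> VoxelGrid:
    """Re-binarize a linearly resampled metal map.

    Linear interpolation leaves a fractional-valued halo around each blob;
    thresholding at the ``rethreshold_percentile`` of the strictly positive
    values removes it. An all-zero input yields an empty mask.
    """
    params = params or SegmentationParams()
    data = np.asarray(mask_grid.data, dtype=float)
    positive = data[data > 0]
    if positive.size == 0:
        return mask_grid.with_data(np.zeros(mask_grid.shape, dtype=np.uint8))
    thr = np.percentile(positive, params.rethreshold_percentile)
    return mask_grid.with_data((data >= thr).astype(np.uint8))


def remove_isolated_voxels(mask: VoxelGrid) -> VoxelGrid:
    """Drop voxels with no face-neighbour in the mask (outlier speckle)."""
    data = grid_as_bool(mask)
    neighbours = ndimage.convolve(
        data.astype(np.uint8), FACE_STRUCTURE.astype(np.uint8), mode="constant", cval=0
    )
    # FACE_STRUCTURE includes the centre, so an isolated voxel counts 1
    out = data & (neighbours >= 2)
    return mask.with_data(out.astype(np.uint8))


def group_components(mask: VoxelGrid) -> list[ContactComponent]:
    """Partition the mask into maximal face-connected (6-neighbour)
    components, ordered by their lexicographically smallest voxel.

    Diagonal adjacency does not join components, which keeps contacts that
    almost touch from clumping together.
    """
    data = grid_as_bool(mask)
    labels, n = ndimage.label(data, structure=FACE_STRUCTURE)
    comps = []
    for idx in ndimage.value_indices(labels, ignore_value=0).values():
        vox = np.stack(idx, axis=1)
        order = np.lexsort((vox[:, 2], vox[:, 1], vox[:, 0]))
        comps.append(ContactComponent(vox[order]))
    comps.sort(key=lambda c: tuple(c.voxels[0]))
    return comps


def _erode_1d(voxels: np.ndarray, axis: int) -> np.ndarray:
    """One 1-D erosion pass along ``axis`` on a voxel set: a voxel survives
    iff both of its neighbours along that axis are in the set."""
    vset = set(map(tuple, voxels))
    keep = []
    for v in voxels:
        lo = list(v)
        hi = list(v)
        lo[axis] -= 1
        hi[axis] += 1
        if tuple(lo) in vset and tuple(hi) in vset:
            keep.append(v)
    return np.array(keep, dtype=np.int64) if keep else np.empty((0, 3), np.int64)


def erode_component(
    component: ContactComponent, params: SegmentationParams | None = None
) -> ContactComponent | None:
    """Apply one pass of the directional erosion rules to an oversized
    component.

    Rules, checked in order: wider than the template along z -> erode
    along x; wider along x -> erode along y; wider along y -> erode along
    x.  Exactly one erosion fires per pass (the first rule whose condition
    holds): grouping re-runs between passes, so a component that splits is
    re-partitioned — and its pieces replaced — before any further erosion
    can destroy them.  If the fired erosion removes nothing (pathological
    shape), one fallback erosion along the widest oversized axis is
    applied so the outer loop always makes progress.  Returns ``None``
    when the component erodes away entirely.
    """
    params = params or SegmentationParams()
    edge = params.template_edge
    ext = component.extent
    if not np.any(ext > edge):
        raise ValueError("component does not exceed the template; nothing to erode")
    vox = component.voxels
    for oversized_axis, erode_axis in ((2, 0), (0, 1), (1, 0)):
        if ext[oversized_axis] > edge:
            vox = _erode_1d(vox, erode_axis)
            break
    if vox.size and len(vox) == len(component.voxels):
        widest = int(np.argmax(np.where(ext > edge, ext, -1)))
        vox = _erode_1d(vox, widest)
    if vox.size == 0:
        logger.warning("component eroded away entirely; dropped")
        return None
    return ContactComponent(vox)


def replace_with_representative(
    component: ContactComponent,
    params: SegmentationParams | None = None,
    shape: tuple[int, int, int] | None = None,
) -> ContactComponent:
    """Replace a sufficiently eroded component by the canonical template
    cube centred on its midpoint (rounded centroid of surviving voxels).

    If ``shape`` is given the cube is clipped to the lattice bounds; the
    midpoint is preserved either way.
    """
    params = params or SegmentationParams()
    edge = params.template_edge
    small = component.size < params.replace_below
    fits = bool(np.all(component.extent <= edge))
    if not (small or fits):
        raise ValueError(
            f"component (n={component.size}, extent={tuple(component.extent)}) "
            "is not yet replaceable"
        )
    mid = component.midpoint
    half = edge // 2
    rng = np.arange(-half, half + 1)
    cube = np.stack(np.meshgrid(rng, rng, rng, indexing="ij"), axis=-1).reshape(-1, 3)
    cube = cube + mid
    if shape is not None:
        inside = np.all((cube >= 0) & (cube < np.asarray(shape)), axis=1)
        cube = cube[inside]
    return ContactComponent(cube, forced_midpoint=mid)


def segment_contacts(
    ct: VoxelGrid,
    brain_mask: VoxelGrid,
    params: SegmentationParams | None = None,
    target_mm: float = 1.0,
) -> ContactSet:
    """Full contact segmentation: isolate metal, clean, move to the 1 mm
    isotropic working space, then group/erode/replace until every contact
    is a representative cube.

    Returns a :class:`ContactSet` whose midpoints are available both as
    voxel indices on the working grid and as world mm.
    """
    params = params or SegmentationParams()
    metal = isolate_metal(ct, brain_mask, params)
    metal = median_filter_sphere(metal, params.median_kernel_radius_mm)
    resampled = resample_isotropic(metal, target_mm, method="linear")
    binary = rethreshold_after_resample(resampled, params)
    binary = remove_isolated_voxels(binary)

    working = grid_as_bool(binary)
    grid = binary.with_data(working.astype(np.uint8))
    replaced: list[ContactComponent] = []
    prev_total = None
    while True:
        comps = group_components(grid.with_data(working.astype(np.uint8)))
        if not comps:
            break
        total = sum(c.size for c in comps)
        if prev_total is not None and total >= prev_total:
            # cannot happen: erosion and replacement both strictly remove
            raise RuntimeError("erosion loop failed to make progress")
        prev_total = total
        next_mask = np.zeros_like(working)
        for comp in comps:
            if comp.size < params.replace_below or np.all(
                comp.extent <= params.template_edge
            ):
                replaced.append(
                    replace_with_representative(comp, params, shape=grid.shape)
                )
            else:
                eroded = erode_component(comp, params)
                if eroded is not None:
                    next_mask[tuple(eroded.voxels.T)] = True
        working = next_mask

    if not replaced:
        warnings.warn("no contacts found in the masked CT")
    replaced = _dedupe(replaced)
    replaced.sort(key=lambda c: tuple(c.midpoint))
    return ContactSet(replaced, grid, params)


def _dedupe(contacts: list[ContactComponent]) -> list[ContactComponent]:
    seen: set[tuple] = set()
    out = []
    for c in contacts:
        key = tuple(c.midpoint)
        if key in seen:
            logger.warning("duplicate contact midpoint %s dropped", key)
            continue
        seen.add(key)
        out.append(c)
    return out
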