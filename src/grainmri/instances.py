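"""Embryo-seeded instance separation of multi-seed volumes.

Each grain carries exactly one embryo, so connected components of the
embryo class provide one marker per grain; instance labels are then
inflated outwards over the foreground with a watershed on the negated
Euclidean distance-to-background map.  Separated instances are centered
into fixed-size crops, with the intensity data carved out under the same
instance mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.segmentation import watershed

from .errors import SizeError
from .io import IntensityVolume, LabelVolume, N_CLASSES

logger = logging.getLogger(__name__)

#: 26-connectivity structuring element used for components and watershed.
STRUCTURE_26 = np.ones((3, 3, 3), dtype=int)


@dataclass
class SeedInstance:
    """One separated grain: congruent label and intensity crops."""

    instance_id: int
    source_id: str
    labels: np.ndarray          # uint8 crop, classes 0-4
    intensity: np.ndarray       # float32 crop, background zeroed
    offset: tuple               # crop corner in source-volume coordinates
    voxel_size: float
    aligned: bool = False
    rotation: np.ndarray | None = None   # principal-axes rotation matrix
    roll_deg: float | None = None

    @property
    def shape(self):
        return self.labels.shape

    def class_counts(self) -> dict:
        counts = np.bincount(self.labels.ravel(), minlength=N_CLASSES)
        return {c: int(counts[c]) for c in range(N_CLASSES)}

    @property
    def foreground(self) -> np.ndarray:
        return self.labels > 0


def find_embryo_seeds(labels: LabelVolume, min_size: int = 50):
    """One watershed seed per embryo: component centroids snapped to voxels.

    Connected components (26-connectivity) of the embryo class with at
    least ``min_size`` voxels each contribute one seed point at their
    centroid, snapped to the nearest voxel of the same component so the
    seed always lies inside the embryo.  Returns a possibly empty list of
    integer (i, j, k) triples.
    """
    embryo = labels.data == 1
    comp, n = ndimage.label(embryo, structure=STRUCTURE_26)
    seeds = []
    for i in range(1, n + 1):
        coords = np.argwhere(comp == i)
        if len(coords) < min_size:
            continue
        centroid = coords.mean(axis=0)
        nearest = coords[np.argmin(((coords - centroid) ** 2).sum(axis=1))]
        seeds.append(tuple(int(v) for v in nearest))
    return seeds


def separate_instances(labels: LabelVolume, intensity: IntensityVolume | None = None,
                       min_size: int = 50, instance_shape=(200, 180, 180)):
    """Split a labeled volume into per-grain :class:`SeedInstance` crops.

    Watershed runs on the negated distance-to-background transform,
    restricted to foreground and seeded by :func:`find_embryo_seeds`, so
    every foreground voxel joins exactly one embryo-anchored instance.
    Foreground components containing no embryo seed are logged as orphans
    and excluded.  Each instance is centered into an ``instance_shape``
    crop (zero padded when the crop extends past the source bounds); an
    instance larger than the crop raises :class:`SizeError`.
    """
    fg = labels.data > 0
    seeds = find_embryo_seeds(labels, min_size=min_size)
    if not seeds:
        logger.warning("no embryo seeds found in %s; nothing to separate", labels.source_id)
        return []
    markers = np.zeros(labels.data.shape, dtype=np.int32)
    for i, pt in enumerate(seeds, start=1):
        markers[pt] = i
    dist = ndimage.distance_transform_edt(fg)
    ws = watershed(-dist, markers=markers, mask=fg, connectivity=STRUCTURE_26)
    orphan = int(np.count_nonzero(fg & (ws == 0)))
    if orphan:
        logger.warning("%d orphan foreground voxels (no embryo) excluded in %s",
                       orphan, labels.source_id)

    instance_shape = tuple(int(v) for v in instance_shape)
    instances = []
    for i in range(1, len(seeds) + 1):
        mask = ws == i
        coords = np.argwhere(mask)
        lo, hi = coords.min(axis=0), coords.max(axis=0)
        extent = hi - lo + 1
        if np.any(extent > np.array(instance_shape)):
            raise SizeError(
                f"instance {i} extent {tuple(extent)} exceeds crop shape {instance_shape}")
        center = (lo + hi) / 2.0
        corner = np.round(center - (np.array(instance_shape) - 1) / 2.0).astype(int)
        lab_crop = _extract(labels.data * mask, corner, instance_shape)
        if intensity is not None:
            int_crop = _extract(intensity.data * mask, corner, instance_shape).astype(np.float32)
        else:
            int_crop = np.zeros(instance_shape, dtype=np.float32)
        instances.append(SeedInstance(
            instance_id=i, source_id=labels.source_id,
            labels=lab_crop.astype(np.uint8), intensity=int_crop,
            offset=tuple(int(v) for v in corner), voxel_size=labels.voxel_size))
    return instances


def _extract(data, corner, shape):
    """Copy a window that may extend past the array bounds (zero fill)."""
    out = np.zeros(shape, dtype=data.dtype)
    src_sl, dst_sl = [], []
    for axis in range(3):
        s0 = int(corner[axis])
        s1 = s0 + shape[axis]
        c0, c1 = max(s0, 0), min(s1, data.shape[axis])
        src_sl.append(slice(c0, c1))
        dst_sl.append(slice(c0 - s0, c1 - s0))
    out[tuple(dst_sl)] = data[tuple(src_sl)]
    return out
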