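"""Deterministic classical segmenter: nearest class intensity + cleanup.

This is the training-free oracle route through the pipeline: when the class
intensity bands are known (as for rendered phantoms), each voxel is assigned
to the class with the nearest mean intensity and small per-class speckle
components are removed.  On a zero-noise rendering this reproduces the
source labels exactly.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..errors import ConfigError
from ..io import IntensityVolume, LabelVolume


def fallback_segment(vol: IntensityVolume, class_intensity_table: dict,
                     tol: float = 10.0, min_size: int = 20) -> LabelVolume:
    """Classify voxels by nearest class mean intensity, then clean speckle.

    Parameters
    ----------
    vol : IntensityVolume
        Raw (unstandardized) intensity volume.
    class_intensity_table : dict
        Mapping class id (0-4) -> expected mean intensity.  Class means must
        be pairwise separated by more than ``2 * tol``.
    tol : float
        Half-width of the intensity band owned by each class; only used for
        the separation precondition.
    min_size : int
        Connected components (26-connectivity) of a tissue class smaller
        than this are reset to background.
    """
    classes = sorted(class_intensity_table)
    means = np.array([class_intensity_table[c] for c in classes], dtype=np.float32)
    gaps = np.abs(means[:, None] - means[None, :])[np.triu_indices(len(means), 1)]
    if np.any(gaps <= 2 * tol):
        raise ConfigError(
            f"class intensity bands overlap: min separation {gaps.min():.3g} <= 2*tol={2 * tol:.3g}")
    nearest = np.abs(vol.data[..., None] - means[None, None, None, :]).argmin(axis=-1)
    labels = np.array(classes, dtype=np.uint8)[nearest]
    if min_size > 0:
        structure = np.ones((3, 3, 3), dtype=int)
        for c in classes:
            if c == 0:
                continue
            comp, n = ndimage.label(labels == c, structure=structure)
            if n == 0:
                continue
            sizes = ndimage.sum_labels(labels == c, comp, index=np.arange(1, n + 1))
            small = np.flatnonzero(sizes < min_size) + 1
            if small.size:
                labels[np.isin(comp, small)] = 0
    return LabelVolume(labels, voxel_size=vol.voxel_size, source_id=vol.source_id)
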