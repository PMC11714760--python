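"""Shared voxel-geometry helpers: central sections and the crease profile.

The crease (the ventral fold of a cereal grain) is measured on the central
cross-section as the hull-deficiency region: the 2D convex hull of the
section minus the section mask, restricted to its largest connected
component.  Its depth is the axis-parallel distance from the bottom of the
section to the farthest (highest) point of that profile.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.morphology import convex_hull_image


def central_section_index(mask: np.ndarray) -> int:
    """Mid index of the foreground span along axis 0 (ties -> lower index)."""
    fg = np.flatnonzero(mask.any(axis=(1, 2)))
    if fg.size == 0:
        raise ValueError("empty mask has no central section")
    return int((fg[0] + fg[-1]) // 2)


def crease_profile(section: np.ndarray) -> np.ndarray:
    """Largest connected component of (2D convex hull minus section mask).

    The raw hull deficiency of a digitized convex shape contains 1-2 px
    slivers along the boundary (rasterization, not anatomy), so the
    deficiency is opened with a 3x3 square before taking the largest
    component; a genuine crease groove (several voxels deep and wide)
    survives the opening, slivers do not.  Returns a boolean image of the
    section's shape; all-False when the section is convex (no crease).
    """
    section = section.astype(bool)
    if not section.any():
        return np.zeros_like(section)
    hull = convex_hull_image(section)
    deficiency = hull & ~section
    deficiency = ndimage.binary_opening(deficiency, structure=np.ones((3, 3), dtype=bool))
    if not deficiency.any():
        return np.zeros_like(section)
    lab, n = ndimage.label(deficiency, structure=np.ones((3, 3), dtype=int))
    sizes = ndimage.sum_labels(deficiency, lab, index=np.arange(1, n + 1))
    return lab == (int(np.argmax(sizes)) + 1)


def crease_depth_voxels(section: np.ndarray) -> float:
    """Crease depth on one cross-section, in voxels.

    Depth = (max axis-1 index of the crease profile) - (min axis-1 index of
    the section foreground), measured along the depth axis (axis 1 of the
    2D section, i.e. volume axis 2).  0 for a convex section.
    """
    section = section.astype(bool)
    profile = crease_profile(section)
    if not profile.any():
        return 0.0
    depth_idx_profile = np.flatnonzero(profile.any(axis=0))
    depth_idx_section = np.flatnonzero(section.any(axis=0))
    return float(depth_idx_profile[-1] - depth_idx_section[0])


def largest_component(mask: np.ndarray, connectivity=None) -> np.ndarray:
    """Largest connected component of a boolean array (26-conn default in 3D)."""
    if connectivity is None:
        connectivity = np.ones((3,) * mask.ndim, dtype=int)
    lab, n = ndimage.label(mask, structure=connectivity)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
    return lab == (int(np.argmax(sizes)) + 1)


def surface_voxel_count(mask: np.ndarray) -> int:
    """Number of foreground voxels with at least one background 6-neighbour.

    Used as a perimeter-roughness measure: a rougher reassembled surface
    exposes more boundary voxels for the same enclosed volume.
    """
    mask = mask.astype(bool)
    eroded = ndimage.binary_erosion(mask, structure=ndimage.generate_binary_structure(3, 1))
    return int(np.count_nonzero(mask & ~eroded))
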