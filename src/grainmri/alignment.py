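"""Canonical pose: principal-axes alignment plus a crease-down roll.

Grains are elongated, so the first principal axis of the foreground voxel
cloud is the grain length; rotating it onto axis 0 lays the grain
horizontally.  PCA leaves the roll about the length axis (and the sign of
each axis) undetermined: the embryo end is sent to the low-axis-0 side,
and the roll angle that brings the ventral crease to the bottom
(-axis 2) is estimated either geometrically from the crease profile of the
central cross-section (default, deterministic) or by a trained regressor
that predicts (cos, sin) of the angle.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import replace

import numpy as np
from scipy import ndimage

from .errors import RotationError, StateError, ValidationError
from .instances import SeedInstance
from .morphology import central_section_index, crease_profile

logger = logging.getLogger(__name__)


def _resample(inst: SeedInstance, rot: np.ndarray) -> SeedInstance:
    """Rotate both crops about the crop center.

    Labels are resampled by linear interpolation of the per-class one-hot
    indicators followed by argmax (label-probability resampling): the class
    boundary stays at the interpolated 0.5 level, which keeps extents
    subvoxel-accurate, and no new class values can be invented.  Intensity
    is interpolated linearly.  The foreground centroid is mapped onto an
    exact voxel center so the output digitization keeps the same sampling
    phase as a body rasterized symmetrically about a voxel center.
    """
    center_in = np.argwhere(inst.labels > 0).mean(axis=0)
    center_out = np.floor((np.array(inst.labels.shape) - 1) / 2.0)
    m = rot.T
    # 1e-3 voxel nudge avoids exact half-integer sampling, where background
    # and tissue votes tie at 0.5 and argmax would eat a whole surface layer
    offset = center_in - m @ center_out + 1e-3
    votes = np.stack([
        ndimage.affine_transform((inst.labels == c).astype(np.float32), m, offset=offset,
                                 order=1, mode="constant", cval=1.0 if c == 0 else 0.0)
        for c in range(5)])
    lab = votes.argmax(axis=0).astype(np.uint8)
    img = ndimage.affine_transform(inst.intensity, m, offset=offset, order=1,
                                   mode="constant", cval=0.0)
    before = int(np.count_nonzero(inst.labels))
    after = int(np.count_nonzero(lab))
    if before > 0 and abs(after - before) / before > 0.02:
        raise RotationError(
            f"alignment rotation lost foreground: {before} -> {after} voxels (clipped?)")
    return replace(inst, labels=lab, intensity=img.astype(np.float32))


def principal_axes_align(inst: SeedInstance) -> SeedInstance:
    """Rotate the instance so its longest principal axis lies along axis 0.

    Foreground voxel coordinates are treated as data points; the
    eigenvectors of their covariance give the principal axes, ordered by
    decreasing eigenvalue onto axes 0, 1, 2 (length, width, depth).  The
    sign ambiguity along the length is fixed by sending the embryo centroid
    to the low-axis-0 end.  Near-spherical instances (top two eigenvalues
    within 1%) trigger a degenerate-orientation warning and keep the input
    axes.
    """
    coords = np.argwhere(inst.foreground)
    if len(coords) < 3:
        raise ValidationError("need at least 3 foreground voxels to orient an instance")
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(centered)
    evals, evecs = np.linalg.eigh(cov)
    if np.linalg.matrix_rank(cov) < 3 and evals[0] <= 1e-12:
        raise ValidationError("foreground voxels are (near-)collinear; orientation undefined")
    order = np.argsort(evals)[::-1]
    if (evals[order[0]] - evals[order[1]]) / max(evals[order[0]], 1e-12) < 0.01:
        warnings.warn("near-degenerate orientation (top two eigenvalues within 1%); "
                      "keeping input axis order", stacklevel=2)
        out = replace(inst, rotation=np.eye(3))
        return out
    rot = evecs[:, order].T          # rows: new axes expressed in old coordinates
    if np.linalg.det(rot) < 0:
        rot[2] *= -1.0

    embryo = np.argwhere(inst.labels == 1)
    if len(embryo):
        mono_c = coords.mean(axis=0)
        emb_new0 = float(rot[0] @ (embryo.mean(axis=0) - mono_c))
        if emb_new0 > 0:  # flip 180 deg about axis 2 to keep det=+1
            rot = np.diag([-1.0, -1.0, 1.0]) @ rot
    out = _resample(inst, rot)
    return replace(out, rotation=rot)


def _wrap_angle(theta: float) -> float:
    """Wrap to (-180, 180]."""
    theta = (theta + 180.0) % 360.0 - 180.0
    return 180.0 if theta == -180.0 else theta


def decode_cos_sin(cos_t: float, sin_t: float) -> float:
    """Angle in degrees from its (cos, sin) encoding (regressor output)."""
    return float(np.degrees(np.arctan2(sin_t, cos_t)))


def estimate_roll(inst: SeedInstance, method: str = "geometric",
                  regressor=None) -> float:
    """Roll angle (degrees) that brings the crease to the bottom (-axis 2).

    Geometric method: on the central cross-section, the crease profile
    (convex-hull deficiency) has angular position phi = atan2 of its
    centroid relative to the section centroid in the (axis 1, axis 2)
    plane; the returned angle rolls phi onto the bottom direction (-90
    degrees).  A convex section (no profile) returns 0 with a warning.

    Regressor method: ``regressor(inst)`` must return ``(cos, sin)`` of the
    angle; the angle is decoded with atan2.
    """
    if method == "regressor":
        if regressor is None:
            raise ValidationError("regressor method requires a regressor callable")
        cos_t, sin_t = regressor(inst)
        return _wrap_angle(decode_cos_sin(cos_t, sin_t))
    if method != "geometric":
        raise ValidationError(f"unknown roll method {method!r}")

    fg = inst.foreground
    section = fg[central_section_index(fg)]
    profile = crease_profile(section)
    if not profile.any():
        warnings.warn("no crease profile found (convex section); roll = 0", stacklevel=2)
        return 0.0
    sec_c = np.argwhere(section).mean(axis=0)
    prof_c = np.argwhere(profile).mean(axis=0)
    du, dv = prof_c - sec_c              # (axis 1, axis 2) offsets
    phi = np.degrees(np.arctan2(dv, du))
    return _wrap_angle(-90.0 - phi)


def apply_roll(inst: SeedInstance, theta: float) -> SeedInstance:
    """Rotate the instance about axis 0 by ``theta`` degrees.

    A point at angular position phi in the (axis 1, axis 2) cross-section
    plane moves to phi + theta.  Labels are resampled nearest-neighbour,
    intensity linearly; class counts must be conserved within 2% (clipping
    raises :class:`RotationError`).  The result is flagged as aligned.
    """
    t = np.deg2rad(theta)
    rot = np.array([[1, 0, 0],
                    [0, np.cos(t), -np.sin(t)],
                    [0, np.sin(t), np.cos(t)]])
    out = _resample(inst, rot)
    return replace(out, aligned=True, roll_deg=float(theta))


def align_instance(inst: SeedInstance, roll_method: str = "geometric",
                   regressor=None) -> SeedInstance:
    """Full canonical alignment: principal axes, then crease-down roll."""
    length_aligned = principal_axes_align(inst)
    theta = estimate_roll(length_aligned, method=roll_method, regressor=regressor)
    return apply_roll(length_aligned, theta)
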