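"""Slice-dataset assembly for 2D and 2.5D training, plus on-the-fly augmentation.

A 2.5D sample is a stack of 2k+1 consecutive cross-sections (the sliding
window) whose target is the segmentation of the central slice; k=0 gives the
pure 2D regime.  Boundary slices are padded by edge replication so every
sample has the full stack depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ..errors import ConfigError, StandardizationError, ValidationError
from ..io import IntensityVolume
from ..phantom import rotate_volume


def standardize_volume(vol: IntensityVolume) -> IntensityVolume:
    """Whole-volume standardization: subtract the mean, divide by the SD."""
    data = vol.data
    sd = float(data.std())
    if sd == 0:
        raise StandardizationError("constant volume cannot be standardized")
    out = (data - float(data.mean())) / sd
    return IntensityVolume(out, voxel_size=vol.voxel_size, source_id=vol.source_id,
                           faulty_frames=list(vol.faulty_frames))


@dataclass
class SliceSample:
    """One training sample: an input stack and its central-slice target."""

    stack: np.ndarray      # (2k+1, H, W) float32
    target: np.ndarray     # (H, W) uint8
    volume_id: str = ""
    slice_index: int = 0

    def __post_init__(self):
        if self.stack.ndim != 3 or self.stack.shape[0] % 2 != 1:
            raise ValidationError("stack must be (2k+1, H, W) with odd depth")
        if self.target.shape != self.stack.shape[1:]:
            raise ValidationError("target must align with the central slice")

    @property
    def k(self) -> int:
        return self.stack.shape[0] // 2


@dataclass
class TrainConfig:
    """Training recipe: Adam + cross-entropy, 100-epoch sessions, best-val selection."""

    context_depth: int = 0
    batch_size: int = 64
    epochs: int = 100
    learning_rate: float = 1e-3
    channels: int = 64
    class_weights: tuple | None = None     # None = plain unweighted cross-entropy
    augment: dict = field(default_factory=dict)  # switches, all off by default
    seed: int = 0

    #: recognized augmentation switches
    AUG_KEYS = ("flip", "rotate", "scale", "shift", "brightness_contrast",
                "gaussian_noise", "faulty_frame")

    def __post_init__(self):
        if self.batch_size < 1:
            raise ConfigError("batch size must be >= 1")
        if self.epochs < 1:
            raise ConfigError("epoch count must be >= 1")
        if self.context_depth < 0:
            raise ConfigError("context depth must be >= 0")
        unknown = set(self.augment) - set(self.AUG_KEYS)
        if unknown:
            raise ConfigError(f"unknown augmentation switches: {sorted(unknown)}")


def make_slice_dataset(pairs, k: int = 0, rotations=()):
    """Cut (intensity, label) volume pairs into per-slice samples.

    One sample is produced per cross-section (axis 0) of every volume and of
    every additionally rotated variant (``rotations`` is a list of Euler
    angle triples; the unrotated volume is always included).  Edge slices
    replicate the first/last plane so each stack has 2k+1 planes.
    """
    if k < 0:
        raise ConfigError("context depth k must be >= 0")
    samples = []
    for img, lab in pairs:
        if img.data.shape != lab.data.shape:
            raise ValidationError(
                f"paired volumes disagree in shape: {img.data.shape} vs {lab.data.shape}")
        variants = [(img, lab, "")]
        for ang in rotations:
            variants.append((rotate_volume(img, ang, order=1),
                             rotate_volume(lab, ang, order=0),
                             f"_rot{tuple(round(a, 1) for a in ang)}"))
        for vimg, vlab, tag in variants:
            n = vimg.data.shape[0]
            for i in range(n):
                idx = np.clip(np.arange(i - k, i + k + 1), 0, n - 1)
                samples.append(SliceSample(
                    stack=vimg.data[idx].astype(np.float32),
                    target=vlab.data[i],
                    volume_id=(vimg.source_id or "vol") + tag,
                    slice_index=i,
                ))
    return samples


def augment_sample(s: SliceSample, cfg: TrainConfig, seed: int) -> SliceSample:
    """Randomly perturb one sample; deterministic under ``seed``.

    Geometric transforms (flips, rotation, scaling, shifts) are applied
    identically to the input stack (bilinear) and the target
    (nearest-neighbour).  Photometric transforms (brightness/contrast,
    Gaussian noise, faulty frames) touch the input only; faulty-frame noise
    corrupts random planes of the stack.
    """
    rng = np.random.default_rng(seed)
    aug = cfg.augment
    stack = s.stack.astype(np.float32, copy=True)
    target = s.target.copy()

    if aug.get("flip"):
        if rng.random() < 0.5:
            stack = stack[:, ::-1, :]
            target = target[::-1, :]
        if rng.random() < 0.5:
            stack = stack[:, :, ::-1]
            target = target[:, ::-1]

    angle = rng.uniform(-15, 15) if aug.get("rotate") else 0.0
    zoom = rng.uniform(0.9, 1.1) if aug.get("scale") else 1.0
    shift = rng.uniform(-5, 5, size=2) if aug.get("shift") else np.zeros(2)
    if angle != 0.0 or zoom != 1.0 or np.any(shift != 0):
        theta = np.deg2rad(angle)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        mat = rot / zoom
        center = (np.array(target.shape) - 1) / 2.0
        offset = center - mat @ (center + shift)
        stack = np.stack([
            ndimage.affine_transform(pl, mat, offset=offset, order=1, mode="nearest")
            for pl in stack])
        target = ndimage.affine_transform(target, mat, offset=offset, order=0,
                                          mode="constant", cval=0)

    if aug.get("brightness_contrast"):
        gain = rng.uniform(0.8, 1.2)
        bias = rng.uniform(-0.2, 0.2) * (stack.std() or 1.0)
        stack = gain * stack + bias
    if aug.get("gaussian_noise"):
        stack = stack + rng.normal(0.0, 0.05 * (stack.std() or 1.0), stack.shape)
    if aug.get("faulty_frame"):
        for p in range(stack.shape[0]):
            if rng.random() < 0.1:
                stack[p] += rng.normal(0.0, 3.0 * (stack.std() or 1.0), stack.shape[1:])

    return SliceSample(stack=np.ascontiguousarray(stack, dtype=np.float32),
                       target=np.ascontiguousarray(target),
                       volume_id=s.volume_id, slice_index=s.slice_index)
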