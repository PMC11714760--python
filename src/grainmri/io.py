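"""Volume containers, NIfTI round-tripping, canonical padding, and configuration.

Volumes are plain numpy arrays wrapped with the isotropic voxel size ``r``
(mm/voxel).  Axis 0 is the grain length axis (the 500-voxel axis of the
canonical 500x180x180 grid); axes 1-2 span the cross-section.  Tissue labels
use five classes: 0 background, 1 embryo, 2 starchy endosperm, 3 aleurone,
4 pericarp.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .errors import ConfigError, SizeError, ValidationError

logger = logging.getLogger(__name__)

#: Tissue class scheme: four target tissues plus background.
CLASS_NAMES = {0: "background", 1: "embryo", 2: "endosperm", 3: "aleurone", 4: "pericarp"}
N_CLASSES = len(CLASS_NAMES)
TISSUE_CLASSES = (1, 2, 3, 4)

#: Nominal isotropic voxel size after zero-filling (mm).
DEFAULT_VOXEL_SIZE = 0.04


@dataclass
class IntensityVolume:
    """A 3D grayscale MR volume with isotropic voxel size in mm."""

    data: np.ndarray
    voxel_size: float = DEFAULT_VOXEL_SIZE
    source_id: str = ""
    faulty_frames: list = field(default_factory=list)
    pad_offset: tuple | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValidationError(f"intensity volume must be 3D, got shape {self.data.shape}")
        if self.voxel_size <= 0:
            raise ValidationError(f"voxel size must be positive, got {self.voxel_size}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("intensity volume contains non-finite values")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class LabelVolume:
    """A 3D segmentation with integer classes 0-4 and isotropic voxel size."""

    data: np.ndarray
    voxel_size: float = DEFAULT_VOXEL_SIZE
    source_id: str = ""
    pad_offset: tuple | None = None

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 3 or min(arr.shape) < 1:
            raise ValidationError(f"label volume must be 3D, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                bad = np.unique(arr[arr != np.round(arr)])[:5]
                raise ValidationError(f"label volume has non-integer values, e.g. {bad}")
            arr = np.round(arr).astype(np.uint8)
        bad = np.setdiff1d(np.unique(arr), list(CLASS_NAMES))
        if bad.size:
            raise ValidationError(f"label volume has out-of-range classes {bad.tolist()}; allowed 0-4")
        self.data = arr.astype(np.uint8)
        if self.voxel_size <= 0:
            raise ValidationError(f"voxel size must be positive, got {self.voxel_size}")

    @property
    def shape(self):
        return self.data.shape

    def class_counts(self) -> dict:
        """Voxel count per class, including background."""
        counts = np.bincount(self.data.ravel(), minlength=N_CLASSES)
        return {c: int(counts[c]) for c in CLASS_NAMES}


def _voxel_size_from_header(img) -> float:
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    if zooms.max() <= 0:
        return DEFAULT_VOXEL_SIZE
    spread = (zooms.max() - zooms.min()) / zooms.max()
    if spread > 0.01:
        warnings.warn(
            f"anisotropic voxels {zooms.tolist()} (>1%); using geometric mean",
            stacklevel=3,
        )
        return float(np.exp(np.mean(np.log(zooms))))
    return float(zooms[0])


def read_nifti(path, kind: str = "intensity"):
    """Read a NIfTI file as an :class:`IntensityVolume` or :class:`LabelVolume`.

    Parameters
    ----------
    path : str or Path
        NIfTI file (.nii or .nii.gz).
    kind : {"intensity", "label"}
        How to interpret the voxel values.  For ``"label"`` the values must
        be integral and within the 5-class scheme.
    """
    path = Path(path)
    if kind not in ("intensity", "label"):
        raise ConfigError(f"kind must be 'intensity' or 'label', got {kind!r}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises several types
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    r = _voxel_size_from_header(img)
    if kind == "label":
        return LabelVolume(data, voxel_size=r, source_id=path.stem.replace(".nii", ""))
    return IntensityVolume(np.asarray(data, dtype=np.float32), voxel_size=r,
                           source_id=path.stem.replace(".nii", ""))


def write_nifti(vol, path) -> Path:
    """Write a volume to NIfTI; labels are stored with an integer dtype."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    r = vol.voxel_size
    affine = np.diag([r, r, r, 1.0])
    if isinstance(vol, LabelVolume):
        data = vol.data.astype(np.uint8)
    else:
        data = vol.data.astype(np.float32)
    nib.save(nib.Nifti1Image(data, affine), str(path))
    return path


def pad_to_canonical(vol, target_shape):
    """Zero-pad a volume to ``target_shape`` with the content centered.

    The per-axis offset ``floor((target - src) / 2)`` is recorded on the
    returned volume (``pad_offset``) so the padding is invertible with
    :func:`crop_from_canonical`.  Inputs larger than the target raise
    :class:`SizeError`; cropping is never silent.
    """
    src = vol.data.shape
    target_shape = tuple(int(t) for t in target_shape)
    if any(s > t for s, t in zip(src, target_shape)):
        raise SizeError(f"input shape {src} exceeds target {target_shape}; refusing to crop")
    offset = tuple((t - s) // 2 for s, t in zip(src, target_shape))
    out = np.zeros(target_shape, dtype=vol.data.dtype)
    sl = tuple(slice(o, o + s) for o, s in zip(offset, src))
    out[sl] = vol.data
    kwargs = dict(voxel_size=vol.voxel_size, source_id=vol.source_id, pad_offset=offset)
    if isinstance(vol, LabelVolume):
        return LabelVolume(out, **kwargs)
    return IntensityVolume(out, **kwargs)


def crop_from_canonical(vol, original_shape, offset=None):
    """Invert :func:`pad_to_canonical` by center-cropping to ``original_shape``."""
    if offset is None:
        offset = vol.pad_offset
    if offset is None:
        offset = tuple((t - s) // 2 for s, t in zip(original_shape, vol.data.shape))
    sl = tuple(slice(o, o + s) for o, s in zip(offset, original_shape))
    out = vol.data[sl]
    kwargs = dict(voxel_size=vol.voxel_size, source_id=vol.source_id)
    if isinstance(vol, LabelVolume):
        return LabelVolume(out, **kwargs)
    return IntensityVolume(out, **kwargs)


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration.

    Defaults mirror the acquisition convention: 500x180x180 canonical volumes
    at 0.04 mm isotropic voxels, 200x180x180 per-instance crops.
    """

    canonical_shape: tuple = (500, 180, 180)
    instance_shape: tuple = (200, 180, 180)
    voxel_size: float = DEFAULT_VOXEL_SIZE
    backend: str = "fallback"
    model_path: str | None = None
    context_depth: int = 0
    class_intensities: dict | None = None
    min_seed_size: int = 50
    seed: int = 0
    roll_method: str = "geometric"

    def __post_init__(self):
        self.canonical_shape = tuple(int(v) for v in self.canonical_shape)
        self.instance_shape = tuple(int(v) for v in self.instance_shape)
        if any(v <= 0 for v in self.canonical_shape + self.instance_shape):
            raise ConfigError("shapes must be positive")
        if (self.instance_shape[1] > self.canonical_shape[1]
                or self.instance_shape[2] > self.canonical_shape[2]):
            raise ConfigError("instance cross-section must fit within canonical cross-section")
        if self.voxel_size <= 0:
            raise ConfigError("voxel_size must be positive")
        if self.backend not in ("unet2d", "unet25d", "fallback", "external3d"):
            raise ConfigError(f"unknown backend {self.backend!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path):
        payload = {
            "canonical_shape": list(self.canonical_shape),
            "instance_shape": list(self.instance_shape),
            "voxel_size": self.voxel_size,
            "backend": self.backend,
            "model_path": self.model_path,
            "context_depth": self.context_depth,
            "class_intensities": self.class_intensities,
            "min_seed_size": self.min_seed_size,
            "seed": self.seed,
            "roll_method": self.roll_method,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)
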