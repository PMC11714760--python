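"""End-to-end pipeline: segment -> separate -> align -> traits.

Every stage's artifacts are written to the output directory so runs can be
audited: the segmented volume, per-instance label/image crops, aligned
crops with their pose, an instance index with offsets, and the final trait
table as CSV.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import align_instance
from .errors import ConfigError, StageError
from .instances import separate_instances
from .io import IntensityVolume, LabelVolume, PipelineConfig, pad_to_canonical, read_nifti, write_nifti
from .phantom import DEFAULT_CLASS_MEANS
from .segmentation import SegmenterModel, fallback_segment, predict_volume
from .traits import build_trait_table

logger = logging.getLogger(__name__)


def segment_volume(config: PipelineConfig, vol: IntensityVolume) -> LabelVolume:
    """Dispatch to the configured segmentation backend."""
    if config.backend == "fallback":
        table = config.class_intensities or dict(DEFAULT_CLASS_MEANS)
        table = {int(k): float(v) for k, v in table.items()}
        return fallback_segment(vol, table)
    if config.backend in ("unet2d", "unet25d"):
        if not config.model_path:
            raise ConfigError(f"backend {config.backend} requires model_path")
        model = SegmenterModel.load(config.model_path)
        return predict_volume(model, vol)
    if config.backend == "external3d":
        # interface to a self-configuring 3D framework: NIfTI paths in/out.
        # model_path names a directory holding <source_id>_seg.nii.gz files
        # produced by the external tool.
        if not config.model_path:
            raise ConfigError("backend external3d requires model_path (directory of segmentations)")
        seg_path = Path(config.model_path) / f"{vol.source_id}_seg.nii.gz"
        if not seg_path.exists():
            seg_path = Path(config.model_path) / f"{vol.source_id}_seg.nii"
        lab = read_nifti(seg_path, kind="label")
        lab.source_id = vol.source_id
        return lab
    raise ConfigError(f"unknown backend {config.backend!r}")


def process_volume(config: PipelineConfig, vol: IntensityVolume, out_dir: Path):
    """Run all stages on one volume; returns the list of aligned instances."""
    sid = vol.source_id or "sample"
    out_dir = Path(out_dir)
    try:
        if any(s < t for s, t in zip(vol.data.shape, config.canonical_shape)):
            vol = pad_to_canonical(vol, config.canonical_shape)
        labels = segment_volume(config, vol)
    except Exception as exc:
        raise StageError("segment", sid, exc) from exc
    write_nifti(labels, out_dir / f"{sid}_seg.nii.gz")

    try:
        instances = separate_instances(labels, vol, min_size=config.min_seed_size,
                                       instance_shape=config.instance_shape)
    except Exception as exc:
        raise StageError("separate", sid, exc) from exc
    if not instances:
        logger.warning("sample %s produced no instances (empty or embryo-free)", sid)
        return []

    index_rows = []
    aligned = []
    for inst in instances:
        try:
            ai = align_instance(inst, roll_method=config.roll_method)
        except Exception as exc:
            raise StageError("align", f"{sid}_i{inst.instance_id}", exc) from exc
        aligned.append(ai)
        stem = f"{sid}_i{inst.instance_id}"
        write_nifti(LabelVolume(ai.labels, voxel_size=ai.voxel_size, source_id=stem),
                    out_dir / f"{stem}_label.nii.gz")
        write_nifti(IntensityVolume(ai.intensity, voxel_size=ai.voxel_size, source_id=stem),
                    out_dir / f"{stem}_image.nii.gz")
        pose = {"rotation": np.asarray(ai.rotation).tolist() if ai.rotation is not None else None,
                "roll_deg": ai.roll_deg}
        (out_dir / f"{stem}_pose.json").write_text(json.dumps(pose, indent=1))
        index_rows.append({"sample_id": sid, "instance_id": inst.instance_id,
                           "offset0": inst.offset[0], "offset1": inst.offset[1],
                           "offset2": inst.offset[2]})
    pd.DataFrame(index_rows).to_csv(out_dir / f"{sid}_instances.csv", index=False)
    return aligned


def run_pipeline(config: PipelineConfig, inputs, out_dir, composition=None) -> pd.DataFrame:
    """Full run over one or more intensity NIfTI files (or volumes).

    Returns the trait table (one row per separated grain) and writes it to
    ``<out_dir>/traits.csv`` along with per-stage artifacts.  Deterministic:
    rerunning with the same config and inputs reproduces the table
    byte-identically.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(composition, (str, Path)):
        composition = pd.read_csv(composition)
    volumes = []
    for item in inputs if isinstance(inputs, (list, tuple)) else [inputs]:
        if isinstance(item, IntensityVolume):
            volumes.append(item)
        else:
            vol = read_nifti(item, kind="intensity")
            volumes.append(vol)
    aligned = []
    for vol in volumes:
        aligned.extend(process_volume(config, vol, out_dir))
    try:
        table = build_trait_table(aligned, composition)
    except Exception as exc:
        raise StageError("traits", "all", exc) from exc
    table.to_csv(out_dir / "traits.csv", index=False, float_format="%.9g")
    return table
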