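"""NIfTI round-trip for BOLD runs and label atlases.

A :class:`~netdisrupt.synthdata.BoldSeries` is stored as a 4D NIfTI-1 file
plus a ``<stem>_mask.nii`` brain mask and a ``<stem>.json`` sidecar carrying
the repetition time, subject id and group.  An atlas is a 3D integer NIfTI
plus a mask volume and a JSON registry of (label, structure, network) rows.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .synthdata import AtlasSet, BoldSeries


class FormatError(ValueError):
    """Malformed on-disk series/atlas: the message names the missing field."""


def _stem(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)])
    return path


def write_series(series: BoldSeries, path: str | Path) -> Path:
    """Write a BoldSeries as ``path`` (+ ``_mask.nii`` + ``.json`` sidecar)."""
    path = Path(path)
    if path.suffix not in (".nii", ".gz"):
        path = path.with_suffix(".nii")
    stem = _stem(path)
    affine = np.eye(4)
    img = nib.Nifti1Image(series.data.astype(np.float32), affine)
    img.header.set_zooms((1.0, 1.0, 1.0, float(series.tr)))
    nib.save(img, str(path))
    nib.save(nib.Nifti1Image(series.brain_mask.astype(np.uint8), affine),
             str(stem) + "_mask.nii")
    sidecar = {"tr": float(series.tr), "subject_id": series.subject_id,
               "group": series.group}
    Path(str(stem) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_series(path: str | Path) -> BoldSeries:
    """Read a BoldSeries written by :func:`write_series`."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise FormatError(f"field 'data': expected 4D BOLD, got {data.ndim}D")
    stem = _stem(path)
    mask_path = Path(str(stem) + "_mask.nii")
    side_path = Path(str(stem) + ".json")
    if not side_path.exists():
        raise FormatError("field 'sidecar': missing JSON sidecar")
    meta = json.loads(side_path.read_text())
    for key in ("tr", "subject_id", "group"):
        if key not in meta:
            raise FormatError(f"field {key!r}: missing from sidecar")
    if mask_path.exists():
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    else:
        raise FormatError("field 'brain_mask': mask volume not found")
    return BoldSeries(data=data, tr=float(meta["tr"]), brain_mask=mask,
                      subject_id=str(meta["subject_id"]),
                      group=str(meta["group"]))


def write_atlas(atlas: AtlasSet, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix not in (".nii", ".gz"):
        path = path.with_suffix(".nii")
    stem = _stem(path)
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(atlas.label_volume.astype(np.int16), affine),
             str(path))
    nib.save(nib.Nifti1Image(atlas.brain_mask.astype(np.uint8), affine),
             str(stem) + "_mask.nii")
    registry = {"structures": [[int(l), n, net] for l, n, net in atlas.structures]}
    Path(str(stem) + ".json").write_text(json.dumps(registry, indent=1))
    return path


def read_atlas(path: str | Path) -> AtlasSet:
    path = Path(path)
    labels = np.asarray(nib.load(str(path)).dataobj).astype(np.int16)
    if labels.ndim != 3:
        raise FormatError(f"field 'label_volume': expected 3D, got {labels.ndim}D")
    stem = _stem(path)
    side = Path(str(stem) + ".json")
    if not side.exists():
        raise FormatError("field 'structures': missing JSON registry")
    meta = json.loads(side.read_text())
    if "structures" not in meta:
        raise FormatError("field 'structures': missing from registry")
    mask_path = Path(str(stem) + "_mask.nii")
    if mask_path.exists():
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    else:
        mask = labels > 0
    structures = [(int(l), str(n), str(net)) for l, n, net in meta["structures"]]
    atlas = AtlasSet(label_volume=labels, brain_mask=mask, structures=structures)
    atlas.validate()
    return atlas
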