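"""Volume trimming, voxel rasterization and group temporal concatenation.

The decompositions operate on voxel x time matrices restricted to in-brain
voxels.  The voxel raster order is ascending linear index with the *first*
spatial axis fastest, and is identical across subjects and stages so that
spatial maps, atlas masks and permutation fields all share one row order.

Group datasets are built by temporally concatenating the trimmed runs of all
subjects of one group (the study design: separate control and injured group
datasets per paradigm, six in total).  Each voxel's time series is centered
(and by default scaled to unit variance) within each subject's span before
concatenation; the sparsity weight of the dictionary-learning stage is
calibrated against that scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthdata import BoldSeries

__all__ = [
    "GroupDataset",
    "trim_initial_volumes",
    "to_voxel_matrix",
    "from_voxel_matrix",
    "concatenate_group",
    "extract_subject",
]


def trim_initial_volumes(series: BoldSeries, k: int) -> BoldSeries:
    """Drop the first ``k`` volumes (pre-steady-state magnetization)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if k >= series.n_volumes:
        raise ValueError(
            f"trimming {k} volumes would empty a {series.n_volumes}-volume series"
        )
    if k == 0:
        return series
    return BoldSeries(data=series.data[..., k:], tr=series.tr,
                      brain_mask=series.brain_mask,
                      subject_id=series.subject_id, group=series.group)


def _raster_indices(mask: np.ndarray) -> np.ndarray:
    """Flat indices of mask voxels, first spatial axis fastest (Fortran order)."""
    return np.flatnonzero(mask.ravel(order="F"))


def to_voxel_matrix(series: BoldSeries | np.ndarray,
                    mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize a 4D volume to (voxel x time), returning the index map.

    The index map contains the Fortran-order flat index of each row's voxel;
    :func:`from_voxel_matrix` inverts the operation exactly.
    """
    data = series.data if isinstance(series, BoldSeries) else np.asarray(series)
    if data.shape[:3] != mask.shape:
        raise ValueError("mask does not match spatial dimensions")
    if not mask.any():
        raise ValueError("empty mask")
    idx = _raster_indices(mask)
    T = data.shape[3]
    flat = data.reshape(-1, T, order="F")  # spatial F-ravel, time preserved
    return flat[idx].copy(), idx


def from_voxel_matrix(matrix: np.ndarray, mask: np.ndarray,
                      fill: float = 0.0) -> np.ndarray:
    """Un-rasterize (voxel x time) or (voxel,) back to a volume."""
    idx = _raster_indices(mask)
    matrix = np.asarray(matrix)
    squeeze = matrix.ndim == 1
    if squeeze:
        matrix = matrix[:, None]
    if matrix.shape[0] != idx.size:
        raise ValueError("row count does not match mask voxel count")
    out = np.full((int(np.prod(mask.shape)), matrix.shape[1]), fill, dtype=float)
    out[idx] = matrix
    vol = out.reshape(mask.shape + (matrix.shape[1],), order="F")
    return vol[..., 0] if squeeze else vol


@dataclass
class GroupDataset:
    """Temporally concatenated group data over in-brain voxels.

    ``subject_spans`` are half-open column ranges tiling [0, total volumes).
    """

    matrix: np.ndarray  # voxel x total_time
    subject_spans: list[tuple[str, int, int]]
    paradigm: str  # rest | task_visual | task_tactile
    group: str
    tr: float
    mask: np.ndarray

    def __post_init__(self) -> None:
        pos = 0
        for sid, start, end in self.subject_spans:
            if start != pos or end <= start:
                raise ValueError(f"spans do not tile columns (at {sid})")
            pos = end
        if pos != self.matrix.shape[1]:
            raise ValueError("spans do not cover all columns")

    @property
    def n_voxels(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def n_volumes(self) -> int:
        return int(self.matrix.shape[1])

    def span(self, subject_id: str) -> tuple[int, int]:
        for sid, start, end in self.subject_spans:
            if sid == subject_id:
                return start, end
        raise KeyError(f"subject {subject_id!r} not in group dataset")

    def subject_matrix(self, subject_id: str) -> np.ndarray:
        start, end = self.span(subject_id)
        return self.matrix[:, start:end]


def concatenate_group(
    series_list: list[BoldSeries],
    mask: np.ndarray,
    paradigm: str,
    group: str,
    center: bool = True,
    scale: bool = True,
) -> GroupDataset:
    """Temporally concatenate trimmed runs into one group dataset.

    Per-voxel centering and unit-variance scaling happen within each
    subject's span (constant voxels are left at zero after centering).
    """
    if not series_list:
        raise ValueError("series_list must be non-empty")
    tr = series_list[0].tr
    blocks, spans, pos = [], [], 0
    for s in series_list:
        if s.data.shape[:3] != mask.shape:
            raise ValueError(f"subject {s.subject_id}: spatial dims do not match mask")
        if s.tr != tr:
            raise ValueError(f"subject {s.subject_id}: TR mismatch")
        m, _ = to_voxel_matrix(s, mask)
        if center or scale:
            mu = m.mean(axis=1, keepdims=True)
            m = m - mu
            if scale:
                sd = m.std(axis=1, keepdims=True)
                sd[sd == 0] = 1.0
                m = m / sd
            if not center:
                m = m + mu
        blocks.append(m)
        spans.append((s.subject_id, pos, pos + s.n_volumes))
        pos += s.n_volumes
    return GroupDataset(matrix=np.concatenate(blocks, axis=1),
                        subject_spans=spans, paradigm=paradigm, group=group,
                        tr=tr, mask=mask.astype(bool))


def extract_subject(group: GroupDataset, subject_id: str) -> np.ndarray:
    """Recover a subject's 4D (preprocessed) volume from its span."""
    return from_voxel_matrix(group.subject_matrix(subject_id), group.mask)
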