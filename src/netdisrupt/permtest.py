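"""Exhaustive two-group voxelwise permutation test on activation maps.

With N_C control and N_T injured subjects, every one of the
C(N_C + N_T, N_C) relabelings of subjects into pseudo-groups of the original
sizes is enumerated, and the voxelwise mean difference

    T = mean_control - mean_injured

is computed for each.  A voxel's activation is flagged as significantly
*decreased* in the injured group when the observed T_actual ranks in the
largest 5% of all T values (one-sided rank p = #{T_perm >= T_actual} / n_perm
<= alpha, the true assignment included, ties counted conservatively), and
*increased* when it ranks in the smallest 5%.  No multiple-comparison
correction is applied by default; the small number of permutations bounds
the achievable p-value at 1/n_perm from below.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterator

import nibabel as nib
import numpy as np

from .preprocess import from_voxel_matrix
from .synthdata import AtlasSet

__all__ = [
    "PermutationField",
    "RegionPercentages",
    "enumerate_assignments",
    "voxelwise_permutation",
    "region_percentages",
    "export_permutation_map",
]


@dataclass
class PermutationField:
    """Voxelwise permutation-test result over the in-brain raster."""

    t_actual: np.ndarray       # voxelwise mean_C - mean_T
    decrease_flags: np.ndarray  # bool, TBI < control
    increase_flags: np.ndarray  # bool, TBI > control
    p_decrease: np.ndarray     # one-sided rank p per voxel
    p_increase: np.ndarray
    n_permutations: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if (self.decrease_flags & self.increase_flags).any():
            raise ValueError("decrease and increase flags must be disjoint")


@dataclass
class RegionPercentages:
    region_name: str
    network: str
    n_voxels: int
    pct_decreasing: float
    pct_increasing: float


def enumerate_assignments(n_control: int, n_injured: int
                          ) -> tuple[Iterator[tuple[int, ...]], int]:
    """All splits of N = n_control + n_injured subjects into pseudo-groups.

    Yields tuples of pseudo-control subject indices in deterministic
    (lexicographic) order; the second element is the total count
    C(N, n_control).  The identity assignment (0..n_control-1) comes first.
    """
    if n_control < 1 or n_injured < 1:
        raise ValueError("both group sizes must be >= 1")
    n = n_control + n_injured
    return combinations(range(n), n_control), math.comb(n, n_control)


def voxelwise_permutation(control_maps, injured_maps, alpha: float = 0.05,
                          chunk: int = 200) -> PermutationField:
    """Exact permutation test at every voxel of the shared raster.

    ``control_maps`` / ``injured_maps`` are lists of 1D voxel vectors (the
    per-subject final activation maps).  At voxels where all subjects carry
    the same value every T ties, p = 1 and no flag is set.
    """
    C = np.asarray(control_maps, dtype=np.float64)
    T_ = np.asarray(injured_maps, dtype=np.float64)
    if C.ndim != 2 or T_.ndim != 2 or C.shape[1] != T_.shape[1]:
        raise ValueError("all maps must share one voxel raster")
    n_c, n_t = C.shape[0], T_.shape[0]
    stack = np.vstack([C, T_])  # N x V
    total = stack.sum(axis=0)

    assigns, n_perm = enumerate_assignments(n_c, n_t)
    idx = np.fromiter((i for tup in assigns for i in tup), dtype=np.intp,
                      count=n_perm * n_c).reshape(n_perm, n_c)

    def t_for(sel):
        sums = stack[sel].sum(axis=1)  # n_sel x V
        return sums / n_c - (total[None, :] - sums) / n_t

    # the identity assignment comes first; computing T_actual through the
    # same arithmetic path keeps its tie with itself exact
    t_actual = t_for(idx[:1])[0]

    ge = np.zeros(stack.shape[1], dtype=np.int64)  # count T_perm >= T_actual
    le = np.zeros(stack.shape[1], dtype=np.int64)
    for start in range(0, n_perm, chunk):
        t_perm = t_for(idx[start:start + chunk])
        ge += (t_perm >= t_actual[None, :]).sum(axis=0)
        le += (t_perm <= t_actual[None, :]).sum(axis=0)
    p_dec = ge / n_perm
    p_inc = le / n_perm
    return PermutationField(
        t_actual=t_actual,
        decrease_flags=p_dec <= alpha,
        increase_flags=p_inc <= alpha,
        p_decrease=p_dec,
        p_increase=p_inc,
        n_permutations=n_perm,
        alpha=alpha,
    )


def region_percentages(field: PermutationField, atlas: AtlasSet,
                       raster_masks: dict[str, np.ndarray],
                       networks: list[str] | None = None
                       ) -> list[RegionPercentages]:
    """Percent of significantly decreasing/increasing voxels per region.

    Percentages are taken over each region's own atlas voxels (networks and
    their member structures).
    """
    out = []
    for net in networks or sorted({n for _l, _s, n in atlas.structures}):
        regions = [(net, net)] + [
            (name, net) for _lab, name in atlas.network_structures(net)
            if net != "CERE"
        ]
        for region, network in regions:
            mask = np.asarray(raster_masks[region], dtype=bool)
            n_vox = int(mask.sum())
            if n_vox == 0:
                raise ValueError(f"region {region!r} has no voxels")
            out.append(RegionPercentages(
                region_name=region, network=network, n_voxels=n_vox,
                pct_decreasing=100.0 * field.decrease_flags[mask].sum() / n_vox,
                pct_increasing=100.0 * field.increase_flags[mask].sum() / n_vox,
            ))
    return out


def export_permutation_map(field: PermutationField, mask: np.ndarray,
                           path: str | Path) -> tuple[Path, Path]:
    """Write the 3-valued flag volume (0 none / 1 decrease / 2 increase)
    and the T_actual field as NIfTI volumes."""
    path = Path(path)
    if path.suffix not in (".nii", ".gz"):
        path = path.with_suffix(".nii")
    labels = np.zeros(field.t_actual.shape, dtype=np.int16)
    labels[field.decrease_flags] = 1
    labels[field.increase_flags] = 2
    vol = from_voxel_matrix(labels.astype(float), mask).round().astype(np.int16)
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(vol, affine), str(path))
    t_path = path.with_name(path.name.replace(".nii", "_tactual.nii"))
    t_vol = from_voxel_matrix(field.t_actual, mask)
    nib.save(nib.Nifti1Image(t_vol.astype(np.float32), affine), str(t_path))
    return path, t_path
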