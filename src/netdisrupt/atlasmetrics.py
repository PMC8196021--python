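"""Atlas-referenced statistics on activation maps and group comparison.

Per-subject maps are first normalized by the maximum absolute group-map
activation of their group fit, then thresholded at a z-score of one over
in-brain voxels (population sd).  Two atlas-referenced metrics summarize a
map against a binary reference atlas:

* **Pearson r** — spatial correlation between map values and the 0/1 atlas
  indicator over in-brain voxels;
* **mean ratio** — mean activation inside the atlas divided by the mean
  activation outside it (within the brain), undefined when the outside mean
  is zero.

For each subject and network the *maximal map* is selected: the single
best-Pearson component for ICA, or the average of the three distinct
best-Pearson atoms for sDL (metrics recomputed on the average).  Group
differences are tested per region with Welch's unequal-variance t-test; a
region counts as significantly different only when both metrics have
p < 0.05 with agreeing directions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .decompose import SpatialMapSet
from .synthdata import AtlasSet

__all__ = [
    "MetricRecord",
    "GroupTestResult",
    "normalize_and_threshold",
    "pearson_to_atlas",
    "mean_ratio",
    "select_maximal_map",
    "structure_metrics",
    "welch_test",
    "group_comparison",
]

_VAR_FLOOR = 1e-12


@dataclass
class MetricRecord:
    subject_id: str
    method: str
    paradigm: str
    region_name: str
    pearson_r: float  # nan when undefined
    mean_ratio: float  # nan when undefined
    mean_ratio_defined: bool = True


@dataclass
class GroupTestResult:
    region_name: str
    metric: str  # "pearson" | "mean_ratio"
    t: float
    p_value: float
    direction: str  # "decrease" | "increase"
    n_dropped: int = 0


def normalize_and_threshold(maps: SpatialMapSet, group_max: float,
                            z_cut: float = 1.0) -> SpatialMapSet:
    """Divide maps by the group maximum and zero sub-threshold voxels.

    z-scores use each map's in-brain population mean/sd; voxels with
    z < ``z_cut`` are set exactly to 0, survivors keep their normalized
    value.  A constant map is zeroed entirely (warning).
    """
    if group_max <= 0:
        raise ValueError("group_max must be positive")
    normalized = maps.maps / group_max
    out = np.zeros_like(normalized)
    for i, row in enumerate(normalized):
        sd = row.std()  # population sd over in-brain voxels
        if sd == 0:
            warnings.warn(f"component {i}: constant map zeroed by threshold")
            continue
        z = (row - row.mean()) / sd
        keep = z >= z_cut
        out[i, keep] = row[keep]
    return SpatialMapSet(maps=out, method=maps.method, state="thresholded",
                         subject_id=maps.subject_id,
                         component_ids=list(maps.component_ids))


def group_map_max(group_maps: SpatialMapSet) -> float:
    """Normalization constant: max |alpha_g| over all group components."""
    return float(np.abs(group_maps.maps).max())


def pearson_to_atlas(map_values: np.ndarray, atlas_mask: np.ndarray) -> float:
    """Pearson r between map values and the 0/1 atlas indicator.

    Both arrays are 1D over the in-brain voxel raster.  Returns nan when
    either side has zero variance (undefined, not an error).
    """
    x = np.asarray(map_values, dtype=float)
    ind = np.asarray(atlas_mask, dtype=float)
    if x.shape != ind.shape:
        raise ValueError("map and atlas indicator must share the raster")
    if x.std() == 0 or ind.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, ind)[0, 1])


def mean_ratio(map_values: np.ndarray, atlas_mask: np.ndarray
               ) -> tuple[float, bool]:
    """Mean activation inside the atlas / mean outside it (within brain).

    Returns ``(ratio, defined)``; ``defined`` is False when the outside
    mean is zero.
    """
    x = np.asarray(map_values, dtype=float)
    m = np.asarray(atlas_mask, dtype=bool)
    if x.shape != m.shape:
        raise ValueError("map and atlas mask must share the raster")
    if not m.any() or m.all():
        raise ValueError("atlas mask must be a proper subset of the brain")
    outside = x[~m].mean()
    if outside == 0:
        return float("nan"), False
    return float(x[m].mean() / outside), True


def select_maximal_map(maps: SpatialMapSet, atlas_mask: np.ndarray,
                       method: str | None = None
                       ) -> tuple[np.ndarray, list[int]]:
    """Pick the final map for one (subject, atlas) pair.

    ICA: the single map with the largest Pearson r against the atlas.
    sDL: the arithmetic mean of the three distinct top-Pearson maps.
    Ties break toward the lowest component index; undefined correlations
    rank last.  Returns (final map, selected component indices).
    """
    method = method or maps.method
    r = np.array([pearson_to_atlas(row, atlas_mask) for row in maps.maps])
    r = np.where(np.isnan(r), -np.inf, r)
    order = np.lexsort((np.arange(len(r)), -r))  # desc r, then low index
    if method == "ica":
        sel = [int(order[0])]
        return maps.maps[sel[0]].copy(), sel
    if method == "sdl":
        if maps.n_components < 3:
            raise ValueError("sDL maximal-map selection needs >= 3 maps")
        sel = [int(i) for i in order[:3]]
        return maps.maps[sel].mean(axis=0), sel
    raise ValueError(f"unknown method {method!r}")


def structure_metrics(final_map: np.ndarray, atlas: AtlasSet, network: str,
                      raster_masks: dict[str, np.ndarray],
                      subject_id: str, method: str, paradigm: str,
                      ) -> list[MetricRecord]:
    """MetricRecords for a network and each member structure.

    ``raster_masks`` maps region names (the network plus its structures) to
    boolean indicator vectors on the in-brain raster.  The cerebellar
    network is reported at network level only (its lobes are not examined).
    """
    regions = [network]
    if network != "CERE":
        regions += [name for _lab, name in atlas.network_structures(network)]
    records = []
    for region in regions:
        mask = raster_masks[region]
        ratio, defined = mean_ratio(final_map, mask)
        records.append(MetricRecord(
            subject_id=subject_id, method=method, paradigm=paradigm,
            region_name=region,
            pearson_r=pearson_to_atlas(final_map, mask),
            mean_ratio=ratio, mean_ratio_defined=defined))
    return records


def welch_test(control_values, injured_values) -> GroupTestResult | None:
    """Welch's two-sample t-test (unequal variances), two-sided.

    Undefined (nan) values are dropped with a count; with fewer than two
    defined values in either group the test is skipped (returns None).
    Zero-variance degeneracy is guarded by a variance floor of 1e-12.
    """
    c = np.asarray(control_values, dtype=float)
    t_ = np.asarray(injured_values, dtype=float)
    n_dropped = int(np.isnan(c).sum() + np.isnan(t_).sum())
    c, t_ = c[~np.isnan(c)], t_[~np.isnan(t_)]
    if len(c) < 2 or len(t_) < 2:
        return None
    vc = max(c.var(ddof=1), _VAR_FLOOR)
    vt = max(t_.var(ddof=1), _VAR_FLOOR)
    se2 = vc / len(c) + vt / len(t_)
    tstat = (c.mean() - t_.mean()) / math.sqrt(se2)
    df = se2 ** 2 / (
        (vc / len(c)) ** 2 / (len(c) - 1) + (vt / len(t_)) ** 2 / (len(t_) - 1)
    )
    p = 2.0 * stats.t.sf(abs(tstat), df)
    direction = "decrease" if t_.mean() < c.mean() else "increase"
    return GroupTestResult(region_name="", metric="", t=float(tstat),
                           p_value=float(p), direction=direction,
                           n_dropped=n_dropped)


def group_comparison(records: list[MetricRecord], control_ids, injured_ids,
                     alpha: float = 0.05):
    """Per-region dual-metric comparison.

    Returns a list of dicts, one per region, with both metrics' tests and
    the dual-metric significance flag (both p < alpha, agreeing direction).
    """
    out = []
    region_names = list(dict.fromkeys(r.region_name for r in records))
    for region in region_names:
        row = {"region_name": region}
        tests = {}
        for metric in ("pearson", "mean_ratio"):
            def val(rec):
                if metric == "pearson":
                    return rec.pearson_r
                return rec.mean_ratio if rec.mean_ratio_defined else float("nan")
            cv = [val(r) for r in records
                  if r.region_name == region and r.subject_id in control_ids]
            iv = [val(r) for r in records
                  if r.region_name == region and r.subject_id in injured_ids]
            res = welch_test(cv, iv)
            if res is not None:
                res.region_name, res.metric = region, metric
            tests[metric] = res
            row[f"{metric}_p"] = res.p_value if res else float("nan")
            row[f"{metric}_direction"] = res.direction if res else ""
        pe, mr = tests["pearson"], tests["mean_ratio"]
        row["significant"] = bool(
            pe is not None and mr is not None
            and pe.p_value < alpha and mr.p_value < alpha
            and pe.direction == mr.direction
        )
        row["direction"] = pe.direction if row["significant"] else ""
        out.append(row)
    return out
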