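"""Config-driven orchestration: simulate -> preprocess -> decompose ->
atlas metrics -> permutation, with seeding, logging and a manifest.

A :class:`RunConfig` fixes the phantom, the three acquisition paradigms
(resting-state, visual-stimulus block, tactile-stimulus block), group sizes,
and decomposition settings.  ``run_pipeline`` executes every stage for each
paradigm and method, writes metric/percentage tables as CSV, permutation
maps as NIfTI, and a JSON manifest with parameters, per-stage seeds and
table checksums.  ``demo_config`` returns scaled-down settings (smaller
cohort, shorter runs, fewer atoms) that exercise the full pipeline quickly;
study-scale settings (305/125 volumes, dictionaries of 300/120 atoms,
70 ICA components) are the defaults of :class:`RunConfig`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import atlasmetrics as am
from . import decompose as dc
from . import permtest as pt
from . import preprocess as pp
from . import synthdata as sd
from .io import write_atlas

__all__ = ["RunConfig", "demo_config", "run_pipeline", "report",
           "atlas_raster_masks", "networks_for"]

logger = logging.getLogger("netdisrupt")

#: which networks each paradigm is expected to drive / be tested against
PARADIGM_NETWORKS = {
    "rest": list(sd.NETWORK_NAMES),
    "task_visual": ["VIS"],
    "task_tactile": ["EX", "SM", "CERE"],
}


def networks_for(paradigm: str) -> list[str]:
    return list(PARADIGM_NETWORKS[paradigm])


@dataclass
class RunConfig:
    # phantom
    grid_dims: tuple[int, int, int] = (24, 24, 16)
    atlas_seed: int = 0
    # acquisition
    tr: float = 3.0
    rest_volumes: int = 305
    dead_time: float = 15.0
    block_on: float = 30.0
    block_off: float = 30.0
    n_cycles: int = 6
    trim: int = 5
    # cohorts: (n_control, n_injured) per paradigm
    n_rest: tuple[int, int] = (7, 5)
    n_visual: tuple[int, int] = (6, 5)
    n_tactile: tuple[int, int] = (4, 5)
    paradigms: tuple[str, ...] = ("rest", "task_visual", "task_tactile")
    # injury effect
    attenuated: dict = field(default_factory=lambda: {"VIS1": 0.3, "EX1": 0.4})
    elevated: dict = field(default_factory=lambda: {"SM2": 1.5})
    noise_sd: float = 1.0
    ar1: float = 0.3
    amplitude_jitter: float = 0.1
    amplitude: float = 1.0
    baseline: float = 100.0
    # decomposition
    methods: tuple[str, ...] = ("sdl", "ica")
    lam: float = 0.15
    n_atoms: int | None = None  # None -> trimmed run length (300 rest / 120 task)
    n_components: int = 70
    sdl_max_outer_iters: int = 10
    # statistics
    alpha: float = 0.05
    z_cut: float = 1.0
    # bookkeeping
    seed: int = 1
    out_dir: str = "netdisrupt_run"

    def effect(self) -> sd.EffectSpec:
        return sd.EffectSpec(attenuated=dict(self.attenuated),
                             elevated=dict(self.elevated),
                             noise_sd=self.noise_sd, ar1=self.ar1,
                             amplitude_jitter=self.amplitude_jitter)

    def cohort(self, paradigm: str) -> tuple[int, int]:
        return {"rest": self.n_rest, "task_visual": self.n_visual,
                "task_tactile": self.n_tactile}[paradigm]

    def design(self, paradigm: str) -> sd.StimulusDesign:
        if paradigm == "rest":
            return sd.make_design("rest", self.tr, n_volumes=self.rest_volumes)
        return sd.make_design("block", self.tr, dead_time=self.dead_time,
                              block_on=self.block_on, block_off=self.block_off,
                              n_cycles=self.n_cycles)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("grid_dims", "n_rest", "n_visual", "n_tactile",
                    "methods", "paradigms"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def demo_config(out_dir: str = "netdisrupt_demo", seed: int = 1) -> RunConfig:
    """Small-phantom demo: full pipeline in minutes on one CPU."""
    return RunConfig(
        rest_volumes=65, n_cycles=2,  # block: 15 + 2x60 s = 45 volumes
        n_rest=(4, 3), n_visual=(4, 3), n_tactile=(4, 3),
        n_atoms=16, n_components=8, sdl_max_outer_iters=6,
        seed=seed, out_dir=out_dir,
    )


def atlas_raster_masks(atlas: sd.AtlasSet) -> dict[str, np.ndarray]:
    """Region name -> boolean indicator on the in-brain voxel raster."""
    masks: dict[str, np.ndarray] = {}
    for net, m3d in atlas.networks.items():
        vec, _ = pp.to_voxel_matrix(m3d[..., None].astype(float),
                                    atlas.brain_mask)
        masks[net] = vec[:, 0] > 0.5
    for label, name, _net in atlas.structures:
        m3d = atlas.label_volume == label
        vec, _ = pp.to_voxel_matrix(m3d[..., None].astype(float),
                                    atlas.brain_mask)
        masks[name] = vec[:, 0] > 0.5
    return masks


def _simulate_cohort(cfg: RunConfig, atlas: sd.AtlasSet, paradigm: str,
                     rng: np.random.Generator) -> list[sd.BoldSeries]:
    design = cfg.design(paradigm)
    n_c, n_t = cfg.cohort(paradigm)
    effect = cfg.effect()
    subjects = []
    for i in range(n_c):
        subjects.append(sd.simulate_subject(
            atlas, design, "control", effect,
            seed=int(rng.integers(2 ** 31)), subject_id=f"C{i + 1:02d}",
            amplitude=cfg.amplitude, baseline=cfg.baseline))
    for i in range(n_t):
        subjects.append(sd.simulate_subject(
            atlas, design, "injured", effect,
            seed=int(rng.integers(2 ** 31)), subject_id=f"T{i + 1:02d}",
            amplitude=cfg.amplitude, baseline=cfg.baseline))
    return subjects


def _subject_maps(cfg: RunConfig, ds: pp.GroupDataset, method: str,
                  seed: int) -> dict[str, dc.SpatialMapSet]:
    """Fit one group dataset and return thresholded per-subject maps."""
    per_run = ds.subject_spans[0][2] - ds.subject_spans[0][1]
    if method == "sdl":
        n_atoms = cfg.n_atoms or per_run
        config = dc.SdlConfig(n_atoms=n_atoms, lam=cfg.lam,
                              max_outer_iters=cfg.sdl_max_outer_iters,
                              seed=seed)
        _D, alpha_g = dc.sdl_fit(ds, config)
        gmax = am.group_map_max(alpha_g)
        out = {}
        for sid, _s, _e in ds.subject_spans:
            _Di, alpha_i = dc.dual_regression(ds.subject_matrix(sid),
                                              alpha_g, cfg.lam)
            alpha_i.subject_id = sid
            out[sid] = am.normalize_and_threshold(alpha_i, gmax, cfg.z_cut)
        return out
    if method == "ica":
        k = min(cfg.n_components, ds.n_volumes, ds.n_voxels)
        model = dc.group_ica(ds, n_components=k, seed=seed)
        gmax = am.group_map_max(model.group_maps)
        out = {}
        for sid, _s, _e in ds.subject_spans:
            alpha_i = dc.back_reconstruct(ds, model, sid)
            out[sid] = am.normalize_and_threshold(alpha_i, gmax, cfg.z_cut)
        return out
    raise ValueError(f"unknown method {method!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages for every paradigm and method; return the manifest."""
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {},
                      "warnings": [], "tables": {}, "maps": {}}
    stage = "simulate"
    try:
        atlas = sd.make_phantom_atlas(config.grid_dims, seed=config.atlas_seed)
        write_atlas(atlas, out_dir / "atlas.nii")
        masks = atlas_raster_masks(atlas)
        rng = np.random.default_rng(config.seed)

        metric_rows, test_rows, pct_rows = [], [], []
        for paradigm in config.paradigms:
            logger.info("paradigm %s: simulating", paradigm)
            stage = f"simulate[{paradigm}]"
            subjects = _simulate_cohort(config, atlas, paradigm, rng)

            stage = f"preprocess[{paradigm}]"
            trimmed = [pp.trim_initial_volumes(s, config.trim) for s in subjects]
            datasets = {
                grp: pp.concatenate_group(
                    [s for s in trimmed if s.group == grp],
                    atlas.brain_mask, paradigm, grp)
                for grp in ("control", "injured")
            }
            manifest["stages"][stage] = {
                grp: {"n_voxels": ds.n_voxels, "n_volumes": ds.n_volumes,
                      "subjects": [s[0] for s in ds.subject_spans]}
                for grp, ds in datasets.items()
            }
            control_ids = [s[0] for s in datasets["control"].subject_spans]
            injured_ids = [s[0] for s in datasets["injured"].subject_spans]

            for method in config.methods:
                stage = f"decompose[{paradigm},{method}]"
                logger.info("%s", stage)
                maps = {}
                for grp, ds in datasets.items():
                    maps.update(_subject_maps(
                        config, ds, method, seed=int(rng.integers(2 ** 31))))

                stage = f"metrics[{paradigm},{method}]"
                finals: dict[str, dict[str, np.ndarray]] = {}
                for network in networks_for(paradigm):
                    records = []
                    finals[network] = {}
                    for sid, mset in maps.items():
                        fmap, _sel = am.select_maximal_map(
                            mset, masks[network], method)
                        finals[network][sid] = fmap
                        records += am.structure_metrics(
                            fmap, atlas, network, masks, sid, method, paradigm)
                    metric_rows += [dataclasses.asdict(r) for r in records]
                    for row in am.group_comparison(records, control_ids,
                                                   injured_ids, config.alpha):
                        row.update(paradigm=paradigm, method=method,
                                   network=network)
                        test_rows.append(row)

                if method == "sdl":
                    stage = f"permtest[{paradigm}]"
                    for network in networks_for(paradigm):
                        field_ = pt.voxelwise_permutation(
                            [finals[network][s] for s in control_ids],
                            [finals[network][s] for s in injured_ids],
                            alpha=config.alpha)
                        for rp in pt.region_percentages(
                                field_, atlas, masks, networks=[network]):
                            pct_rows.append({**dataclasses.asdict(rp),
                                             "paradigm": paradigm})
                        p1, p2 = pt.export_permutation_map(
                            field_, atlas.brain_mask,
                            out_dir / f"perm_{paradigm}_{network}.nii")
                        manifest["maps"][f"perm_{paradigm}_{network}"] = [
                            str(p1), str(p2)]
    except Exception as exc:  # persist partial outputs, then re-raise
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline failed at stage {stage}: {exc}") from exc

    tables = {
        "metrics": pd.DataFrame(metric_rows),
        "group_tests": pd.DataFrame(test_rows),
        "permutation_percentages": pd.DataFrame(pct_rows),
    }
    for name, df in tables.items():
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest["tables"][name] = {"path": str(path), "sha256": digest}
    manifest["elapsed_s"] = round(time.time() - t0, 2)
    manifest["n_group_datasets"] = 2 * len(config.paradigms)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def report(manifest: dict | str | Path) -> str:
    """Human-readable summary: per-region dual-metric tables with
    decrease (*) / increase (#) markers, plus permutation percentages."""
    if not isinstance(manifest, dict):
        manifest = json.loads(Path(manifest).read_text())
    lines = ["netdisrupt run report", "=" * 60]
    missing = [n for n, t in manifest.get("tables", {}).items()
               if not Path(t["path"]).exists()]
    if missing:
        lines.append(f"missing artifacts: {', '.join(missing)}")
    tests_info = manifest.get("tables", {}).get("group_tests")
    if tests_info and Path(tests_info["path"]).exists():
        df = pd.read_csv(tests_info["path"])
        for (paradigm, method), sub in df.groupby(["paradigm", "method"]):
            lines.append(f"\n[{paradigm} / {method}]  (control vs injured)")
            lines.append(f"{'region':42s} {'Pearson p':>10s} "
                         f"{'MeanRatio p':>12s}  sig")
            for _, row in sub.iterrows():
                if row["significant"]:
                    marker = "*" if row["direction"] == "decrease" else "#"
                else:
                    marker = ""
                lines.append(
                    f"{row['region_name']:42s} {row['pearson_p']:>10.4f} "
                    f"{row['mean_ratio_p']:>12.4f}  {marker}")
    pct_info = manifest.get("tables", {}).get("permutation_percentages")
    if pct_info and Path(pct_info["path"]).exists():
        df = pd.read_csv(pct_info["path"])
        lines.append("\nPermutation analysis: % significant voxels per region")
        lines.append(f"{'paradigm':14s} {'region':42s} "
                     f"{'% decr':>8s} {'% incr':>8s}")
        for _, row in df.iterrows():
            lines.append(f"{row['paradigm']:14s} {row['region_name']:42s} "
                         f"{row['pct_decreasing']:>8.1f} "
                         f"{row['pct_increasing']:>8.1f}")
    return "\n".join(lines)
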