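"""Sparse coding, dictionary learning, dual regression, and group ICA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netdisrupt import decompose as dc
from netdisrupt import preprocess as pp
from netdisrupt import synthdata as sd
from netdisrupt import atlasmetrics as am

from conftest import fista_lasso, lasso_objective


def _unit_dict(T, n, seed=0):
    rng = np.random.default_rng(seed)
    D = rng.normal(size=(T, n))
    return D / np.linalg.norm(D, axis=0)


class TestSparseCode:
    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10_000),
           lam=st.floats(0.01, 2.0, allow_nan=False))
    def test_single_atom_soft_threshold_closed_form(self, seed, lam):
        rng = np.random.default_rng(seed)
        d = rng.normal(size=(15, 1))
        d /= np.linalg.norm(d)
        s = rng.normal(size=(1, 15))
        code = dc.sparse_code(s, dc.TimeDictionary(d), lam).maps[0, 0]
        proj = float(d[:, 0] @ s[0])
        expected = np.sign(proj) * max(abs(proj) - lam, 0.0)
        assert code == pytest.approx(expected, abs=1e-8)

    def test_large_lambda_gives_null_solution(self):
        rng = np.random.default_rng(1)
        D = _unit_dict(20, 5)
        X = rng.normal(size=(8, 20))
        lam = float(np.abs(X @ D).max()) + 1.0
        maps = dc.sparse_code(X, dc.TimeDictionary(D), lam).maps
        assert not maps.any()

    def test_matches_independent_fista_oracle(self):
        rng = np.random.default_rng(7)
        D = _unit_dict(20, 5, seed=7)
        X = rng.normal(size=(50, 20))
        res = dc.sparse_code(X, dc.TimeDictionary(D), 0.15)
        oracle = fista_lasso(X, D, 0.15)
        obj_o = lasso_objective(X, D, oracle, 0.15)
        obj_c = lasso_objective(X, D, res.maps.T, 0.15)
        assert abs(obj_c - obj_o) / obj_o <= 1e-6

    def test_scale_consistency(self):
        rng = np.random.default_rng(3)
        D = _unit_dict(12, 4, seed=3)
        X = rng.normal(size=(6, 12))
        a1 = dc.sparse_code(X, dc.TimeDictionary(D), 0.2).maps
        a2 = dc.sparse_code(5.0 * X, dc.TimeDictionary(D), 5.0 * 0.2).maps
        assert np.allclose(a2, 5.0 * a1, atol=1e-6)

    def test_non_finite_input_rejected(self):
        D = _unit_dict(5, 2)
        X = np.full((3, 5), np.nan)
        with pytest.raises(ValueError):
            dc.sparse_code(X, dc.TimeDictionary(D), 0.1)


class TestSdlFit:
    def test_exact_factorization_recovered_when_rank_matches(self):
        rng = np.random.default_rng(0)
        D0, _ = np.linalg.qr(rng.normal(size=(30, 4)))  # orthonormal atoms
        A0 = rng.normal(size=(60, 4))
        X = A0 @ D0.T
        cfg = dc.SdlConfig(n_atoms=4, lam=0.0, max_outer_iters=10, seed=0)
        D, maps = dc.sdl_fit(X, cfg)
        resid = X - maps.maps.T @ D.atoms.T
        assert np.linalg.norm(resid) <= 1e-8

    def test_objective_non_increasing(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(120, 25))
        cfg = dc.SdlConfig(n_atoms=8, lam=0.1, max_outer_iters=8, seed=5)
        _, maps = dc.sdl_fit(X, cfg)
        path = np.array(maps.objective_path)
        slack = cfg.code_tolerance * np.maximum(np.abs(path[:-1]), 1.0)
        assert (np.diff(path) <= slack).all()

    def test_atoms_unit_norm_and_signs_fixed(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(80, 20))
        D, maps = dc.sdl_fit(X, dc.SdlConfig(n_atoms=6, lam=0.1,
                                             max_outer_iters=5, seed=6))
        live = ~D.dead
        assert np.allclose(np.linalg.norm(D.atoms[:, live], axis=0), 1.0)
        peak = np.take_along_axis(maps.maps,
                                  np.abs(maps.maps).argmax(axis=1)[:, None],
                                  axis=1)[:, 0]
        assert (peak[np.abs(peak) > 0] > 0).all()

    def test_planted_networks_recovered_in_thresholded_group_maps(
            self, atlas, masks):
        design = sd.make_design("rest", 3.0, n_volumes=100)
        eff = sd.EffectSpec()
        subs = [sd.simulate_subject(atlas, design, "control", eff,
                                    seed=100 + i, subject_id=f"C{i}")
                for i in range(7)]
        trimmed = [pp.trim_initial_volumes(s, 5) for s in subs]
        ds = pp.concatenate_group(trimmed, atlas.brain_mask, "rest",
                                  "control")
        _, alpha_g = dc.sdl_fit(ds, dc.SdlConfig(n_atoms=24, lam=0.15,
                                                 max_outer_iters=10, seed=0))
        thr = am.normalize_and_threshold(alpha_g, am.group_map_max(alpha_g))
        for net in sd.NETWORK_NAMES:
            best = max(am.pearson_to_atlas(row, masks[net])
                       for row in thr.maps if row.any())
            assert best >= 0.5, f"network {net} not recovered (r={best:.2f})"


class TestDualRegression:
    def test_exact_model_recovered_noiseless(self):
        rng = np.random.default_rng(2)
        D_star = _unit_dict(40, 5, seed=2)
        alpha_g = rng.normal(size=(5, 90)) * (rng.random((5, 90)) < 0.3)
        S = (D_star @ alpha_g).T  # voxel x time
        g = dc.SpatialMapSet(maps=alpha_g, method="sdl")
        _D_i, alpha_i = dc.dual_regression(S, g, lam=0.0)
        for k in range(5):
            r = np.corrcoef(alpha_i.maps[k], alpha_g[k])[0, 1]
            assert r == pytest.approx(1.0, abs=1e-8)

    def test_indicator_map_gives_mean_regional_time_course(self):
        rng = np.random.default_rng(4)
        V, T = 50, 30
        S = rng.normal(size=(V, T))
        ind = np.zeros(V)
        ind[:10] = 1.0
        g = dc.SpatialMapSet(maps=ind[None, :], method="sdl")
        D_i, _ = dc.dual_regression(S, g, lam=0.1)
        mean_course = S[:10].mean(axis=0)
        expected = mean_course / np.linalg.norm(mean_course)
        assert np.allclose(D_i.atoms[:, 0], expected, atol=1e-10)

    def test_huge_lambda_zeroes_subject_maps(self):
        rng = np.random.default_rng(8)
        S = rng.normal(size=(40, 25))
        g = dc.SpatialMapSet(maps=rng.normal(size=(3, 40)), method="sdl")
        _, alpha_i = dc.dual_regression(S, g, lam=1e6)
        assert not alpha_i.maps.any()

    def test_scale_consistency(self):
        rng = np.random.default_rng(9)
        S = rng.normal(size=(40, 25))
        g = dc.SpatialMapSet(maps=rng.normal(size=(3, 40)), method="sdl")
        _, a1 = dc.dual_regression(S, g, lam=0.2)
        _, a2 = dc.dual_regression(3.0 * S, g, lam=3.0 * 0.2)
        assert np.allclose(a2.maps, 3.0 * a1.maps, atol=1e-6)


class _Group:
    """Minimal GroupDataset stand-in for decomposition unit tests."""

    def __init__(self, matrix, spans):
        self.matrix = matrix
        self.subject_spans = spans


class TestGroupIca:
    def _two_source_group(self, seed=0, T=60, V=400):
        rng = np.random.default_rng(seed)
        S = np.zeros((2, V))
        S[0, :80] = rng.exponential(1.0, 80)  # disjoint non-Gaussian sources
        S[1, 200:300] = rng.exponential(1.0, 100)
        M = rng.normal(size=(T, 2))
        X = (M @ S).T + 1e-6 * rng.normal(size=(V, T))
        return _Group(X, [("S0", 0, T)]), S

    def test_disjoint_nongaussian_sources_identified(self):
        group, S = self._two_source_group()
        model = dc.group_ica(group, n_components=2, seed=0)
        for true in S:
            r = max(abs(np.corrcoef(true, est)[0, 1])
                    for est in model.group_maps.maps)
            assert r >= 0.99

    def test_maps_mutually_decorrelated(self):
        group, _ = self._two_source_group(seed=3)
        model = dc.group_ica(group, n_components=2, seed=0)
        maps = model.group_maps.maps
        c = np.corrcoef(maps)
        assert abs(c[0, 1]) <= 1e-6

    def test_rank_one_data_single_component(self):
        rng = np.random.default_rng(1)
        pattern = rng.exponential(size=200)
        course = rng.normal(size=30)
        X = np.outer(pattern, course)
        model = dc.group_ica(_Group(X, [("S0", 0, 30)]), n_components=1,
                             seed=0)
        r = abs(np.corrcoef(model.group_maps.maps[0], pattern)[0, 1])
        assert r == pytest.approx(1.0, abs=1e-8)

    def test_component_count_validated(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 10))
        with pytest.raises(ValueError):
            dc.group_ica(_Group(X, [("S0", 0, 10)]), n_components=20)


class TestBackReconstruction:
    def test_single_subject_group_reproduces_group_maps(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(300, 40))
        group = _Group(X, [("S0", 0, 40)])
        model = dc.group_ica(group, n_components=3, seed=1)
        alpha_i = dc.back_reconstruct(group, model, "S0")
        assert np.allclose(alpha_i.maps, model.group_maps.maps, atol=1e-8)

    def test_identical_subjects_get_identical_maps(self):
        rng = np.random.default_rng(1)
        block = rng.normal(size=(300, 30))
        X = np.concatenate([block, block], axis=1)
        group = _Group(X, [("S0", 0, 30), ("S1", 30, 60)])
        model = dc.group_ica(group, n_components=3, seed=1)
        a0 = dc.back_reconstruct(group, model, "S0")
        a1 = dc.back_reconstruct(group, model, "S1")
        assert np.allclose(a0.maps, a1.maps, atol=1e-6)

    def test_planted_amplitudes_order_subject_maps(self):
        rng = np.random.default_rng(2)
        V, T = 400, 40
        pattern = np.zeros(V)
        pattern[:60] = rng.exponential(1.0, 60)
        amps = [0.5, 1.0, 2.0]
        blocks, spans, pos = [], [], 0
        for i, a in enumerate(amps):
            course = rng.normal(size=T)
            noise = 0.01 * rng.normal(size=(V, T))
            blocks.append(a * np.outer(pattern, course) + noise)
            spans.append((f"S{i}", pos, pos + T))
            pos += T
        group = _Group(np.concatenate(blocks, axis=1), spans)
        model = dc.group_ica(group, n_components=2, seed=0)
        # component matching the pattern
        k = int(np.argmax([abs(np.corrcoef(m, pattern)[0, 1])
                           for m in model.group_maps.maps]))
        mags = [np.abs(dc.back_reconstruct(group, model, f"S{i}").maps[k][:60]).mean()
                for i in range(3)]
        assert mags[0] < mags[1] < mags[2]

    def test_unknown_subject_rejected(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100, 20))
        group = _Group(X, [("S0", 0, 20)])
        model = dc.group_ica(group, n_components=2, seed=0)
        with pytest.raises(KeyError):
            dc.back_reconstruct(group, model, "nope")
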