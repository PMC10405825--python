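"""Maxent core: features, fitting against brute-force oracles, prediction, AUC."""

import numpy as np
import pytest

from enmpipe.geodata import EnvStack, OccurrenceSet
from enmpipe.maxent import (MaxentModel, auc, build_features, feature_matrix,
                            fit_maxent, penalized_objective, predict,
                            predict_scores, response_curve, sample_background,
                            training_gain)
from enmpipe import synthetic

from conftest import make_grid


def _line_stack(cols: dict[str, np.ndarray]) -> EnvStack:
    n = len(next(iter(cols.values())))
    return EnvStack({k: make_grid(np.asarray(v, dtype=float).reshape(1, n))
                     for k, v in cols.items()})


class TestFeatures:
    def test_linear_feature_count(self, study_system):
        spec = build_features(study_system["stack"], "L")
        assert spec.n_features == 4

    def test_lqp_combinatorial_count(self):
        rng = np.random.default_rng(0)
        st = _line_stack({f"v{i}": rng.normal(size=20) for i in range(3)})
        spec = build_features(st, "LQP")
        assert spec.n_features == 3 + 3 + 3  # L + Q + C(3,2) products

    def test_scaling_endpoints(self):
        st = _line_stack({"v": np.array([2.0, 4.0, 8.0])})
        spec = build_features(st, "L")
        F = feature_matrix(np.array([[2.0], [8.0]]), ["v"], spec)
        assert F[0, 0] == 0.0 and F[1, 0] == 1.0

    def test_all_features_unit_interval_on_background(self, study_system):
        st = study_system["stack"]
        spec = build_features(st, "LQPHT", n_knots=5)
        X = np.column_stack([st[n].values[st.mask] for n in st.names])
        F = feature_matrix(X, st.names, spec)
        assert F.min() >= 0.0 and F.max() <= 1.0 + 1e-12

    def test_constant_variable_warns_and_skips(self):
        st = _line_stack({"v": np.array([1.0, 1.0, 1.0]),
                          "w": np.array([0.0, 1.0, 2.0])})
        with pytest.warns(UserWarning, match="constant"):
            spec = build_features(st, "LQ")
        assert {f.variables[0] for f in spec.features} == {"w"}


class TestSampleBackground:
    def test_exhaustion_returns_all_cells(self, small_grid):
        st = EnvStack({"v": small_grid})
        assert len(sample_background(st, n=10000, seed=0)) == 3

    def test_seed_reproducible(self, study_system):
        st = study_system["stack"]
        assert sample_background(st, 100, seed=1) == sample_background(st, 100, seed=1)

    def test_inclusion_probability_near_half(self):
        g = make_grid(np.zeros((10, 10)))
        st = EnvStack({"v": g})
        hits = np.zeros(100)
        for seed in range(200):
            for (r, c) in sample_background(st, 50, seed=seed):
                hits[r * 10 + c] += 1
        assert np.abs(hits / 200 - 0.5).max() < 0.15  # binomial sd ~ 0.035


class TestFit:
    def test_no_signal_shrinks_to_uniform(self):
        rng = np.random.default_rng(1)
        st = _line_stack({"v": rng.normal(size=50)})
        bg = [(0, i) for i in range(50)]
        pres = [(0, int(i)) for i in rng.integers(0, 50, size=30)]
        spec = build_features(st, "L", background_cells=bg)
        m = fit_maxent(pres, bg, st, spec, rm=1.0)
        raw = predict_scores(m, st, bg, "raw")
        assert np.allclose(raw, 1 / 50, atol=5e-3)

    @pytest.mark.parametrize("seed", range(5))
    def test_one_dim_grid_search_oracle(self, seed):
        """Coordinate descent matches a dense 1-D search of the same objective."""
        rng = np.random.default_rng(seed)
        st = _line_stack({"v": rng.normal(size=20)})
        bg = [(0, i) for i in range(20)]
        pres = [(0, int(i)) for i in rng.integers(0, 20, size=5)]
        spec = build_features(st, "L", background_cells=bg)
        m = fit_maxent(pres, bg, st, spec, rm=0.5, tolerance=1e-10)
        X_bg = st.values_at_cells(m.background_cells)
        F_bg = feature_matrix(X_bg, st.names, spec, clamp=False)
        grid = np.linspace(-50, 50, 400001)
        objs = np.array([penalized_objective(np.array([l]), F_bg,
                                             m.presence_feature_mean, m.beta)
                         for l in grid[:: 2000]])
        fine0 = grid[::2000][np.argmax(objs)]
        fine = np.linspace(fine0 - 0.5, fine0 + 0.5, 10001)
        objs = np.array([penalized_objective(np.array([l]), F_bg,
                                             m.presence_feature_mean, m.beta)
                         for l in fine])
        best = fine[np.argmax(objs)]
        assert m.lam[0] == pytest.approx(best, abs=1e-3)

    def test_objective_matches_grid_search_two_features(self):
        rng = np.random.default_rng(7)
        st = _line_stack({"v": rng.normal(size=25)})
        bg = [(0, i) for i in range(25)]
        pres = [(0, int(i)) for i in rng.integers(0, 25, size=8)]
        spec = build_features(st, "LQ", background_cells=bg)
        m = fit_maxent(pres, bg, st, spec, rm=1.0, tolerance=1e-10)
        X_bg = st.values_at_cells(m.background_cells)
        F_bg = feature_matrix(X_bg, st.names, spec, clamp=False)
        grid = np.linspace(-20, 20, 161)
        best = -np.inf
        for l1 in grid:
            for l2 in grid:
                best = max(best, penalized_objective(
                    np.array([l1, l2]), F_bg, m.presence_feature_mean, m.beta))
        ours = penalized_objective(m.lam, F_bg, m.presence_feature_mean, m.beta)
        assert ours >= best - 1e-3

    def test_rm_monotone_shrinkage(self, study_system):
        st, occ = study_system["stack"], study_system["occ"]
        from enmpipe.geodata import occurrence_cells
        cells = occurrence_cells(occ, st.grid)
        bg = sample_background(st, 1000, seed=0)
        spec = build_features(st, "L", background_cells=bg)
        norms = []
        for rm in (0.5, 1.0, 2.0, 4.0):
            m = fit_maxent(cells, bg, st, spec, rm=rm)
            norms.append(np.abs(m.lam).sum())
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_raw_normalizes_over_background(self, study_system):
        st, occ = study_system["stack"], study_system["occ"]
        from enmpipe.geodata import occurrence_cells
        cells = occurrence_cells(occ, st.grid)
        bg = sample_background(st, 800, seed=2)
        spec = build_features(st, "LQ", background_cells=bg)
        m = fit_maxent(cells, bg, st, spec, rm=1.0)
        raw = predict_scores(m, st, m.background_cells, "raw")
        assert raw.sum() == pytest.approx(1.0, abs=1e-6)
        assert m.entropy >= 0

    def test_empty_presences_rejected(self, study_system):
        st = study_system["stack"]
        spec = build_features(st, "L")
        with pytest.raises(ValueError):
            fit_maxent([], [(0, 0)], st, spec)


class TestPredict:
    def test_hand_normalization_three_cells(self):
        """lam.f = (0, ln2, ln4) over 3 background cells -> raw = (1,2,4)/7."""
        st = _line_stack({"v": np.array([0.0, 0.5, 1.0])})
        bg = [(0, 0), (0, 1), (0, 2)]
        spec = build_features(st, "L", background_cells=bg)
        m = fit_maxent([(0, 2)], bg, st, spec, rm=1.0)
        m.lam = np.array([2 * np.log(2.0)])  # f = (0, .5, 1) -> lam.f = (0, ln2, ln4)
        from scipy.special import logsumexp
        F = feature_matrix(st.values_at_cells(bg), st.names, spec)
        m.log_partition = float(logsumexp(F @ m.lam))
        raw = predict_scores(m, st, bg, "raw")
        assert np.allclose(raw, np.array([1, 2, 4]) / 7)

    def test_uniform_model_logistic_half(self):
        rng = np.random.default_rng(3)
        st = _line_stack({"v": rng.normal(size=30)})
        bg = [(0, i) for i in range(30)]
        spec = build_features(st, "L", background_cells=bg)
        m = fit_maxent([(0, 0)], bg, st, spec, rm=1.0)
        m.lam = np.zeros(1)
        m.log_partition = np.log(len(m.background_cells))
        m.entropy = np.log(len(m.background_cells))
        sm = predict(m, st, "logistic")
        assert np.allclose(sm.grid.values[0], 0.5)

    def test_monotone_single_variable_model(self):
        st = _line_stack({"v": np.linspace(0, 1, 40)})
        bg = [(0, i) for i in range(40)]
        spec = build_features(st, "L", background_cells=bg)
        m = fit_maxent([(0, 35), (0, 38)], bg, st, spec, rm=0.5)
        assert m.lam[0] > 0
        sm = predict(m, st, "logistic")
        vals = sm.grid.values[0]
        assert (np.diff(vals) >= -1e-12).all()

    def test_missing_variable_raises(self, study_system):
        st = study_system["stack"]
        spec = build_features(st, "L")
        from enmpipe.geodata import occurrence_cells
        cells = occurrence_cells(study_system["occ"], st.grid)
        m = fit_maxent(cells[:10], sample_background(st, 200, seed=0), st, spec)
        partial = EnvStack({"bio01": st["bio01"]})
        with pytest.raises(KeyError):
            predict(m, partial)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_all_ties_half(self):
        assert auc([0.5] * 3, [0.5] * 4) == 0.5

    def test_hand_enumeration(self):
        assert auc([0.9, 0.4], [0.5, 0.1]) == 0.75

    @pytest.mark.parametrize("seed", range(5))
    def test_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.choice(np.linspace(0, 1, 11), size=50)
        b = rng.choice(np.linspace(0, 1, 11), size=80)
        direct = np.mean([[1.0 if x > y else 0.5 if x == y else 0.0
                           for y in b] for x in p])
        assert auc(p, b) == pytest.approx(direct, abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(9)
        p = rng.normal(1, 1, size=60)
        b = rng.normal(0, 1, size=90)
        y = np.r_[np.ones(60), np.zeros(90)]
        assert auc(p, b) == pytest.approx(roc_auc_score(y, np.r_[p, b]), abs=1e-12)


class TestResponseCurve:
    def test_positive_linear_model_increasing(self):
        st = _line_stack({"v": np.linspace(0, 1, 30)})
        bg = [(0, i) for i in range(30)]
        spec = build_features(st, "L", background_cells=bg)
        m = fit_maxent([(0, 28)], bg, st, spec, rm=0.5)
        curve = response_curve(m, st, "v", n_points=20)
        ys = [y for _, y in curve]
        assert m.lam[0] > 0 and all(b >= a for a, b in zip(ys, ys[1:]))

    def test_quadratic_truth_recovers_interior_optimum(self):
        """Presences near v=0.6 with Q features -> response peak near 0.6."""
        st = _line_stack({"v": np.linspace(0, 1, 101)})
        bg = [(0, i) for i in range(101)]
        rng = np.random.default_rng(4)
        pres_idx = np.clip(rng.normal(60, 6, size=200).round().astype(int), 0, 100)
        pres = [(0, int(i)) for i in pres_idx]
        spec = build_features(st, "LQ", background_cells=bg)
        m = fit_maxent(pres, bg, st, spec, rm=1.0)
        curve = response_curve(m, st, "v", n_points=101)
        peak = max(curve, key=lambda t: t[1])[0]
        assert peak == pytest.approx(0.6, abs=0.05)

    def test_unknown_variable_raises(self, study_system):
        st = study_system["stack"]
        spec = build_features(st, "L")
        m = fit_maxent([(5, 5)], sample_background(st, 100, seed=0), st, spec)
        with pytest.raises(KeyError):
            response_curve(m, st, "nope")


class TestSerialization:
    def test_text_round_trip_exact(self, study_system):
        st, occ = study_system["stack"], study_system["occ"]
        from enmpipe.geodata import occurrence_cells
        cells = occurrence_cells(occ, st.grid)
        bg = sample_background(st, 300, seed=1)
        spec = build_features(st, "LQH", n_knots=4, background_cells=bg)
        m = fit_maxent(cells, bg, st, spec, rm=1.0)
        m2 = MaxentModel.from_text(m.to_text())
        assert np.array_equal(m2.lam, m.lam)
        assert m2.log_partition == m.log_partition
        assert m2.entropy == m.entropy
        assert [f.label for f in m2.spec.features] == [f.label for f in m.spec.features]
        sm = predict(m, st)
        sm2 = predict(m2, st)
        assert np.array_equal(sm.grid.values, sm2.grid.values, equal_nan=True)
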