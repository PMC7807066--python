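"""Gating, TSS weighting, binarization, and range-change arithmetic."""

import numpy as np
import pytest

from emusdm import (
    EnsembleModel,
    GateThresholds,
    Grid,
    GridSurface,
    PredictorStack,
    binarize,
    build_ensemble,
    ensemble_predict,
    range_change,
    select_members,
    uncertainty_map,
)
from emusdm.ensemble import EmptyEnsembleError
from emusdm.evaluation import EvaluationScores
from emusdm.models import FittedModel


class StubLearner:
    def __init__(self, value):
        self.value = value

    def predict_suitability(self, X):
        return np.full(len(np.atleast_2d(X)), self.value)


def stub_model(tss=0.8, auc=0.95, kappa=0.8, value=0.5, algorithm="stub", repeat=0):
    return FittedModel(
        algorithm=algorithm,
        repeat=repeat,
        learner=StubLearner(value),
        feature_names=["a"],
        calib_idx=np.arange(5),
        holdout_idx=np.arange(5, 10),
        scores=EvaluationScores(
            sensitivity=0.9, specificity=0.9, tss=tss, kappa=kappa, auc=auc, threshold=0.5
        ),
        seed=0,
    )


class TestSelectMembers:
    def test_low_tss_excluded_with_reason(self):
        members, report = select_members([stub_model(tss=0.69, auc=0.95, kappa=0.8)])
        assert members == []
        assert "TSS" in report[0]["exclusion_reasons"][0]

    def test_all_gates_met_inclusive(self):
        m = stub_model(tss=0.7, auc=0.9, kappa=0.7)  # boundary: >= passes
        members, report = select_members([m])
        assert members == [m] and report[0]["passed"]

    @pytest.mark.parametrize(
        "tss,auc,kappa,included",
        [
            (0.75, 0.92, 0.71, True),
            (0.69, 0.95, 0.80, False),
            (0.75, 0.89, 0.80, False),
            (0.75, 0.95, 0.69, False),
        ],
    )
    def test_each_gate_enforced(self, tss, auc, kappa, included):
        members, _ = select_members([stub_model(tss=tss, auc=auc, kappa=kappa)])
        assert bool(members) == included

    def test_failed_fit_excluded(self):
        m = stub_model()
        m.error, m.scores, m.learner = "boom", None, None
        members, report = select_members([m])
        assert members == [] and "fit failed" in report[0]["exclusion_reasons"][0]

    def test_raising_gates_never_adds_members(self):
        models = [stub_model(tss=t, auc=a, kappa=k)
                  for t, a, k in [(0.7, 0.9, 0.7), (0.8, 0.95, 0.8), (0.9, 0.99, 0.9)]]
        base, _ = select_members(models, GateThresholds())
        tighter, _ = select_members(models, GateThresholds(tss_min=0.85))
        assert set(id(m) for m in tighter) <= set(id(m) for m in base)

    def test_empty_survivor_set_is_fatal_for_ensembling(self):
        with pytest.raises(EmptyEnsembleError):
            build_ensemble([stub_model(tss=0.1)])


class TestEnsemblePredict:
    def grid_stack(self):
        grid = Grid(3, 3, 1.0)
        return PredictorStack(grid, {"a": np.zeros(grid.shape)})

    def test_single_member_is_identity(self):
        m = stub_model(value=0.37)
        ens = EnsembleModel(members=[m], weights=np.array([1.0]))
        out = ensemble_predict(ens, self.grid_stack())
        np.testing.assert_allclose(out.values, 0.37)

    def test_equal_tss_gives_arithmetic_mean(self):
        ens, _ = build_ensemble([stub_model(tss=0.8, value=0.2),
                                 stub_model(tss=0.8, value=0.6)])
        np.testing.assert_allclose(ens.weights, [0.5, 0.5])
        out = ensemble_predict(ens, self.grid_stack())
        np.testing.assert_allclose(out.values, 0.4)

    def test_tss_weighted_arithmetic_example(self):
        # TSS 0.9 and 0.45 predicting 0.6 and 0.3 -> 0.5
        ens, _ = build_ensemble(
            [stub_model(tss=0.9, value=0.6), stub_model(tss=0.45, value=0.3)],
            GateThresholds(tss_min=0.0, auc_min=0.0, kappa_min=0.0),
        )
        np.testing.assert_allclose(ens.weights, [0.9 / 1.35, 0.45 / 1.35])
        out = ensemble_predict(ens, self.grid_stack())
        np.testing.assert_allclose(out.values, 0.5, atol=1e-12)

    def test_weights_sum_to_one_and_envelope_bound(self, separable_table):
        from emusdm import fit_all

        models = fit_all(separable_table, roster=["glm", "rf", "fda"], n_repeats=2, seed=0)
        ens, _ = build_ensemble(models, GateThresholds(tss_min=0.0, auc_min=0.0, kappa_min=0.0))
        assert abs(ens.weights.sum() - 1.0) < 1e-12
        X = separable_table[["bio13", "bio15"]].to_numpy()
        member_preds = ens.member_predictions(X)
        combined = ens.predict(X)
        assert np.all(combined <= member_preds.max(axis=0) + 1e-12)
        assert np.all(combined >= member_preds.min(axis=0) - 1e-12)

    def test_missing_predictor_rejected(self):
        ens = EnsembleModel(members=[stub_model()], weights=np.array([1.0]))
        grid = Grid(2, 2, 1.0)
        stack = PredictorStack(grid, {"zzz": np.zeros(grid.shape)})
        with pytest.raises(KeyError):
            ensemble_predict(ens, stack)


class TestUncertaintyMap:
    def test_identical_members_cv_zero(self):
        ens = EnsembleModel(
            members=[stub_model(value=0.4), stub_model(value=0.4)],
            weights=np.array([0.5, 0.5]),
        )
        grid = Grid(2, 2, 1.0)
        stack = PredictorStack(grid, {"a": np.zeros(grid.shape)})
        np.testing.assert_allclose(uncertainty_map(ens, stack).values, 0.0)

    def test_sample_sd_over_mean_example(self):
        ens = EnsembleModel(
            members=[stub_model(value=0.2), stub_model(value=0.6)],
            weights=np.array([0.5, 0.5]),
        )
        grid = Grid(2, 2, 1.0)
        stack = PredictorStack(grid, {"a": np.zeros(grid.shape)})
        expected = np.std([0.2, 0.6], ddof=1) / 0.4  # ~ 0.707
        np.testing.assert_allclose(uncertainty_map(ens, stack).values, expected)

    def test_single_member_rejected(self):
        ens = EnsembleModel(members=[stub_model()], weights=np.array([1.0]))
        grid = Grid(2, 2, 1.0)
        with pytest.raises(ValueError):
            uncertainty_map(ens, PredictorStack(grid, {"a": np.zeros(grid.shape)}))


class TestBinarize:
    def test_threshold_extremes(self):
        grid = Grid(2, 2, 1.0)
        surf = GridSurface(grid, np.array([[0.1, 0.9], [0.5, np.nan]]))
        assert binarize(surf, 0.0).n_present == 3  # NaN cells stay absent
        assert binarize(surf, 1.0).n_present == 0

    def test_hand_written_mask(self):
        grid = Grid(3, 3, 1.0)
        vals = np.array([[0.1, 0.5, 0.9], [0.4, 0.6, 0.2], [0.7, 0.3, 0.5]])
        bm = binarize(GridSurface(grid, vals), 0.5)
        np.testing.assert_array_equal(
            bm.present,
            np.array([[False, True, True], [False, True, False], [True, False, True]]),
        )

    def test_out_of_range_threshold_rejected(self):
        grid = Grid(2, 2, 1.0)
        with pytest.raises(ValueError):
            binarize(GridSurface(grid, np.zeros(grid.shape)), 1.5)


def binary_map(mask, grid=None):
    mask = np.asarray(mask, dtype=bool)
    grid = grid or Grid(*mask.shape, 1.0)
    from emusdm import BinaryRangeMap

    return BinaryRangeMap(grid, mask, 0.5, "x")


class TestRangeChange:
    def test_identity_gives_zero_change(self):
        m = binary_map(np.eye(4))
        rc = range_change(m, m)
        assert rc.pct_change_unlimited == 0.0 and rc.pct_change_no_dispersal == 0.0

    def test_cell_count_example(self):
        grid = Grid(20, 20, 1.0)
        cur = np.zeros((20, 20), dtype=bool)
        cur.ravel()[:100] = True
        oth = np.zeros((20, 20), dtype=bool)
        oth.ravel()[10:190] = True  # 180 cells, overlap 90
        rc = range_change(binary_map(cur, grid), binary_map(oth, grid))
        assert rc.cells_current == 100 and rc.cells_other == 180 and rc.cells_overlap == 90
        assert rc.pct_change_unlimited == pytest.approx(80.0)
        assert rc.pct_change_no_dispersal == pytest.approx(-10.0)

    def test_disjoint_other_no_dispersal_is_minus_100(self):
        cur = np.zeros((4, 4), dtype=bool); cur[0] = True
        oth = np.zeros((4, 4), dtype=bool); oth[2] = True
        rc = range_change(binary_map(cur), binary_map(oth))
        assert rc.pct_change_no_dispersal == -100.0

    def test_no_dispersal_never_exceeds_unlimited(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            cur = rng.uniform(size=(8, 8)) < 0.5
            if not cur.any():
                cur[0, 0] = True
            oth = rng.uniform(size=(8, 8)) < 0.5
            rc = range_change(binary_map(cur), binary_map(oth))
            assert rc.pct_change_no_dispersal <= rc.pct_change_unlimited + 1e-12
            assert rc.cells_overlap <= min(rc.cells_current, rc.cells_other)

    def test_transition_codes_partition_grid(self):
        cur = np.array([[True, True], [False, False]])
        oth = np.array([[True, False], [True, False]])
        rc = range_change(binary_map(cur), binary_map(oth))
        np.testing.assert_array_equal(rc.transitions, np.array([[1, 3], [2, 0]]))

    def test_empty_current_rejected(self):
        cur = np.zeros((2, 2), dtype=bool)
        oth = np.ones((2, 2), dtype=bool)
        with pytest.raises(ValueError):
            range_change(binary_map(cur), binary_map(oth))
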