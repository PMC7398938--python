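import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from invasdm import (ConfigError, DataError, GateError, Grid,
                     build_ensemble, compute_auc, evaluate_model,
                     performance_band, select_threshold_max_tss)
from invasdm.evaluation import EvaluationResult


def auc_pair_counting(scores, labels):
    """Exhaustive O(n^2) concordance oracle."""
    scores = np.asarray(scores, dtype=float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestComputeAuc:
    def test_perfect_separation(self):
        assert compute_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert compute_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_worked_example(self):
        # 3 of 4 presence/absence pairs concordant
        assert compute_auc([0.9, 0.8, 0.4, 0.1],
                           [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_matches_pair_counting_oracle(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(10, 500))
            scores = np.round(rng.random(n), 2)  # force some ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert compute_auc(scores, labels) == pytest.approx(
                auc_pair_counting(scores, labels), abs=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.integers(0, 1000), min_size=4, max_size=60),
           st.floats(0.1, 5.0))
    def test_invariant_under_monotone_transform(self, scores, scale):
        labels = (np.arange(len(scores)) % 2).tolist()
        trans = (np.asarray(scores, dtype=float) * scale) ** 3 + 1.0
        assert compute_auc(scores, labels) == pytest.approx(
            compute_auc(trans, labels), abs=1e-12)

    def test_single_class_error(self):
        with pytest.raises(DataError):
            compute_auc([0.1, 0.9], [1, 1])


class TestMaxTssThreshold:
    def test_perfect_separation(self):
        thr, sens, spec, tss = select_threshold_max_tss(
            [0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert tss == 1.0
        assert thr == 0.8  # smallest presence score

    def test_worked_example_enumerated(self):
        thr, sens, spec, tss = select_threshold_max_tss(
            [0.9, 0.8, 0.4, 0.1], [1, 0, 1, 0])
        assert tss == pytest.approx(0.5)
        assert thr == 0.4 and sens == 1.0 and spec == 0.5

    def test_identity_tss_sens_spec(self):
        rng = np.random.default_rng(0)
        scores = rng.random(200)
        labels = rng.integers(0, 2, 200)
        _, sens, spec, tss = select_threshold_max_tss(scores, labels)
        assert tss == pytest.approx(sens + spec - 1, abs=1e-15)
        assert -1 <= tss <= 1

    def test_null_scores_give_small_nonnegative_tss(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            scores = rng.random(2000)
            labels = rng.integers(0, 2, 2000)
            _, _, _, tss = select_threshold_max_tss(scores, labels)
            assert tss >= 0
            if tss < 0.1:
                hits += 1
        assert hits >= 19


class TestPerformanceBand:
    @pytest.mark.parametrize("auc,band", [
        (0.96, "high"),      # best single model reported
        (0.87, "moderate"),  # weakest single model reported
        (0.91, "high"),
        (0.9, "moderate"),   # boundary: 'high' needs strictly > 0.9
        (0.7, "low"),
        (0.55, "low"),
        (0.5, "random"),
        (0.2, "random"),
    ])
    def test_band_boundaries(self, auc, band):
        assert performance_band(auc) == band

    def test_out_of_range(self):
        with pytest.raises(ConfigError):
            performance_band(1.2)


def const_surface(v, shape=(4, 4)):
    return Grid(np.full(shape, float(v)))


def eval_with_tss(alg, tss):
    return EvaluationResult(algorithm_id=alg, auc=0.9, threshold=0.5,
                            sensitivity=(tss + 1) / 2,
                            specificity=(tss + 1) / 2, tss=tss,
                            performance_band="moderate")


class TestEnsemble:
    def test_single_qualifying_member_passthrough(self):
        surf = const_surface(0.3)
        ens = build_ensemble({"GLM": surf},
                             {"GLM": eval_with_tss("GLM", 0.9)}, 0.75)
        np.testing.assert_array_equal(ens.surface.values, surf.values)

    def test_two_members_average(self):
        ens = build_ensemble(
            {"a": const_surface(0.2), "b": const_surface(0.6)},
            {"a": eval_with_tss("a", 0.8), "b": eval_with_tss("b", 0.9)},
            0.75)
        np.testing.assert_allclose(ens.surface.values, 0.4)

    def test_gating_excludes_weak_members(self):
        tss = {"GLM": 0.88, "SVM": 0.9, "RF": 0.8, "BRT": 0.7,
               "MARS": 0.76}
        surfaces = {k: const_surface(i / 10)
                    for i, k in enumerate(tss)}
        ens = build_ensemble(surfaces,
                             {k: eval_with_tss(k, v)
                              for k, v in tss.items()}, 0.75)
        assert set(ens.member_ids) == {"GLM", "SVM", "RF", "MARS"}
        assert list(ens.excluded) == ["BRT"]
        expected = np.mean([0.0, 0.1, 0.2, 0.4])
        np.testing.assert_allclose(ens.surface.values, expected)

    def test_surface_bounded_by_members(self):
        rng = np.random.default_rng(1)
        surfaces = {f"m{i}": Grid(rng.random((5, 5))) for i in range(4)}
        evals = {k: eval_with_tss(k, 0.8 + 0.01 * i)
                 for i, k in enumerate(surfaces)}
        ens = build_ensemble(surfaces, evals, 0.75)
        stack = np.stack([s.values for s in surfaces.values()])
        assert (ens.surface.values >= stack.min(axis=0) - 1e-12).all()
        assert (ens.surface.values <= stack.max(axis=0) + 1e-12).all()

    def test_no_qualifying_member_is_gate_error(self):
        with pytest.raises(GateError):
            build_ensemble({"a": const_surface(0.5)},
                           {"a": eval_with_tss("a", 0.5)}, 0.75)

    def test_geometry_mismatch(self):
        from invasdm import AlignmentError

        with pytest.raises(AlignmentError):
            build_ensemble(
                {"a": const_surface(0.5), "b": const_surface(0.5, (3, 3))},
                {k: eval_with_tss(k, 0.9) for k in "ab"}, 0.75)

    def test_tss_weighted_mean_optional(self):
        ens = build_ensemble(
            {"a": const_surface(0.0), "b": const_surface(1.0)},
            {"a": eval_with_tss("a", 0.8), "b": eval_with_tss("b", 1.0)},
            0.75, tss_weighted=True)
        np.testing.assert_allclose(ens.surface.values, 1.0 / 1.8)


class TestVariableImportance:
    def test_sums_to_100_and_flags_unused_variable(self, pipeline_run):
        from invasdm import load_model, variable_importance

        rundir = pipeline_run["rundir"]
        table = pd.read_csv(rundir / "features.csv")
        test = table[table["partition"] == "test"]
        models = [load_model(rundir / "models" / f"{a}.joblib")
                  for a in ("GLM", "RF", "MARS")]
        imp = variable_importance(models, test, seed=0, n_permutations=5)
        assert sum(imp.values()) == pytest.approx(100.0, abs=1e-6)
        # variables removed by the VIF screen are never seen by the
        # models, so their permutation importance must be ~0
        unused = [v for v in imp if v not in models[0].feature_names]
        assert unused
        for v in unused:
            assert imp[v] < 5.0
        # the top-importance variable is one the true response uses
        top = max(imp, key=imp.get)
        assert top in models[0].feature_names


def test_evaluate_model_composite():
    rng = np.random.default_rng(3)
    scores = np.concatenate([rng.beta(5, 2, 300), rng.beta(2, 5, 300)])
    labels = np.repeat([1, 0], 300)
    res = evaluate_model("GLM", scores, labels)
    assert res.tss == pytest.approx(res.sensitivity + res.specificity - 1)
    assert res.performance_band == performance_band(res.auc)
    assert 0 <= res.threshold <= 1
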