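"""The iterative witness-selection heuristic and its building blocks."""

import numpy as np
import pytest

from isomil.containers import BagMap, ExpressionMatrix, InstanceLabeling, Label
from isomil.gold_standard import TermGoldStandard
from isomil.mil_core import (
    MILConfig,
    aggregate_gene_scores,
    compute_threshold,
    has_converged,
    initialize_labels,
    run_mil,
    score_instances,
    svm_objective,
    train_margin_classifier,
    update_labels_MI,
    update_labels_mi,
)


def lab(d):
    return InstanceLabeling({k: Label[v] for k, v in d.items()})


@pytest.fixture
def two_bags():
    bags = BagMap({"gp": ("gp.1", "gp.2"), "gn": ("gn.1",)})
    std = TermGoldStandard("t", frozenset({"gp"}), frozenset({"gn"}))
    return bags, std


class TestInitializeLabels:
    def test_positive_bag_all_pos(self, two_bags):
        bags, std = two_bags
        labeling = initialize_labels(std, bags)
        assert labeling["gp.1"] is Label.POS
        assert labeling["gp.2"] is Label.POS
        assert labeling["gn.1"] is Label.NEG
        assert not labeling.with_label(Label.NEUTRAL)

    def test_unknown_gene_errors(self):
        bags = BagMap({"gx": ("gx.1",)})
        std = TermGoldStandard("t", frozenset({"gp"}), frozenset({"gn"}))
        with pytest.raises(ValueError, match="gx"):
            initialize_labels(std, bags)


class TestTrainAndScore:
    def _separable(self):
        X = np.vstack([np.full((5, 3), 2.0), np.full((5, 3), -2.0)])
        X += np.random.default_rng(0).normal(0, 0.1, X.shape)
        isos = tuple(f"i{k}" for k in range(10))
        mat = ExpressionMatrix(isos, ("a", "b", "c"), X, space="log2")
        labels = lab({f"i{k}": "POS" if k < 5 else "NEG" for k in range(10)})
        return mat, labels

    def test_separable_clouds_ordered(self):
        mat, labels = self._separable()
        model = train_margin_classifier(mat, labels, MILConfig())
        s = score_instances(model, mat)
        assert min(s[f"i{k}"] for k in range(5)) > max(s[f"i{k}"] for k in range(5, 10))

    def test_conflicting_duplicates_tolerated(self):
        X = np.vstack([np.ones((2, 2)), np.ones((2, 2))])
        mat = ExpressionMatrix(("a", "b", "c", "d"), ("e1", "e2"), X, space="log2")
        labels = lab({"a": "POS", "b": "POS", "c": "NEG", "d": "NEG"})
        model = train_margin_classifier(mat, labels, MILConfig())
        s = score_instances(model, mat)
        assert all(np.isfinite(v) for v in s.values())

    def test_single_class_is_error(self):
        mat, _ = self._separable()
        labels = lab({f"i{k}": "POS" for k in range(10)})
        with pytest.raises(ValueError, match="single class"):
            train_margin_classifier(mat, labels, MILConfig(), term_id="GO:X")

    def test_neutral_excluded_from_fit(self):
        mat, labels = self._separable()
        # flip i0 to NEUTRAL but place it far on the negative side: if it
        # entered the fit as anything, the boundary would move measurably
        d = {f"i{k}": ("POS" if k < 5 else "NEG") for k in range(10)}
        d["i0"] = "NEUTRAL"
        model = train_margin_classifier(mat, lab(d), MILConfig())
        ref = {k: v for k, v in d.items() if v != "NEUTRAL"}
        sub = mat.subset_isoforms(tuple(ref))
        model_ref = train_margin_classifier(sub, lab(ref), MILConfig())
        assert np.allclose(model.coef, model_ref.coef)

    def test_scores_equal_hyperplane_dot_product(self):
        mat, labels = self._separable()
        model = train_margin_classifier(mat, labels, MILConfig())
        s = score_instances(model, mat)
        for iso in mat.isoform_ids:
            by_hand = float(mat.row(iso) @ model.coef + model.intercept)
            assert s[iso] == pytest.approx(by_hand, abs=1e-9)

    def test_column_mismatch_rejected(self):
        mat, labels = self._separable()
        model = train_margin_classifier(mat, labels, MILConfig())
        permuted = mat.subset_experiments(("b", "a", "c"))
        with pytest.raises(ValueError, match="columns"):
            score_instances(model, permuted)


class TestComputeThreshold:
    def test_max(self):
        assert compute_threshold([-1, 0, 2], "max") == 2

    def test_p75_linear_interpolation(self):
        # hand-derived: 75th percentile of [0,1,2,3] interpolates to 2.25
        assert compute_threshold([0, 1, 2, 3], "p75") == pytest.approx(2.25)

    def test_mode_recovers_gaussian_peak(self):
        rng = np.random.default_rng(1)
        draws = rng.normal(-2.0, 1.0, 10_000)
        assert compute_threshold(draws, "mode") == pytest.approx(-2.0, abs=0.2)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            compute_threshold([], "max")

    def test_strictness_ordering_on_unimodal_sample(self):
        rng = np.random.default_rng(2)
        draws = rng.normal(0, 1, 5000)
        t_mode = compute_threshold(draws, "mode")
        t_p75 = compute_threshold(draws, "p75")
        t_max = compute_threshold(draws, "max")
        assert t_mode <= t_p75 <= t_max


class TestLabelUpdates:
    def test_mi_direct_thresholding(self, two_bags):
        bags, std = two_bags
        out = update_labels_mi({"gp.1": 0.2, "gp.2": -0.5, "gn.1": -1}, bags, std, 0.0)
        assert out["gp.1"] is Label.POS and out["gp.2"] is Label.NEG

    def test_mi_at_least_one_rescue(self, two_bags):
        bags, std = two_bags
        out = update_labels_mi({"gp.1": -0.3, "gp.2": -0.5, "gn.1": -1}, bags, std, 0.0)
        assert out["gp.1"] is Label.POS and out["gp.2"] is Label.NEG

    def test_mi_rescue_tie_breaks_lexicographically(self, two_bags):
        bags, std = two_bags
        out = update_labels_mi({"gp.1": -0.5, "gp.2": -0.5, "gn.1": -1}, bags, std, 0.0)
        assert out["gp.1"] is Label.POS and out["gp.2"] is Label.NEG

    def test_mi_matches_per_bag_oracle(self):
        rng = np.random.default_rng(5)
        bag_def, labels_true = {}, {}
        for g in range(50):
            k = int(rng.integers(1, 5))
            bag_def[f"g{g}"] = tuple(f"g{g}.{j}" for j in range(k))
        bags = BagMap(bag_def)
        pos = frozenset(g for g in bags.genes if rng.random() < 0.5)
        std = TermGoldStandard("t", pos, frozenset(set(bags.genes) - pos))
        scores = {i: float(rng.normal()) for i in bags.isoforms}
        thr = 0.3
        out = update_labels_mi(scores, bags, std, thr)
        for g in bags.genes:
            isos = bags[g]
            if g not in pos:
                assert all(out[i] is Label.NEG for i in isos)
            else:
                above = {i for i in isos if scores[i] > thr}
                if above:
                    expect = above
                else:
                    top = max(scores[i] for i in isos)
                    expect = {min(i for i in isos if scores[i] == top)}
                assert {i for i in isos if out[i] is Label.POS} == expect

    def test_MI_argmax_witness(self):
        bags = BagMap({"gp": ("a", "b", "c"), "gn": ("d",)})
        std = TermGoldStandard("t", frozenset({"gp"}), frozenset({"gn"}))
        out = update_labels_MI({"a": 0.9, "b": 0.1, "c": -0.2, "d": 0}, bags, std)
        assert out["a"] is Label.POS
        assert out["b"] is Label.NEUTRAL and out["c"] is Label.NEUTRAL
        assert out["d"] is Label.NEG

    def test_MI_single_isoform_forced(self):
        bags = BagMap({"gp": ("a",), "gn": ("d",)})
        std = TermGoldStandard("t", frozenset({"gp"}), frozenset({"gn"}))
        out = update_labels_MI({"a": -5.0, "d": 0}, bags, std)
        assert out["a"] is Label.POS

    def test_MI_random_witness_uniform(self):
        bags = BagMap({"gp": ("a", "b", "c"), "gn": ("d",)})
        std = TermGoldStandard("t", frozenset({"gp"}), frozenset({"gn"}))
        scores = {"a": 0.9, "b": 0.1, "c": -0.2, "d": 0}
        counts = {"a": 0, "b": 0, "c": 0}
        n = 10_000
        for seed in range(n):
            out = update_labels_MI(scores, bags, std, random_witness=True, seed=seed)
            (w,) = [i for i in ("a", "b", "c") if out[i] is Label.POS]
            counts[w] += 1
        for iso in counts:
            assert counts[iso] / n == pytest.approx(1 / 3, abs=0.02)


class TestConvergence:
    def test_fixed_point(self):
        a = lab({"x": "POS"})
        assert has_converged([a], lab({"x": "POS"}))

    def test_cycle_detected(self):
        a, b, c = lab({"x": "POS"}), lab({"x": "NEG"}), lab({"x": "NEUTRAL"})
        assert has_converged([a, b, c], lab({"x": "POS"}))

    def test_all_distinct_not_converged(self):
        a, b = lab({"x": "POS"}), lab({"x": "NEG"})
        assert not has_converged([a, b], lab({"x": "NEUTRAL"}))


class TestRunMil:
    def test_planted_witness_converges_fast(self, small_synth, fast_config):
        matrix, bags, std, _ = small_synth
        run = run_mil(matrix, bags, std, fast_config)
        assert run.converged
        assert run.n_iterations <= 10

    def test_single_isoform_bags_two_iterations(self):
        rng = np.random.default_rng(3)
        bags = BagMap({f"g{k}": (f"g{k}.1",) for k in range(10)})
        X = rng.normal(0, 1, (10, 4))
        X[:3] += 2.0
        mat = ExpressionMatrix(tuple(bags.isoforms), ("a", "b", "c", "d"), X, space="log2")
        std = TermGoldStandard(
            "t", frozenset({"g0", "g1", "g2"}),
            frozenset(f"g{k}" for k in range(3, 10)),
        )
        run = run_mil(mat, bags, std, MILConfig())
        assert run.converged
        assert run.n_iterations == 2

    def test_bag_constraint_after_run(self, small_synth, fast_config):
        matrix, bags, std, _ = small_synth
        run = run_mil(matrix, bags, std, fast_config)
        for g in bags.genes:
            if g in std.positives:
                assert any(run.labeling[i] is Label.POS for i in bags[g])
            else:
                assert all(run.labeling[i] is Label.NEG for i in bags[g])

    def test_determinism(self, small_synth, fast_config):
        matrix, bags, std, _ = small_synth
        r1 = run_mil(matrix, bags, std, fast_config)
        r2 = run_mil(matrix, bags, std, fast_config)
        assert r1.labeling == r2.labeling
        assert r1.model.decision_scores(matrix) == r2.model.decision_scores(matrix)

    def test_MI_exactly_one_witness_per_bag(self, small_synth):
        matrix, bags, std, _ = small_synth
        run = run_mil(matrix, bags, std, MILConfig(formulation="MI_svm"))
        for g in std.positives:
            n_pos = sum(run.labeling[i] is Label.POS for i in bags[g])
            n_neutral = sum(run.labeling[i] is Label.NEUTRAL for i in bags[g])
            assert n_pos == 1 and n_pos + n_neutral == len(bags[g])

    def test_no_positive_genes_refused(self):
        bags = BagMap({"g1": ("g1.1",), "g2": ("g2.1",)})
        mat = ExpressionMatrix(
            ("g1.1", "g2.1"), ("a",), np.zeros((2, 1)), space="log2"
        )
        std = TermGoldStandard("t", frozenset(), frozenset({"g1", "g2"}))
        with pytest.raises(ValueError, match="positive"):
            run_mil(mat, bags, std, MILConfig())

    def test_final_objective_not_worse_than_init(self, tiny_problem):
        matrix, bags, std = tiny_problem
        config = MILConfig(regularization_strength=1.0)
        init = initialize_labels(std, bags)
        m_init = train_margin_classifier(matrix, init, config)
        run = run_mil(matrix, bags, std, config)
        obj_init = svm_objective(m_init, matrix, init)
        obj_final = svm_objective(run.model, matrix, run.labeling)
        assert obj_final <= obj_init + 1e-6


class TestAggregateGeneScores:
    def test_max_rule(self):
        bags = BagMap({"g": ("a", "b"), "h": ("c",)})
        out = aggregate_gene_scores({"a": 0.1, "b": 0.9, "c": -1.0}, bags)
        assert out == {"g": 0.9, "h": -1.0}

    def test_unscored_isoform_errors(self):
        bags = BagMap({"g": ("a", "b")})
        with pytest.raises(KeyError, match="b"):
            aggregate_gene_scores({"a": 0.1}, bags)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(9)
        bag_def = {f"g{k}": tuple(f"g{k}.{j}" for j in range(int(rng.integers(1, 6))))
                   for k in range(100)}
        bags = BagMap(bag_def)
        scores = {i: float(rng.normal()) for i in bags.isoforms}
        out = aggregate_gene_scores(scores, bags)
        for g, isos in bag_def.items():
            best = -np.inf
            for i in isos:
                best = max(best, scores[i])
            assert out[g] == best
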