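import numpy as np
import pytest

from nbprog.core_io import LabelPair, OmicsMatrix
from nbprog.modeling import (
    BlockSpec,
    Combination,
    ExperimentPlan,
    MMoE,
    MmoeSpec,
    evaluate_multitask,
    intersect_feature_sets,
    run_experiment,
    train_mmoe,
    train_single_task,
)


class TestTrainSingleTask:
    def test_separable_data_trains_to_perfection(self, rng):
        X = np.vstack([rng.normal(size=(20, 2)) - 3, rng.normal(size=(20, 2)) + 3])
        y = np.array([0] * 20 + [1] * 20)
        model, scores = train_single_task(X, y, seed=0)
        assert (model.predict(X) == y).all()
        assert scores.shape == (40,)

    def test_same_seed_same_predictions(self, rng):
        X = rng.normal(size=(30, 3))
        y = rng.integers(0, 2, size=30)
        y[:2] = [0, 1]
        m1, s1 = train_single_task(X, y, seed=4)
        m2, s2 = train_single_task(X, y, seed=4)
        assert (s1 == s2).all()
        assert (m1.predict(X) == m2.predict(X)).all()

    def test_xor_pattern_fit_by_rbf_kernel(self, rng):
        base = rng.uniform(-1, 1, size=(200, 2))
        y = ((base[:, 0] > 0) ^ (base[:, 1] > 0)).astype(int)
        X = base + rng.normal(scale=0.05, size=base.shape)
        model, _ = train_single_task(X, y, seed=0)
        assert (model.predict(X) == y).mean() > 0.9

    def test_single_class_raises(self, rng):
        with pytest.raises(ValueError):
            train_single_task(rng.normal(size=(10, 2)), np.zeros(10, dtype=int))


class TestIntersectFeatureSets:
    def test_disjoint_empty(self):
        assert intersect_feature_sets(["a", "b"], ["c"]) == []

    def test_subset_returns_first_order(self):
        assert intersect_feature_sets(["b", "a"], ["a", "b", "c"]) == ["b", "a"]

    def test_multitask_widths_from_singletask_sets(self):
        # per-modality intersection of the two single-task selections gives
        # the multi-task input widths: clinical 1, gene 4, methylation 151
        surv_cli, vit_cli = [f"c{i}" for i in range(3)], ["c0"]
        surv_gene = [f"g{i}" for i in range(69)]
        vit_gene = [f"g{i}" for i in range(4)] + [f"h{i}" for i in range(51)]
        surv_meth = [f"m{i}" for i in range(250)]
        vit_meth = [f"m{i}" for i in range(151)] + [f"x{i}" for i in range(86)]
        assert len(intersect_feature_sets(surv_cli, vit_cli)) == 1
        assert len(intersect_feature_sets(surv_gene, vit_gene)) == 4
        assert len(intersect_feature_sets(surv_meth, vit_meth)) == 151


def _correlated_task_data(n=300, seed=0):
    from nbprog.synthetic import SynthConfig, generate

    return generate(SynthConfig(n_samples=n, seed=seed))


class TestMmoe:
    def test_gates_are_probability_vectors(self, rng):
        c = _correlated_task_data(seed=2)
        m = train_mmoe(c.expression, c.labels, MmoeSpec(seed=0, max_epochs=50))
        G = m.gate_weights(rng.normal(size=(17, c.expression.n_features)))
        assert G.shape[0] == 2 and G.shape[1] == 17
        assert np.allclose(G.sum(axis=2), 1.0)
        assert (G >= 0).all()

    def test_training_reduces_loss(self):
        c = _correlated_task_data(seed=3)
        m = train_mmoe(c.expression, c.labels, MmoeSpec(seed=0, max_epochs=100))
        h = m.history["train_loss"]
        assert h[-1] < h[0]

    def test_same_seed_identical_predictions(self):
        c = _correlated_task_data(n=120, seed=4)
        spec = MmoeSpec(seed=9, max_epochs=60)
        p1 = train_mmoe(c.expression, c.labels, spec).predict_proba(c.expression.values)
        p2 = train_mmoe(c.expression, c.labels, spec).predict_proba(c.expression.values)
        assert (p1 == p2).all()

    def test_probabilities_in_open_interval(self):
        c = _correlated_task_data(n=120, seed=5)
        m = train_mmoe(c.expression, c.labels, MmoeSpec(seed=0, max_epochs=40))
        p = m.predict_proba(c.expression.values)
        assert p.shape == (120, 2)
        assert (p > 0).all() and (p < 1).all()

    def test_single_expert_gate_degenerates_to_shared_bottom(self):
        # with one expert the softmax gate is identically 1 for both tasks:
        # the model is exactly a shared-bottom two-head network
        c = _correlated_task_data(n=120, seed=6)
        m = train_mmoe(c.expression, c.labels, MmoeSpec(n_experts=1, seed=0, max_epochs=40))
        G = m.gate_weights(c.expression.values)
        assert (G == 1.0).all()

    def test_divergent_lr_raises(self):
        c = _correlated_task_data(n=120, seed=7)
        with pytest.raises(ValueError, match="learning rate"):
            train_mmoe(c.expression, c.labels, MmoeSpec(seed=0, learning_rate=1e6,
                                                        max_epochs=200))

    def test_too_few_samples_raises(self, rng):
        lp = LabelPair(np.array([0, 1, 0, 1]), np.array([0, 1, 1, 0]))
        with pytest.raises(ValueError):
            MMoE(MmoeSpec(seed=0)).fit(rng.normal(size=(4, 3)),
                                       np.column_stack([lp.survival_label, lp.vital_label]))

    def test_gradients_match_finite_differences(self, rng):
        """Hand-written backprop against central finite differences."""
        spec = MmoeSpec(n_experts=2, expert_hidden=3, tower_hidden=2, seed=0)
        model = MMoE(spec)
        X = rng.normal(size=(12, 4))
        Y = rng.integers(0, 2, size=(12, 2)).astype(float)
        p = model._init_params(4, np.random.default_rng(1))
        cache = model._forward(X, p)
        grads = model._gradients(cache, Y, p)
        eps = 1e-6
        for key in ("We0", "Vg1", "Ut0", "uo1", "be1", "cg0", "dt1", "eo0"):
            flat = p[key].ravel()
            for idx in [0, flat.size // 2]:
                orig = flat[idx]
                flat[idx] = orig + eps
                lp_ = model._loss(model._forward(X, p), Y)
                flat[idx] = orig - eps
                lm = model._loss(model._forward(X, p), Y)
                flat[idx] = orig
                fd = (lp_ - lm) / (2 * eps)
                assert grads[key].ravel()[idx] == pytest.approx(fd, rel=1e-4, abs=1e-7)


class TestEvaluateMultitask:
    def test_report_structure_and_bounds(self):
        c = _correlated_task_data(n=120, seed=8)
        m = train_mmoe(c.expression, c.labels, MmoeSpec(seed=0, max_epochs=60))
        rep = evaluate_multitask(m, c.expression.values, c.labels)
        assert 0 <= rep["absolute_accuracy"] <= 1
        assert rep["absolute_accuracy"] <= min(rep["survival"]["acc"], rep["vital"]["acc"]) + 1e-12


class TestRunExperiment:
    def test_single_combination_single_split(self, small_cohort):
        plan = ExperimentPlan(
            combinations=(
                Combination("Cli", (BlockSpec("clinical"),)),
                Combination("Cli+G_FS", (BlockSpec("clinical"),
                                         BlockSpec("expression", "fisher", k=10))),
            ),
            seeds=(0,),
        )
        rep = run_experiment(
            small_cohort.clinical,
            {"expression": small_cohort.expression},
            small_cohort.labels,
            plan,
            task="survival",
        )
        assert set(rep) == {"Cli", "Cli+G_FS"}
        row = rep["Cli"]["splits"][0]
        assert set(row) == {"seed", "acc", "auc", "n_features"}
        # survival task: age + INSS one-hot (5) + MYCN one-hot (2) = 8 columns
        assert row["n_features"] == 8
        assert rep["Cli+G_FS"]["splits"][0]["n_features"] == 18

    def test_vital_task_uses_age_only(self, small_cohort):
        plan = ExperimentPlan(
            combinations=(Combination("Cli", (BlockSpec("clinical"),)),), seeds=(0,)
        )
        rep = run_experiment(
            small_cohort.clinical, {}, small_cohort.labels, plan, task="vital"
        )
        assert rep["Cli"]["splits"][0]["n_features"] == 1

    def test_results_deterministic_across_calls(self, small_cohort):
        plan = ExperimentPlan(
            combinations=(Combination("Cli", (BlockSpec("clinical"),)),), seeds=(1, 2)
        )
        args = (small_cohort.clinical, {}, small_cohort.labels, plan)
        assert run_experiment(*args, task="survival") == run_experiment(*args, task="survival")
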