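import numpy as np
import pytest

from hedlm import (
    DomainKnowledge,
    HeuristicBackend,
    NearestShotBackend,
    ScriptedBackend,
    SelectionConfig,
    TranscriptLogger,
    evaluate_all,
    macro_f1,
    make_user_split,
    run_distance_baseline,
    run_hedlm,
    run_ml_baseline,
    run_random_baseline,
)

from conftest import make_fv


def cluster_pool(rng, n=12, user_id="u1", spread=0.05):
    """Alternating-label pool with class-separated Gaussian clusters."""
    out = []
    for i in range(n):
        label = "fatigue" if i % 2 == 0 else "non_fatigue"
        center = 0.2 if label == "fatigue" else 0.8
        out.append(
            make_fv(f"i{i:02d}", rng.normal(center, spread, 30), label=label, user_id=user_id)
        )
    return out


class TestMacroF1:
    def test_perfect_and_hand_computed_values(self):
        assert macro_f1(["fatigue", "non_fatigue"], ["fatigue", "non_fatigue"]) == 1.0
        # everything predicted fatigue on a balanced truth of 2+2:
        # fatigue F1 = 2*1*0.5/1.5 = 2/3, non_fatigue F1 = 0 -> macro 1/3
        got = macro_f1(
            ["fatigue", "fatigue", "non_fatigue", "non_fatigue"], ["fatigue"] * 4
        )
        assert got == pytest.approx(1 / 3, abs=1e-12)
        # one error per class on 2+2 truth: both per-class F1 = 0.5
        got = macro_f1(
            ["fatigue", "fatigue", "non_fatigue", "non_fatigue"],
            ["fatigue", "non_fatigue", "non_fatigue", "fatigue"],
        )
        assert got == pytest.approx(0.5, abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            macro_f1(["fatigue"], [])
        with pytest.raises(ValueError):
            macro_f1([], [])


class TestUserSplit:
    def test_pair_has_one_instance_per_class_and_test_is_rest(self):
        pool = cluster_pool(np.random.default_rng(0), n=10)
        split = make_user_split(pool, seed=3)
        assert sorted(fv.label for fv in split.ml_train_pair) == ["fatigue", "non_fatigue"]
        assert len(split.test_set) == 8
        pair_ids = {fv.instance_id for fv in split.ml_train_pair}
        assert pair_ids.isdisjoint({fv.instance_id for fv in split.test_set})
        assert len(split.support_pool) == 10

    def test_seed_determinism_and_sensitivity(self):
        pool = cluster_pool(np.random.default_rng(0), n=20)
        ids = lambda s: tuple(fv.instance_id for fv in s.ml_train_pair)
        assert ids(make_user_split(pool, 5)) == ids(make_user_split(pool, 5))
        pairs = {ids(make_user_split(pool, s)) for s in range(10)}
        assert len(pairs) > 1  # different seeds pick different pairs

    def test_pool_for_excludes_only_the_query(self):
        pool = cluster_pool(np.random.default_rng(1), n=8)
        split = make_user_split(pool, seed=0)
        query = split.test_set[0]
        sub = split.pool_for(query)
        assert len(sub) == 7
        assert query.instance_id not in {fv.instance_id for fv in sub}

    def test_single_class_user_rejected(self):
        rng = np.random.default_rng(2)
        pool = [make_fv(f"i{i}", rng.normal(size=30), label="fatigue", user_id="u") for i in range(4)]
        with pytest.raises(ValueError, match="lacks"):
            make_user_split(pool, 0)

    def test_mixed_users_rejected(self):
        pool = cluster_pool(np.random.default_rng(3), n=4, user_id="a")
        pool += cluster_pool(np.random.default_rng(3), n=4, user_id="b")
        with pytest.raises(ValueError, match="user_id"):
            make_user_split(pool, 0)


class TestBaselines:
    dk = DomainKnowledge.default()

    def test_random_baseline_is_seed_deterministic(self):
        split = make_user_split(cluster_pool(np.random.default_rng(4), n=14), seed=1)
        backend = NearestShotBackend()
        r1 = run_random_baseline(split, backend, self.dk, seed=9)
        r2 = run_random_baseline(split, backend, self.dk, seed=9)
        assert r1.macro_f1 == r2.macro_f1
        assert [p.shot_ids for p in r1.predictions] == [p.shot_ids for p in r2.predictions]

    def test_distance_baseline_is_perfect_on_separated_clusters(self):
        split = make_user_split(cluster_pool(np.random.default_rng(5), n=14), seed=1)
        res = run_distance_baseline(split, NearestShotBackend(), self.dk)
        assert res.macro_f1 == 1.0
        # nearest neighbor of a clustered query shares its label
        for query, pred in zip(split.test_set, res.predictions):
            assert pred.label == query.label

    def test_ml_baseline_separable_toy(self):
        split = make_user_split(cluster_pool(np.random.default_rng(6), n=14), seed=2)
        res = run_ml_baseline(split, seed=2)
        assert res.method == "ml"
        assert res.macro_f1 == 1.0

    def test_ml_baseline_deterministic(self):
        split = make_user_split(cluster_pool(np.random.default_rng(7), n=10, spread=0.4), seed=0)
        assert run_ml_baseline(split, 0).macro_f1 == run_ml_baseline(split, 0).macro_f1


class TestHedlm:
    dk = DomainKnowledge.default()

    def test_constant_score_topk2_equals_distance_baseline(self):
        """With a constant scoring backend and top_k=2, re-ranking reduces to
        distance order, so shots match the distance baseline exactly."""
        split = make_user_split(cluster_pool(np.random.default_rng(8), n=14, spread=0.3), seed=1)
        backend = NearestShotBackend()
        scripted = ScriptedBackend(default="SCORE: 0.5\nREASON: constant")
        hed = run_hedlm(
            split, SelectionConfig(5, 2), backend, self.dk, scoring_backend=scripted
        )
        base = run_distance_baseline(split, backend, self.dk)
        assert [set(p.shot_ids) for p in hed.predictions] == [
            set(p.shot_ids) for p in base.predictions
        ]
        assert [p.label for p in hed.predictions] == [p.label for p in base.predictions]
        assert hed.macro_f1 == base.macro_f1

    def test_hedlm_perfect_on_separated_clusters(self):
        split = make_user_split(cluster_pool(np.random.default_rng(9), n=14), seed=1)
        res = run_hedlm(
            split, SelectionConfig(5, 3), NearestShotBackend(), self.dk,
            scoring_backend=HeuristicBackend(), method_name="hedlm_paramA",
        )
        assert res.method == "hedlm_paramA"
        assert res.macro_f1 == 1.0

    def test_transcript_count_is_tests_times_distance_k_plus_classifications(self):
        split = make_user_split(cluster_pool(np.random.default_rng(10), n=10), seed=1)
        log = TranscriptLogger()
        run_hedlm(
            split, SelectionConfig(5, 3), ScriptedBackend(default="fatigue"), self.dk,
            scoring_backend=ScriptedBackend(default="SCORE: 0.7"), transcript=log,
        )
        n_test = len(split.test_set)
        kinds = [r["kind"] for r in log.records]
        assert kinds.count("scoring") == n_test * 5
        assert kinds.count("classification") == n_test


class TestEvaluateAll:
    dk = DomainKnowledge.default()

    def _dataset(self, rng, n_users=3, n=10):
        return {
            f"u{k}": cluster_pool(rng, n=n, user_id=f"u{k}", spread=0.3)
            for k in range(n_users)
        }

    def test_table_shape_and_percent_scale(self):
        rng = np.random.default_rng(11)
        table = evaluate_all(
            self._dataset(rng),
            ("ml", "random", "distance", "hedlm_paramA"),
            backend=NearestShotBackend(),
            dk=self.dk,
            seed=3,
            scoring_backend=HeuristicBackend(),
        )
        assert table.values.shape == (3, 4)
        assert table.users == ("u0", "u1", "u2")
        assert np.all(table.values >= 0) and np.all(table.values <= 100)

    def test_single_class_user_skipped_with_warning(self):
        rng = np.random.default_rng(12)
        dataset = self._dataset(rng, n_users=2)
        dataset["bad"] = [
            make_fv(f"i{i}", rng.normal(size=30), label="fatigue", user_id="bad")
            for i in range(6)
        ]
        with pytest.warns(UserWarning, match="bad"):
            table = evaluate_all(
                dataset, ("ml", "distance"), backend=NearestShotBackend(),
                dk=self.dk, seed=0,
            )
        assert "bad" not in table.users and len(table.users) == 2

    def test_unknown_method_rejected(self):
        rng = np.random.default_rng(13)
        with pytest.raises(ValueError, match="unknown method"):
            evaluate_all(
                self._dataset(rng, n_users=1), ("oracle",),
                backend=NearestShotBackend(), dk=self.dk, seed=0,
            )

    def test_repeat_run_is_bitwise_identical(self):
        rng1, rng2 = np.random.default_rng(14), np.random.default_rng(14)
        kwargs = dict(
            methods=("ml", "random", "distance", "hedlm_paramA", "hedlm_paramB"),
            backend=NearestShotBackend(), dk=self.dk, seed=5,
            scoring_backend=HeuristicBackend(),
        )
        t1 = evaluate_all(self._dataset(rng1), **kwargs)
        t2 = evaluate_all(self._dataset(rng2), **kwargs)
        assert np.array_equal(t1.values, t2.values)
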