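import numpy as np
import pytest

from hedlm import (
    Candidate,
    DomainKnowledge,
    HeuristicBackend,
    NearestShotBackend,
    RelevanceScore,
    ScoredCandidate,
    ScriptedBackend,
    SelectionConfig,
    ShotPair,
    TranscriptLogger,
    build_classification_prompt,
    parse_label_reply,
    pick_shots,
    predict,
    rerank_top_k,
)

from conftest import make_fv


def sc(instance_id, score, label="fatigue", distance=1.0, values=None, user_id="u"):
    fv = make_fv(instance_id, np.full(30, 0.4) if values is None else values,
                 label=label, user_id=user_id)
    return ScoredCandidate(
        candidate=Candidate(ref=fv, distance=distance),
        score=RelevanceScore(score, reason=f"reason-{instance_id}"),
    )


@pytest.fixture
def mixed_shots():
    return ShotPair(shot1=sc("s1", 0.9, "fatigue"), shot2=sc("s2", 0.6, "non_fatigue"))


class TestRerank:
    def test_keeps_highest_scores(self):
        scored = [sc("a", 0.2), sc("b", 0.9), sc("c", 0.5), sc("d", 0.7)]
        top = rerank_top_k(scored, 3)
        assert [s.candidate.ref.instance_id for s in top] == ["b", "d", "c"]

    def test_score_ties_break_toward_smaller_distance(self):
        scored = [sc("far", 0.5, distance=3.0), sc("near", 0.5, distance=1.0)]
        top = rerank_top_k(scored, 1)
        assert top[0].candidate.ref.instance_id == "near"

    def test_full_tie_breaks_by_identifier(self):
        scored = [sc("b", 0.5), sc("a", 0.5)]
        assert [s.candidate.ref.instance_id for s in rerank_top_k(scored, 2)] == ["a", "b"]

    def test_k_larger_than_pool_and_invalid_k(self):
        scored = [sc("a", 0.2)]
        assert len(rerank_top_k(scored, 5)) == 1
        with pytest.raises(ValueError):
            rerank_top_k(scored, 0)
        with pytest.raises(ValueError):
            rerank_top_k([], 2)


class TestPickShots:
    def test_balanced_when_both_labels_present(self):
        top = [
            sc("f1", 0.9, "fatigue"),
            sc("f2", 0.8, "fatigue"),
            sc("n1", 0.3, "non_fatigue"),
        ]
        shots = pick_shots(top)
        assert set(shots.labels) == {"fatigue", "non_fatigue"}
        assert shots.instance_ids == ("f1", "n1")

    def test_single_label_takes_two_best(self):
        top = [sc("f1", 0.9), sc("f2", 0.8), sc("f3", 0.1)]
        shots = pick_shots(top)
        assert shots.instance_ids == ("f1", "f2")
        assert shots.labels == ("fatigue", "fatigue")

    def test_shot1_always_higher_scored(self):
        top = [sc("n1", 0.95, "non_fatigue"), sc("f1", 0.2, "fatigue")]
        shots = pick_shots(top)
        assert shots.shot1.score.value >= shots.shot2.score.value
        assert shots.shot1.candidate.ref.instance_id == "n1"

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            pick_shots([sc("only", 0.5)])

    def test_duplicate_instances_rejected(self):
        with pytest.raises(ValueError):
            ShotPair(shot1=sc("same", 0.9), shot2=sc("same", 0.1))


class TestClassificationPrompt:
    def test_contains_both_examples_query_and_instruction(self, mixed_shots):
        query = make_fv("q", np.linspace(0.0, 1.0, 30))
        prompt = build_classification_prompt(mixed_shots, query)
        assert "Example 1:" in prompt and "Example 2:" in prompt
        assert "Conclusion: The label is fatigue" in prompt
        assert "Conclusion: The label is non-fatigue" in prompt
        assert "Relevance score: 0.9000" in prompt
        assert "Relevance score: 0.6000" in prompt
        assert "reason-s1" in prompt and "reason-s2" in prompt
        assert "New data (unlabeled)" in prompt
        assert "single word" in prompt

    def test_query_numbers_round_trip_at_4_decimals(self):
        rng = np.random.default_rng(12)
        values = rng.uniform(0, 1, 30)
        query = make_fv("q", values)
        shots = ShotPair(shot1=sc("s1", 0.9), shot2=sc("s2", 0.6, "non_fatigue"))
        prompt = build_classification_prompt(shots, query)
        query_block = prompt.split("New data (unlabeled):")[1].split("\n\n")[0]
        rendered = [
            float(tok.split("=")[1])
            for line in query_block.strip().splitlines()
            for tok in line.split(": ", 1)[1].split(", ")
        ]
        assert np.allclose(rendered, values, atol=1e-4 / 2 + 1e-12)


class TestParseLabelReply:
    def test_direct_tokens(self, mixed_shots):
        for text, label in [
            ("fatigue", "fatigue"),
            ("Non-fatigue", "non_fatigue"),
            (" non fatigue.", "non_fatigue"),
            ("NONFATIGUE", "non_fatigue"),
            ("'fatigue'", "fatigue"),
        ]:
            p = parse_label_reply(text, mixed_shots)
            assert (p.label, p.resolution) == (label, "direct")

    def test_frequency_fallback_counts_without_double_counting(self, mixed_shots):
        # "non-fatigue" contains "fatigue"; it must be consumed first
        p = parse_label_reply(
            "The data resembles non-fatigue; Example 2 is also non-fatigue, "
            "though Example 1 shows fatigue.",
            mixed_shots,
        )
        assert p.label == "non_fatigue" and p.resolution == "frequency_fallback"

    def test_fatigue_majority(self, mixed_shots):
        p = parse_label_reply(
            "fatigue is likely: the pattern matches fatigue, not non-fatigue",
            mixed_shots,
        )
        assert p.label == "fatigue" and p.resolution == "frequency_fallback"

    def test_tie_and_empty_resolve_to_higher_scored_shot(self, mixed_shots):
        assert mixed_shots.shot1.candidate.ref.label == "fatigue"
        for text in ("", "I cannot decide", "fatigue vs non-fatigue"):
            p = parse_label_reply(text, mixed_shots)
            assert p.label == "fatigue" and p.resolution == "tie_rule"

    def test_shot_ids_recorded(self, mixed_shots):
        p = parse_label_reply("fatigue", mixed_shots)
        assert p.shot_ids == ("s1", "s2")


class TestNearestShotBackend:
    def test_answers_with_nearer_shots_label(self):
        query = make_fv("q", np.zeros(30))
        near = sc("near", 0.5, "non_fatigue", distance=0.1, values=np.full(30, 0.1))
        far = sc("far", 0.9, "fatigue", distance=3.0, values=np.full(30, 3.0))
        shots = ShotPair(shot1=far, shot2=near)
        assert NearestShotBackend().classify_pair(shots, query) == "non-fatigue"

    def test_tie_goes_to_shot1(self):
        query = make_fv("q", np.zeros(30))
        a = sc("a", 0.9, "fatigue", values=np.eye(30)[0])
        b = sc("b", 0.5, "non_fatigue", values=-np.eye(30)[0])
        assert NearestShotBackend().classify_pair(ShotPair(a, b), query) == "fatigue"


class TestPredict:
    def _pool(self, rng, n=8, user_id="u"):
        pool = []
        for i in range(n):
            label = "fatigue" if i % 2 == 0 else "non_fatigue"
            center = 0.2 if label == "fatigue" else 0.8
            pool.append(
                make_fv(f"p{i}", rng.normal(center, 0.05, 30), label=label, user_id=user_id)
            )
        return pool

    def test_end_to_end_with_scripted_constant_backend(self):
        rng = np.random.default_rng(21)
        pool = self._pool(rng)
        query = make_fv("q", rng.normal(0.2, 0.05, 30), user_id="u")
        backend = ScriptedBackend(default="fatigue")
        log = TranscriptLogger()
        pred = predict(
            query, pool, SelectionConfig(5, 3), backend,
            DomainKnowledge.default(), scoring_backend=ScriptedBackend(default="SCORE: 0.7"),
            transcript=log,
        )
        assert pred.label == "fatigue" and pred.resolution == "direct"
        # 5 scoring transcripts + 1 classification transcript
        kinds = [r["kind"] for r in log.records]
        assert kinds.count("scoring") == 5 and kinds.count("classification") == 1

    def test_nearest_shot_backend_predicts_matching_cluster(self):
        rng = np.random.default_rng(22)
        pool = self._pool(rng, n=10)
        for center, expected in [(0.2, "fatigue"), (0.8, "non_fatigue")]:
            query = make_fv("q", rng.normal(center, 0.05, 30), user_id="u")
            pred = predict(
                query, pool, SelectionConfig(5, 3), NearestShotBackend(),
                DomainKnowledge.default(), scoring_backend=HeuristicBackend(),
            )
            assert pred.label == expected

    def test_pool_of_two_and_top_k_one_still_yields_two_shots(self):
        rng = np.random.default_rng(23)
        pool = [
            make_fv("a", rng.normal(0.2, 0.05, 30), label="fatigue", user_id="u"),
            make_fv("b", rng.normal(0.8, 0.05, 30), label="non_fatigue", user_id="u"),
        ]
        query = make_fv("q", rng.normal(0.2, 0.05, 30), user_id="u")
        pred = predict(
            query, pool, SelectionConfig(2, 1), NearestShotBackend(),
            DomainKnowledge.default(), scoring_backend=HeuristicBackend(),
        )
        assert set(pred.shot_ids) == {"a", "b"}
        assert pred.label == "fatigue"

    def test_query_in_pool_is_leakage_error(self):
        rng = np.random.default_rng(24)
        pool = self._pool(rng)
        query = pool[0]
        with pytest.raises(ValueError, match="leakage"):
            predict(
                query, pool, SelectionConfig(5, 3), NearestShotBackend(),
                DomainKnowledge.default(),
            )

    def test_deterministic_across_repeats(self):
        rng = np.random.default_rng(25)
        pool = self._pool(rng, n=12)
        query = make_fv("q", rng.normal(0.5, 0.3, 30), user_id="u")
        preds = [
            predict(
                query, pool, SelectionConfig(10, 5), NearestShotBackend(),
                DomainKnowledge.default(), scoring_backend=HeuristicBackend(),
            )
            for _ in range(3)
        ]
        assert len({(p.label, p.shot_ids) for p in preds}) == 1
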