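"""Per-user, leakage-free evaluation of example-selection strategies.

Every experiment runs on one user's data in isolation. Two instances (one
per class, seeded) are set aside as the machine-learning baseline's
training pair; all remaining instances form the test set, which is reused
unchanged by every method. For each test instance the prompt-based methods
draw their support examples from all of that user's other instances — the
test instance itself is never selectable (asserted on every prediction).

Methods compared (mirroring the published protocol):

* ``ml`` — Random Forest (100 trees, random_state=42) trained on the
  2-example pair, fully offline;
* ``random`` — 2 support examples sampled uniformly without replacement;
* ``distance`` — the 2 Euclidean-nearest pool members as shots;
* ``hedlm_paramA`` / ``hedlm_paramB`` — the full hybrid pipeline with the
  (distance_k=5, top_k=3) and (10, 5) presets.

All methods are scored with macro F1 over the two classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score

from .inference import (
    Prediction,
    ShotPair,
    build_classification_prompt,
    parse_label_reply,
    predict,
)
from .preprocessing import FATIGUE, LABELS, NON_FATIGUE, FeatureVector
from .scoring import (
    DomainKnowledge,
    LLMBackend,
    RelevanceScore,
    ScoredCandidate,
    TranscriptLogger,
)
from .selection import Candidate, SelectionConfig, euclidean_distance, nearest_candidates
from .stats import MethodScoreTable

__all__ = [
    "UserSplit",
    "MethodResult",
    "make_user_split",
    "macro_f1",
    "run_random_baseline",
    "run_distance_baseline",
    "run_ml_baseline",
    "run_hedlm",
    "evaluate_all",
    "DEFAULT_METHODS",
]

DEFAULT_METHODS = ("ml", "random", "distance", "hedlm_paramA", "hedlm_paramB")


@dataclass(frozen=True)
class UserSplit:
    """One user's instances partitioned for the shared evaluation protocol."""

    user_id: str
    support_pool: tuple[FeatureVector, ...]  # every instance of the user
    test_set: tuple[FeatureVector, ...]  # support_pool minus the ML train pair
    ml_train_pair: tuple[FeatureVector, ...]

    def pool_for(self, test_fv: FeatureVector) -> list[FeatureVector]:
        """Selectable support examples for one test instance (leakage-free)."""
        return [
            fv
            for fv in self.support_pool
            if (fv.user_id, fv.instance_id) != (test_fv.user_id, test_fv.instance_id)
        ]


@dataclass(frozen=True)
class MethodResult:
    method: str
    user_id: str
    macro_f1: float
    predictions: tuple = ()


def make_user_split(instances: Sequence[FeatureVector], seed: int) -> UserSplit:
    """Seeded split: first fatigue + first non-fatigue instance after a
    shuffle become the ML training pair; the rest are the shared test set."""
    if not instances:
        raise ValueError("no instances for user split")
    user_id = instances[0].user_id
    for fv in instances:
        if fv.user_id != user_id:
            raise ValueError("all instances in a split must share one user_id")
        if fv.label is None:
            raise ValueError("evaluation instances must be labeled")
    labels = {fv.label for fv in instances}
    if labels != set(LABELS):
        raise ValueError(f"user {user_id} lacks one of the classes: has {labels}")
    rng = np.random.default_rng(seed)
    order = list(instances)
    rng.shuffle(order)
    first = {}
    for fv in order:
        first.setdefault(fv.label, fv)
    pair = (first[FATIGUE], first[NON_FATIGUE])
    pair_ids = {(fv.user_id, fv.instance_id) for fv in pair}
    test = tuple(
        fv for fv in instances if (fv.user_id, fv.instance_id) not in pair_ids
    )
    if not test:
        raise ValueError(f"user {user_id} has no instances left for testing")
    return UserSplit(
        user_id=user_id,
        support_pool=tuple(instances),
        test_set=test,
        ml_train_pair=pair,
    )


def macro_f1(truth: Sequence[str], pred: Sequence[str]) -> float:
    """Unweighted mean of the two per-class F1 scores.

    Both classes always enter the average; a class with zero
    precision+recall contributes an F1 of 0.
    """
    if len(truth) != len(pred):
        raise ValueError(f"length mismatch: {len(truth)} vs {len(pred)}")
    if len(truth) == 0:
        raise ValueError("need at least one prediction")
    return float(
        f1_score(list(truth), list(pred), labels=list(LABELS), average="macro", zero_division=0)
    )


def _neutral_shot(fv: FeatureVector, query: FeatureVector, reason: str) -> ScoredCandidate:
    return ScoredCandidate(
        candidate=Candidate(ref=fv, distance=euclidean_distance(query, fv)),
        score=RelevanceScore(0.5, reason=reason),
    )


def _assert_no_leakage(shots: ShotPair, query: FeatureVector) -> None:
    if query.instance_id in shots.instance_ids:
        raise AssertionError(
            f"leakage: test instance {query.instance_id} selected as its own shot"
        )


def _classify(
    shots: ShotPair,
    query: FeatureVector,
    backend: LLMBackend,
    transcript: Optional[TranscriptLogger],
    kind: str,
) -> Prediction:
    _assert_no_leakage(shots, query)
    prompt = build_classification_prompt(shots, query)
    if hasattr(backend, "classify_pair"):
        reply = backend.classify_pair(shots, query)
    else:
        reply = backend.complete(prompt)
    prediction = parse_label_reply(reply, shots)
    if transcript is not None:
        transcript.log(
            kind=kind,
            query_id=query.instance_id,
            candidate_id=None,
            prompt=prompt,
            reply=reply,
            score=None,
            status=prediction.resolution,
        )
    return prediction


def run_random_baseline(
    split: UserSplit,
    backend: LLMBackend,
    dk: DomainKnowledge,
    seed: int,
    transcript: Optional[TranscriptLogger] = None,
) -> MethodResult:
    """2 support examples drawn uniformly without replacement per test instance."""
    rng = np.random.default_rng(seed)
    preds: list[Prediction] = []
    for query in split.test_set:
        pool = split.pool_for(query)
        if len(pool) < 2:
            raise ValueError("support pool smaller than 2")
        idx = rng.choice(len(pool), size=2, replace=False)
        shots = ShotPair(
            shot1=_neutral_shot(pool[idx[0]], query, "random selection"),
            shot2=_neutral_shot(pool[idx[1]], query, "random selection"),
        )
        preds.append(_classify(shots, query, backend, transcript, "random"))
    truth = [fv.label for fv in split.test_set]
    return MethodResult(
        "random", split.user_id, macro_f1(truth, [p.label for p in preds]), tuple(preds)
    )


def run_distance_baseline(
    split: UserSplit,
    backend: LLMBackend,
    dk: DomainKnowledge,
    transcript: Optional[TranscriptLogger] = None,
) -> MethodResult:
    """The 2 Euclidean-nearest pool members become the shots (no scoring)."""
    preds: list[Prediction] = []
    for query in split.test_set:
        pool = split.pool_for(query)
        if len(pool) < 2:
            raise ValueError("support pool smaller than 2")
        near = nearest_candidates(query, pool, 2)
        shots = ShotPair(
            shot1=_neutral_shot(near[0].ref, query, "nearest neighbor"),
            shot2=_neutral_shot(near[1].ref, query, "second nearest neighbor"),
        )
        preds.append(_classify(shots, query, backend, transcript, "distance"))
    truth = [fv.label for fv in split.test_set]
    return MethodResult(
        "distance", split.user_id, macro_f1(truth, [p.label for p in preds]), tuple(preds)
    )


def run_ml_baseline(split: UserSplit, seed: int) -> MethodResult:
    """Random Forest trained on the seeded 2-example pair, tested on the rest.

    ``seed`` fixes the train-pair selection (via :func:`make_user_split`
    upstream); the forest itself uses the protocol's fixed random_state=42.
    """
    X_train = np.vstack([fv.values for fv in split.ml_train_pair])
    y_train = [fv.label for fv in split.ml_train_pair]
    if len(set(y_train)) < 2:
        raise ValueError("ML baseline needs one training example per class")
    clf = RandomForestClassifier(n_estimators=100, random_state=42)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # 2-sample fits can warn about class counts
        clf.fit(X_train, y_train)
    X_test = np.vstack([fv.values for fv in split.test_set])
    pred = list(clf.predict(X_test))
    truth = [fv.label for fv in split.test_set]
    return MethodResult("ml", split.user_id, macro_f1(truth, pred))


def run_hedlm(
    split: UserSplit,
    cfg: SelectionConfig,
    backend: LLMBackend,
    dk: DomainKnowledge,
    scoring_backend: Optional[LLMBackend] = None,
    transcript: Optional[TranscriptLogger] = None,
    method_name: str = "hedlm",
) -> MethodResult:
    """Full hybrid pipeline per test instance with the given preset."""
    preds: list[Prediction] = []
    for query in split.test_set:
        pool = split.pool_for(query)
        if len(pool) < 2:
            raise ValueError("support pool smaller than 2")
        pred = predict(
            query,
            pool,
            cfg,
            backend,
            dk,
            scoring_backend=scoring_backend,
            transcript=transcript,
        )
        if query.instance_id in pred.shot_ids:
            raise AssertionError(
                f"leakage: test instance {query.instance_id} among its shots"
            )
        preds.append(pred)
    truth = [fv.label for fv in split.test_set]
    return MethodResult(
        method_name,
        split.user_id,
        macro_f1(truth, [p.label for p in preds]),
        tuple(preds),
    )


def evaluate_all(
    dataset: dict[str, Sequence[FeatureVector]],
    methods: Sequence[str],
    backend: LLMBackend,
    dk: DomainKnowledge,
    seed: int,
    presets: Optional[dict[str, SelectionConfig]] = None,
    scoring_backend: Optional[LLMBackend] = None,
    transcript: Optional[TranscriptLogger] = None,
) -> MethodScoreTable:
    """Per-user x per-method macro-F1 matrix.

    ``dataset`` maps user_id to that user's labeled feature vectors. Users
    lacking either class are skipped with a warning. ``methods`` entries of
    the form ``hedlm_<preset>`` use ``presets`` (defaulting to the built-in
    paramA/paramB table).
    """
    from .selection import PRESETS  # local import to keep module deps one-way

    presets = dict(PRESETS) if presets is None else presets
    rows: list[list[float]] = []
    users: list[str] = []
    for user_id in sorted(dataset, key=str):
        instances = list(dataset[user_id])
        labels = {fv.label for fv in instances}
        if labels != set(LABELS):
            warnings.warn(f"user {user_id} lacks both classes; skipped")
            continue
        split = make_user_split(instances, seed)
        row: list[float] = []
        for method in methods:
            if method == "ml":
                res = run_ml_baseline(split, seed)
            elif method == "random":
                res = run_random_baseline(split, backend, dk, seed, transcript)
            elif method == "distance":
                res = run_distance_baseline(split, backend, dk, transcript)
            elif method.startswith("hedlm"):
                preset_name = method.split("_", 1)[1] if "_" in method else "paramA"
                cfg = presets[preset_name]
                res = run_hedlm(
                    split,
                    cfg,
                    backend,
                    dk,
                    scoring_backend=scoring_backend,
                    transcript=transcript,
                    method_name=method,
                )
            else:
                raise ValueError(f"unknown method {method!r}")
            row.append(res.macro_f1 * 100.0)
        users.append(str(user_id))
        rows.append(row)
    if not users:
        raise ValueError("no user with both classes present")
    return MethodScoreTable(
        users=tuple(users), methods=tuple(methods), values=np.array(rows)
    )
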