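"""Re-ranking, shot selection, prompt assembly and label prediction.

After relevance scoring, candidates are re-ranked by score, the top-K kept,
and a label-balanced 2-shot pair chosen (one fatigue + one non-fatigue
example whenever both labels are present; otherwise the two highest-scored
overall). The classification prompt presents each shot's per-segment
numeric summary, its relevance score and reason, and a label conclusion,
then the query's numbers and an instruction to answer with a single word.
Reply parsing is total: clean single-token answers map directly, anything
ambiguous falls back to counting label mentions ("non-fatigue" is counted
first and consumed so its "fatigue" substring is not double-counted), and
count ties resolve to the higher-scored shot's label.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .preprocessing import FATIGUE, NON_FATIGUE, SEGMENT_FEATURE_NAMES, FeatureVector
from .scoring import (
    DomainKnowledge,
    LLMBackend,
    ScoredCandidate,
    TranscriptLogger,
    score_candidates,
)
from .selection import SelectionConfig, euclidean_distance, nearest_candidates

__all__ = [
    "ShotPair",
    "Prediction",
    "NearestShotBackend",
    "rerank_top_k",
    "pick_shots",
    "build_classification_prompt",
    "parse_label_reply",
    "predict",
]

DIRECT = "direct"
FREQUENCY_FALLBACK = "frequency_fallback"
TIE_RULE = "tie_rule"


@dataclass(frozen=True)
class ShotPair:
    """The two support examples embedded in the classification prompt.

    ``shot1`` carries the higher (or equal) relevance score and is rendered
    first.
    """

    shot1: ScoredCandidate
    shot2: ScoredCandidate

    def __post_init__(self) -> None:
        a, b = self.shot1.candidate.ref, self.shot2.candidate.ref
        if (a.user_id, a.instance_id) == (b.user_id, b.instance_id):
            raise ValueError("the two shots must be distinct instances")

    def __iter__(self):
        return iter((self.shot1, self.shot2))

    @property
    def labels(self) -> tuple[str, str]:
        return (self.shot1.candidate.ref.label, self.shot2.candidate.ref.label)

    @property
    def instance_ids(self) -> tuple[str, str]:
        return (
            self.shot1.candidate.ref.instance_id,
            self.shot2.candidate.ref.instance_id,
        )


@dataclass(frozen=True)
class Prediction:
    label: str
    raw_reply: str
    resolution: str
    shot_ids: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        if self.label not in (FATIGUE, NON_FATIGUE):
            raise ValueError(f"invalid predicted label {self.label!r}")
        if self.resolution not in (DIRECT, FREQUENCY_FALLBACK, TIE_RULE):
            raise ValueError(f"invalid resolution {self.resolution!r}")


def _rank_key(sc: ScoredCandidate):
    # descending score, then ascending distance, then identifiers
    return (
        -sc.score.value,
        sc.candidate.distance,
        str(sc.candidate.ref.user_id),
        str(sc.candidate.ref.instance_id),
    )


def rerank_top_k(
    scored: Sequence[ScoredCandidate], top_k: int
) -> list[ScoredCandidate]:
    """Keep the ``min(top_k, n)`` candidates with the highest relevance.

    Ties on score break toward the smaller Euclidean distance, then
    identifiers, so the ordering is deterministic.
    """
    if not scored:
        raise ValueError("no scored candidates to re-rank")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    return sorted(scored, key=_rank_key)[:top_k]


def pick_shots(top: Sequence[ScoredCandidate]) -> ShotPair:
    """Label-balanced 2-shot selection from the re-ranked top-K.

    When both labels appear among the top-K, take the best-scored example
    of each class; otherwise take the two best-scored overall. The
    higher-scored shot is always rendered first.
    """
    if len(top) < 2:
        raise ValueError(f"need at least 2 candidates to build shots, got {len(top)}")
    ranked = sorted(top, key=_rank_key)
    by_label: dict[str, ScoredCandidate] = {}
    for sc in ranked:
        by_label.setdefault(sc.candidate.ref.label, sc)
    if len(by_label) == 2:
        pair = sorted(by_label.values(), key=_rank_key)
    else:
        pair = ranked[:2]
    return ShotPair(shot1=pair[0], shot2=pair[1])


def _render_segments(fv: FeatureVector, title: str) -> str:
    n = len(SEGMENT_FEATURE_NAMES)
    lines = [f"{title}:"]
    for seg in range(1, len(fv) // n + 1):
        parts = ", ".join(
            f"{name}={fv.segment_feature(seg, name):.4f}"
            for name in SEGMENT_FEATURE_NAMES
        )
        lines.append(f"  Segment {seg}: {parts}")
    return "\n".join(lines)


def build_classification_prompt(shots: ShotPair, query: FeatureVector) -> str:
    """2-shot classification prompt: two example blocks then the new data."""
    blocks = [
        "You classify accelerometer-magnitude instances as fatigue or "
        "non-fatigue from per-segment numeric features."
    ]
    for idx, sc in enumerate(shots, start=1):
        label = sc.candidate.ref.label.replace("_", "-")
        blocks.append(
            "\n".join(
                [
                    f"Example {idx}:",
                    _render_segments(sc.candidate.ref, "Numeric data summary"),
                    f"Relevance score: {sc.score.value:.4f}",
                    f"Reason: {sc.score.reason or 'n/a'}",
                    f"Conclusion: The label is {label}",
                ]
            )
        )
    blocks.append(_render_segments(query, "New data (unlabeled)"))
    blocks.append(
        "Please compare the new data with Example 1 and Example 2 and "
        "determine the final label: 'fatigue' or 'non-fatigue'. Answer with "
        "that single word only."
    )
    return "\n\n".join(blocks)


_NON_FATIGUE_RE = re.compile(r"non[\s_-]?fatigue", re.IGNORECASE)
_FATIGUE_RE = re.compile(r"fatigue", re.IGNORECASE)


def parse_label_reply(reply_text: str, shots: ShotPair) -> Prediction:
    """Total reply parser with frequency fallback and shot-based tie rule.

    A reply that normalizes to exactly one label maps directly. Otherwise
    non-overlapping "non-fatigue" mentions are counted and consumed first,
    then remaining "fatigue" mentions; the more frequent label wins, and a
    tie (including zero mentions) resolves to the label of the
    higher-relevance shot.
    """
    text = reply_text or ""
    token = text.strip().strip(".!?'\"").lower().replace("-", "_").replace(" ", "_")
    if token == FATIGUE:
        return Prediction(FATIGUE, text, DIRECT, shots.instance_ids)
    if token in (NON_FATIGUE, "nonfatigue"):
        return Prediction(NON_FATIGUE, text, DIRECT, shots.instance_ids)

    n_non = len(_NON_FATIGUE_RE.findall(text))
    remainder = _NON_FATIGUE_RE.sub(" ", text)
    n_fat = len(_FATIGUE_RE.findall(remainder))
    if n_non > n_fat:
        return Prediction(NON_FATIGUE, text, FREQUENCY_FALLBACK, shots.instance_ids)
    if n_fat > n_non:
        return Prediction(FATIGUE, text, FREQUENCY_FALLBACK, shots.instance_ids)
    return Prediction(
        shots.shot1.candidate.ref.label, text, TIE_RULE, shots.instance_ids
    )


class NearestShotBackend(LLMBackend):
    """Deterministic mock predictor: answers with the nearer shot's label.

    Distances are measured between feature vectors, so better example
    selection measurably improves accuracy — the closed loop used by the
    offline end-to-end experiments. Ties go to the first (higher-scored)
    shot.
    """

    model_name = "nearest-shot"

    def classify_pair(self, shots: ShotPair, query: FeatureVector) -> str:
        d1 = euclidean_distance(shots.shot1.candidate.ref, query)
        d2 = euclidean_distance(shots.shot2.candidate.ref, query)
        winner = shots.shot1 if d1 <= d2 else shots.shot2
        return winner.candidate.ref.label.replace("_", "-")

    def complete(self, prompt_text: str) -> str:
        raise NotImplementedError(
            "NearestShotBackend classifies feature pairs directly"
        )


def predict(
    query: FeatureVector,
    pool: Sequence[FeatureVector],
    cfg: SelectionConfig,
    backend: LLMBackend,
    dk: DomainKnowledge,
    scoring_backend: Optional[LLMBackend] = None,
    transcript: Optional[TranscriptLogger] = None,
) -> Prediction:
    """Full selection + inference loop for one query.

    distance filter -> relevance scoring (``scoring_backend``, defaulting
    to ``backend``) -> top-K re-rank -> label-balanced shots ->
    classification prompt -> ``backend`` -> total label parsing. The pool
    must exclude the query's own instance.
    """
    for fv in pool:
        if (fv.user_id, fv.instance_id) == (query.user_id, query.instance_id):
            raise ValueError(
                f"pool contains the query instance {query.user_id}/"
                f"{query.instance_id} (leakage)"
            )
    scoring_backend = scoring_backend if scoring_backend is not None else backend
    candidates = nearest_candidates(query, pool, cfg.distance_k)
    scored = score_candidates(candidates, query, scoring_backend, dk, transcript)
    top = rerank_top_k(scored, cfg.top_k)
    if len(top) < 2:  # top_k=1 or a single candidate: pad from remaining scored
        top = rerank_top_k(scored, 2)
    shots = pick_shots(top)
    prompt = build_classification_prompt(shots, query)
    if hasattr(backend, "classify_pair"):
        reply = backend.classify_pair(shots, query)
    else:
        reply = backend.complete(prompt)
    prediction = parse_label_reply(reply, shots)
    if transcript is not None:
        transcript.log(
            kind="classification",
            query_id=query.instance_id,
            candidate_id=None,
            prompt=prompt,
            reply=reply,
            score=None,
            status=prediction.resolution,
        )
    return prediction
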