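"""Contextual relevance scoring of distance-filtered candidates.

Each candidate surviving the Euclidean filter is scored in [0, 1] for how
well it would serve as a prompt example for the query: high numeric
similarity AND a label that fits the query's signal pattern ("label
synergy"). Scoring is delegated to a pluggable backend:

* :class:`APIBackend` — a remote OpenAI-compatible chat model, prompted
  with a structured comparison template and parsed via ``SCORE:``/
  ``REASON:`` markers;
* :class:`ScriptedBackend` — a fixed prompt->reply map for replay tests;
* :class:`HeuristicBackend` — a deterministic rule scorer combining an
  exponential distance similarity term with a domain-knowledge synergy
  term, for fully offline operation.

Domain knowledge is a small set of threshold rules over segment features
(e.g. high late-segment RMS, or low segment mean, suggest fatigue) that is
rendered into scoring prompts and drives the heuristic synergy term.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
import os
import re
import urllib.request
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .preprocessing import FATIGUE, NON_FATIGUE, SEGMENT_FEATURE_NAMES, FeatureVector
from .selection import Candidate

__all__ = [
    "DomainRule",
    "DomainKnowledge",
    "RelevanceScore",
    "ScoredCandidate",
    "LLMBackend",
    "ScriptedBackend",
    "HeuristicBackend",
    "APIBackend",
    "BackendError",
    "TranscriptLogger",
    "build_scoring_prompt",
    "parse_score_reply",
    "heuristic_score",
    "score_candidates",
]


class BackendError(RuntimeError):
    """Raised when a scoring/classification backend is permanently unavailable."""


# ---------------------------------------------------------------------------
# Domain knowledge
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DomainRule:
    """One threshold rule over a named segment feature.

    ``mode`` controls how the rule combines its segments: ``all`` fires only
    when the condition holds in every listed segment, ``any`` when it holds
    in at least one.
    """

    feature: str
    segments: tuple[int, ...]
    op: str  # ">" or "<"
    threshold: float
    implied_label: str
    mode: str = "all"

    def __post_init__(self) -> None:
        if self.feature not in SEGMENT_FEATURE_NAMES:
            raise ValueError(f"unknown feature {self.feature!r}")
        if self.op not in (">", "<"):
            raise ValueError("op must be '>' or '<'")
        if self.mode not in ("all", "any"):
            raise ValueError("mode must be 'all' or 'any'")
        if not self.segments:
            raise ValueError("rule must reference at least one segment")

    def fires(self, fv: FeatureVector) -> bool:
        vals = [fv.segment_feature(s, self.feature) for s in self.segments]
        hits = [(v > self.threshold) if self.op == ">" else (v < self.threshold) for v in vals]
        return all(hits) if self.mode == "all" else any(hits)

    def render(self) -> str:
        segs = " and ".join(str(s) for s in self.segments)
        comp = "above" if self.op == ">" else "below"
        quant = "all of" if self.mode == "all" else "any of"
        return (
            f"{self.feature} values {comp} {self.threshold:g} in {quant} "
            f"segment(s) {segs} typically indicate {self.implied_label.replace('_', '-')}"
        )


@dataclass(frozen=True)
class DomainKnowledge:
    """A rule set injected into scoring prompts and the heuristic scorer."""

    rules: tuple[DomainRule, ...] = ()

    @property
    def enabled(self) -> bool:
        return bool(self.rules)

    @classmethod
    def default(cls) -> "DomainKnowledge":
        """Expert rules for normalized running-magnitude segments:
        elevated RMS in both later phase windows, or a depressed segment
        mean, point to the fatigued state."""
        return cls(
            rules=(
                DomainRule("rms", (2, 3), ">", 0.5, FATIGUE, mode="all"),
                DomainRule("mean", (1, 2, 3), "<", 0.31, FATIGUE, mode="any"),
            )
        )

    @classmethod
    def disabled(cls) -> "DomainKnowledge":
        return cls(rules=())

    @property
    def rendered_text(self) -> str:
        if not self.enabled:
            return ""
        lines = [f"- {rule.render()}" for rule in self.rules]
        return "Domain knowledge (expert threshold rules):\n" + "\n".join(lines)

    def implied_label(self, fv: FeatureVector) -> Optional[str]:
        """Majority label among fired rules; None when nothing fires."""
        fired = [r.implied_label for r in self.rules if r.fires(fv)]
        if not fired:
            return None
        counts = {lab: fired.count(lab) for lab in set(fired)}
        top = max(counts.values())
        winners = sorted(lab for lab, c in counts.items() if c == top)
        if len(winners) > 1:
            return None  # tied evidence is treated as indeterminate
        return winners[0]


# ---------------------------------------------------------------------------
# Scores and transcripts
# ---------------------------------------------------------------------------

PARSED = "parsed"
CLAMPED = "clamped"
FALLBACK = "fallback"


@dataclass(frozen=True)
class RelevanceScore:
    value: float
    reason: str = ""
    parse_status: str = PARSED

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"relevance score {self.value} outside [0, 1]")
        if self.parse_status not in (PARSED, CLAMPED, FALLBACK):
            raise ValueError(f"unknown parse status {self.parse_status!r}")


@dataclass(frozen=True)
class ScoredCandidate:
    candidate: Candidate
    score: RelevanceScore


class TranscriptLogger:
    """Collects prompt/reply records; optionally mirrors them to a JSONL file."""

    def __init__(self, path: Optional[str] = None) -> None:
        self.records: list[dict] = []
        self.path = path

    def log(self, **record) -> None:
        record.setdefault("timestamp", _dt.datetime.now(_dt.timezone.utc).isoformat())
        self.records.append(record)
        if self.path:
            with open(self.path, "a", encoding="utf-8") as fh:
                fh.write(json.dumps(record) + "\n")


# ---------------------------------------------------------------------------
# Backends
# ---------------------------------------------------------------------------


class LLMBackend:
    """Text-completion contract all backends implement.

    Backends may additionally provide the duck-typed fast paths
    ``score_pair(candidate, query, dk, tau)`` (used during relevance
    scoring) and ``classify_pair(shots, query)`` (used during label
    prediction); the pipeline prefers those when present.
    """

    model_name: str = "none"
    temperature: float = 0.3

    def complete(self, prompt_text: str) -> str:  # pragma: no cover - abstract
        raise NotImplementedError


class ScriptedBackend(LLMBackend):
    """Replays a fixed prompt->reply map (exact match), else a default reply.

    ``default`` may be a string or a callable prompt -> reply. All prompts
    seen are recorded in ``calls``.
    """

    model_name = "scripted"

    def __init__(
        self,
        replies: Optional[dict[str, str]] = None,
        default: str | Callable[[str], str] = "SCORE: 0.5\nREASON: scripted default",
    ) -> None:
        self.replies = dict(replies or {})
        self.default = default
        self.calls: list[str] = []

    def complete(self, prompt_text: str) -> str:
        self.calls.append(prompt_text)
        if prompt_text in self.replies:
            return self.replies[prompt_text]
        if callable(self.default):
            return self.default(prompt_text)
        return self.default


class HeuristicBackend(LLMBackend):
    """Deterministic offline scorer implementing the similarity+synergy rule."""

    model_name = "heuristic"

    def __init__(self, w_similarity: float = 0.5, w_synergy: float = 0.5) -> None:
        if w_similarity < 0 or w_synergy < 0 or w_similarity + w_synergy == 0:
            raise ValueError("weights must be non-negative and not both zero")
        self.w_similarity = w_similarity
        self.w_synergy = w_synergy

    def score_pair(
        self,
        candidate: Candidate,
        query: FeatureVector,
        dk: DomainKnowledge,
        tau: float,
    ) -> RelevanceScore:
        return heuristic_score(
            candidate,
            query,
            dk,
            tau=tau,
            w_similarity=self.w_similarity,
            w_synergy=self.w_synergy,
        )

    def complete(self, prompt_text: str) -> str:
        raise BackendError(
            "HeuristicBackend scores feature pairs directly and cannot "
            "complete free-form prompts"
        )


class APIBackend(LLMBackend):
    """Minimal OpenAI-compatible chat-completions client (stdlib only).

    The API key is read from the environment (never from config files).
    Network use is entirely optional: every offline code path in the
    package runs on the scripted or heuristic backends.
    """

    def __init__(
        self,
        model_name: str = "gpt-4o-mini",
        temperature: float = 0.3,
        api_key_env: str = "OPENAI_API_KEY",
        base_url: str = "https://api.openai.com/v1",
        timeout_s: float = 60.0,
    ) -> None:
        self.model_name = model_name
        self.temperature = temperature
        self.api_key_env = api_key_env
        self.base_url = base_url.rstrip("/")
        self.timeout_s = timeout_s

    def complete(self, prompt_text: str) -> str:
        api_key = os.environ.get(self.api_key_env)
        if not api_key:
            raise BackendError(
                f"no API key in environment variable {self.api_key_env!r}"
            )
        payload = json.dumps(
            {
                "model": self.model_name,
                "temperature": self.temperature,
                "messages": [{"role": "user", "content": prompt_text}],
            }
        ).encode()
        req = urllib.request.Request(
            f"{self.base_url}/chat/completions",
            data=payload,
            headers={
                "Content-Type": "application/json",
                "Authorization": f"Bearer {api_key}",
            },
        )
        try:
            with urllib.request.urlopen(req, timeout=self.timeout_s) as resp:
                body = json.loads(resp.read().decode())
        except Exception as exc:  # transport failure -> retried by caller
            raise BackendError(f"chat completion request failed: {exc}") from exc
        try:
            return body["choices"][0]["message"]["content"]
        except (KeyError, IndexError, TypeError) as exc:
            raise BackendError(f"malformed completion response: {body!r}") from exc


# ---------------------------------------------------------------------------
# Prompt construction and reply parsing
# ---------------------------------------------------------------------------


def _render_segments(fv: FeatureVector, title: str) -> str:
    n = len(SEGMENT_FEATURE_NAMES)
    n_segments = len(fv) // n
    lines = [f"{title}:"]
    for seg in range(1, n_segments + 1):
        parts = ", ".join(
            f"{name}={fv.segment_feature(seg, name):.4f}"
            for name in SEGMENT_FEATURE_NAMES
        )
        lines.append(f"  Segment {seg}: {parts}")
    return "\n".join(lines)


_GUIDANCE = (
    "Please compare the numeric data segment by segment. If the differences "
    "in Mean, Std, RMS etc. are very small => high relevance. Also check "
    "whether the labeled subject's label (Fatigue/Non-Fatigue) is aligned "
    "with the numeric pattern of the new subject."
)


def build_scoring_prompt(
    candidate: Candidate, query: FeatureVector, dk: DomainKnowledge
) -> str:
    """Structured relevance prompt for one candidate/query pair.

    Contains both instances' per-segment features, the candidate's label,
    the comparison guidance, the rendered domain-knowledge rules (when
    enabled), and the required SCORE/REASON output template.
    """
    blocks = [
        "You assess how relevant a labeled example is for classifying a new "
        "accelerometer-magnitude instance as fatigue or non-fatigue.",
        _render_segments(candidate.ref, "Labeled subject numeric features"),
        f"Labeled subject label: {candidate.ref.label.replace('_', '-')}",
        _render_segments(query, "New subject numeric features"),
        _GUIDANCE,
    ]
    if dk.enabled:
        blocks.append(dk.rendered_text)
    blocks.append(
        "Reply with exactly two lines and nothing else:\n"
        "SCORE: <a number between 0 and 1>\n"
        "REASON: <one concise sentence>"
    )
    return "\n\n".join(blocks)


_SCORE_RE = re.compile(r"score\s*[:=]?\s*(-?\d+(?:\.\d+)?)", re.IGNORECASE)
_REASON_RE = re.compile(r"reason\s*[:=]?\s*(.+)", re.IGNORECASE | re.DOTALL)


def parse_score_reply(reply_text: str) -> RelevanceScore:
    """Total parser for scoring replies.

    Extracts the first number after a (case-insensitive) SCORE marker,
    clamping to [0, 1] when out of range; captures the REASON text; replies
    with no parsable score yield the neutral 0.5 fallback.
    """
    text = reply_text or ""
    reason_match = _REASON_RE.search(text)
    reason = reason_match.group(1).strip() if reason_match else ""
    score_match = _SCORE_RE.search(text)
    if not score_match:
        return RelevanceScore(0.5, reason=reason or text.strip(), parse_status=FALLBACK)
    raw = float(score_match.group(1))
    clamped = min(1.0, max(0.0, raw))
    status = PARSED if clamped == raw else CLAMPED
    return RelevanceScore(clamped, reason=reason, parse_status=status)


# ---------------------------------------------------------------------------
# Heuristic scorer
# ---------------------------------------------------------------------------


def heuristic_score(
    candidate: Candidate,
    query: FeatureVector,
    dk: DomainKnowledge,
    tau: float = 1.0,
    w_similarity: float = 0.5,
    w_synergy: float = 0.5,
) -> RelevanceScore:
    """Deterministic relevance rule: similarity term + label-synergy term.

    ``score = w_sim * exp(-distance / tau) + w_syn * synergy`` where the
    synergy term is 1 when the domain rules' implied label for the query
    matches the candidate's label, 0 when it contradicts it, and 0.5 when
    the rules are indeterminate (or disabled). Weights are normalized to
    sum to 1 so the score stays in [0, 1].
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    w_total = w_similarity + w_synergy
    w_sim, w_syn = w_similarity / w_total, w_synergy / w_total
    similarity = math.exp(-candidate.distance / tau)
    implied = dk.implied_label(query) if dk.enabled else None
    if implied is None:
        synergy, verdict = 0.5, "indeterminate"
    elif implied == candidate.ref.label:
        synergy, verdict = 1.0, f"matches implied label {implied}"
    else:
        synergy, verdict = 0.0, f"contradicts implied label {implied}"
    value = w_sim * similarity + w_syn * synergy
    reason = (
        f"similarity exp(-{candidate.distance:.4f}/{tau:.4f})={similarity:.4f}; "
        f"label synergy {synergy:.1f} ({verdict})"
    )
    return RelevanceScore(min(1.0, max(0.0, value)), reason=reason, parse_status=PARSED)


# ---------------------------------------------------------------------------
# Batch scoring
# ---------------------------------------------------------------------------


def _candidate_tau(candidates: Sequence[Candidate]) -> float:
    """Distance scale for the similarity term: median candidate distance."""
    med = float(np.median([c.distance for c in candidates]))
    return med if med > 0 else 1.0


def score_candidates(
    candidates: Sequence[Candidate],
    query: FeatureVector,
    backend: LLMBackend,
    dk: DomainKnowledge,
    transcript: Optional[TranscriptLogger] = None,
) -> list[ScoredCandidate]:
    """Score each candidate independently, preserving order.

    Backends exposing ``score_pair`` are called directly on the feature
    pair; prompt-based backends get one retry per candidate on transport
    failure, after which the neutral fallback score is recorded. If every
    candidate fails at the transport level the backend is considered
    permanently unavailable and :class:`BackendError` is raised (transcripts
    already logged are preserved).
    """
    if not candidates:
        raise ValueError("no candidates to score")
    tau = _candidate_tau(candidates)
    scored: list[ScoredCandidate] = []
    n_transport_failures = 0
    for cand in candidates:
        prompt = build_scoring_prompt(cand, query, dk)
        if hasattr(backend, "score_pair"):
            score = backend.score_pair(cand, query, dk, tau)
            reply = f"SCORE: {score.value:.4f}\nREASON: {score.reason}"
        else:
            reply = None
            for _attempt in range(2):
                try:
                    reply = backend.complete(prompt)
                    break
                except BackendError:
                    continue
            if reply is None:
                n_transport_failures += 1
                score = RelevanceScore(
                    0.5, reason="backend unavailable", parse_status=FALLBACK
                )
                reply = "<no reply>"
            else:
                score = parse_score_reply(reply)
        if transcript is not None:
            transcript.log(
                kind="scoring",
                query_id=query.instance_id,
                candidate_id=cand.ref.instance_id,
                prompt=prompt,
                reply=reply,
                score=score.value,
                status=score.parse_status,
            )
        scored.append(ScoredCandidate(candidate=cand, score=score))
    if n_transport_failures == len(candidates):
        raise BackendError(
            f"backend {backend.model_name!r} failed for all "
            f"{len(candidates)} candidates (after one retry each)"
        )
    return scored
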