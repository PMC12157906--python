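"""Euclidean-distance candidate filtering.

Given a query feature vector and a pool of labeled vectors from the same
user, rank the pool by Euclidean distance in the 30-dimensional feature
space and keep the ``distance_k`` nearest as candidates for relevance
scoring. Ties are broken by (distance, user_id, instance_id) so results are
reproducible across runs and pool orderings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .preprocessing import FeatureVector

__all__ = [
    "Candidate",
    "SelectionConfig",
    "PRESETS",
    "euclidean_distance",
    "nearest_candidates",
]


@dataclass(frozen=True)
class Candidate:
    """A labeled pool member together with its distance to the query."""

    ref: FeatureVector
    distance: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.distance) or self.distance < 0:
            raise ValueError(f"invalid candidate distance {self.distance}")
        if self.ref.label is None:
            raise ValueError(
                f"candidate {self.ref.user_id}/{self.ref.instance_id} must be labeled"
            )


@dataclass(frozen=True)
class SelectionConfig:
    """distance-K / top-K retrieval parameters.

    ``distance_k`` pool members survive the distance filter; ``top_k`` of
    them survive relevance re-ranking and supply the prompt shots.
    """

    distance_k: int = 5
    top_k: int = 3

    def __post_init__(self) -> None:
        if not 1 <= self.top_k <= self.distance_k:
            raise ValueError(
                f"need 1 <= top_k <= distance_k, got top_k={self.top_k}, "
                f"distance_k={self.distance_k}"
            )


#: named parameter presets: paramA favors speed, paramB favors coverage
PRESETS = {
    "paramA": SelectionConfig(distance_k=5, top_k=3),
    "paramB": SelectionConfig(distance_k=10, top_k=5),
}


def euclidean_distance(a: FeatureVector, b: FeatureVector) -> float:
    """Euclidean distance between two feature vectors of equal dimension."""
    if len(a) != len(b):
        raise ValueError(f"dimension mismatch: {len(a)} vs {len(b)}")
    return float(np.linalg.norm(a.values - b.values))


def nearest_candidates(
    query: FeatureVector,
    pool: Sequence[FeatureVector],
    distance_k: int,
) -> list[Candidate]:
    """The ``min(distance_k, |pool|)`` pool members nearest to the query.

    The pool must already exclude the query's own instance (the caller owns
    the leakage contract). Candidates come back sorted ascending by
    distance, ties broken by (user_id, instance_id).
    """
    if not pool:
        raise ValueError("candidate pool is empty")
    if distance_k < 1:
        raise ValueError("distance_k must be >= 1")
    scored = [Candidate(ref=fv, distance=euclidean_distance(query, fv)) for fv in pool]
    scored.sort(key=lambda c: (c.distance, str(c.ref.user_id), str(c.ref.instance_id)))
    return scored[:distance_k]
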