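"""Fingerprint similarity indices and nearest-neighbor ranking.

Similarity between two binary fingerprints with A and B set bits, c shared:

    Tanimoto  c / (A + B − c)
    Dice      2c / (A + B)
    cosine    c / sqrt(A·B)

Count fingerprints use the real-valued generalizations with the sparse dot
product a·b:  Tanimoto a·b/(‖a‖²+‖b‖²−a·b), Dice 2a·b/(‖a‖²+‖b‖²), cosine
a·b/(‖a‖‖b‖).  Distance is 1 − similarity; the smaller the distance, the
more similar the pair.  Which index–fingerprint pair to use is left to the
user, so every index is available on every fingerprint kind.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

from .base import ValidationError
from .chemistry import Fingerprint

__all__ = ["NeighborHit", "similarity", "find_neighbors", "SIMILARITY_INDICES"]

SIMILARITY_INDICES = ("tanimoto", "dice", "cosine")


def _binary_similarity(a: Fingerprint, b: Fingerprint, index: str) -> float:
    A, B = len(a.bits), len(b.bits)
    if A == 0 and B == 0:
        warnings.warn(
            "both fingerprints are empty; similarity defined as 1 (uninformative)",
            stacklevel=3,
        )
        return 1.0
    if A == 0 or B == 0:
        return 0.0
    c = len(a.bits & b.bits)
    if index == "tanimoto":
        return c / (A + B - c)
    if index == "dice":
        return 2.0 * c / (A + B)
    return c / (A * B) ** 0.5  # cosine


def _count_similarity(a: Fingerprint, b: Fingerprint, index: str) -> float:
    na2 = sum(v * v for v in a.counts.values())
    nb2 = sum(v * v for v in b.counts.values())
    if na2 == 0 and nb2 == 0:
        warnings.warn(
            "both fingerprints are empty; similarity defined as 1 (uninformative)",
            stacklevel=3,
        )
        return 1.0
    if na2 == 0 or nb2 == 0:
        return 0.0
    dot = sum(v * b.counts[k] for k, v in a.counts.items() if k in b.counts)
    if index == "tanimoto":
        return dot / (na2 + nb2 - dot)
    if index == "dice":
        return 2.0 * dot / (na2 + nb2)
    return dot / (na2 * nb2) ** 0.5  # cosine


def similarity(a: Fingerprint, b: Fingerprint, index: str = "tanimoto") -> float:
    """Similarity of two fingerprints of the same kind and length, in [0, 1]."""
    if index not in SIMILARITY_INDICES:
        raise ValidationError(
            f"unknown similarity index {index!r}; available: {SIMILARITY_INDICES}"
        )
    if a.kind != b.kind:
        raise ValidationError(f"fingerprint kind mismatch: {a.kind!r} vs {b.kind!r}")
    if a.length != b.length:
        raise ValidationError(
            f"fingerprint length mismatch: {a.length} vs {b.length}"
        )
    if a.is_count != b.is_count:
        raise ValidationError("cannot compare a binary and a count fingerprint")
    if a.is_count:
        return _count_similarity(a, b, index)
    return _binary_similarity(a, b, index)


@dataclass(frozen=True)
class NeighborHit:
    training_id: str
    similarity: float
    distance: float
    y: object
    rank: int


def find_neighbors(
    target: Fingerprint,
    training: Sequence[Fingerprint],
    index: str = "tanimoto",
    k: int = 5,
    ids: Optional[Sequence[str]] = None,
    y: Optional[Sequence] = None,
) -> list:
    """Top-k training chemicals by ascending distance to the target.

    Ties are broken by training order (stable), ranks run 1..k, and k larger
    than the training set returns everything.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if not training:
        raise ValidationError("training fingerprint list is empty")
    ids = list(ids) if ids is not None else [str(i) for i in range(len(training))]
    ys = list(y) if y is not None else [None] * len(training)
    if len(ids) != len(training) or len(ys) != len(training):
        raise ValidationError("ids/y length must match the training list")
    scored = [
        (1.0 - similarity(target, fp, index=index), i) for i, fp in enumerate(training)
    ]
    scored.sort(key=lambda t: (t[0], t[1]))
    hits = []
    for rank, (dist, i) in enumerate(scored[:k], start=1):
        hits.append(
            NeighborHit(
                training_id=ids[i],
                similarity=1.0 - dist,
                distance=dist,
                y=ys[i],
                rank=rank,
            )
        )
    return hits
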