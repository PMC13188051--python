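"""Inverse-variance-weighted consensus of regression predictions.

When several models predict the same endpoint in the same units, the combined
prediction is the weighted average with weights w_i = 1/σ_i², where σ_i is
each member's prediction-interval halfwidth:

    value       = Σ w_i ŷ_i / Σ w_i
    uncertainty = sqrt(1 / Σ w_i)

The combined uncertainty is strictly below the smallest member σ whenever
N ≥ 2.  Entropy is not a σ, so classification predictions never enter a
consensus; only MLR members are combined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .base import QsarError, ValidationError
from .chemistry import ChemicalStructure, resolve_descriptor_vector
from .mlr import MlrModel, prediction_interval

__all__ = ["ConsensusMember", "ConsensusResult", "combine", "consensus_for_subgroup"]


@dataclass(frozen=True)
class ConsensusMember:
    model_id: str
    value: float
    uncertainty: float
    in_ad: bool = True


@dataclass(frozen=True)
class ConsensusResult:
    """A combined prediction; ``members`` empty marks 'no applicable model'."""

    members: tuple
    weights: tuple
    value: Optional[float]
    uncertainty: Optional[float]
    excluded: tuple = ()  # (model_id, reason) pairs

    @property
    def is_empty(self) -> bool:
        return not self.members


def combine(
    predictions: Sequence,
    model_ids: Optional[Sequence[str]] = None,
    in_ad: Optional[Sequence[bool]] = None,
    excluded: Sequence = (),
) -> ConsensusResult:
    """Inverse-variance combination of (value, uncertainty) pairs."""
    if not predictions:
        raise ValidationError("cannot combine an empty prediction list")
    ids = list(model_ids) if model_ids is not None else [
        f"model{i + 1}" for i in range(len(predictions))
    ]
    flags = list(in_ad) if in_ad is not None else [True] * len(predictions)
    members, weights = [], []
    for (value, sigma), mid, flag in zip(predictions, ids, flags):
        if not (sigma > 0.0):
            raise ValidationError(
                f"member {mid!r} has non-positive uncertainty {sigma!r}; "
                "inverse-variance weights are undefined"
            )
        members.append(ConsensusMember(model_id=mid, value=float(value),
                                       uncertainty=float(sigma), in_ad=flag))
        weights.append(1.0 / (sigma * sigma))
    wsum = sum(weights)
    value = sum(w * m.value for w, m in zip(weights, members)) / wsum
    return ConsensusResult(
        members=tuple(members),
        weights=tuple(weights),
        value=value,
        uncertainty=math.sqrt(1.0 / wsum),
        excluded=tuple(excluded),
    )


def consensus_for_subgroup(
    registry,
    subgroup: str,
    target,
    policy: str = "user_selected",
    selected: Optional[Sequence[str]] = None,
    supplied: Optional[Mapping[str, float]] = None,
    group: Optional[str] = None,
    alpha: float = 0.05,
) -> ConsensusResult:
    """Combine the predictions of a subgroup's MLR models for one target.

    ``target`` is a ChemicalStructure or a mapping of supplied descriptor
    values.  ``policy`` is "all", "in_ad_only", or "user_selected" (with
    ``selected`` model ids).  Members that cannot predict the target, are
    not MLR, are out of AD (under in_ad_only), or are not selected are
    recorded in ``excluded`` with a reason; no applicable model yields an
    empty-result marker, not an exception.
    """
    if policy not in ("all", "in_ad_only", "user_selected"):
        raise ValidationError(f"unknown consensus policy {policy!r}")
    if policy == "user_selected" and selected is None:
        raise ValidationError("policy 'user_selected' needs a selected id list")

    structure = target if isinstance(target, ChemicalStructure) else None
    if structure is None and supplied is None and isinstance(target, Mapping):
        supplied = target

    preds, ids, flags, excluded = [], [], [], []
    for model in registry.in_subgroup(subgroup, group=group):
        mid = model.metadata.model_id
        if not isinstance(model, MlrModel):
            excluded.append((mid, "not a regression model"))
            continue
        if policy == "user_selected" and mid not in set(selected):
            excluded.append((mid, "not selected"))
            continue
        try:
            vec = resolve_descriptor_vector(model.specs, structure=structure,
                                            supplied=supplied)
            pred = prediction_interval(model, vec.values, alpha=alpha)
        except QsarError as exc:
            excluded.append((mid, str(exc)))
            continue
        in_ad = pred.structural_in_ad and pred.endpoint_in_ad
        if policy == "in_ad_only" and not in_ad:
            excluded.append((mid, "out of applicability domain: "
                             + "; ".join(pred.reasons)))
            continue
        if pred.halfwidth <= 0.0:
            excluded.append((mid, "degenerate zero-uncertainty prediction"))
            continue
        preds.append((pred.value, pred.halfwidth))
        ids.append(mid)
        flags.append(in_ad)

    if not preds:
        return ConsensusResult(members=(), weights=(), value=None,
                               uncertainty=None, excluded=tuple(excluded))
    return combine(preds, model_ids=ids, in_ad=flags, excluded=excluded)
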