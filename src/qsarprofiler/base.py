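"""Shared domain types: descriptor specs, training records, metadata, AD verdicts."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence, Union


class QsarError(Exception):
    """Base class for all package errors."""


class ValidationError(QsarError):
    """A model or input failed a consistency check."""


class MissingDescriptorError(QsarError):
    """A descriptor value required for prediction is unavailable."""

    def __init__(self, descriptor: str, message: str | None = None):
        self.descriptor = descriptor
        super().__init__(message or f"missing value for descriptor {descriptor!r}")


@dataclass(frozen=True)
class DescriptorSpec:
    """One model descriptor: a named column of the design matrix.

    ``source`` records whether values are computed by the built-in chemistry
    backend ("computed") or must be supplied externally ("supplied"), e.g.
    experimental measurements or descriptors from third-party software.
    """

    name: str
    source: str = "computed"
    description: str = ""

    def __post_init__(self):
        if not self.name:
            raise ValidationError("descriptor name must be non-empty")
        if self.source not in ("computed", "supplied"):
            raise ValidationError(
                f"descriptor {self.name!r}: source must be 'computed' or "
                f"'supplied', got {self.source!r}"
            )


@dataclass(frozen=True)
class TrainingRecord:
    """A training-set chemical: id, optional SMILES, descriptor values, endpoint.

    ``y`` is a float endpoint for regression models and a class-label string
    for classification models.
    """

    id: str
    descriptor_values: tuple
    y: Union[float, str]
    smiles: str | None = None

    def __post_init__(self):
        object.__setattr__(
            self, "descriptor_values", tuple(float(v) for v in self.descriptor_values)
        )
        for v in self.descriptor_values:
            if math.isnan(v):
                raise ValidationError(f"training record {self.id!r} has a missing value")


@dataclass(frozen=True)
class ModelMetadata:
    model_id: str
    endpoint_name: str = ""
    units: str = ""
    group: str = ""
    subgroup: str = ""
    citation: str = ""


class CriterionStatus(str, Enum):
    PASS = "pass"
    FAIL = "fail"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class ADVerdict:
    """Outcome of an applicability-domain check.

    ``criteria`` maps criterion name -> CriterionStatus; ``details`` holds the
    numeric evidence (leverage, cutoff, standardized residual, ...) so every
    verdict is auditable in exported reports. ``in_ad`` is True iff all
    applicable criteria pass (or, under the strict-AND reading documented in
    the methods note, per the combination there).
    """

    in_ad: bool
    criteria: Mapping[str, CriterionStatus]
    details: Mapping[str, float]
    reasons: tuple = ()


def check_specs(specs: Sequence[DescriptorSpec]) -> tuple:
    """Validate a descriptor-spec list: non-empty, unique names."""
    specs = tuple(specs)
    if not specs:
        raise ValidationError("model needs at least one descriptor")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicate descriptor names: {dupes}")
    return specs


def check_training(
    specs: Sequence[DescriptorSpec], training: Sequence[TrainingRecord]
) -> tuple:
    """Validate training records against the spec list (arity, no missing)."""
    training = tuple(training)
    p = len(specs)
    for rec in training:
        if len(rec.descriptor_values) != p:
            raise ValidationError(
                f"training record {rec.id!r} has {len(rec.descriptor_values)} "
                f"descriptor values, expected {p}"
            )
    return training
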