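"""Linear discriminant analysis with entropy uncertainty and similarity-based AD.

Classification QSA(P)Rs here are Gaussian LDA with a pooled within-class
covariance and empirical priors.  Posterior class probabilities come from a
softmax over the linear discriminant scores

    δ_k(x) = x·Σ⁻¹μ_k − ½ μ_kᵀΣ⁻¹μ_k + ln π_k,

prediction uncertainty is the Shannon entropy of the posteriors (bits by
default), the structural applicability domain is a cosine-similarity
percentile rule over the training set, and the endpoint applicability domain
flags posteriors inside the indecision band (0.25, 0.75).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .base import (
    ADVerdict,
    CriterionStatus,
    DescriptorSpec,
    ModelMetadata,
    TrainingRecord,
    ValidationError,
    check_specs,
    check_training,
)

__all__ = [
    "LdaClassifier",
    "LdaModel",
    "ClassPrediction",
    "fit_lda",
    "predict_lda",
    "shannon_entropy",
    "cosine_similarity",
    "structural_ad_check_lda",
    "endpoint_ad_check_lda",
]


def shannon_entropy(posteriors, base: float = 2.0) -> float:
    """−Σ p·log p over class posteriors, with 0·log 0 = 0.  Bits for base 2."""
    p = np.asarray(posteriors, dtype=float)
    if p.ndim != 1 or abs(p.sum() - 1.0) > 1e-8 or np.any(p < -1e-12):
        raise ValidationError("posteriors must be non-negative and sum to 1")
    p = np.clip(p, 0.0, 1.0)
    nz = p[p > 0.0]
    return float(-(nz * np.log(nz)).sum() / math.log(base))


def cosine_similarity(a, b) -> float:
    """a·b / (‖a‖·‖b‖) for two equal-length non-zero real vectors."""
    a = np.asarray(a, dtype=float).reshape(-1)
    b = np.asarray(b, dtype=float).reshape(-1)
    if a.shape != b.shape:
        raise ValidationError(f"vector lengths differ: {a.shape[0]} vs {b.shape[0]}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValidationError("cosine similarity is undefined for a zero vector")
    return float(a @ b / (na * nb))


class LdaClassifier(ClassifierMixin, BaseEstimator):
    """Gaussian LDA with pooled covariance, entropy uncertainty and a
    cosine-similarity structural AD.

    Parameters
    ----------
    ad_percentile : float, default 95.0
        The percentile cited by the structural-AD rule.  By default the
        cutoff is the ``100 - ad_percentile`` percentile of training
        similarity scores, so that roughly ``ad_percentile`` percent of the
        training set lies inside its own AD.
    literal_percentile : bool, default False
        Use the verbatim rule instead: cutoff at the ``ad_percentile``-th
        percentile of training scores (which leaves most of the training set
        outside its own AD; provided for comparability).
    similarity_mode : {"centroid", "max_train"}, default "centroid"
        Score a chemical by cosine similarity of its SD-scaled descriptor
        vector against the SD-scaled training centroid, or by its maximum
        cosine similarity to any single training chemical.
    entropy_base : float, default 2.0
        Logarithm base of the Shannon entropy (2 -> bits).
    condition_threshold : float, default 1e10
        Pooled-covariance condition number above which fitting fails.

    Notes
    -----
    Similarity scoring scales each descriptor by its training standard
    deviation but does not center it: centering would place the training
    centroid at the origin, where the cosine is undefined.  Percentiles use
    the linear-interpolation convention of ``numpy.percentile``.
    """

    def __init__(
        self,
        ad_percentile: float = 95.0,
        literal_percentile: bool = False,
        similarity_mode: str = "centroid",
        entropy_base: float = 2.0,
        condition_threshold: float = 1e10,
    ):
        self.ad_percentile = ad_percentile
        self.literal_percentile = literal_percentile
        self.similarity_mode = similarity_mode
        self.entropy_base = entropy_base
        self.condition_threshold = condition_threshold

    def fit(self, X, y):
        X = check_array(X, dtype=np.float64)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValidationError("X and y length mismatch")
        n, p = X.shape
        # declared class order = order of first appearance in the training set
        classes, first = np.unique(y, return_index=True)
        self.classes_ = classes[np.argsort(first)]
        K = len(self.classes_)
        if K < 2:
            raise ValidationError("LDA needs at least 2 classes")
        counts = np.array([(y == c).sum() for c in self.classes_])
        if np.any(counts < 2):
            small = [str(c) for c, m in zip(self.classes_, counts) if m < 2]
            raise ValidationError(f"each class needs >= 2 members; too small: {small}")
        if n - K < p:
            raise ValidationError(
                f"pooled covariance needs n - K >= p (got n={n}, K={K}, p={p})"
            )

        self.priors_ = counts / n
        self.means_ = np.array([X[y == c].mean(axis=0) for c in self.classes_])
        pooled = np.zeros((p, p))
        for c, mu in zip(self.classes_, self.means_):
            D = X[y == c] - mu
            pooled += D.T @ D
        pooled /= n - K
        cond = np.linalg.cond(pooled)
        if not np.isfinite(cond) or cond > self.condition_threshold:
            sd = np.sqrt(np.diag(pooled))
            bad = [f"x{j + 1}" for j in range(p) if sd[j] <= sd.max() * 1e-12]
            raise ValidationError(
                f"pooled within-class covariance is singular "
                f"(condition number {cond:.3g}); offending descriptors: {bad or 'correlated set'}"
            )
        self.covariance_ = pooled
        self._cov_inv = np.linalg.inv(pooled)
        self.coef_ = self.means_ @ self._cov_inv  # (K, p)
        self.intercept_ = (
            -0.5 * np.einsum("kj,kj->k", self.means_ @ self._cov_inv, self.means_)
            + np.log(self.priors_)
        )
        # autoscaling parameters (reported for auditability; similarity uses scale only)
        self.scaler_mean_ = X.mean(axis=0)
        self.scaler_scale_ = X.std(axis=0, ddof=1)
        if np.any(self.scaler_scale_ == 0.0):
            raise ValidationError("a descriptor is constant across the training set")
        self._train_scaled = X / self.scaler_scale_
        self._centroid = self._train_scaled.mean(axis=0)
        self.train_scores_ = self.similarity_scores(X)
        q = (self.ad_percentile if self.literal_percentile
             else 100.0 - self.ad_percentile)
        self.sim_cutoff_ = float(np.percentile(self.train_scores_, q))
        self.n_features_in_ = p
        self.n_samples_ = n
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=np.float64)
        return X @ self.coef_.T + self.intercept_

    def predict_proba(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        scores = scores - scores.max(axis=1, keepdims=True)
        e = np.exp(scores)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def entropy(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return np.array([shannon_entropy(p, base=self.entropy_base) for p in proba])

    def similarity_scores(self, X) -> np.ndarray:
        """Structural-AD similarity score per row (see class notes)."""
        check_is_fitted(self, "scaler_scale_")
        X = check_array(X, dtype=np.float64)
        Z = X / self.scaler_scale_

        def safe_cos(u, v):
            # a zero vector (query at the origin of the scaled space) has no
            # direction; score it 0, the conservative "no similarity" value
            nu, nv = np.linalg.norm(u), np.linalg.norm(v)
            if nu == 0.0 or nv == 0.0:
                return 0.0
            return float(u @ v / (nu * nv))

        if self.similarity_mode == "centroid":
            return np.array([safe_cos(z, self._centroid) for z in Z])
        if self.similarity_mode == "max_train":
            T = self._train_scaled
            out = np.empty(Z.shape[0])
            for i, z in enumerate(Z):
                out[i] = max(safe_cos(t, z) for t in T)
            return out
        raise ValidationError(f"unknown similarity_mode {self.similarity_mode!r}")


@dataclass(frozen=True)
class ClassPrediction:
    """A classification prediction with posteriors, entropy and AD verdicts."""

    label: object
    posteriors: Mapping
    entropy: float
    similarity: float
    structural_in_ad: bool
    endpoint_in_ad: bool
    tie: bool = False
    reasons: tuple = ()
    structural_verdict: ADVerdict | None = None
    endpoint_verdict: ADVerdict | None = None


@dataclass
class LdaModel:
    """A fitted LDA QSA(P)R with training set and AD statistics."""

    specs: tuple
    training: tuple
    metadata: ModelMetadata
    estimator: LdaClassifier = field(repr=False)

    @property
    def n(self) -> int:
        return self.estimator.n_samples_

    @property
    def p(self) -> int:
        return self.estimator.n_features_in_

    @property
    def classes(self) -> list:
        return list(self.estimator.classes_)

    @property
    def priors(self) -> np.ndarray:
        return self.estimator.priors_

    @property
    def train_scores(self) -> np.ndarray:
        return self.estimator.train_scores_

    @property
    def sim_cutoff(self) -> float:
        return self.estimator.sim_cutoff_

    @property
    def model_type(self) -> str:
        return "lda"

    def descriptor_names(self) -> list:
        return [s.name for s in self.specs]

    def training_matrix(self) -> np.ndarray:
        return np.array([r.descriptor_values for r in self.training], dtype=float)

    def predict(self, x) -> ClassPrediction:
        return predict_lda(self, x)

    def equals(self, other: "LdaModel", tol: float = 1e-12) -> bool:
        if not isinstance(other, LdaModel):
            return False
        if self.specs != other.specs or self.metadata != other.metadata:
            return False
        if len(self.training) != len(other.training):
            return False
        for a, b in zip(self.training, other.training):
            if a.id != b.id or a.smiles != b.smiles or str(a.y) != str(b.y):
                return False
            if not np.allclose(a.descriptor_values, b.descriptor_values,
                               rtol=0.0, atol=tol):
                return False
        return bool(
            np.allclose(self.estimator.coef_, other.estimator.coef_,
                        rtol=0.0, atol=max(tol, 1e-10))
        )


def fit_lda(
    specs: Sequence[DescriptorSpec],
    training: Sequence[TrainingRecord],
    metadata: ModelMetadata | None = None,
    ad_percentile: float = 95.0,
    literal_percentile: bool = False,
    similarity_mode: str = "centroid",
) -> LdaModel:
    """Fit an LDA QSA(P)R from descriptor specs and class-labeled records."""
    specs = check_specs(specs)
    training = check_training(specs, training)
    X = np.array([r.descriptor_values for r in training], dtype=float)
    y = np.array([str(r.y) for r in training])
    est = LdaClassifier(
        ad_percentile=ad_percentile,
        literal_percentile=literal_percentile,
        similarity_mode=similarity_mode,
    )
    est.fit(X, y)
    if metadata is None:
        metadata = ModelMetadata(model_id="lda_model")
    return LdaModel(specs=specs, training=training, metadata=metadata, estimator=est)


def _as_row(model: LdaModel, x) -> np.ndarray:
    x = np.asarray(x, dtype=float).reshape(-1)
    if x.shape[0] != model.p:
        raise ValidationError(
            f"query has {x.shape[0]} descriptor values, model "
            f"{model.metadata.model_id!r} has {model.p}"
        )
    return x.reshape(1, -1)


def structural_ad_check_lda(model: LdaModel, x) -> ADVerdict:
    """Out of the structural AD iff the similarity score falls below the
    percentile-derived cutoff on training scores."""
    score = float(model.estimator.similarity_scores(_as_row(model, x))[0])
    cutoff = model.sim_cutoff
    fail = score < cutoff
    reasons = (f"similarity {score:.6g} < cutoff {cutoff:.6g}",) if fail else ()
    return ADVerdict(
        in_ad=not fail,
        criteria={"similarity": CriterionStatus.FAIL if fail else CriterionStatus.PASS},
        details={"similarity": score, "similarity_cutoff": cutoff},
        reasons=reasons,
    )


def endpoint_ad_check_lda(
    pred: ClassPrediction, band: tuple = (0.25, 0.75)
) -> ADVerdict:
    """Out of the endpoint AD iff the winning posterior lies strictly inside
    the indecision band (bounds themselves are in the AD)."""
    p = max(pred.posteriors.values())
    lo, hi = band
    fail = lo < p < hi
    reasons = (f"posterior {p:.4g} inside indecision band ({lo}, {hi})",) if fail else ()
    return ADVerdict(
        in_ad=not fail,
        criteria={"posterior_band": CriterionStatus.FAIL if fail else CriterionStatus.PASS},
        details={"posterior": p, "band_low": lo, "band_high": hi},
        reasons=reasons,
    )


def predict_lda(model: LdaModel, x) -> ClassPrediction:
    """Classify a query chemical with posteriors, entropy and both AD checks."""
    row = _as_row(model, x)
    if np.any(np.isnan(row)):
        raise ValidationError("query has missing descriptor values")
    proba = model.estimator.predict_proba(row)[0]
    best = float(proba.max())
    winners = np.flatnonzero(np.isclose(proba, best, rtol=0.0, atol=1e-12))
    tie = len(winners) > 1
    label = model.estimator.classes_[winners[0]]  # first declared class wins ties
    posteriors = {c: float(p) for c, p in zip(model.estimator.classes_, proba)}
    ent = shannon_entropy(proba, base=model.estimator.entropy_base)
    sv = structural_ad_check_lda(model, x)
    base = ClassPrediction(
        label=label, posteriors=posteriors, entropy=ent,
        similarity=sv.details["similarity"], structural_in_ad=sv.in_ad,
        endpoint_in_ad=True, tie=tie,
    )
    ev = endpoint_ad_check_lda(base)
    reasons = sv.reasons + ev.reasons
    if tie:
        reasons = reasons + ("tied posteriors: maximal uncertainty",)
    return ClassPrediction(
        label=label, posteriors=posteriors, entropy=ent,
        similarity=sv.details["similarity"], structural_in_ad=sv.in_ad,
        endpoint_in_ad=ev.in_ad, tie=tie, reasons=reasons,
        structural_verdict=sv, endpoint_verdict=ev,
    )
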