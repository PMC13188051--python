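"""Multiple linear regression with prediction intervals and applicability domains.

The regression model behind a quantitative structure-activity/property
relationship (QSA(P)R) is ordinary least squares on an intercept-augmented
design matrix.  The quantities this module computes around the fit are the
ones a regulatory QSAR report needs:

* the residual standard error ``s = sqrt(sum(r_i^2) / (n - p - 1))``,
* per-chemical leverages ``h = x̃ (X̃ᵀX̃)⁻¹ x̃ᵀ`` (diagonal of the hat matrix
  for training chemicals),
* the prediction-interval halfwidth ``t(1-α/2, n-p-1) · s · sqrt(1 + h)``,
* the structural applicability-domain (AD) leverage cutoff ``3·(p+1)/n``
  (a chemical with ``h >= cutoff`` is outside the structural AD), and
* endpoint-AD diagnostics: standardized residuals ``r' = r / (s·sqrt(1-h))``
  with the ``|r'| > 2.5`` outlier rule, the training experimental range, and
  the training prediction-interval halfwidth range.

`MlrRegressor` is the scikit-learn style estimator holding the numerics;
`MlrModel` wraps it together with descriptor specs, training records and
metadata, and the module-level functions mirror that domain surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.linalg import qr
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .base import (
    ADVerdict,
    CriterionStatus,
    DescriptorSpec,
    MissingDescriptorError,
    ModelMetadata,
    TrainingRecord,
    ValidationError,
    check_specs,
    check_training,
)

__all__ = [
    "MlrRegressor",
    "MlrModel",
    "Prediction",
    "fit_mlr",
    "leverage",
    "leverage_cutoff",
    "prediction_interval",
    "structural_ad_check",
    "endpoint_ad_check",
    "standardized_residuals",
]


class MlrRegressor(RegressorMixin, BaseEstimator):
    """Ordinary least squares with leverage-based AD diagnostics.

    Parameters
    ----------
    alpha : float, default 0.05
        Two-sided significance level of the prediction interval; the
        halfwidth uses the t quantile at ``1 - alpha/2`` with ``n - p - 1``
        degrees of freedom.
    condition_threshold : float, default 1e10
        Condition number of the intercept-augmented design above which the
        fit is rejected as rank deficient.  AD statistics on a deficient
        design are meaningless, so this is a hard error, not a silent
        pseudo-inverse.

    Attributes
    ----------
    intercept_, coef_ : least-squares solution (coef_ has shape (p,)).
    beta_ : full coefficient vector (intercept first), shape (p+1,).
    s_ : residual standard error.
    df_ : residual degrees of freedom, n - p - 1.
    r2_ : coefficient of determination.
    residuals_ : y - ŷ on the training set.
    hat_diag_ : training leverages h_ii.
    leverage_cutoff_ : 3·(p+1)/n.
    y_range_ : (min, max) of training y.
    halfwidth_range_ : (min, max) of training prediction-interval halfwidths.
    """

    def __init__(self, alpha: float = 0.05, condition_threshold: float = 1e10):
        self.alpha = alpha
        self.condition_threshold = condition_threshold

    def fit(self, X, y, feature_names: Optional[Sequence[str]] = None):
        X, y = check_X_y(X, y, dtype=np.float64, y_numeric=True)
        n, p = X.shape
        if n < p + 2:
            raise ValidationError(
                f"need n >= p + 2 training chemicals for a residual degree of "
                f"freedom (got n={n}, p={p})"
            )
        names = list(feature_names) if feature_names is not None else [
            f"x{j + 1}" for j in range(p)
        ]
        Xd = np.column_stack([np.ones(n), X])
        cond = np.linalg.cond(Xd)
        if not np.isfinite(cond) or cond > self.condition_threshold:
            bad = _collinear_columns(Xd, names)
            raise ValidationError(
                f"design matrix is rank deficient (condition number {cond:.3g}); "
                f"collinear descriptors: {bad}"
            )
        XtX = Xd.T @ Xd
        self._xtx_inv = np.linalg.inv(XtX)
        beta = np.linalg.solve(XtX, Xd.T @ y)
        fitted = Xd @ beta
        residuals = y - fitted
        df = n - p - 1
        rss = float(residuals @ residuals)
        tss = float(np.sum((y - y.mean()) ** 2))

        self.n_features_in_ = p
        self.feature_names_ = names
        self.n_samples_ = n
        self.beta_ = beta
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:].copy()
        self.df_ = df
        self.s_ = float(np.sqrt(rss / df))
        self.r2_ = 1.0 - rss / tss if tss > 0 else 1.0
        self.fitted_ = fitted
        self.residuals_ = residuals
        self.hat_diag_ = np.einsum("ij,jk,ik->i", Xd, self._xtx_inv, Xd)
        self.leverage_cutoff_ = 3.0 * (p + 1) / n
        if self.leverage_cutoff_ > 1.0:
            warnings.warn(
                f"leverage cutoff 3·(p+1)/n = {self.leverage_cutoff_:.3g} exceeds 1; "
                "no chemical can ever fall outside the structural AD",
                stacklevel=2,
            )
        self.y_range_ = (float(y.min()), float(y.max()))
        tq = self._t_quantile(self.alpha)
        train_hw = tq * self.s_ * np.sqrt(1.0 + self.hat_diag_)
        self.halfwidth_range_ = (float(train_hw.min()), float(train_hw.max()))
        return self

    def _t_quantile(self, alpha: float) -> float:
        return float(stats.t.ppf(1.0 - alpha / 2.0, self.df_))

    def _design(self, X) -> np.ndarray:
        X = check_array(X, dtype=np.float64, ensure_2d=True)
        if X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"query has {X.shape[1]} descriptors, model has {self.n_features_in_}"
            )
        return np.column_stack([np.ones(X.shape[0]), X])

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "beta_")
        return self._design(X) @ self.beta_

    def leverage(self, X) -> np.ndarray:
        """h = x̃ (X̃ᵀX̃)⁻¹ x̃ᵀ for each query row, intercept-augmented."""
        check_is_fitted(self, "beta_")
        Xd = self._design(X)
        return np.einsum("ij,jk,ik->i", Xd, self._xtx_inv, Xd)

    def predict_interval(self, X, alpha: Optional[float] = None):
        """Return (ŷ, halfwidth) arrays; halfwidth = t·s·sqrt(1+h)."""
        check_is_fitted(self, "beta_")
        if alpha is None:
            alpha = self.alpha
        Xd = self._design(X)
        yhat = Xd @ self.beta_
        h = np.einsum("ij,jk,ik->i", Xd, self._xtx_inv, Xd)
        hw = self._t_quantile(alpha) * self.s_ * np.sqrt(1.0 + h)
        return yhat, hw

    def standardized_residuals(self) -> np.ndarray:
        """r'_i = r_i / (s·sqrt(1-h_ii)); zero for an exact fit (s = 0)."""
        check_is_fitted(self, "beta_")
        if np.any(self.hat_diag_ >= 1.0 - 1e-12):
            raise ValidationError(
                "a training leverage is (numerically) 1; standardized residuals "
                "are undefined in a saturated direction"
            )
        if self.s_ == 0.0:
            return np.zeros_like(self.residuals_)
        return self.residuals_ / (self.s_ * np.sqrt(1.0 - self.hat_diag_))

    def loo_q2(self) -> float:
        """Leave-one-out Q² via the hat identity: PRESS = Σ (r_i/(1-h_ii))²."""
        check_is_fitted(self, "beta_")
        press = float(np.sum((self.residuals_ / (1.0 - self.hat_diag_)) ** 2))
        tss = float(np.sum((self.fitted_ + self.residuals_ - np.mean(self.fitted_ + self.residuals_)) ** 2))
        return 1.0 - press / tss if tss > 0 else 1.0


def _collinear_columns(Xd: np.ndarray, names: Sequence[str]) -> list:
    """Name the descriptor columns implicated in a rank deficiency (QR pivots)."""
    _, R, piv = qr(Xd, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Xd.shape) * np.finfo(float).eps
    bad_cols = [piv[i] for i in range(len(diag)) if diag[i] <= max(tol, 1e-300)]
    if not bad_cols:  # ill-conditioned but technically full rank: report all
        bad_cols = list(range(1, Xd.shape[1]))
    labels = ["<intercept>"] + list(names)
    return sorted(labels[c] for c in bad_cols)


@dataclass(frozen=True)
class Prediction:
    """A single MLR prediction with uncertainty and AD verdicts."""

    value: float
    halfwidth: float
    interval: tuple
    leverage: float
    structural_in_ad: bool
    endpoint_in_ad: bool
    reasons: tuple = ()
    structural_verdict: ADVerdict | None = None
    endpoint_verdict: ADVerdict | None = None


@dataclass
class MlrModel:
    """A fitted MLR QSA(P)R: descriptor specs, training set, and fit statistics."""

    specs: tuple
    training: tuple
    metadata: ModelMetadata
    estimator: MlrRegressor = field(repr=False)

    # -- fitted statistics, delegated to the estimator ------------------
    @property
    def n(self) -> int:
        return self.estimator.n_samples_

    @property
    def p(self) -> int:
        return self.estimator.n_features_in_

    @property
    def beta(self) -> np.ndarray:
        return self.estimator.beta_

    @property
    def s(self) -> float:
        return self.estimator.s_

    @property
    def r2(self) -> float:
        return self.estimator.r2_

    @property
    def df(self) -> int:
        return self.estimator.df_

    @property
    def hat_diag(self) -> np.ndarray:
        return self.estimator.hat_diag_

    @property
    def residuals(self) -> np.ndarray:
        return self.estimator.residuals_

    @property
    def leverage_cutoff(self) -> float:
        return self.estimator.leverage_cutoff_

    @property
    def y_range(self) -> tuple:
        return self.estimator.y_range_

    @property
    def halfwidth_range(self) -> tuple:
        return self.estimator.halfwidth_range_

    @property
    def model_type(self) -> str:
        return "mlr"

    def descriptor_names(self) -> list:
        return [s.name for s in self.specs]

    def training_matrix(self) -> np.ndarray:
        return np.array([r.descriptor_values for r in self.training], dtype=float)

    def training_y(self) -> np.ndarray:
        return np.array([r.y for r in self.training], dtype=float)

    def predict(self, x, alpha: float = 0.05, y_observed: float | None = None,
                strict_and: bool = False) -> Prediction:
        return prediction_interval(self, x, alpha=alpha, y_observed=y_observed,
                                   strict_and=strict_and)

    def equals(self, other: "MlrModel", tol: float = 1e-12) -> bool:
        """Field-by-field equality with a numeric tolerance (round-trip checks)."""
        if not isinstance(other, MlrModel):
            return False
        if self.specs != other.specs or self.metadata != other.metadata:
            return False
        if len(self.training) != len(other.training):
            return False
        for a, b in zip(self.training, other.training):
            if a.id != b.id or a.smiles != b.smiles:
                return False
            if not np.allclose(a.descriptor_values, b.descriptor_values,
                               rtol=0.0, atol=tol):
                return False
            if abs(a.y - b.y) > tol:
                return False
        return bool(np.allclose(self.beta, other.beta, rtol=0.0, atol=max(tol, 1e-10)))


def fit_mlr(
    specs: Sequence[DescriptorSpec],
    training: Sequence[TrainingRecord],
    metadata: ModelMetadata | None = None,
    alpha: float = 0.05,
) -> MlrModel:
    """Fit an MLR QSA(P)R from descriptor specs and training records."""
    specs = check_specs(specs)
    training = check_training(specs, training)
    X = np.array([r.descriptor_values for r in training], dtype=float)
    y = np.array([float(r.y) for r in training], dtype=float)
    est = MlrRegressor(alpha=alpha)
    est.fit(X, y, feature_names=[s.name for s in specs])
    if metadata is None:
        metadata = ModelMetadata(model_id="mlr_model")
    return MlrModel(specs=specs, training=training, metadata=metadata, estimator=est)


def _as_row(model: MlrModel, x) -> np.ndarray:
    x = np.asarray(x, dtype=float).reshape(-1)
    if x.shape[0] != model.p:
        raise ValidationError(
            f"query has {x.shape[0]} descriptor values, model "
            f"{model.metadata.model_id!r} has {model.p}"
        )
    if np.any(np.isnan(x)):
        j = int(np.flatnonzero(np.isnan(x))[0])
        raise MissingDescriptorError(model.specs[j].name)
    return x.reshape(1, -1)


def leverage(model: MlrModel, x) -> float:
    """Leverage of a query chemical in the model's descriptor space."""
    return float(model.estimator.leverage(_as_row(model, x))[0])


def leverage_cutoff(model: MlrModel) -> float:
    """Structural-AD leverage cutoff, 3·(p+1)/n."""
    return model.leverage_cutoff


def standardized_residuals(model: MlrModel) -> np.ndarray:
    return model.estimator.standardized_residuals()


def structural_ad_check(model: MlrModel, x) -> ADVerdict:
    """Out of the structural AD iff leverage >= 3·(p+1)/n (boundary is out)."""
    h = leverage(model, x)
    cutoff = model.leverage_cutoff
    fail = h >= cutoff
    reasons = (f"leverage {h:.6g} >= cutoff {cutoff:.6g}",) if fail else ()
    return ADVerdict(
        in_ad=not fail,
        criteria={"leverage": CriterionStatus.FAIL if fail else CriterionStatus.PASS},
        details={"leverage": h, "leverage_cutoff": cutoff},
        reasons=reasons,
    )


def endpoint_ad_check(
    model: MlrModel,
    pred: Prediction,
    y_observed: float | None = None,
    strict_and: bool = False,
) -> ADVerdict:
    """Endpoint (response-space) AD check with three criteria.

    (a) standardized residual: |y_obs - ŷ| / (s·sqrt(1-h)) > 2.5 -> fail
        (not applicable without an observed y, or when h >= 1);
    (b) experimental range: ŷ outside [min y, max y] of training -> fail;
    (c) interval range: the prediction halfwidth outside the training
        halfwidth range -> fail.

    By default any applicable failure puts the chemical out of the AD and all
    reasons are recorded.  With ``strict_and=True`` criteria (a) and (b) are
    combined conjunctively (out only if both fail) when (a) is applicable,
    which is the literal conjunction reading; criterion (c) stays independent.
    """
    criteria: dict = {}
    details: dict = {"value": pred.value, "halfwidth": pred.halfwidth,
                     "y_min": model.y_range[0], "y_max": model.y_range[1],
                     "halfwidth_min": model.halfwidth_range[0],
                     "halfwidth_max": model.halfwidth_range[1]}
    reasons: list = []

    # (a) standardized residual
    h = pred.leverage
    if y_observed is None or h >= 1.0 - 1e-12:
        criteria["standardized_residual"] = CriterionStatus.NOT_APPLICABLE
        details["standardized_residual"] = float("nan")
        a_fail = None
    else:
        if model.s == 0.0:
            r_std = 0.0
        else:
            r_std = (y_observed - pred.value) / (model.s * np.sqrt(1.0 - h))
        details["standardized_residual"] = r_std
        a_fail = abs(r_std) > 2.5  # exactly 2.5 is in ("greater than 2.5")
        criteria["standardized_residual"] = (
            CriterionStatus.FAIL if a_fail else CriterionStatus.PASS
        )
        if a_fail:
            reasons.append(f"|standardized residual| {abs(r_std):.4g} > 2.5")

    # (b) experimental range
    lo, hi = model.y_range
    b_fail = pred.value < lo or pred.value > hi
    criteria["experimental_range"] = (
        CriterionStatus.FAIL if b_fail else CriterionStatus.PASS
    )
    if b_fail:
        reasons.append(
            f"prediction {pred.value:.6g} outside training range [{lo:.6g}, {hi:.6g}]"
        )

    # (c) prediction-interval halfwidth range
    hlo, hhi = model.halfwidth_range
    c_fail = pred.halfwidth < hlo or pred.halfwidth > hhi
    criteria["interval_range"] = CriterionStatus.FAIL if c_fail else CriterionStatus.PASS
    if c_fail:
        reasons.append(
            f"halfwidth {pred.halfwidth:.6g} outside training halfwidth range "
            f"[{hlo:.6g}, {hhi:.6g}]"
        )

    if strict_and and a_fail is not None:
        out = (a_fail and b_fail) or c_fail
    else:
        out = any(v is CriterionStatus.FAIL for v in criteria.values())
    return ADVerdict(in_ad=not out, criteria=criteria, details=details,
                     reasons=tuple(reasons))


def prediction_interval(
    model: MlrModel,
    x,
    alpha: float = 0.05,
    y_observed: float | None = None,
    strict_and: bool = False,
) -> Prediction:
    """Predict a query chemical with its interval and both AD verdicts."""
    row = _as_row(model, x)
    yhat, hw = model.estimator.predict_interval(row, alpha=alpha)
    value, halfwidth = float(yhat[0]), float(hw[0])
    h = float(model.estimator.leverage(row)[0])
    base = Prediction(
        value=value,
        halfwidth=halfwidth,
        interval=(value - halfwidth, value + halfwidth),
        leverage=h,
        structural_in_ad=True,
        endpoint_in_ad=True,
    )
    sv = structural_ad_check(model, x)
    ev = endpoint_ad_check(model, base, y_observed=y_observed, strict_and=strict_and)
    return Prediction(
        value=value,
        halfwidth=halfwidth,
        interval=(value - halfwidth, value + halfwidth),
        leverage=h,
        structural_in_ad=sv.in_ad,
        endpoint_in_ad=ev.in_ad,
        reasons=sv.reasons + ev.reasons,
        structural_verdict=sv,
        endpoint_verdict=ev,
    )
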