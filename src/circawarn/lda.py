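"""Two-class linear discriminant for 3-day early warning.

The classifier is Fisher's linear discriminant with a small ridge on the
pooled within-class covariance: features are standardized, the
coefficient vector is ``(S_w + ridge_rel * mean(diag(S_w)) * I)^-1
(mu_1 - mu_0)``, and the decision threshold sits at the midpoint of the
projected class means under equal priors.  Unequal priors shift the
threshold by the log prior ratio, as in classical discriminant
analysis.  Larger discriminant scores are more event-like; a score
exactly at the threshold is classified negative (conservative for an
alarm system).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NumericalError, SchemaError, UnfittableError

__all__ = [
    "LDAModel",
    "ConfusionMatrix",
    "MetricsReport",
    "fit_lda",
    "discriminant_score",
    "classify",
    "evaluate",
    "metrics",
    "rank_coefficients",
    "run_experiment",
    "ExperimentResult",
]

DEFAULT_RIDGE = 1e-6  # relative to the mean diagonal of the pooled covariance


@dataclass
class LDAModel:
    """Fitted linear discriminant.

    ``center``/``scale`` are the per-feature standardization parameters
    (identity when the model was fitted unstandardized); ``coef`` holds
    one coefficient per feature in fixed feature order; ``threshold``
    is the decision cut on the discriminant score.  ``ridge`` is the
    relative ridge used on the pooled covariance.  ``degenerate`` flags
    a fit with identical class means (all-zero coefficients).
    """

    feature_names: tuple[str, ...]
    center: np.ndarray
    scale: np.ndarray
    coef: np.ndarray
    threshold: float
    priors: tuple[float, float] = (0.5, 0.5)
    ridge: float = DEFAULT_RIDGE
    degenerate: bool = False
    n_train: int = 0
    n_positive: int = 0

    def __post_init__(self) -> None:
        self.feature_names = tuple(self.feature_names)
        self.center = np.asarray(self.center, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        self.coef = np.asarray(self.coef, dtype=float)
        k = len(self.feature_names)
        if not (self.center.size == self.scale.size == self.coef.size == k):
            raise SchemaError("model parameter vectors must match feature count")
        if np.any(self.scale <= 0):
            raise SchemaError("scale parameters must be positive")

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "coef": self.coef.tolist(),
            "threshold": self.threshold,
            "priors": list(self.priors),
            "ridge": self.ridge,
            "degenerate": self.degenerate,
            "n_train": self.n_train,
            "n_positive": self.n_positive,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "LDAModel":
        return cls(
            feature_names=tuple(d["feature_names"]),
            center=np.asarray(d["center"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            coef=np.asarray(d["coef"], dtype=float),
            threshold=float(d["threshold"]),
            priors=tuple(d["priors"]),
            ridge=float(d["ridge"]),
            degenerate=bool(d.get("degenerate", False)),
            n_train=int(d.get("n_train", 0)),
            n_positive=int(d.get("n_positive", 0)),
        )

    @classmethod
    def from_json(cls, path) -> "LDAModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class ConfusionMatrix:
    """Patient-day counts by (predicted, actual)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    """Percentages derived from a confusion matrix.

    A metric whose denominator is zero is undefined and reported as
    ``None`` (never as 0).
    """

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None
    confusion: ConfusionMatrix | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "accuracy": self.accuracy,
        }
        if self.confusion is not None:
            d["confusion"] = {
                "tp": self.confusion.tp,
                "fp": self.confusion.fp,
                "fn": self.confusion.fn,
                "tn": self.confusion.tn,
            }
        return d


def _as_matrix(X, feature_names=None):
    if isinstance(X, pd.DataFrame):
        if feature_names is not None:
            missing = [c for c in feature_names if c not in X.columns]
            if missing:
                raise SchemaError(f"feature columns missing: {missing}")
            X = X[list(feature_names)]
        names = tuple(X.columns)
        return X.to_numpy(dtype=float), names
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(1, -1)
    if feature_names is None:
        names = tuple(f"x{i}" for i in range(arr.shape[1]))
    else:
        names = tuple(feature_names)
    return arr, names


def fit_lda(
    X,
    y,
    ridge: float = DEFAULT_RIDGE,
    standardize: bool = True,
    priors: tuple[float, float] | None = None,
    feature_names=None,
) -> LDAModel:
    """Fit the regularized linear discriminant.

    Parameters
    ----------
    X
        Feature matrix (DataFrame or array), valid rows only.
    y
        Boolean labels (True = pre-admission day).
    ridge
        Relative ridge: the pooled within-class covariance receives
        ``ridge * mean(diag)`` on its diagonal.  With 21 features and
        few positive days the pooled covariance is easily
        near-singular; the tiny default stabilizes the solve without
        materially biasing the direction.
    standardize
        Centre and scale features before fitting (default), making the
        coefficients rank-comparable across items on different scales.
    priors
        Class priors ``(pi_0, pi_1)``; ``None`` means equal priors, i.e.
        the threshold is the midpoint of the projected class means.

    The fit is fully deterministic.
    """
    Xa, names = _as_matrix(X, feature_names)
    y = np.asarray(y, dtype=bool).ravel()
    if Xa.shape[0] != y.size:
        raise SchemaError("X and y have different numbers of rows")
    n, k = Xa.shape
    n1 = int(y.sum())
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        raise UnfittableError(
            "both classes must be present to fit the discriminant "
            f"(got {n1} positives of {n} rows)"
        )
    if n < k + 2:
        raise UnfittableError(f"need at least {k + 2} rows for {k} features, got {n}")
    if np.isnan(Xa).any():
        raise SchemaError("feature matrix contains missing values")

    if standardize:
        center = Xa.mean(axis=0)
        scale = Xa.std(axis=0, ddof=1)
        scale = np.where(scale > 0, scale, 1.0)  # constant feature: leave unscaled
    else:
        center = np.zeros(k)
        scale = np.ones(k)
    Z = (Xa - center) / scale

    mu0 = Z[~y].mean(axis=0)
    mu1 = Z[y].mean(axis=0)
    d0 = Z[~y] - mu0
    d1 = Z[y] - mu1
    pooled = (d0.T @ d0 + d1.T @ d1) / (n - 2)

    mean_diag = float(np.mean(np.diag(pooled)))
    if mean_diag <= 0:
        mean_diag = 1.0
    reg = pooled + ridge * mean_diag * np.eye(k)
    diff = mu1 - mu0
    degenerate = bool(np.allclose(diff, 0.0))
    try:
        coef = np.linalg.solve(reg, diff)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            "singular pooled covariance; refit with ridge > 0"
        ) from exc

    m0 = float(coef @ mu0)
    m1 = float(coef @ mu1)
    threshold = (m0 + m1) / 2.0
    if priors is None:
        priors_t = (0.5, 0.5)
    else:
        p0, p1 = float(priors[0]), float(priors[1])
        if p0 <= 0 or p1 <= 0:
            raise SchemaError("priors must be positive")
        s = p0 + p1
        priors_t = (p0 / s, p1 / s)
        # Gaussian equal-covariance decision rule: the prior ratio
        # shifts the cut by log(pi0/pi1) in score units per unit of
        # projected mean separation.
        sep = m1 - m0
        if sep != 0:
            sigma2 = float(coef @ reg @ coef)
            threshold = (m0 + m1) / 2.0 + sigma2 * np.log(priors_t[0] / priors_t[1]) / sep

    return LDAModel(
        feature_names=names,
        center=center,
        scale=scale,
        coef=coef,
        threshold=threshold,
        priors=priors_t,
        ridge=ridge,
        degenerate=degenerate,
        n_train=n,
        n_positive=n1,
    )


def discriminant_score(model: LDAModel, rows) -> np.ndarray:
    """Discriminant score(s): standardized features dotted with the
    coefficients.  Larger scores are more event-like."""
    Xa, names = _as_matrix(rows, model.feature_names if isinstance(rows, pd.DataFrame) else None)
    if isinstance(rows, pd.DataFrame):
        pass  # _as_matrix already selected/ordered the columns
    elif Xa.shape[1] != len(model.feature_names):
        raise SchemaError(
            f"expected {len(model.feature_names)} features, got {Xa.shape[1]}"
        )
    if np.isnan(Xa).any():
        raise SchemaError("feature rows contain missing values")
    Z = (Xa - model.center) / model.scale
    return Z @ model.coef


def classify(model: LDAModel, rows) -> np.ndarray:
    """Predicted labels: positive iff score strictly exceeds the
    threshold (ties negative)."""
    return discriminant_score(model, rows) > model.threshold


def evaluate(predicted, actual) -> ConfusionMatrix:
    """Confusion matrix of aligned predicted/actual boolean vectors."""
    p = np.asarray(predicted, dtype=bool).ravel()
    a = np.asarray(actual, dtype=bool).ravel()
    if p.size != a.size:
        raise SchemaError(f"length mismatch: {p.size} predictions, {a.size} labels")
    return ConfusionMatrix(
        tp=int(np.count_nonzero(p & a)),
        fp=int(np.count_nonzero(p & ~a)),
        fn=int(np.count_nonzero(~p & a)),
        tn=int(np.count_nonzero(~p & ~a)),
    )


def _pct(num: int, den: int) -> float | None:
    return 100.0 * num / den if den > 0 else None


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Sensitivity, specificity, PPV, NPV and accuracy in percent."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return MetricsReport(
        sensitivity=_pct(cm.tp, cm.tp + cm.fn),
        specificity=_pct(cm.tn, cm.tn + cm.fp),
        ppv=_pct(cm.tp, cm.tp + cm.fp),
        npv=_pct(cm.tn, cm.tn + cm.fn),
        accuracy=_pct(cm.tp + cm.tn, cm.total),
        confusion=cm,
    )


def rank_coefficients(model: LDAModel) -> pd.DataFrame:
    """Features sorted by descending absolute coefficient (signed values
    reported); ties broken by the fixed feature order."""
    order = sorted(
        range(len(model.feature_names)),
        key=lambda i: (-abs(model.coef[i]), i),
    )
    return pd.DataFrame(
        {
            "parameter": [model.feature_names[i] for i in order],
            "coefficient": [model.coef[i] for i in order],
        }
    )


@dataclass
class ExperimentResult:
    model: LDAModel
    confusion: ConfusionMatrix
    report: MetricsReport
    predictions: pd.DataFrame
    mode: str
    train_day_limit: int


def run_experiment(
    feature_set,
    train_day_limit: int = 30,
    mode: str = "whole",
    ridge: float = DEFAULT_RIDGE,
    standardize: bool = True,
    priors: tuple[float, float] | str | None = "empirical",
    threshold: float | None = None,
) -> ExperimentResult:
    """Fit on the early monitoring span and evaluate the early-warning rule.

    The model learns from valid patient-days with day number at most
    ``train_day_limit``.  ``mode='whole'`` evaluates on all valid days
    (learning span plus the later validation span together);
    ``mode='split'`` evaluates on the later days only.  ``threshold``
    overrides the fitted decision cut when given.

    ``priors='empirical'`` (default) uses the training-span class
    frequencies, so the decision cut accounts for pre-admission days
    being rare; pass ``None`` for the equal-prior midpoint, or an
    explicit ``(pi_0, pi_1)`` pair.
    """
    if mode not in ("whole", "split"):
        raise ValueError("mode must be 'whole' or 'split'")
    rows = feature_set.valid_rows()
    names = list(feature_set.feature_names)
    train = rows[rows["day"] <= train_day_limit]
    if train.empty or not train["label"].any():
        raise UnfittableError(
            "no positive patient-days in the training span; extend "
            "train_day_limit or check the event table"
        )
    if isinstance(priors, str):
        if priors != "empirical":
            raise ValueError("priors must be 'empirical', None or a pair")
        p1 = float(train["label"].mean())
        priors = (1.0 - p1, p1)
    model = fit_lda(
        train[names],
        train["label"],
        ridge=ridge,
        standardize=standardize,
        priors=priors,
    )
    if threshold is not None:
        model.threshold = float(threshold)

    eval_rows = rows if mode == "whole" else rows[rows["day"] > train_day_limit]
    scores = discriminant_score(model, eval_rows[names])
    predicted = scores > model.threshold
    cm = evaluate(predicted, eval_rows["label"])
    predictions = pd.DataFrame(
        {
            "patient_id": eval_rows["patient_id"].to_numpy(),
            "date": eval_rows["date"].to_numpy(),
            "score": scores,
            "predicted": predicted,
            "actual": eval_rows["label"].to_numpy(dtype=bool),
        }
    )
    return ExperimentResult(
        model=model,
        confusion=cm,
        report=metrics(cm),
        predictions=predictions,
        mode=mode,
        train_day_limit=train_day_limit,
    )
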