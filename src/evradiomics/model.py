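"""Combined ΔEV PD-L1 + radiomics logistic model of durable non-response.

The positive class throughout is the **non-responder** (progressive disease
at the ~6-month evaluation): the model predicts the probability of durable
non-response, AUCs are "to predict non-responders", and sensitivity counts
correctly flagged non-responders.  Responders are patients with partial
response or stable disease at 21 ± 3 weeks (configurable rule).

The 6 selected radiomic features and the dynamic EV PD-L1 change are
z-scored on the training data before a maximum-likelihood logistic fit, so
coefficients are on a comparable per-SD scale.  Perfect separation — likely
at cohort sizes of a few dozen — triggers a ridge (small-L2) fallback with
a warning.  The high/low cutoff is the Youden-index-optimal threshold on
training scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve

from .errors import ParameterError, UndefinedAUCError, ValidationError

__all__ = [
    "CombinedModel",
    "ROCResult",
    "DichotomyResult",
    "delta_ev",
    "fit_combined",
    "score",
    "roc_auc",
    "youden_cutoff",
    "dichotomize",
]

LABEL_COL = "durable_responder"
DELTA_COL = "delta_ev_pdl1"


def delta_ev(baseline_level: float, on_treatment_level: float, mode: str = "relative") -> float:
    """Dynamic EV PD-L1 change between baseline and early on-treatment.

    ``relative`` (default): (on - base) / base; ``absolute``: on - base;
    ``log_ratio``: log(on / base).
    """
    base = float(baseline_level)
    on = float(on_treatment_level)
    if mode == "relative":
        if base == 0:
            raise ValidationError("baseline level must be nonzero for relative change")
        return (on - base) / base
    if mode == "absolute":
        return on - base
    if mode == "log_ratio":
        if base <= 0 or on <= 0:
            raise ValidationError("log-ratio mode requires positive levels")
        return float(np.log(on / base))
    raise ParameterError(f"unknown delta mode {mode!r}")


@dataclass
class CombinedModel:
    """Fitted logistic model over 6 radiomic features + ΔEV PD-L1."""

    feature_names: list[str]          # the 6 radiomic feature columns
    input_names: list[str]            # feature_names + [delta column]
    mean_: np.ndarray                 # standardization per input
    std_: np.ndarray
    intercept_: float
    coef_: np.ndarray                 # one weight per input
    coef_se_: np.ndarray | None = None
    intercept_se_: float | None = None
    cutoff: float = 0.5
    separation_fallback: bool = False

    def __post_init__(self) -> None:
        if len(self.feature_names) != 6:
            raise ParameterError(f"model requires exactly 6 radiomic features, "
                                 f"got {len(self.feature_names)}")
        if not np.all(np.isfinite(self.coef_)) or not np.isfinite(self.intercept_):
            raise ValidationError("model coefficients must be finite")

    def to_json(self, path=None) -> str:
        payload = {
            "feature_names": self.feature_names,
            "input_names": self.input_names,
            "mean": self.mean_.tolist(),
            "std": self.std_.tolist(),
            "intercept": self.intercept_,
            "coef": self.coef_.tolist(),
            "coef_se": None if self.coef_se_ is None else self.coef_se_.tolist(),
            "intercept_se": self.intercept_se_,
            "cutoff": self.cutoff,
            "separation_fallback": self.separation_fallback,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CombinedModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            feature_names=payload["feature_names"],
            input_names=payload["input_names"],
            mean_=np.asarray(payload["mean"]),
            std_=np.asarray(payload["std"]),
            intercept_=payload["intercept"],
            coef_=np.asarray(payload["coef"]),
            coef_se_=None if payload["coef_se"] is None else np.asarray(payload["coef_se"]),
            intercept_se_=payload.get("intercept_se"),
            cutoff=payload["cutoff"],
            separation_fallback=payload["separation_fallback"],
        )


@dataclass
class ROCResult:
    auc: float
    thresholds: np.ndarray
    sensitivity: np.ndarray  # TPR at each threshold
    specificity: np.ndarray  # 1 - FPR
    arm: str = ""


@dataclass
class DichotomyResult:
    high: np.ndarray          # score >= cutoff
    sensitivity: float
    specificity: float
    table: np.ndarray         # 2x2 counts [[TP, FN], [FP, TN]]


def _design(records: pd.DataFrame, input_names: Sequence[str]) -> np.ndarray:
    missing = [c for c in input_names if c not in records.columns]
    if missing:
        raise ValidationError(f"records are missing model inputs: {missing}")
    X = records.loc[:, list(input_names)].to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValidationError("model inputs contain non-finite values")
    return X


def fit_combined(records: pd.DataFrame, feature_names: Sequence[str],
                 delta_col: str = DELTA_COL, label_col: str = LABEL_COL,
                 ridge_alpha: float = 1.0) -> CombinedModel:
    """Maximum-likelihood logistic fit of non-response on the standardized
    6 radiomic features + ΔEV PD-L1.

    The binary outcome is 1 for non-responders (``label_col`` False).
    Standardization parameters are estimated on the training records.  If
    the MLE does not exist (perfect separation) or fails to converge, the
    fit falls back to an L2-penalized solution with a warning and no
    standard errors.
    """
    feature_names = list(feature_names)
    if len(feature_names) != 6:
        raise ParameterError(f"exactly 6 radiomic features required, got {len(feature_names)}")
    input_names = feature_names + [delta_col]
    X = _design(records, input_names)
    if label_col not in records.columns:
        raise ValidationError(f"records lack label column {label_col!r}")
    y = 1.0 - records[label_col].astype(bool).to_numpy().astype(np.float64)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValidationError("need at least 2 records in each response class")

    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=0)
    if np.any(std == 0):
        bad = [input_names[k] for k in np.where(std == 0)[0]]
        raise ValidationError(f"constant model inputs cannot be standardized: {bad}")
    Z = (X - mean) / std

    intercept_se = None
    coef_se = None
    fallback = False
    try:
        from statsmodels.tools.sm_exceptions import ConvergenceWarning
        with warnings.catch_warnings():
            warnings.simplefilter("error", RuntimeWarning)
            warnings.simplefilter("error", ConvergenceWarning)
            res = sm.Logit(y, sm.add_constant(Z)).fit(disp=0, maxiter=200)
        params = np.asarray(res.params)
        converged = bool(res.mle_retvals.get("converged", False))
        if not converged or not np.all(np.isfinite(params)) or np.abs(params).max() > 50:
            raise np.linalg.LinAlgError("separation suspected")
        bse = np.asarray(res.bse)
        intercept = float(params[0])
        coef = params[1:]
        intercept_se = float(bse[0])
        coef_se = bse[1:]
    except Exception:
        warnings.warn("logistic MLE unstable (perfect separation likely); "
                      "refitting with an L2 penalty", stacklevel=2)
        clf = LogisticRegression(C=1.0 / ridge_alpha, solver="lbfgs", max_iter=1000)
        clf.fit(Z, y)
        intercept = float(clf.intercept_[0])
        coef = clf.coef_[0].astype(np.float64)
        fallback = True

    model = CombinedModel(
        feature_names=feature_names, input_names=input_names,
        mean_=mean, std_=std, intercept_=intercept, coef_=np.asarray(coef),
        coef_se_=None if coef_se is None else np.asarray(coef_se),
        intercept_se_=intercept_se, separation_fallback=fallback,
    )
    model.cutoff = youden_cutoff(score(model, records), y)
    return model


def score(model: CombinedModel, records: pd.DataFrame) -> np.ndarray:
    """Probability of durable non-response for each record."""
    X = _design(records, model.input_names)
    Z = (X - model.mean_) / model.std_
    eta = model.intercept_ + Z @ model.coef_
    return 1.0 / (1.0 + np.exp(-eta))


def roc_auc(scores: np.ndarray, labels: np.ndarray, arm: str = "") -> ROCResult:
    """ROC over all thresholds with trapezoidal AUC (labels: 1 = non-responder).

    Midrank tie handling makes the AUC equal the Mann-Whitney U statistic
    divided by n1*n0.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must have the same length")
    if labels.min() == labels.max():
        raise UndefinedAUCError(f"AUC undefined: arm subset {arm!r} has a single class")
    fpr, tpr, thr = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(auc=auc, thresholds=thr, sensitivity=tpr, specificity=1.0 - fpr, arm=arm)


def youden_cutoff(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximizing sensitivity + specificity - 1 on the given data.

    Ties are broken toward the highest qualifying threshold (the first
    maximum on the descending threshold grid), a deterministic rule.
    """
    roc = roc_auc(scores, labels)
    j = roc.sensitivity + roc.specificity - 1.0
    return float(roc.thresholds[int(np.argmax(j))])


def dichotomize(model: CombinedModel, records: pd.DataFrame,
                label_col: str = LABEL_COL) -> DichotomyResult:
    """Split patients at the model cutoff and report sensitivity/specificity
    for identifying non-responders (high score = predicted non-responder)."""
    s = score(model, records)
    y = 1 - records[label_col].astype(bool).to_numpy().astype(int)
    high = s >= model.cutoff
    tp = int(np.sum(high & (y == 1)))
    fn = int(np.sum(~high & (y == 1)))
    fp = int(np.sum(high & (y == 0)))
    tn = int(np.sum(~high & (y == 0)))
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return DichotomyResult(high=high, sensitivity=sens, specificity=spec,
                           table=np.array([[tp, fn], [fp, tn]]))
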