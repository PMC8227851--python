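"""LOOCV eye-colour prediction models and their error measures.

For a given SNP panel and reporting system, each sample is predicted by a
model trained on all other samples (leave-one-out cross-validation):

quantitative
    linear regression of the transformed PIE-score; error is the mean
    squared error on the transformed scale;
two-category
    binomial logistic regression with blue = 1, brown = 0; error is the
    mean negative log-probability assigned to the true category;
three-category
    multinomial logistic regression over blue/intermediate/brown; error is
    the mean Kullback-Leibler divergence from the one-hot truth, i.e. the
    mean of -log p(observed category).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort, encode_cohort
from .glm import fit_linear, fit_multinomial, softmax_probs
from .panels import PanelDef
from .transforms import (
    THREE_CATEGORY,
    TWO_CATEGORY,
    inverse_transform,
    transform_pie,
)

__all__ = [
    "FittedModel",
    "LOOCVResult",
    "fit_system_model",
    "loocv_predict",
    "prediction_error",
    "SYSTEMS",
]

SYSTEMS = ("quantitative", "two_category", "three_category")
PROB_CLIP = 1e-12

#: class order of categorical fits; the last class is the GLM reference
TWO_CLASSES = ("blue", "brown")
THREE_CLASSES = ("blue", "intermediate", "brown")


@dataclass
class FittedModel:
    """Coefficients of one reporting-system model on a fixed variable set."""

    system: str
    variables: tuple
    coef: np.ndarray  # quantitative: (p,); categorical: (K-1, p+1) with intercepts
    intercept: float  # quantitative only; 0.0 otherwise
    classes: tuple
    panel_name: str = ""

    def predict(self, values: pd.DataFrame):
        """Predict from coded genotypes.

        quantitative: Series of transformed-scale predictions; categorical:
        DataFrame of class probabilities (columns in ``self.classes``,
        rows summing to one).
        """
        X = values[list(self.variables)].to_numpy(dtype=float)
        if self.system == "quantitative":
            return pd.Series(self.intercept + X @ self.coef, index=values.index)
        eta = np.column_stack([np.ones(len(X)), X]) @ self.coef.T
        probs = softmax_probs(eta)
        return pd.DataFrame(probs, index=values.index, columns=list(self.classes))


def _class_index(labels, classes) -> np.ndarray:
    lut = {c: i for i, c in enumerate(classes)}
    return np.array([lut[l] for l in labels])


def fit_system_model(
    values: pd.DataFrame, pie: pd.Series, system: str, panel_name: str = ""
) -> FittedModel:
    """Fit one reporting-system model on coded genotypes + PIE-scores."""
    pie = pie.loc[values.index]
    X = values.to_numpy(dtype=float)
    if system == "quantitative":
        y = transform_pie(pie.to_numpy())
        b0, coef = fit_linear(X, y)
        return FittedModel(system, tuple(values.columns), coef, b0, (), panel_name)
    if system == "two_category":
        classes = TWO_CLASSES
        labels = TWO_CATEGORY.categorise(pie.to_numpy())
    elif system == "three_category":
        classes = THREE_CLASSES
        labels = THREE_CATEGORY.categorise(pie.to_numpy())
    else:
        raise ValueError(f"unknown reporting system {system!r}")
    present = [c for c in classes if c in set(labels)]
    if len(present) < 2:
        raise ValueError(f"{system}: single category in training data")
    y_idx = _class_index(labels, present)
    B = fit_multinomial(X, y_idx, len(present))
    if len(present) < len(classes):
        # absent categories get probability ~0: logit -inf is represented by
        # rebuilding B over the full class set with a large negative intercept
        B = _expand_classes(B, present, classes)
    return FittedModel(system, tuple(values.columns), B, 0.0, classes, panel_name)


_ABSENT_LOGIT = -1e3


def _expand_classes(B, present, classes):
    # per-class logit vectors relative to the fitted (present) reference;
    # absent classes get intercept -1e3 (probability ~0), then everything is
    # re-expressed relative to the full class set's reference class
    p1 = B.shape[1]
    logits = {c: np.zeros(p1) for c in classes}
    for k, c in enumerate(present[:-1]):
        logits[c] = B[k]
    for c in classes:
        if c not in present:
            v = np.zeros(p1)
            v[0] = _ABSENT_LOGIT
            logits[c] = v
    base = logits[classes[-1]]
    return np.vstack([logits[c] - base for c in classes[:-1]])


@dataclass
class LOOCVResult:
    """Per-sample out-of-sample predictions plus the scalar error."""

    per_sample: pd.DataFrame
    system: str
    panel_name: str
    error: float = np.nan

    @property
    def n(self) -> int:
        return len(self.per_sample)

    def prob_matrix(self) -> pd.DataFrame:
        classes = TWO_CLASSES if self.system == "two_category" else THREE_CLASSES
        return self.per_sample[[f"p_{c}" for c in classes]].rename(
            columns=lambda c: c[2:]
        )


def loocv_predict(cohort: Cohort, panel: PanelDef, system: str) -> LOOCVResult:
    """Leave-one-out predictions for every complete-profile sample.

    Each sample is predicted by a model fitted on the remaining n-1
    samples; the scalar error is attached via :func:`prediction_error`.
    """
    coded = encode_cohort(cohort, panel, on_missing="drop")
    values = coded.values
    if len(values) < 10:
        raise ValueError("LOOCV needs at least 10 complete samples")
    pie = cohort.pie.loc[values.index]
    rows = []
    for sid in values.index:
        rest = values.drop(index=sid)
        try:
            model = fit_system_model(rest, pie.drop(index=sid), system, panel.name)
        except Exception as exc:
            raise RuntimeError(f"LOOCV refit failed leaving out {sid!r}: {exc}") from exc
        pred = model.predict(values.loc[[sid]])
        if system == "quantitative":
            y_true = transform_pie(float(pie.loc[sid]))
            y_pred = float(pred.iloc[0])
            rows.append(
                {
                    "sample_id": sid,
                    "pie_true": float(pie.loc[sid]),
                    "y_true": y_true,
                    "y_pred": y_pred,
                    "pie_pred": inverse_transform(y_pred),
                }
            )
        else:
            sys_obj = TWO_CATEGORY if system == "two_category" else THREE_CATEGORY
            truth = sys_obj.categorise(float(pie.loc[sid]))
            row = {"sample_id": sid, "truth": truth}
            for c in pred.columns:
                row[f"p_{c}"] = float(pred[c].iloc[0])
            rows.append(row)
    per_sample = pd.DataFrame(rows).set_index("sample_id")
    result = LOOCVResult(per_sample=per_sample, system=system, panel_name=panel.name)
    result.error = prediction_error(result)
    return result


def prediction_error(result: LOOCVResult) -> float:
    """The reporting system's scalar out-of-sample error (see module docs).

    Probabilities are clipped to [1e-12, 1 - 1e-12] before taking logs.
    """
    df = result.per_sample
    if len(df) == 0:
        raise ValueError("empty LOOCV result")
    if result.system == "quantitative":
        return float(np.mean((df["y_pred"] - df["y_true"]) ** 2))
    p_true = np.array(
        [df.loc[i, f"p_{df.loc[i, 'truth']}"] for i in df.index], dtype=float
    )
    p_true = np.clip(p_true, PROB_CLIP, 1 - PROB_CLIP)
    return float(-np.mean(np.log(p_true)))
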