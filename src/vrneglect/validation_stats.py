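"""Diagnostic-accuracy statistics and Poisson risk models.

Compares a binary reference assessment (e.g. pen-and-paper neglect
screening) against the three-class VR labels.  Two cross-tabulations are
supported: Model 1 keeps all three VR classes (the binary predictor's
"minor atypicality" row exists with zero counts), Model 2 pools
non-neglect and minor atypicality into a single not-neglect class.

All confusion metrics follow the standard one-vs-rest formulas
(sensitivity TP/(TP+FN) through detection prevalence (TP+FP)/n); overall
accuracy carries an exact Clopper–Pearson 95% CI and an exact one-sided
binomial test against the no-information rate (always guessing the most
prevalent class).  Agreement beyond chance is Cohen's
κ = (P_o − P_c)/(1 − P_c).  Undefined metrics (zero denominators)
propagate as ``nan``, never silently as 0.

Risk modelling: univariable Poisson regression (log link, ML fit) of the
atypicality count on one covariate; effect sizes are incidence rate
ratios (exponentiated coefficients) with Wald 95% CIs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ConfusionResult",
    "RiskModelResult",
    "crosstab",
    "class_metrics",
    "overall_accuracy",
    "null_accuracy",
    "accuracy_vs_null_test",
    "cohen_kappa",
    "confusion_analysis",
    "poisson_risk",
]

PREDICTOR_CLASSES = ("neglect", "non_neglect", "minor_atypicality")
TRUTH_CLASSES = ("neglect", "non_neglect", "minor_atypicality")
MERGED_CLASSES = ("neglect", "not_neglect")


def crosstab(
    predictor_labels: Sequence[str],
    truth_labels: Sequence[str],
    merge_minor: bool = False,
) -> pd.DataFrame:
    """Cross-tabulate predictor (rows) against truth (columns).

    Model 1 (``merge_minor=False``): rows and columns over all three
    classes, including the predictor's empty minor-atypicality row.
    Model 2 (``merge_minor=True``): non-neglect and minor atypicality are
    pooled into ``not_neglect`` on both axes.

    Raises
    ------
    ValueError
        On empty or unequal-length inputs or unknown label values.
    """
    pred = pd.Series(list(predictor_labels), dtype=object)
    truth = pd.Series(list(truth_labels), dtype=object)
    if len(pred) == 0:
        raise ValueError("empty label sequences")
    if len(pred) != len(truth):
        raise ValueError("predictor and truth label sequences differ in length")
    bad = set(pred) - set(PREDICTOR_CLASSES)
    bad |= set(truth) - set(TRUTH_CLASSES)
    if bad:
        raise ValueError(f"unknown label values: {sorted(bad)}")
    if merge_minor:
        mapping = {
            "neglect": "neglect",
            "non_neglect": "not_neglect",
            "minor_atypicality": "not_neglect",
        }
        pred = pred.map(mapping)
        truth = truth.map(mapping)
        classes = MERGED_CLASSES
    else:
        classes = TRUTH_CLASSES
    matrix = pd.crosstab(pred, truth)
    matrix = matrix.reindex(index=classes, columns=classes, fill_value=0)
    matrix.index.name = "predictor"
    matrix.columns.name = "truth"
    return matrix


def _one_vs_rest(matrix: pd.DataFrame, positive_class: str) -> tuple[int, int, int, int]:
    if positive_class not in matrix.columns:
        raise ValueError(f"unknown class {positive_class!r}")
    tp = int(matrix.loc[positive_class, positive_class])
    fn = int(matrix[positive_class].sum() - tp)
    fp = int(matrix.loc[positive_class].sum() - tp)
    tn = int(matrix.values.sum() - tp - fn - fp)
    return tp, fn, fp, tn


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else math.nan


def class_metrics(matrix: pd.DataFrame, positive_class: str) -> dict[str, float]:
    """The nine one-vs-rest statistics for ``positive_class``, as proportions."""
    tp, fn, fp, tn = _one_vs_rest(matrix, positive_class)
    n = tp + fn + fp + tn
    sensitivity = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, fp + tn)
    prevalence = _safe_div(tp + fn, n)
    ppv_num = sensitivity * prevalence
    ppv_den = ppv_num + (1 - specificity) * (1 - prevalence)
    ppv = _safe_div(ppv_num, ppv_den) if not math.isnan(ppv_den) else math.nan
    npv_num = specificity * (1 - prevalence)
    npv_den = (1 - sensitivity) * prevalence + npv_num
    npv = _safe_div(npv_num, npv_den) if not math.isnan(npv_den) else math.nan
    precision = ppv
    f1 = (
        _safe_div(2 * precision * sensitivity, precision + sensitivity)
        if not (math.isnan(precision) or math.isnan(sensitivity))
        else math.nan
    )
    return {
        "sensitivity": sensitivity,
        "specificity": specificity,
        "balanced_accuracy": (sensitivity + specificity) / 2,
        "ppv": ppv,
        "npv": npv,
        "f1": f1,
        "prevalence": prevalence,
        "detection_rate": _safe_div(tp, n),
        "detection_prevalence": _safe_div(tp + fp, n),
    }


def overall_accuracy(matrix: pd.DataFrame) -> tuple[float, tuple[float, float]]:
    """Agreement proportion with its exact (Clopper–Pearson) 95% CI."""
    n = int(matrix.values.sum())
    if n < 1:
        raise ValueError("empty matrix")
    agree = int(sum(matrix.loc[c, c] for c in matrix.columns if c in matrix.index))
    ci = stats.binomtest(agree, n).proportion_ci(confidence_level=0.95, method="exact")
    return agree / n, (float(ci.low), float(ci.high))


def null_accuracy(truth_labels_or_matrix) -> float:
    """No-information rate: frequency of the most prevalent truth class."""
    if isinstance(truth_labels_or_matrix, pd.DataFrame):
        counts = truth_labels_or_matrix.sum(axis=0)
    else:
        counts = pd.Series(list(truth_labels_or_matrix)).value_counts()
        if not len(counts):
            raise ValueError("empty truth labels")
    return float(counts.max() / counts.sum())


def accuracy_vs_null_test(correct: int, n: int, null_p: float) -> float:
    """Exact one-sided binomial tail P(X >= correct | n, null_p)."""
    if not 0 <= correct <= n:
        raise ValueError("need 0 <= correct <= n")
    if not 0 < null_p < 1:
        raise ValueError("null_p must be in (0, 1)")
    return float(stats.binom.sf(correct - 1, n, null_p))


def cohen_kappa(matrix: pd.DataFrame) -> float:
    """Cohen's κ = (P_o − P_c)/(1 − P_c) on a square-aligned matrix."""
    classes = sorted(set(matrix.index) | set(matrix.columns))
    m = matrix.reindex(index=classes, columns=classes, fill_value=0).to_numpy(float)
    n = m.sum()
    if n == 0:
        raise ValueError("empty matrix")
    po = np.trace(m) / n
    pc = float(m.sum(axis=1) @ m.sum(axis=0)) / n**2
    if pc == 1:
        return math.nan
    return float((po - pc) / (1 - pc))


@dataclass
class ConfusionResult:
    """Cross-tabulation plus the full set of validation statistics."""

    matrix: pd.DataFrame
    model: str
    accuracy: float
    accuracy_ci95: tuple[float, float]
    null_accuracy: float
    p_vs_null: float
    kappa: float
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)


def confusion_analysis(
    predictor_labels: Sequence[str],
    truth_labels: Sequence[str],
    merge_minor: bool = False,
) -> ConfusionResult:
    """Full confusion analysis of one model (1: three-class, 2: merged)."""
    matrix = crosstab(predictor_labels, truth_labels, merge_minor=merge_minor)
    acc, ci = overall_accuracy(matrix)
    null_p = null_accuracy(matrix)
    n = int(matrix.values.sum())
    agree = round(acc * n)
    p = accuracy_vs_null_test(int(agree), n, null_p)
    kappa = cohen_kappa(matrix)
    per_class = {c: class_metrics(matrix, c) for c in matrix.columns}
    return ConfusionResult(
        matrix=matrix,
        model="model2_2x2" if merge_minor else "model1_3x2",
        accuracy=acc,
        accuracy_ci95=ci,
        null_accuracy=null_p,
        p_vs_null=p,
        kappa=kappa,
        per_class=per_class,
    )


@dataclass
class RiskModelResult:
    """One univariable Poisson regression effect."""

    predictor: str
    level: str | None
    reference: str | None
    irr: float
    ci95: tuple[float, float]
    p: float
    n: int


def _reference_level(series: pd.Series) -> list:
    """Least frequent level (ties broken by label order for determinism)."""
    counts = series.value_counts(ascending=True)
    return [counts.index[0]]


def poisson_risk(
    atypicality: Sequence[int],
    predictor: Sequence,
    predictor_name: str = "predictor",
    reference: Sequence | object | None = None,
) -> list[RiskModelResult]:
    """Univariable Poisson regression of atypicality counts on one covariate.

    Numeric predictors enter as-is (IRR per unit); categorical/boolean
    predictors are dummy-coded against a reference category, by default
    the least frequent level.  ``reference`` may be a single level or a
    collection of levels to combine (e.g. pooling the two rarest levels
    into one reference group).

    Returns one :class:`RiskModelResult` per non-reference level (a single
    result for continuous or binary predictors).

    Raises
    ------
    ValueError
        On constant predictors or negative counts; non-convergence or
        perfect separation surfaces as a diagnostic error.
    """
    y = np.asarray(atypicality, dtype=float)
    if (y < 0).any():
        raise ValueError("atypicality counts must be >= 0")
    x = pd.Series(list(predictor))
    keep = x.notna().to_numpy() & np.isfinite(y)
    y, x = y[keep], x[keep].reset_index(drop=True)
    if x.nunique() < 2:
        raise ValueError(f"predictor {predictor_name!r} has < 2 distinct values")
    n = int(len(y))

    numeric = pd.api.types.is_numeric_dtype(x) and not (
        pd.api.types.is_bool_dtype(x) or x.nunique() == 2
    )
    if numeric:
        X = sm.add_constant(x.to_numpy(dtype=float))
        levels = [None]
        ref_label = None
    else:
        cats = x.astype(str)
        if reference is None:
            ref_levels = [str(v) for v in _reference_level(cats)]
        elif isinstance(reference, (list, tuple, set)):
            ref_levels = [str(v) for v in reference]
        else:
            ref_levels = [str(reference)]
        levels = [lv for lv in sorted(cats.unique()) if lv not in ref_levels]
        if not levels:
            raise ValueError("all levels assigned to the reference category")
        dummies = np.column_stack([(cats == lv).astype(float) for lv in levels])
        X = sm.add_constant(dummies)
        ref_label = "+".join(sorted(ref_levels))

    model = sm.GLM(y, X, family=sm.families.Poisson())
    try:
        fit = model.fit()
    except Exception as err:  # pragma: no cover - surfaced as diagnostic
        raise ValueError(f"Poisson fit failed for {predictor_name!r}: {err}") from err
    if not np.all(np.isfinite(fit.params)) or not np.all(np.isfinite(fit.bse)):
        raise ValueError(
            f"Poisson fit for {predictor_name!r} is degenerate (separation?)"
        )

    results = []
    for i, level in enumerate(levels, start=1):
        coef = fit.params[i]
        se = fit.bse[i]
        z = stats.norm.ppf(0.975)
        results.append(
            RiskModelResult(
                predictor=predictor_name,
                level=None if level is None else str(level),
                reference=ref_label,
                irr=float(np.exp(coef)),
                ci95=(float(np.exp(coef - z * se)), float(np.exp(coef + z * se))),
                p=float(fit.pvalues[i]),
                n=n,
            )
        )
    return results
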