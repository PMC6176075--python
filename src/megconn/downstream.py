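"""Subnetwork biomarker evaluation: strength, correlations, classification.

Once a significant subnetwork is established, each subject is summarized by
the subnetwork *strength* (mean PLV over the subnetwork's links).  The
strength is compared between groups with the same age-adjusted ANCOVA used
per link, correlated (Spearman) with cognitive scores, and evaluated as a
single-feature classifier with leave-one-out (LOO) logistic regression.

Classification metrics follow the standard definitions with the
"deleterious" group as the positive class: sensitivity = TP/(TP+FN) is the
fraction of positive-class subjects correctly classified, specificity =
TN/(TN+FP) the fraction of the reference class, PPV = TP/(TP+FP),
NPV = TN/(TN+FN).  The accuracy confidence interval is Clopper-Pearson by
default (Wilson offered).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .nbs import NBSError, SubjectTable, Subnetwork, _design_basis, _group_f_stats, _residualize

logger = logging.getLogger(__name__)


class DownstreamError(ValueError):
    """Invalid input to a downstream operation."""


@dataclass
class StrengthVector:
    """Per-subject mean connectivity over a subnetwork's links."""

    values: np.ndarray
    subnetwork_id: str | None = None
    band: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise DownstreamError("strength must be a vector (one value per subject)")


def _rate(numer: int, denom: int) -> float:
    return numer / denom if denom else float("nan")


@dataclass
class ClassificationReport:
    """Confusion counts and all derived two-class metrics."""

    tp: int
    fp: int
    tn: int
    fn: int
    feature: str = ""
    ci_method: str = "clopper-pearson"
    ci_level: float = 0.95

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return _rate(self.tp + self.tn, self.n)

    @property
    def sensitivity(self) -> float:
        return _rate(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return _rate(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return _rate(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return _rate(self.tn, self.tn + self.fn)

    @property
    def ci(self) -> tuple[float, float]:
        return accuracy_interval(
            self.tp + self.tn, self.n, method=self.ci_method, level=self.ci_level
        )

    @property
    def ci_lower(self) -> float:
        return self.ci[0]

    @property
    def ci_upper(self) -> float:
        return self.ci[1]

    def as_dict(self) -> dict:
        return {
            "feature": self.feature,
            "TP": self.tp,
            "FP": self.fp,
            "TN": self.tn,
            "FN": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "ci_method": self.ci_method,
        }

    def __str__(self) -> str:
        return (
            f"{self.feature or 'feature'}: acc={self.accuracy:.3f} "
            f"sens={self.sensitivity:.3f} spec={self.specificity:.3f} "
            f"ppv={self.ppv:.3f} npv={self.npv:.3f} "
            f"CI=[{self.ci_lower:.3f}, {self.ci_upper:.3f}]"
        )


def accuracy_interval(
    correct: int, n: int, method: str = "clopper-pearson", level: float = 0.95
) -> tuple[float, float]:
    """Binomial confidence interval for a classification accuracy."""
    if not 0 <= correct <= n or n == 0:
        raise DownstreamError("invalid confusion counts for CI")
    alpha = 1.0 - level
    if method == "clopper-pearson":
        lower = 0.0 if correct == 0 else stats.beta.ppf(alpha / 2, correct, n - correct + 1)
        upper = 1.0 if correct == n else stats.beta.ppf(1 - alpha / 2, correct + 1, n - correct)
        return float(lower), float(upper)
    if method == "wilson":
        z = stats.norm.isf(alpha / 2)
        p_hat = correct / n
        denom = 1 + z**2 / n
        center = (p_hat + z**2 / (2 * n)) / denom
        half = z * math.sqrt(p_hat * (1 - p_hat) / n + z**2 / (4 * n**2)) / denom
        return float(center - half), float(center + half)
    raise DownstreamError(f"unknown CI method {method!r}")


def subnetwork_strength(
    fc_stack: np.ndarray,
    subnetwork: Subnetwork | list[tuple[int, int]],
    subnetwork_id: str | None = None,
    band: str | None = None,
) -> StrengthVector:
    """Per-subject unweighted mean of PLV over the subnetwork's links."""
    fc_stack = np.asarray(fc_stack, dtype=float)
    links = subnetwork.links if isinstance(subnetwork, Subnetwork) else list(subnetwork)
    if not links:
        raise DownstreamError("subnetwork has no links")
    n_rois = fc_stack.shape[1]
    for i, j in links:
        if not (0 <= i < n_rois and 0 <= j < n_rois) or i == j:
            raise DownstreamError(f"link ({i}, {j}) not present in FC matrices")
    rows = np.array([l[0] for l in links])
    cols = np.array([l[1] for l in links])
    return StrengthVector(
        values=fc_stack[:, rows, cols].mean(axis=1),
        subnetwork_id=subnetwork_id,
        band=band,
    )


def strength_ancova(
    strength: StrengthVector | np.ndarray, table: SubjectTable
) -> tuple[float, float]:
    """Age-adjusted group F and p for a single strength variable.

    Same contract as the per-link ANCOVA applied to one column.
    """
    values = strength.values if isinstance(strength, StrengthVector) else np.asarray(strength, float)
    if values.size != table.n_subjects:
        raise NBSError("strength length does not match metadata")
    if values.size < 4:
        raise NBSError("need at least 4 subjects for the ANCOVA")
    basis_q = _design_basis(table.age)
    y_resid = _residualize(values[:, None], basis_q)
    g_resid = _residualize(table.group_indicator[:, None], basis_q)[:, 0]
    df_denom = values.size - 3
    f_stat, _ = _group_f_stats(
        y_resid, np.array([y_resid[:, 0] @ y_resid[:, 0]]), g_resid, df_denom
    )
    f_value = float(f_stat[0])
    return f_value, float(stats.f.sf(f_value, 1, df_denom))


def spearman_correlations(
    features: pd.DataFrame | dict[str, np.ndarray],
    table: SubjectTable,
    scores: list[str] | None = None,
    per_group: bool = True,
) -> pd.DataFrame:
    """Spearman rank correlations between FC features and cognitive scores.

    Returns a long-format table with one row per (feature, score, subgroup)
    with mid-rank rho and the two-sided t-approximation p-value.  These are
    exploratory, uncorrected correlations.  Zero-variance inputs yield
    NaN rho and are flagged in the log.
    """
    feat = pd.DataFrame(features)
    if len(feat) != table.n_subjects:
        raise DownstreamError("feature rows do not match metadata")
    if scores is None:
        scores = table.score_columns
    subgroups: list[tuple[str, np.ndarray]] = [
        ("all", np.ones(table.n_subjects, dtype=bool))
    ]
    if per_group:
        for label in table.group_labels:
            subgroups.append(
                (label, (table.frame["group"] == label).to_numpy())
            )
    rows = []
    for feature_name in feat.columns:
        x_all = feat[feature_name].to_numpy(dtype=float)
        for score in scores:
            y_all = table.frame[score].to_numpy(dtype=float)
            for subgroup, mask in subgroups:
                keep = mask & ~np.isnan(x_all) & ~np.isnan(y_all)
                n = int(keep.sum())
                if n < 3:
                    raise DownstreamError(
                        f"fewer than 3 paired values for {feature_name}/{score} "
                        f"in subgroup {subgroup}"
                    )
                x, y = x_all[keep], y_all[keep]
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    logger.warning(
                        "zero variance for %s/%s in %s; rho undefined",
                        feature_name, score, subgroup,
                    )
                    rho, p = float("nan"), float("nan")
                else:
                    rho, p = stats.spearmanr(x, y)
                rows.append(
                    {
                        "feature": feature_name,
                        "score": score,
                        "subgroup": subgroup,
                        "rho": float(rho),
                        "p": float(p),
                        "n": n,
                    }
                )
    return pd.DataFrame(rows)


def _fit_logistic_newton(
    x: np.ndarray, y: np.ndarray, tol: float = 1e-10, max_iter: int = 100
) -> np.ndarray | None:
    """Unpenalized single-feature logistic fit by Newton-Raphson.

    Returns [intercept, slope], or None when the training data are
    perfectly separated (the MLE diverges).
    """
    # perfect separation test is exact for a single feature
    upper_0 = x[y == 0].max()
    lower_1 = x[y == 1].min()
    if upper_0 < lower_1 or x[y == 1].max() < x[y == 0].min():
        return None
    design = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = design @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        grad = design.T @ (y - mu)
        hess = (design * w[:, None]).T @ design
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return None  # degenerate (e.g. constant feature); caller falls back
        beta = beta + step
        if np.abs(step).max() < tol:
            return beta
    return beta


def loo_logistic_classify(
    feature: np.ndarray,
    labels: np.ndarray,
    feature_name: str = "",
    threshold: float = 0.5,
    ci_method: str = "clopper-pearson",
) -> ClassificationReport:
    """Leave-one-out logistic classification of a single feature.

    For each subject an unpenalized logistic regression (Newton fit,
    convergence tolerance 1e-10 on the step) is trained on the remaining
    n-1 subjects and the held-out subject is classified at probability
    ``threshold``.  ``labels`` is binary with 1 for the positive
    (deleterious) class.  When a training fold is perfectly separated the
    fold falls back to a midpoint-threshold rule on the feature (logged);
    when the feature is degenerate (constant) the fold predicts the
    training majority class.  The procedure has no random element.
    """
    x = np.asarray(feature, dtype=float)
    y = np.asarray(labels)
    if set(np.unique(y)) - {0, 1}:
        raise DownstreamError("labels must be binary 0/1")
    y = y.astype(int)
    if x.shape != y.shape or x.ndim != 1:
        raise DownstreamError("feature and labels must be matching vectors")
    if x.size < 4:
        raise DownstreamError("need at least 4 subjects")
    tp = fp = tn = fn = 0
    n_separated = 0
    for held in range(x.size):
        mask = np.ones(x.size, dtype=bool)
        mask[held] = False
        x_train, y_train = x[mask], y[mask]
        if y_train.min() == y_train.max():
            logger.warning("fold %d skipped: single-class training set", held)
            continue
        if np.ptp(x_train) == 0:
            pred = int(y_train.mean() > 0.5)  # constant feature: majority class
        else:
            beta = _fit_logistic_newton(x_train, y_train)
            if beta is None:
                n_separated += 1
                upper_0 = x_train[y_train == 0].max()
                lower_1 = x_train[y_train == 1].min()
                if upper_0 < lower_1:
                    midpoint, orient = 0.5 * (upper_0 + lower_1), 1
                else:
                    midpoint = 0.5 * (x_train[y_train == 1].max() + x_train[y_train == 0].min())
                    orient = -1
                pred = int(orient * (x[held] - midpoint) > 0)
            else:
                prob = 1.0 / (1.0 + np.exp(-(beta[0] + beta[1] * x[held])))
                pred = int(prob > threshold)
        if y[held] == 1:
            tp, fn = (tp + 1, fn) if pred == 1 else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if pred == 1 else (fp, tn + 1)
    if n_separated:
        logger.info(
            "%s: %d/%d folds perfectly separated; midpoint rule used",
            feature_name or "feature", n_separated, x.size,
        )
    return ClassificationReport(
        tp=tp, fp=fp, tn=tn, fn=fn, feature=feature_name, ci_method=ci_method
    )


def confusion_from_rates(
    sensitivity: float,
    specificity: float,
    n_pos: int,
    n_neg: int,
    feature: str = "",
    ci_method: str = "clopper-pearson",
) -> ClassificationReport:
    """Reconstruct the full confusion matrix from printed sensitivity and
    specificity with known group sizes.

    TP = round(sensitivity * n_pos) and TN = round(specificity * n_neg) must
    land within 0.5 of an integer (guaranteed when the rates were themselves
    computed from integer counts); all derived metrics and the accuracy CI
    follow from the counts.
    """
    for name, rate in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= rate <= 1.0:
            raise DownstreamError(f"{name} outside [0, 1]")
    tp = round(sensitivity * n_pos)
    tn = round(specificity * n_neg)
    for name, value, target in (
        ("sensitivity", sensitivity * n_pos, tp),
        ("specificity", specificity * n_neg, tn),
    ):
        if abs(value - target) > 0.5:
            raise DownstreamError(f"{name} inconsistent with group size")
    return ClassificationReport(
        tp=tp,
        fp=n_neg - tn,
        tn=tn,
        fn=n_pos - tp,
        feature=feature,
        ci_method=ci_method,
    )
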