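"""Group-level evaluation: mixed ANOVA effects, correlations and ROC curves.

The group contrast is assessed per variable with a mixed-design
(split-plot) ANOVA — group as the between-subject factor, time point as
the within-subject factor — reporting F, p and the partial eta squared
effect size ``eta_p^2 = SS_effect / (SS_effect + SS_error)`` for the
group, time and group×time effects.  Significance across the family of
examined variables is controlled with a Bonferroni-corrected threshold.
Discrimination between two groups on a single variable is summarised by
the ROC curve, its area (AUC) and an operating point with its
sensitivity/specificity pair.

The ANOVA is evaluated through :func:`pingouin.mixed_anova`; Spearman
correlations through :func:`scipy.stats.spearmanr`; ROC curves through
scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import AnalysisError, ValidationError

__all__ = [
    "EffectResult",
    "RocResult",
    "group_time_effects",
    "apply_bonferroni",
    "bonferroni_threshold",
    "spearman_r",
    "roc_analysis",
]


@dataclass
class EffectResult:
    """One effect (group, time or group×time) of the mixed ANOVA."""

    variable: str
    factor: str  # "group" | "time" | "group x time"
    F: float
    p: float
    partial_eta_sq: float
    significant: bool | None = None  # set by apply_bonferroni


@dataclass(frozen=True)
class RocResult:
    """ROC curve with AUC and a chosen operating point."""

    thresholds: np.ndarray
    sensitivity: np.ndarray  # TPR per threshold
    specificity: np.ndarray  # 1 - FPR per threshold
    auc: float
    operating_threshold: float
    operating_sensitivity: float
    operating_specificity: float


def _validate_cohort(
    data: pd.DataFrame, dv: str, subject: str, group: str, time: str
) -> tuple[list, list]:
    for col in (dv, subject, group, time):
        if col not in data.columns:
            raise ValidationError(f"cohort table lacks column {col!r}")
    if data[dv].isna().any():
        raise ValidationError(f"cohort table has missing values in {dv!r}")
    groups = sorted(data[group].unique())
    if len(groups) != 2:
        raise ValidationError(f"need exactly 2 groups, got {groups}")
    per_subject_groups = data.groupby(subject)[group].nunique()
    if (per_subject_groups > 1).any():
        raise ValidationError("a subject appears in more than one group")
    times = sorted(data[time].unique())
    cell_counts = data.groupby([subject, time]).size()
    if (cell_counts != 1).any():
        raise ValidationError("each subject needs exactly one value per time point")
    counts = data.drop_duplicates(subject).groupby(group).size()
    if (counts < 2).any():
        raise ValidationError("each group needs at least 2 subjects")
    n_times = data.groupby(subject)[time].nunique()
    if (n_times != len(times)).any():
        raise ValidationError("every subject must have all time points (complete cells)")
    return groups, times


def _one_way_between(data: pd.DataFrame, dv: str, group: str, variable: str) -> EffectResult:
    # degenerate single-time-point path: plain one-way between-group ANOVA
    values = [g[dv].to_numpy(dtype=float) for _, g in data.groupby(group)]
    grand = np.concatenate(values).mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in values)
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in values)
    df_b = len(values) - 1
    df_w = sum(len(v) for v in values) - len(values)
    eta = ss_between / (ss_between + ss_within) if ss_between + ss_within > 0 else 0.0
    if ss_within == 0:
        f_stat = np.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
    else:
        f_stat = (ss_between / df_b) / (ss_within / df_w)
        p = float(sps.f.sf(f_stat, df_b, df_w))
    return EffectResult(variable=variable, factor="group", F=float(f_stat), p=p,
                        partial_eta_sq=float(eta))


def group_time_effects(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    group: str = "group",
    time: str = "time",
    variable: str | None = None,
) -> list[EffectResult]:
    """Mixed between(group)–within(time) ANOVA for one variable.

    ``data`` is long-format: one row per (subject, time) with the
    dependent variable in ``dv``.  Requires exactly two groups, at least
    two subjects per group, and a complete set of time points per subject.
    Returns the group, time and group×time effects, each with F, p and
    partial eta squared.  With a single time point in the table, the
    degenerate path reduces to a one-way between-group ANOVA and only the
    group effect is returned.
    """
    variable = variable if variable is not None else dv
    groups, times = _validate_cohort(data, dv, subject, group, time)
    if len(times) == 1:
        return [_one_way_between(data, dv, group, variable)]
    if np.ptp(data[dv].to_numpy(dtype=float)) == 0.0:
        # constant dependent variable: every SS is zero, no effect of anything
        return [
            EffectResult(variable=variable, factor=f, F=0.0, p=1.0, partial_eta_sq=0.0)
            for f in ("group", "time", "group x time")
        ]
    try:
        aov = pg.mixed_anova(
            data=data, dv=dv, within=time, subject=subject, between=group,
            correction=False,
        )
    except Exception as exc:  # pingouin chokes on some degenerate designs
        raise AnalysisError(
            f"mixed ANOVA failed for {variable!r}: {exc!r}; "
            "the data may be degenerate (e.g. no within-subject variance)"
        ) from exc
    factor_names = {group: "group", time: "time", "Interaction": "group x time"}
    results = []
    for _, row in aov.iterrows():
        name = factor_names.get(row["Source"], str(row["Source"]))
        f_stat = float(row["F"]) if np.isfinite(row["F"]) else float(row["F"])
        p = float(row["p_unc"])
        if np.isnan(p):
            # zero error SS: effect either absent (F=0) or perfectly determined
            p = 1.0 if (np.isnan(f_stat) or f_stat == 0.0) else 0.0
        results.append(
            EffectResult(
                variable=variable,
                factor=name,
                F=f_stat,
                p=p,
                partial_eta_sq=float(row["np2"]),
            )
        )
    return results


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance level alpha / m for a family of m tests."""
    if not (0.0 < alpha < 1.0):
        raise ValidationError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValidationError("number of tests m must be >= 1")
    return alpha / m


def apply_bonferroni(
    results: list[EffectResult], alpha: float = 0.05, m: int | None = None
) -> float:
    """Set each result's ``significant`` flag at the Bonferroni threshold.

    ``m`` defaults to the number of results in the family.  Returns the
    adjusted per-test threshold.
    """
    m = m if m is not None else len(results)
    threshold = bonferroni_threshold(alpha, m)
    for r in results:
        r.significant = r.p < threshold
    return threshold


def spearman_r(x: np.ndarray | list, y: np.ndarray | list) -> float:
    """Spearman rank correlation (mid-ranks on ties) of paired observations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-d arrays of equal length")
    if x.size < 3:
        raise ValidationError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise AnalysisError("correlation undefined for a constant vector")
    rho, _ = sps.spearmanr(x, y)
    return float(rho)


def roc_analysis(
    scores: np.ndarray | list,
    labels: np.ndarray | list,
    rule: str = "youden",
    fixed_threshold: float | None = None,
) -> RocResult:
    """ROC curve, AUC and an operating point for a two-class score.

    ``labels`` are binary (1 = positive class); higher scores are taken to
    indicate the positive class.  The AUC is the trapezoidal area, equal
    to the Mann–Whitney probability of correct pairwise ordering with ties
    counted 1/2.  The operating point maximises Youden's
    J = sensitivity + specificity − 1, breaking ties toward higher
    sensitivity; with ``rule="fixed-threshold"`` the point is the curve
    threshold closest to ``fixed_threshold``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError("scores and labels must be 1-d arrays of equal length")
    classes = np.unique(labels)
    if len(classes) != 2:
        raise AnalysisError(f"need both classes present, got labels {classes}")
    y = labels == classes.max() if labels.dtype != bool else labels

    fpr, tpr, thresholds = _sk_roc_curve(y, scores, drop_intermediate=False)
    roc_auc = float(_trapezoid_auc(fpr, tpr))

    if rule == "youden":
        j = tpr - fpr
        best_j = j.max()
        candidates = np.flatnonzero(j >= best_j - 1e-12)
        idx = candidates[np.argmax(tpr[candidates])]
    elif rule == "fixed-threshold":
        if fixed_threshold is None:
            raise ValidationError("fixed-threshold rule needs fixed_threshold")
        idx = int(np.argmin(np.abs(thresholds[1:] - fixed_threshold))) + 1
    else:
        raise ValidationError(f"unknown operating-point rule {rule!r}")

    return RocResult(
        thresholds=thresholds,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=roc_auc,
        operating_threshold=float(thresholds[idx]),
        operating_sensitivity=float(tpr[idx]),
        operating_specificity=float(1.0 - fpr[idx]),
    )
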