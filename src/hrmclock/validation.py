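"""Validation battery for the age-estimation model.

Covers the practical-utility checks applied to a fitted epigenetic clock:

* management age classes (calf < 1 y, juvenile 1-5 y, subadult 5-15 y,
  adult >= 15 y) with chance-corrected agreement (Cohen's kappa) between
  predicted and true class;
* one-way ANOVA plus Tukey-Kramer pairwise comparisons of predicted age
  across true age classes;
* a sex effect test on the Δage residuals (residuals of regressing
  predicted on chronological age, with chronological age as covariate);
* a longitudinal within-individual assessment: for individuals sampled
  repeatedly, does the model predict the later sample to be older?
  (exact two-sided binomial test of the correct-pair count against 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.api import OLS, add_constant
from statsmodels.stats.inter_rater import cohens_kappa as _sm_kappa
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .age_model import PredictionSet, pearson_correlation
from .errors import ValidationError

__all__ = [
    "AgeClass",
    "KappaResult",
    "AnovaResult",
    "SexEffectResult",
    "LongitudinalResult",
    "assign_age_class",
    "cohen_kappa",
    "anova_age_classes",
    "delta_age_residuals",
    "sex_effect_test",
    "longitudinal_assessment",
    "exact_binomial_test",
    "accuracy_rate",
]


class AgeClass(str, Enum):
    CALF = "calf"
    JUVENILE = "juvenile"
    SUBADULT = "subadult"
    ADULT = "adult"


_CLASS_ORDER = [AgeClass.CALF, AgeClass.JUVENILE, AgeClass.SUBADULT, AgeClass.ADULT]
_BOUNDARIES = (1.0, 5.0, 15.0)


def assign_age_class(age_years: float, boundary_to_older: bool = True) -> AgeClass:
    """Map an age to its management class.

    The published class ranges overlap at 1, 5 and 15 years; by default the
    intervals are half-open with the boundary age assigned to the older
    class ([0,1), [1,5), [5,15), [15,inf)).  ``boundary_to_older=False``
    assigns boundaries to the younger class instead.
    """
    if age_years < 0:
        raise ValidationError(f"negative age {age_years}")
    side = "right" if boundary_to_older else "left"
    idx = int(np.searchsorted(_BOUNDARIES, age_years, side=side))
    return _CLASS_ORDER[idx]


@dataclass
class KappaResult:
    kappa: float
    ci_low: float
    ci_high: float
    p: float


def cohen_kappa(true_classes, predicted_classes) -> KappaResult:
    """Unweighted Cohen's kappa with large-sample 95% CI and two-sided p.

    Inputs are equal-length label sequences (AgeClass or any hashable
    labels).  The confusion matrix is assembled over the union of observed
    categories; kappa is undefined when both vectors contain a single
    identical category.
    """
    true = [getattr(c, "value", c) for c in true_classes]
    pred = [getattr(c, "value", c) for c in predicted_classes]
    if len(true) != len(pred) or not true:
        raise ValidationError("kappa needs two equal-length, non-empty label vectors")
    labels = sorted(set(true) | set(pred))
    if len(labels) < 2:
        raise ValidationError("kappa undefined: a single category observed in both vectors")
    table = pd.crosstab(
        pd.Categorical(true, categories=labels),
        pd.Categorical(pred, categories=labels),
        dropna=False,
    ).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        res = _sm_kappa(table, return_results=True)
    return KappaResult(
        kappa=float(res.kappa),
        ci_low=float(res.kappa_low),
        ci_high=float(res.kappa_upp),
        p=float(res.pvalue_two_sided),
    )


@dataclass
class AnovaResult:
    f: float
    p: float
    tukey: pd.DataFrame  # group1, group2, meandiff, p_adj, lower, upper, reject


def anova_age_classes(predicted_ages, true_classes) -> AnovaResult:
    """One-way ANOVA of predicted age across true age classes + Tukey-Kramer.

    Classes with fewer than 2 members carry no within-class variance
    information and are excluded; at least two usable classes must remain.
    The Tukey-Kramer honest-significant-difference table covers all retained
    class pairs and handles unequal group sizes.
    """
    pred = np.asarray(predicted_ages, dtype=float)
    labels = np.array([getattr(c, "value", c) for c in true_classes])
    if pred.size != labels.size:
        raise ValidationError("predicted ages and classes must align")
    counts = pd.Series(labels).value_counts()
    keep = np.isin(labels, counts[counts >= 2].index.to_numpy())
    pred, labels = pred[keep], labels[keep]
    groups = [pred[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValidationError("ANOVA needs >=2 age classes with >=2 members each")
    f, p = stats.f_oneway(*groups)
    hsd = pairwise_tukeyhsd(endog=pred, groups=labels, alpha=0.05)
    tukey = pd.DataFrame(
        hsd.summary().data[1:],
        columns=["group1", "group2", "meandiff", "p_adj", "lower", "upper", "reject"],
    )
    return AnovaResult(float(f), float(p), tukey)


def delta_age_residuals(pred: PredictionSet) -> np.ndarray:
    """Δage residuals: OLS residuals of predicted age ~ chronological age."""
    if len(pred) < 3:
        raise ValidationError("need >=3 predictions for the Δage regression")
    age = pred.frame["age_years"].to_numpy(dtype=float)
    if np.ptp(age) == 0:
        raise ValidationError("zero chronological-age variance")
    y = pred.frame["predicted_age"].to_numpy(dtype=float)
    model = OLS(y, add_constant(age)).fit()
    return np.asarray(model.resid)


@dataclass
class SexEffectResult:
    coef: float  # male-vs-female offset in residual years
    p: float


def sex_effect_test(residuals, sex, age_years) -> SexEffectResult:
    """Does sex shift the Δage residuals, adjusting for chronological age?

    OLS of residual ~ sex + age; reports the two-sided p of the sex term.
    Rows with unknown sex are excluded; both sexes must remain.
    """
    residuals = np.asarray(residuals, dtype=float)
    sex = np.asarray([str(s) for s in sex])
    age = np.asarray(age_years, dtype=float)
    keep = np.isin(sex, ("female", "male"))
    residuals, sex, age = residuals[keep], sex[keep], age[keep]
    if len(set(sex)) < 2:
        raise ValidationError("sex effect test needs both sexes present")
    design = add_constant(np.column_stack([(sex == "male").astype(float), age]))
    fit = OLS(residuals, design).fit()
    return SexEffectResult(coef=float(fit.params[1]), p=float(fit.pvalues[1]))


@dataclass
class LongitudinalResult:
    n_pairs: int
    n_correct: int
    p_binomial: float
    within_r2: float


def exact_binomial_test(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial test: sum of outcome probabilities <= P(X=k)."""
    if not 0 < p0 < 1:
        raise ValidationError(f"null proportion {p0} outside (0, 1)")
    if not 0 <= k <= n:
        raise ValidationError(f"successes {k} outside [0, {n}]")
    return float(stats.binomtest(k, n, p0).pvalue)


def longitudinal_assessment(pred: PredictionSet, all_pairs: bool = False) -> LongitudinalResult:
    """Within-individual age tracking for repeatedly sampled individuals.

    For each individual with >=2 samples, chronologically ordered samples are
    paired (consecutively by default; ``all_pairs`` for every ordered pair).
    A pair counts as correct when the later sample's predicted age is
    strictly greater (ties count as incorrect).  The correct-pair count is
    tested against 0.5 with the exact two-sided binomial test, and
    ``within_r2`` is the squared correlation of predicted vs chronological
    age over the multi-sample individuals' samples.
    """
    frame = pred.frame
    multi_rows = []
    n_pairs = n_correct = 0
    for _, grp in frame.groupby("individual_id", sort=True):
        if len(grp) < 2:
            continue
        grp = grp.sort_values("age_years", kind="mergesort")
        multi_rows.append(grp)
        p = grp["predicted_age"].to_numpy()
        if all_pairs:
            pairs = [(i, j) for i in range(len(p)) for j in range(i + 1, len(p))]
        else:
            pairs = [(i, i + 1) for i in range(len(p) - 1)]
        n_pairs += len(pairs)
        n_correct += sum(p[j] > p[i] for i, j in pairs)
    if not multi_rows:
        raise ValidationError("no individual has >=2 samples")
    multi = pd.concat(multi_rows)
    r, _ = pearson_correlation(multi["age_years"], multi["predicted_age"])
    return LongitudinalResult(
        n_pairs=int(n_pairs),
        n_correct=int(n_correct),
        p_binomial=exact_binomial_test(int(n_correct), int(n_pairs), 0.5),
        within_r2=float(r**2),
    )


def accuracy_rate(error_years: float, lifespan_years: float) -> float:
    """Accuracy rate convention 100 * (1 - error/lifespan), in percent.

    Puts a model's MAE/MAD on a comparable scale across species with very
    different lifespans (e.g. MAE 7.36 y against a 60-year lifespan).
    """
    if lifespan_years <= 0:
        raise ValidationError("lifespan must be positive")
    return 100.0 * (1.0 - error_years / lifespan_years)
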