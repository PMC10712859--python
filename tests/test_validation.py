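import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hrmclock import (
    AgeClass,
    PredictionSet,
    ValidationError,
    accuracy_rate,
    anova_age_classes,
    assign_age_class,
    cohen_kappa,
    delta_age_residuals,
    exact_binomial_test,
    longitudinal_assessment,
    sex_effect_test,
)


def make_pred(ages, predicted, individuals=None):
    n = len(ages)
    frame = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "individual_id": individuals if individuals is not None else [f"i{i}" for i in range(n)],
            "age_years": ages,
            "predicted_age": predicted,
            "fold_id": "all",
        }
    )
    return PredictionSet(frame, "loiocv")


# ---------------------------------------------------------------- age classes

def oracle_age_class(age, boundary_to_older=True):
    if boundary_to_older:
        if age < 1:
            return AgeClass.CALF
        if age < 5:
            return AgeClass.JUVENILE
        if age < 15:
            return AgeClass.SUBADULT
        return AgeClass.ADULT
    if age <= 1:
        return AgeClass.CALF
    if age <= 5:
        return AgeClass.JUVENILE
    if age <= 15:
        return AgeClass.SUBADULT
    return AgeClass.ADULT


def test_age_class_examples():
    assert assign_age_class(0.5) is AgeClass.CALF
    assert assign_age_class(10.0) is AgeClass.SUBADULT
    assert assign_age_class(5.0) is AgeClass.SUBADULT  # boundary goes to the older class
    assert assign_age_class(5.0, boundary_to_older=False) is AgeClass.JUVENILE
    assert assign_age_class(65.0) is AgeClass.ADULT
    with pytest.raises(ValidationError):
        assign_age_class(-0.1)


@settings(deadline=None, derandomize=True, max_examples=200)
@given(
    age=st.floats(min_value=0.0, max_value=80.0),
    to_older=st.booleans(),
)
def test_age_classes_partition_matches_oracle(age, to_older):
    assert assign_age_class(age, to_older) is oracle_age_class(age, to_older)


# ---------------------------------------------------------------------- kappa

def brute_force_kappa(true, pred):
    labels = sorted(set(true) | set(pred))
    n = len(true)
    po = sum(t == p for t, p in zip(true, pred)) / n
    pe = sum(
        (true.count(l) / n) * (pred.count(l) / n) for l in labels
    )
    return (po - pe) / (1 - pe)


def test_kappa_examples():
    perfect = ["a"] * 5 + ["b"] * 5
    assert cohen_kappa(perfect, perfect).kappa == pytest.approx(1.0)

    # 2x2 counts [[25,25],[25,25]]: agreement no better than chance
    true = ["x"] * 50 + ["y"] * 50
    pred = (["x"] * 25 + ["y"] * 25) * 2
    assert cohen_kappa(true, pred).kappa == pytest.approx(0.0, abs=1e-12)

    # [[20,5],[10,15]]: po=0.7, pe=0.5 -> kappa=0.4
    true = ["x"] * 25 + ["y"] * 25
    pred = ["x"] * 20 + ["y"] * 5 + ["x"] * 10 + ["y"] * 15
    res = cohen_kappa(true, pred)
    assert res.kappa == pytest.approx(0.4)
    assert res.ci_low <= res.kappa <= res.ci_high
    assert 0 <= res.p <= 1


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.tuples(st.sampled_from("abcd"), st.sampled_from("abcd")), min_size=5, max_size=60))
def test_kappa_matches_brute_force(pairs):
    true = [t for t, _ in pairs]
    pred = [p for _, p in pairs]
    if len(set(true) | set(pred)) < 2:
        return
    expected = brute_force_kappa(true, pred)
    if not np.isfinite(expected):
        return
    assert cohen_kappa(true, pred).kappa == pytest.approx(expected, abs=1e-9)


def test_kappa_single_category_undefined():
    with pytest.raises(ValidationError):
        cohen_kappa(["a", "a"], ["a", "a"])


# ---------------------------------------------------------------------- anova

def test_anova_identical_means_f_near_zero():
    rng = np.random.default_rng(0)
    pred = np.concatenate([rng.normal(20, 3, 15) for _ in range(3)])
    classes = ["calf"] * 15 + ["juvenile"] * 15 + ["adult"] * 15
    res = anova_age_classes(pred, classes)
    assert res.p > 0.05
    assert not res.tukey["reject"].any()


def test_anova_two_groups_matches_t_squared():
    from scipy import stats

    rng = np.random.default_rng(1)
    a = rng.normal(0, 1, 10)
    b = rng.normal(10, 1, 10)
    res = anova_age_classes(np.concatenate([a, b]), ["g1"] * 10 + ["g2"] * 10)
    t, _ = stats.ttest_ind(a, b)
    assert res.f == pytest.approx(t**2, rel=1e-9)


def test_anova_ordered_groups_extreme_pair_significant():
    rng = np.random.default_rng(2)
    groups = {"calf": 0.5, "juvenile": 3.0, "subadult": 10.0, "adult": 35.0}
    pred, classes = [], []
    for cls, mean in groups.items():
        pred.extend(rng.normal(mean, 2.0, 10))
        classes.extend([cls] * 10)
    res = anova_age_classes(np.array(pred), classes)
    assert res.p < 0.001
    pair = res.tukey[
        ((res.tukey["group1"] == "adult") & (res.tukey["group2"] == "calf"))
        | ((res.tukey["group1"] == "calf") & (res.tukey["group2"] == "adult"))
    ]
    assert pair["reject"].all()


def test_anova_drops_singleton_classes():
    pred = np.array([1.0, 2.0, 3.0, 20.0, 21.0, 22.0, 50.0])
    classes = ["a"] * 3 + ["b"] * 3 + ["lone"]
    res = anova_age_classes(pred, classes)
    assert {"a", "b"} == set(res.tukey["group1"]) | set(res.tukey["group2"])


# ----------------------------------------------------------- delta residuals

def test_delta_residuals_absorb_linear_maps():
    ages = np.array([5.0, 20.0, 40.0, 60.0])
    assert np.allclose(delta_age_residuals(make_pred(ages, ages)), 0.0, atol=1e-10)
    assert np.allclose(delta_age_residuals(make_pred(ages, 2 * ages)), 0.0, atol=1e-10)


def test_delta_residuals_match_hand_ols():
    # y = (1, 3, 4) on x = (0, 1, 2): slope 3/2, intercept 7/6
    pred = make_pred([0.0, 1.0, 2.0], [1.0, 3.0, 4.0])
    resid = delta_age_residuals(pred)
    expected = np.array([1.0, 3.0, 4.0]) - (7 / 6 + 1.5 * np.array([0.0, 1.0, 2.0]))
    assert np.allclose(resid, expected, atol=1e-10)


def test_delta_residuals_zero_age_variance_errors():
    with pytest.raises(ValidationError):
        delta_age_residuals(make_pred([5.0, 5.0, 5.0], [1.0, 2.0, 3.0]))


# -------------------------------------------------------------------- sex test

def test_sex_effect_null_is_calibrated():
    rng = np.random.default_rng(3)
    pvals = []
    for _ in range(200):
        n = 40
        sex = np.where(rng.random(n) < 0.5, "male", "female")
        age = rng.uniform(0, 60, n)
        resid = rng.normal(0, 5, n)  # independent of sex by construction
        pvals.append(sex_effect_test(resid, sex, age).p)
    assert 0.35 < np.median(pvals) < 0.65


def test_sex_effect_detects_injected_offset():
    rng = np.random.default_rng(4)
    n = 50
    sex = np.array(["male"] * 25 + ["female"] * 25)
    age = rng.uniform(0, 60, n)
    resid = rng.normal(0, 2, n) + np.where(sex == "male", 5.0, 0.0)
    res = sex_effect_test(resid, sex, age)
    assert res.p < 0.01
    assert res.coef == pytest.approx(5.0, abs=2.0)


def test_sex_effect_single_sex_errors():
    with pytest.raises(ValidationError):
        sex_effect_test([1.0, 2.0, 3.0], ["female"] * 3, [10.0, 20.0, 30.0])


# ---------------------------------------------------------------- longitudinal

def test_longitudinal_all_increasing_counts_all_pairs():
    ages = [10.0, 12.0, 14.0, 30.0, 33.0]
    pred = [11.0, 13.0, 15.0, 29.0, 35.0]
    individuals = ["A", "A", "A", "B", "B"]
    res = longitudinal_assessment(make_pred(ages, pred, individuals))
    assert res.n_pairs == 3  # consecutive pairs: 2 for A, 1 for B
    assert res.n_correct == 3
    assert res.within_r2 > 0.9


def test_longitudinal_all_pairs_switch():
    ages = [10.0, 12.0, 14.0]
    pred = [11.0, 13.0, 15.0]
    res = longitudinal_assessment(make_pred(ages, pred, ["A"] * 3), all_pairs=True)
    assert res.n_pairs == 3


def test_longitudinal_ties_count_as_incorrect():
    res = longitudinal_assessment(make_pred([10.0, 12.0, 20.0], [15.0, 15.0, 30.0], ["A", "A", "A"]))
    assert res.n_correct == 1


def test_longitudinal_no_multisample_individual_errors():
    with pytest.raises(ValidationError):
        longitudinal_assessment(make_pred([1.0, 2.0], [1.0, 2.0], ["A", "B"]))


# ---------------------------------------------------------------- binomial test

def test_exact_binomial_examples():
    assert exact_binomial_test(3, 3, 0.5) == pytest.approx(0.25)
    assert exact_binomial_test(0, 1, 0.5) == pytest.approx(1.0)
    assert exact_binomial_test(14, 28, 0.5) == pytest.approx(1.0)
    assert exact_binomial_test(20, 28, 0.5) == pytest.approx(0.03570, abs=5e-6)


def test_exact_binomial_matches_enumeration():
    from math import comb

    for k, n in [(20, 28), (3, 3), (7, 10), (0, 6)]:
        pmf = [comb(n, i) * 0.5**n for i in range(n + 1)]
        brute = sum(p for p in pmf if p <= pmf[k] * (1 + 1e-12))
        assert exact_binomial_test(k, n, 0.5) == pytest.approx(brute, rel=1e-9)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(st.integers(min_value=0, max_value=40), st.integers(min_value=1, max_value=40))
def test_exact_binomial_symmetric_at_half(k, n):
    if k > n:
        return
    assert exact_binomial_test(k, n, 0.5) == pytest.approx(
        exact_binomial_test(n - k, n, 0.5), rel=1e-12
    )


def test_exact_binomial_validates_inputs():
    with pytest.raises(ValidationError):
        exact_binomial_test(1, 2, 0.0)
    with pytest.raises(ValidationError):
        exact_binomial_test(5, 2, 0.5)


# -------------------------------------------------------------- accuracy rate

def test_accuracy_rate_convention():
    assert accuracy_rate(7.36, 60.0) == pytest.approx(87.73, abs=0.005)
    assert accuracy_rate(7.71, 80.0) == pytest.approx(90.36, abs=0.005)
    assert accuracy_rate(3.83, 18.0) == pytest.approx(78.72, abs=0.05)
    with pytest.raises(ValidationError):
        accuracy_rate(5.0, 0.0)
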