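"""Validation battery on the combined model's LOIOCV predictions.

Age-class agreement (Cohen's kappa over calf/juvenile/subadult/adult),
one-way ANOVA with Tukey-Kramer pairwise class comparisons, the sex effect
on Δage residuals (age-adjusted), the within-individual longitudinal
binomial test, and the cross-species accuracy-rate arithmetic
100 * (1 - error / lifespan).

Writes results/validation.json.
"""

import json
import pathlib

import pandas as pd

from hrmclock import (
    PredictionSet,
    accuracy_rate,
    anova_age_classes,
    assign_age_class,
    cohen_kappa,
    delta_age_residuals,
    longitudinal_assessment,
    sex_effect_test,
)

RESULTS = pathlib.Path(__file__).resolve().parent.parent / "results"


def main():
    frame = pd.read_csv(RESULTS / "loiocv_predictions.csv")
    pred = PredictionSet(frame, "loiocv")
    meta = pd.read_csv(RESULTS / "cohort_true_methylation.csv").set_index("sample_id")

    true_cls = [assign_age_class(a) for a in frame["age_years"]]
    pred_cls = [assign_age_class(max(0.0, a)) for a in frame["predicted_age"]]
    kappa = cohen_kappa(true_cls, pred_cls)
    print(
        f"age-class kappa = {kappa.kappa:.3f} "
        f"(95% CI {kappa.ci_low:.3f}-{kappa.ci_high:.3f}, p = {kappa.p:.2g})"
    )

    anova = anova_age_classes(frame["predicted_age"].to_numpy(), true_cls)
    print(f"one-way ANOVA across age classes: F = {anova.f:.2f}, p = {anova.p:.2g}")
    significant = anova.tukey[anova.tukey["reject"]]
    for _, row in significant.iterrows():
        print(f"  Tukey: {row['group1']} vs {row['group2']} p_adj = {row['p_adj']:.3g}")

    residuals = delta_age_residuals(pred)
    sexes = [str(meta.loc[s, "sex"]) for s in frame["sample_id"]]
    sex_res = sex_effect_test(residuals, sexes, frame["age_years"].to_numpy())
    print(f"sex effect on Δage residuals: coef = {sex_res.coef:.2f} years, p = {sex_res.p:.2g}")

    lng = longitudinal_assessment(pred)
    print(
        f"longitudinal: {lng.n_correct}/{lng.n_pairs} later samples predicted older "
        f"(exact binomial p = {lng.p_binomial:.3g}); within-individual R² = {lng.within_r2:.2f}"
    )

    combined_mae = float((frame["predicted_age"] - frame["age_years"]).abs().mean())
    acc = accuracy_rate(combined_mae, 60.0)
    print(
        f"accuracy rate at a 60-year lifespan: {acc:.2f}% "
        f"(printed-value check: MAE 7.36 -> {accuracy_rate(7.36, 60.0):.2f}%, "
        f"MAD 7.71 / 80 y -> {accuracy_rate(7.71, 80.0):.2f}%)"
    )

    report = {
        "kappa": {"kappa": kappa.kappa, "ci": [kappa.ci_low, kappa.ci_high], "p": kappa.p},
        "anova": {"f": anova.f, "p": anova.p, "tukey": anova.tukey.to_dict(orient="records")},
        "sex_effect": {"coef": sex_res.coef, "p": sex_res.p},
        "longitudinal": {
            "n_correct": lng.n_correct, "n_pairs": lng.n_pairs,
            "p_binomial": lng.p_binomial, "within_r2": lng.within_r2,
        },
        "accuracy_rate_pct": acc,
    }
    out = RESULTS / "validation.json"
    with open(out, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
    print(f"report written to {out}")


if __name__ == "__main__":
    main()
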