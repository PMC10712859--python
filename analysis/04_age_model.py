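"""Fit and cross-validate the SVR age model on the quantified cohort.

Compares the two single-locus models with the combined two-locus model,
reporting refit (train-on-all) and leave-one-individual-out (LOIOCV)
MAE and R².  Hyperparameters are grid-searched once per model with
individual-grouped k-fold MAE (the single-global-tune workflow).  The
expected pattern: each locus alone predicts age poorly, while the
combination — which can cancel the shared per-individual methylation shift —
does far better, and LOIOCV error exceeds the refit error.

Writes results/model_report.json.
"""

import json
import pathlib

from hrmclock import read_methylation_dataset
from hrmclock.pipeline import PipelineConfig, analyze_dataset, summary_to_jsonable

SEED = 0
RESULTS = pathlib.Path(__file__).resolve().parent.parent / "results"


def main():
    ds = read_methylation_dataset(
        RESULTS / "cohort_quantified_methylation.csv", genes=["RALYL", "TET2"]
    )
    config = PipelineConfig(tune_once=True, seed=SEED)
    summary = analyze_dataset(ds, config)
    print(f"{'model':10s} {'refit MAE':>9s} {'refit R²':>9s} {'CV MAE':>7s} {'CV R²':>6s}")
    for name, rep in summary["models"].items():
        print(
            f"{name:10s} {rep['refit']['mae']:9.2f} {rep['refit']['r2']:9.2f} "
            f"{rep['loiocv']['mae']:7.2f} {rep['loiocv']['r2']:6.2f}"
        )
    combined = summary["models"]["combined"]
    print(
        f"\ncombined-model LOIOCV MAE {combined['loiocv']['mae']:.2f} years >= "
        f"refit MAE {combined['refit']['mae']:.2f} years, as expected for an "
        "honest out-of-individual error"
    )
    out = RESULTS / "model_report.json"
    with open(out, "w", encoding="utf-8") as fh:
        json.dump(summary_to_jsonable(summary), fh, indent=2)
    # keep the LOIOCV predictions for the validation script
    combined_pred = summary["models"]["combined"]["_loiocv_pred"]
    combined_pred.frame.to_csv(RESULTS / "loiocv_predictions.csv", index=False)
    print(f"report written to {out}")


if __name__ == "__main__":
    main()
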