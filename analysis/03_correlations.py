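"""Screen methylation-age correlations on the quantified cohort.

Pearson product-moment correlation of each locus' methylation rate with
chronological age, on both the melt-quantified table (02_quantify.py) and
the generator's true methylation values, to show how much the melt/
calibration stages attenuate the signal.
"""

import pathlib

from hrmclock import pearson_correlation, read_methylation_dataset

RESULTS = pathlib.Path(__file__).resolve().parent.parent / "results"
GENES = ["RALYL", "TET2"]


def main():
    for label, name in [
        ("true (generator)", "cohort_true_methylation.csv"),
        ("melt-quantified", "cohort_quantified_methylation.csv"),
    ]:
        ds = read_methylation_dataset(RESULTS / name, genes=GENES)
        parts = []
        for gene in GENES:
            r, p = pearson_correlation(ds.feature_matrix([gene])[:, 0], ds.ages)
            parts.append(f"{gene} r = {r:+.3f} (p = {p:.2g})")
        print(f"{label:18s}: " + ", ".join(parts))


if __name__ == "__main__":
    main()
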