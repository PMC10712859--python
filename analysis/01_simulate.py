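"""Generate the synthetic study inputs: melt plates and an age-structured cohort.

Writes, under results/:
  - per-gene melt-plate CSVs (standard series + duplicate sample reactions),
    well maps, and truth tables (true fraction, amplified fraction, expected Df);
  - the cohort methylation table (the ground-truth values the plates encode)
    and its latent-truth table.

The two loci carry opposite-signed linear age trends; the TET2-like assay is
simulated with stronger PCR bias (b = 3) than the RALYL-like assay (b = 1.5),
so its standard curve is visibly less linear.
"""

import pathlib

from hrmclock import CohortSpec, SimSpec, simulate_cohort_plates, write_melt_table
from hrmclock.io_formats import write_methylation_dataset

SEED = 0
RESULTS = pathlib.Path(__file__).resolve().parent.parent / "results"


def main():
    RESULTS.mkdir(exist_ok=True)
    cohort_spec = CohortSpec(seed=SEED)
    sim_specs = {
        "RALYL": SimSpec.for_gene("RALYL", bias_factor=1.5),
        "TET2": SimSpec.for_gene("TET2", bias_factor=3.0),
    }
    dataset, plates = simulate_cohort_plates(cohort_spec, sim_specs=sim_specs, seed=SEED)

    write_methylation_dataset(dataset, RESULTS / "cohort_true_methylation.csv")
    for gene, (plate, well_map, truth) in plates.items():
        write_melt_table(plate, RESULTS / f"{gene}_melt.csv")
        well_map.to_csv(RESULTS / f"{gene}_wells.csv", index=False)
        truth.to_csv(RESULTS / f"{gene}_truth.csv", index=False)
        print(
            f"{gene}: {len(plate.curves)} wells "
            f"(bias b = {sim_specs[gene].bias_factor}, expected a = "
            f"{1 / sim_specs[gene].bias_factor:.3f})"
        )
    print(
        f"cohort: {len(dataset)} samples from {len(dataset.individuals)} individuals, "
        f"ages {dataset.ages.min():.1f}-{dataset.ages.max():.1f} years"
    )
    print(f"inputs written to {RESULTS}/")


if __name__ == "__main__":
    main()
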