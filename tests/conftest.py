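import numpy as np
import pytest

from hrmclock import (
    CohortSpec,
    DEFAULT_ASSAYS,
    MethylationDataset,
    SampleRecord,
    SimSpec,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def ralyl_assay():
    return DEFAULT_ASSAYS["RALYL"]


@pytest.fixture(scope="session")
def quiet_spec():
    """Noise-free RALYL melt simulator."""
    return SimSpec.for_gene("RALYL", noise_sd=0.0)


@pytest.fixture(scope="session")
def cohort():
    """Default 25-individual / 53-sample cohort, fixed seed."""
    dataset, truth = simulate_cohort(CohortSpec(seed=11))
    return dataset, truth


def make_linear_dataset(
    n_individuals=8,
    samples_per_individual=2,
    slope=0.5,
    intercept=20.0,
    noise_sd=0.0,
    seed=0,
    genes=("G1",),
):
    """Tiny dataset with exactly linear (optionally noisy) methylation-age maps."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_individuals):
        base_age = rng.uniform(1, 50)
        for s in range(samples_per_individual):
            age = base_age + 2.0 * s
            meth = {
                g: float(np.clip(intercept + slope * age + rng.normal(0, noise_sd), 0, 100))
                for g in genes
            }
            records.append(
                SampleRecord(
                    sample_id=f"I{i}S{s}",
                    individual_id=f"I{i}",
                    sex="female" if i % 2 else "male",
                    age_years=age,
                    methylation=meth,
                )
            )
    return MethylationDataset(records, list(genes))


@pytest.fixture
def linear_dataset():
    return make_linear_dataset()
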