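"""Synthetic melt plates and age-structured cohorts with known ground truth.

Two generators provide truth for every pipeline stage:

``simulate_melt_curve`` builds a raw HRM fluorescence curve as a two-species
mixture.  Each species (methylated / unmethylated amplicon) melts with a
logistic helicity profile centred on its Tm; the methylated species melts
``delta_tm`` °C higher.  PCR bias is modelled as a single amplification
advantage ``b >= 1`` for the unmethylated template, acting once on the final
product: a true methylated fraction ``p`` yields an amplified fraction

    q = p / (p + b * (1 - p)).

This makes the fitted standard-curve coefficient analytically ``a = 1/b``
(since Df/(Dfmax-Df) = q/(1-q) = p/(b(1-p)) = (1/b) * M/(100-M)), giving an
exact oracle for the calibration stage.  The logistic profile is truncated
(rescaled to saturate exactly at Tm ± ``saturation_mult`` transition widths)
so that both species are perfectly flat inside the normalization windows and
the measured Df is exactly linear in q on noise-free plates.

``simulate_cohort`` draws an age-structured cohort of repeatedly sampled
individuals with two loci whose methylation trends with age have opposite
signs, a shared per-individual random factor loading on both loci (global
methylation shifts, the component that cancels when the loci are combined in
one model) and per-sample residual noise.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import PlateExport
from .age_model import MethylationDataset, SampleRecord
from .melt import (
    DEFAULT_ASSAYS,
    GeneAssay,
    MeltCurve,
    df_value,
    difference_curve,
    normalize_curve,
)

__all__ = [
    "SimSpec",
    "GeneTrend",
    "CohortSpec",
    "amplified_fraction",
    "simulate_melt_curve",
    "simulate_standard_plate",
    "simulate_plate",
    "simulate_cohort",
    "simulate_cohort_plates",
    "STANDARD_FRACTIONS",
]

#: Nominal methylation fractions (%) of the standard dilution series.
STANDARD_FRACTIONS: tuple[float, ...] = (0.0, 5.0, 10.0, 15.0, 25.0, 40.0, 50.0, 75.0, 100.0)


@dataclass(frozen=True)
class SimSpec:
    """Generative parameters for one gene's melt curves.

    Baselines are straight lines in arbitrary fluorescence units; the grid
    spans 65-95 °C at 0.02 °C (coarser than the instrument's acquisition
    rate implies, for tractability).  Default Tm placements keep both melt
    transitions strictly between the gene's normalization windows.
    """

    gene_id: str = "RALYL"
    tm_unmethylated: float = 73.0
    delta_tm: float = 3.0
    transition_width: float = 0.8
    pre_intercept: float = 950.0
    pre_slope: float = -5.0
    post_intercept: float = 120.0
    post_slope: float = -0.5
    bias_factor: float = 1.0
    noise_sd: float = 2.0
    grid: tuple[float, float, float] = (65.0, 95.0, 0.02)
    saturation_mult: float = 6.0

    def __post_init__(self):
        if self.bias_factor < 1.0:
            raise ValidationError("bias factor b must be >= 1 (unmethylated advantage)")
        if self.delta_tm <= 0:
            raise ValidationError("delta_tm must be positive (methylated melts higher)")
        if self.transition_width <= 0 or self.saturation_mult <= 0:
            raise ValidationError("transition width and saturation multiple must be positive")

    @classmethod
    def for_gene(cls, gene_id: str, **overrides) -> "SimSpec":
        """Per-gene defaults whose transitions fit that gene's windows."""
        overrides.setdefault("tm_unmethylated", {"RALYL": 73.0, "TET2": 71.9}.get(gene_id, 73.0))
        return cls(gene_id=gene_id, **overrides)

    @property
    def temperatures(self) -> np.ndarray:
        lo, hi, step = self.grid
        return np.arange(lo, hi + step / 2, step)

    def validate_against_assay(self, assay: GeneAssay) -> None:
        """Both melt transitions must lie strictly between the windows."""
        half = self.saturation_mult * self.transition_width
        pre_hi = assay.pre_melt_window[1]
        post_lo = assay.post_melt_window[0]
        for tm in (self.tm_unmethylated, self.tm_unmethylated + self.delta_tm):
            if not (pre_hi < tm - half and tm + half < post_lo):
                raise ValidationError(
                    f"spec {self.gene_id!r}: melt transition at Tm={tm} °C "
                    f"(±{half} °C) not strictly inside windows ({pre_hi}, {post_lo}) °C"
                )


def amplified_fraction(p: float, bias_factor: float) -> float:
    """Post-PCR methylated product fraction q for true fraction p in [0, 1]."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"true methylated fraction {p} outside [0, 1]")
    return p / (p + bias_factor * (1.0 - p))


def _helicity(temps: np.ndarray, tm: float, width: float, mult: float) -> np.ndarray:
    """Truncated logistic helicity: 1 below Tm - mult*width, 0 above Tm + mult*width.

    The logistic core is affinely rescaled so it meets the plateaus exactly,
    keeping the curve continuous while making the plateaus exactly flat —
    required for Df to be exactly linear in the species mixture fraction.
    """
    lo, hi = tm - mult * width, tm + mult * width
    sig = 1.0 / (1.0 + np.exp(np.clip((temps - tm) / width, -500, 500)))
    s_lo = 1.0 / (1.0 + np.exp(-mult))
    s_hi = 1.0 / (1.0 + np.exp(mult))
    core = (sig - s_hi) / (s_lo - s_hi)
    return np.where(temps <= lo, 1.0, np.where(temps >= hi, 0.0, core))


def simulate_melt_curve(
    spec: SimSpec,
    true_fraction: float,
    seed: int | np.random.Generator | None = None,
    well_id: str = "W1",
) -> MeltCurve:
    """Raw fluorescence curve for a sample with true methylated fraction p."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    temps = spec.temperatures
    q = amplified_fraction(true_fraction, spec.bias_factor)
    h_u = _helicity(temps, spec.tm_unmethylated, spec.transition_width, spec.saturation_mult)
    h_m = _helicity(
        temps, spec.tm_unmethylated + spec.delta_tm, spec.transition_width, spec.saturation_mult
    )
    l_pre = spec.pre_intercept + spec.pre_slope * temps
    l_post = spec.post_intercept + spec.post_slope * temps
    signal = l_post + (l_pre - l_post) * (q * h_m + (1.0 - q) * h_u)
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, temps.size)
    return MeltCurve(well_id, spec.gene_id, temps, signal)


def _design_dfmax(spec: SimSpec, assay: GeneAssay) -> float:
    """Noise-free Df of the pure methylated curve vs the pure unmethylated one."""
    quiet = replace(spec, noise_sd=0.0)
    pure0 = normalize_curve(simulate_melt_curve(quiet, 0.0), assay)
    pure1 = normalize_curve(simulate_melt_curve(quiet, 1.0), assay)
    return df_value(difference_curve(pure1, pure0)).df


def simulate_plate(
    spec: SimSpec,
    sample_fractions: dict[str, float] | None = None,
    standard_fractions: tuple[float, ...] = STANDARD_FRACTIONS,
    replicates: int = 2,
    seed: int | None = None,
    plate_id: str = "plate1",
    assay: GeneAssay | None = None,
) -> tuple[PlateExport, pd.DataFrame, pd.DataFrame]:
    """Simulate a plate of standards plus optional samples, in duplicate.

    Returns ``(plate, well_map, truth)``.  ``well_map`` assigns each well a
    role (standard/baseline/sample), nominal fraction and replicate index —
    the metadata the quantification stage needs.  ``truth`` records each
    well's true fraction p, amplified fraction q and the noise-free expected
    Df (q times the design Dfmax).
    """
    assay = assay or DEFAULT_ASSAYS[spec.gene_id]
    spec.validate_against_assay(assay)
    if 0.0 not in standard_fractions or 100.0 not in standard_fractions:
        raise ValidationError("standard series must include the 0% and 100% fractions")
    rng = np.random.default_rng(seed)
    dfmax = _design_dfmax(spec, assay)

    curves, map_rows, truth_rows = [], [], []

    def add_well(well_id, sample_id, role, fraction_pct, rep):
        p = fraction_pct / 100.0
        curves.append(simulate_melt_curve(spec, p, rng, well_id=well_id))
        map_rows.append(
            {
                "well_id": well_id,
                "sample_id": sample_id,
                "role": role,
                "nominal_fraction_pct": fraction_pct if role != "sample" else np.nan,
                "replicate": rep,
            }
        )
        q = amplified_fraction(p, spec.bias_factor)
        truth_rows.append(
            {
                "well_id": well_id,
                "true_fraction_pct": fraction_pct,
                "amplified_fraction": q,
                "expected_df": q * dfmax,
            }
        )

    for frac in standard_fractions:
        role = "baseline" if frac == 0.0 else "standard"
        for rep in range(1, replicates + 1):
            add_well(f"STD{frac:g}R{rep}", f"STD{frac:g}", role, frac, rep)
    for sample_id, frac in (sample_fractions or {}).items():
        for rep in range(1, replicates + 1):
            add_well(f"{sample_id}R{rep}", sample_id, "sample", frac, rep)

    plate = PlateExport(curves=curves, plate_id=plate_id, dialect="long")
    return plate, pd.DataFrame(map_rows), pd.DataFrame(truth_rows)


def simulate_standard_plate(
    spec: SimSpec,
    fractions: tuple[float, ...] = STANDARD_FRACTIONS,
    replicates: int = 2,
    seed: int | None = None,
    plate_id: str = "standards",
) -> tuple[PlateExport, pd.DataFrame, pd.DataFrame]:
    """Standards-only plate (the calibration fixture)."""
    return simulate_plate(
        spec, None, standard_fractions=fractions, replicates=replicates,
        seed=seed, plate_id=plate_id,
    )


@dataclass(frozen=True)
class GeneTrend:
    """Linear age trend of one locus' methylation, in % units.

    ``individual_sd`` is the loading of the shared per-individual factor on
    this locus: every sample of individual i is shifted by
    ``individual_sd * u_i`` with u_i ~ N(0, 1) shared across loci.  This
    correlated component is what a multi-locus model can cancel, so the
    combined model outperforms single-locus models, as observed in real
    cohorts.  ``residual_sd`` is independent per sample and locus.
    """

    intercept: float
    slope_per_year: float
    residual_sd: float
    individual_sd: float


def _default_gene_trends() -> dict[str, GeneTrend]:
    # Calibrated so a 25-individual / 53-sample cohort realizes age
    # correlations near +0.52 (RALYL-like) and -0.60 (TET2-like).
    return {
        "RALYL": GeneTrend(intercept=25.0, slope_per_year=+0.35, residual_sd=5.0, individual_sd=9.4),
        "TET2": GeneTrend(intercept=35.0, slope_per_year=-0.25, residual_sd=3.0, individual_sd=5.5),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for an age-structured, repeatedly sampled cohort.

    Defaults emulate the study design this pipeline targets: 25 captive
    individuals, 53 blood samples collected over ~18 years, ages from a few
    months to 65 years, a heavily female-skewed sex ratio and a handful of
    wild-born individuals with estimated (rather than recorded) birth years.
    """

    n_individuals: int = 25
    n_samples: int = 53
    age_range: tuple[float, float] = (0.2, 65.0)
    genes: dict[str, GeneTrend] = field(default_factory=_default_gene_trends)
    sex_ratio_male: float = 0.12
    resample_interval_years: tuple[float, float] = (1.0, 4.0)
    n_estimated_birth: int = 6
    first_collection_window: tuple[datetime.date, datetime.date] = (
        datetime.date(2004, 1, 1),
        datetime.date(2019, 1, 1),
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < self.n_individuals:
            raise ValidationError("need at least one sample per individual")
        if self.n_individuals < 2:
            raise ValidationError("cohort needs >=2 individuals")
        if not 0.0 <= self.sex_ratio_male <= 1.0:
            raise ValidationError("sex ratio outside [0, 1]")


def simulate_cohort(
    spec: CohortSpec, seed: int | None = None
) -> tuple[MethylationDataset, pd.DataFrame]:
    """Draw a cohort dataset plus a truth table of latent quantities.

    All randomness flows from one seed (``seed`` argument, else
    ``spec.seed``); identical seeds give identical datasets.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_individuals
    genes = list(spec.genes)

    first_ages = rng.uniform(*spec.age_range, n)
    counts = np.ones(n, dtype=int)
    for _ in range(spec.n_samples - n):
        counts[rng.integers(0, n)] += 1
    n_males = int(round(spec.sex_ratio_male * n))
    sexes = np.array(["female"] * n)
    sexes[rng.choice(n, size=n_males, replace=False)] = "male"
    estimated = set(rng.choice(n, size=min(spec.n_estimated_birth, n), replace=False))
    shared_factor = rng.normal(0.0, 1.0, n)

    window_days = (spec.first_collection_window[1] - spec.first_collection_window[0]).days
    records, truth_rows = [], []
    for i in range(n):
        ind_id = f"I{i + 1:02d}"
        age = first_ages[i]
        collection = spec.first_collection_window[0] + datetime.timedelta(
            days=int(rng.integers(0, window_days + 1))
        )
        for s in range(counts[i]):
            if s:
                gap = rng.uniform(*spec.resample_interval_years)
                age += gap
                collection += datetime.timedelta(days=round(gap * 365.25))
            meth = {}
            for g in genes:
                tr = spec.genes[g]
                value = (
                    tr.intercept
                    + tr.slope_per_year * age
                    + tr.individual_sd * shared_factor[i]
                    + rng.normal(0.0, tr.residual_sd)
                )
                meth[g] = float(np.clip(value, 0.0, 100.0))
            sample_id = f"{ind_id}S{s + 1}"
            records.append(
                SampleRecord(
                    sample_id=sample_id,
                    individual_id=ind_id,
                    sex=str(sexes[i]),
                    age_years=float(age),
                    methylation=meth,
                    birth_known=i not in estimated,
                    collection_date=collection,
                )
            )
            truth_rows.append(
                {
                    "sample_id": sample_id,
                    "individual_id": ind_id,
                    "true_age_years": float(age),
                    "shared_factor": float(shared_factor[i]),
                    **{f"true_{g}": meth[g] for g in genes},
                }
            )
    dataset = MethylationDataset(records, genes)
    return dataset, pd.DataFrame(truth_rows)


def simulate_cohort_plates(
    cohort_spec: CohortSpec,
    sim_specs: dict[str, SimSpec] | None = None,
    seed: int | None = None,
    replicates: int = 2,
) -> tuple[MethylationDataset, dict[str, tuple[PlateExport, pd.DataFrame, pd.DataFrame]]]:
    """Full-circle fixture: a cohort plus one melt plate per gene.

    Each gene's plate contains the standard series and a duplicate reaction
    per cohort sample at that sample's true methylation fraction, so the
    whole pipeline (melt -> Df -> calibration -> model) can run end to end
    against known truth.
    """
    base_seed = cohort_spec.seed if seed is None else seed
    dataset, truth = simulate_cohort(cohort_spec, seed=base_seed)
    if sim_specs is None:
        sim_specs = {
            "RALYL": SimSpec.for_gene("RALYL", bias_factor=1.5),
            "TET2": SimSpec.for_gene("TET2", bias_factor=3.0),
        }
    plates = {}
    for offset, gene in enumerate(dataset.genes):
        fractions = {r.sample_id: r.methylation[gene] for r in dataset.records}
        plates[gene] = simulate_plate(
            sim_specs[gene],
            sample_fractions=fractions,
            replicates=replicates,
            seed=base_seed + 1000 + offset,
            plate_id=f"{gene}_plate",
        )
    return dataset, plates
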