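"""End-to-end orchestration: melt plates -> methylation -> age model -> validation.

Two entry points mirror the two kinds of input a user has:

* :func:`run_pipeline` starts from raw melt plates plus per-well metadata
  (normalize -> difference -> Df -> calibrate -> quantify), then hands the
  quantified methylation table to the model stages;
* :func:`analyze_dataset` starts from an already quantified methylation
  table (the deposited-dataset path) and runs correlation screening, the
  SVR model with LOIOCV, and the validation battery.

Each stage failure is re-raised with the stage name so an aborted run says
where it died.  The summary is a plain JSON-able dict.
"""

from __future__ import annotations

import contextlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import age_model as am
from . import calibration as cal
from . import validation as val
from .errors import HrmError, ReplicateConcordanceWarning
from .io_formats import PlateExport
from .melt import (
    DEFAULT_ASSAYS,
    GeneAssay,
    aggregate_replicates,
    df_value,
    difference_curve,
    melt_derivative,
    normalize_curve,
)

__all__ = ["PipelineConfig", "process_plate", "analyze_dataset", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything tunable about a pipeline run, with study defaults."""

    assays: dict[str, GeneAssay] = field(default_factory=lambda: dict(DEFAULT_ASSAYS))
    difference_mode: str = "normalized"  # or 'derivative'
    concordance_limit_frac: float = 0.2  # of Dfmax, for duplicate agreement
    include_anchor_points: bool = False
    cost_grid: tuple[float, ...] = am.DEFAULT_COST_GRID
    epsilon_grid: tuple[float, ...] = am.DEFAULT_EPSILON_GRID
    gammas: tuple[float, ...] = am.DEFAULT_GAMMAS
    tune_once: bool = False
    scale: bool = True
    r2_method: str = "pearson"
    boundary_to_older: bool = True
    all_pairs: bool = False
    seed: int = 0


@contextlib.contextmanager
def _stage(name: str):
    try:
        yield
    except HrmError as exc:
        raise type(exc)(f"[stage {name}] {exc}") from exc


def process_plate(
    plate: PlateExport,
    well_map: pd.DataFrame,
    config: PipelineConfig | None = None,
    gene_id: str | None = None,
) -> tuple[cal.CalibrationFit, pd.DataFrame]:
    """One plate/gene: normalize, difference vs 0% baseline, Df, calibrate, quantify.

    ``well_map`` columns: well_id, sample_id, role (sample/standard/baseline),
    nominal_fraction_pct, replicate.  Returns the calibration fit and the
    per-sample quantified methylation table.
    """
    config = config or PipelineConfig()
    gene_id = gene_id or plate.curves[0].gene_id
    if gene_id not in config.assays:
        raise HrmError(f"no assay configured for gene {gene_id!r}")
    assay = config.assays[gene_id]
    meta = well_map.set_index("well_id")

    with _stage("normalize"):
        normalized = {}
        for curve in plate.curves:
            if not curve.gene_id:
                curve.gene_id = gene_id
            nc = normalize_curve(curve, assay)
            if config.difference_mode == "derivative":
                nc = melt_derivative(nc)
            normalized[curve.well_id] = nc

    with _stage("difference"):
        baseline_wells = [w for w in normalized if meta.loc[w, "role"] == "baseline"]
        if not baseline_wells:
            raise HrmError("plate has no 0% baseline wells")
        grid = normalized[baseline_wells[0]].temperatures
        base_signal = np.mean(
            [
                np.interp(grid, normalized[w].temperatures, normalized[w].normalized_signal)
                for w in baseline_wells
            ],
            axis=0,
        )
        baseline = type(normalized[baseline_wells[0]])(
            "baseline", gene_id, grid, base_signal
        )
        dfs = {w: df_value(difference_curve(nc, baseline)) for w, nc in normalized.items()}

    with _stage("calibrate"):
        by_sample: dict[str, list] = {}
        for w, dfv in dfs.items():
            by_sample.setdefault(str(meta.loc[w, "sample_id"]), []).append(dfv)
        aggregated = {s: aggregate_replicates(reps) for s, reps in by_sample.items()}
        standards = {}
        for w in normalized:
            if meta.loc[w, "role"] in ("standard", "baseline"):
                frac = float(meta.loc[w, "nominal_fraction_pct"])
                standards[frac] = aggregated[str(meta.loc[w, "sample_id"])].df
        series = cal.StandardSeries(gene_id, sorted(standards.items()))
        fit = cal.fit_standard_curve(series, include_anchors=config.include_anchor_points)
        # duplicate-concordance check, now that Dfmax is known
        limit = config.concordance_limit_frac * fit.dfmax
        for s, reps in by_sample.items():
            if len(reps) > 1:
                spread = max(r.df for r in reps) - min(r.df for r in reps)
                if spread > limit:
                    warnings.warn(
                        f"sample {s!r}: replicate Df spread {spread:.3g} exceeds "
                        f"{config.concordance_limit_frac:.0%} of Dfmax",
                        category=ReplicateConcordanceWarning,
                        stacklevel=2,
                    )

    with _stage("quantify"):
        sample_ids = {
            str(meta.loc[w, "sample_id"]) for w in normalized if meta.loc[w, "role"] == "sample"
        }
        table = cal.quantify_plate({s: aggregated[s] for s in sorted(sample_ids)}, fit)
    return fit, table


def _model_report(dataset, genes, config: PipelineConfig) -> dict:
    params = am.tune_hyperparameters(
        dataset, config.cost_grid, config.epsilon_grid, config.gammas,
        seed=config.seed, genes=genes, scale=config.scale,
    )
    refit = am.refit_predictions(dataset, params, genes=genes, scale=config.scale)
    cv = am.loiocv(
        dataset, config.cost_grid, config.epsilon_grid, config.gammas,
        seed=config.seed, genes=genes, scale=config.scale,
        tune_once=config.tune_once, params=params if config.tune_once else None,
    )
    return {
        "genes": list(genes),
        "params": {"cost": params.cost, "epsilon": params.epsilon, "gamma": params.gamma},
        "refit": {"mae": refit.mae(), "r2": refit.r_squared(config.r2_method)},
        "loiocv": {"mae": cv.mae(), "r2": cv.r_squared(config.r2_method)},
        "_refit_pred": refit,
        "_loiocv_pred": cv,
    }


def analyze_dataset(dataset: am.MethylationDataset, config: PipelineConfig | None = None) -> dict:
    """Correlation screening, per-gene and combined SVR models, validation.

    Returns a summary dict; the keys prefixed ``_`` hold the in-memory
    prediction sets and are stripped by :func:`summary_to_jsonable`.
    """
    config = config or PipelineConfig()
    summary: dict = {"n_samples": len(dataset), "n_individuals": len(dataset.individuals)}

    with _stage("correlate"):
        ages = dataset.ages
        summary["correlations"] = {}
        for gene in dataset.genes:
            r, p = am.pearson_correlation(dataset.feature_matrix([gene])[:, 0], ages)
            summary["correlations"][gene] = {"r": r, "p": p}

    with _stage("model"):
        summary["models"] = {}
        for gene in dataset.genes:
            summary["models"][gene] = _model_report(dataset, [gene], config)
        summary["models"]["combined"] = _model_report(dataset, list(dataset.genes), config)

    with _stage("validate"):
        cv = summary["models"]["combined"]["_loiocv_pred"]
        frame = cv.frame
        true_cls = [
            val.assign_age_class(a, config.boundary_to_older) for a in frame["age_years"]
        ]
        pred_cls = [
            val.assign_age_class(max(0.0, a), config.boundary_to_older)
            for a in frame["predicted_age"]
        ]
        kappa = val.cohen_kappa(true_cls, pred_cls)
        anova = val.anova_age_classes(frame["predicted_age"].to_numpy(), true_cls)
        residuals = val.delta_age_residuals(cv)
        sexes = {r.sample_id: r.sex for r in dataset.records}
        sex_res = val.sex_effect_test(
            residuals, [sexes[s] for s in frame["sample_id"]], frame["age_years"].to_numpy()
        )
        longitudinal = val.longitudinal_assessment(cv, all_pairs=config.all_pairs)
        summary["validation"] = {
            "kappa": {
                "kappa": kappa.kappa, "ci_low": kappa.ci_low,
                "ci_high": kappa.ci_high, "p": kappa.p,
            },
            "anova": {
                "f": anova.f, "p": anova.p,
                "tukey": anova.tukey.to_dict(orient="records"),
            },
            "sex_effect": {"coef": sex_res.coef, "p": sex_res.p},
            "longitudinal": {
                "n_pairs": longitudinal.n_pairs,
                "n_correct": longitudinal.n_correct,
                "p_binomial": longitudinal.p_binomial,
                "within_r2": longitudinal.within_r2,
            },
        }
    return summary


def run_pipeline(
    plates: dict[str, tuple[PlateExport, pd.DataFrame]],
    metadata: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> dict:
    """Raw-melt entry point: quantify every gene's plate, then model + validate.

    ``plates`` maps gene id -> (plate, well_map); ``metadata`` is a table
    with sample_id, individual_id, sex, birth_known and either age_years or
    birth/collection dates for the role=sample wells.
    """
    config = config or PipelineConfig()
    summary: dict = {"calibration": {}, "quantification": {}}
    tables = {}
    for gene, (plate, well_map) in plates.items():
        fit, table = process_plate(plate, well_map, config, gene_id=gene)
        summary["calibration"][gene] = {
            "a": fit.a, "dfmax": fit.dfmax, "rss": fit.rss, "n_points": fit.n_points,
        }
        summary["quantification"][gene] = {
            "n_samples": int(len(table)), "n_clamped": int(table["clamped"].sum()),
        }
        tables[gene] = table.set_index("sample_id")["methylation_pct"]

    with _stage("assemble"):
        meta = metadata.set_index("sample_id")
        genes = list(plates)
        records = []
        for sample_id in tables[genes[0]].index:
            rec = meta.loc[sample_id]
            age = float(rec["age_years"])
            records.append(
                am.SampleRecord(
                    sample_id=str(sample_id),
                    individual_id=str(rec["individual_id"]),
                    sex=str(rec["sex"]),
                    age_years=age,
                    methylation={g: float(tables[g].loc[sample_id]) for g in genes},
                    birth_known=bool(rec.get("birth_known", True)),
                )
            )
        dataset = am.MethylationDataset(records, genes)

    summary.update(analyze_dataset(dataset, config))
    summary["_dataset"] = dataset
    return summary


def summary_to_jsonable(summary: dict):
    """Strip in-memory objects and coerce numpy scalars for JSON output."""

    def convert(obj):
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items() if not str(k).startswith("_")}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.bool_):
            return bool(obj)
        return obj

    return convert(summary)
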