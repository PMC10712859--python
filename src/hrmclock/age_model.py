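"""Methylation-age correlation screening and SVR age estimation.

The age model is an epsilon support vector regression (radial kernel) on
per-gene methylation rates, the standard small-n epigenetic-clock choice
when only a handful of loci are assayed.  Because individuals are sampled
repeatedly over years, all cross-validation is grouped by individual:
leave-one-individual-out cross-validation (LOIOCV) holds out every sample
of one individual at a time, so no within-individual information leaks from
training to test.

Hyperparameters (cost, epsilon, gamma in {0.5, 1}) are grid-searched with
individual-grouped k-fold mean absolute error, either once on the full
dataset (``tune_once``, mirroring a single global ``tune.svm`` call) or
independently inside every LOIOCV training fold (the default; fully
leakage-free).  Features are z-scored using training-fold statistics only.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVR

from .errors import ValidationError

__all__ = [
    "SampleRecord",
    "MethylationDataset",
    "SvrParams",
    "PredictionSet",
    "AgeModel",
    "DEFAULT_COST_GRID",
    "DEFAULT_EPSILON_GRID",
    "DEFAULT_GAMMAS",
    "compute_age",
    "pearson_correlation",
    "tune_hyperparameters",
    "fit_age_model",
    "loiocv",
    "refit_predictions",
    "mae",
    "r_squared",
]

# tune.svm-style default search ranges; printed results depend on these, so
# they are arguments everywhere and only defaulted here.
DEFAULT_COST_GRID: tuple[float, ...] = tuple(float(2.0**k) for k in range(-2, 8))
DEFAULT_EPSILON_GRID: tuple[float, ...] = (0.05, 0.1, 0.2, 0.5, 1.0)
DEFAULT_GAMMAS: tuple[float, ...] = (0.5, 1.0)


def compute_age(birth_date: datetime.date, collection_date: datetime.date) -> float:
    """Age in decimal years: (collection - birth) in days / 365.25."""
    days = (collection_date - birth_date).days
    if days < 0:
        raise ValidationError(
            f"collection date {collection_date} precedes birth date {birth_date}"
        )
    return days / 365.25


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson product-moment r with the two-sided t-test p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("Pearson correlation needs two equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("Pearson correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class SampleRecord:
    """One blood sample: identity, age at collection and per-gene methylation."""

    sample_id: str
    individual_id: str
    sex: str
    age_years: float
    methylation: dict[str, float]
    birth_known: bool = True
    collection_date: datetime.date | None = None

    def __post_init__(self):
        if self.age_years < 0:
            raise ValidationError(f"sample {self.sample_id!r}: negative age")
        if self.sex not in ("female", "male", "unknown"):
            raise ValidationError(f"sample {self.sample_id!r}: sex {self.sex!r}")
        for gene, m in self.methylation.items():
            if not 0.0 <= m <= 100.0:
                raise ValidationError(
                    f"sample {self.sample_id!r}: {gene} methylation {m} outside [0, 100]"
                )


@dataclass
class MethylationDataset:
    """Per-sample methylation rates with individual identity and ages."""

    records: list[SampleRecord]
    genes: list[str]

    def __post_init__(self):
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sample ids: {dup}")
        for r in self.records:
            missing = [g for g in self.genes if g not in r.methylation]
            if missing:
                raise ValidationError(
                    f"sample {r.sample_id!r}: missing methylation for gene {missing[0]!r}"
                )

    def __len__(self):
        return len(self.records)

    @property
    def individuals(self) -> list[str]:
        return sorted({r.individual_id for r in self.records})

    def feature_matrix(self, genes: list[str] | None = None) -> np.ndarray:
        genes = self.genes if genes is None else genes
        return np.array([[r.methylation[g] for g in genes] for r in self.records])

    @property
    def ages(self) -> np.ndarray:
        return np.array([r.age_years for r in self.records])

    @property
    def individual_ids(self) -> np.ndarray:
        return np.array([r.individual_id for r in self.records])

    def subset(self, mask: np.ndarray) -> "MethylationDataset":
        return MethylationDataset(
            [r for r, keep in zip(self.records, mask) if keep], list(self.genes)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "sample_id": r.sample_id,
                "individual_id": r.individual_id,
                "sex": r.sex,
                "age_years": r.age_years,
                "birth_known": r.birth_known,
                "collection_date": "" if r.collection_date is None else r.collection_date.isoformat(),
            }
            row.update({g: r.methylation[g] for g in self.genes})
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SvrParams:
    """Epsilon-SVR hyperparameters; kernel and mode are fixed."""

    cost: float
    epsilon: float
    gamma: float
    kernel: str = field(default="radial")
    mode: str = field(default="eps-regression")

    def __post_init__(self):
        if self.cost <= 0 or self.epsilon <= 0 or self.gamma <= 0:
            raise ValidationError("SVR cost, epsilon and gamma must be positive")


@dataclass
class PredictionSet:
    """Per-sample predicted vs chronological age with fold provenance."""

    frame: pd.DataFrame  # sample_id, individual_id, age_years, predicted_age, fold_id
    provenance: str  # 'refit_full' or 'loiocv'

    COLUMNS = ["sample_id", "individual_id", "age_years", "predicted_age", "fold_id"]

    def __post_init__(self):
        missing = [c for c in self.COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"prediction table missing columns {missing}")
        if self.provenance not in ("refit_full", "loiocv"):
            raise ValidationError(f"unknown provenance {self.provenance!r}")

    def __len__(self):
        return len(self.frame)

    def mae(self) -> float:
        return mae(self)

    def r_squared(self, method: str = "pearson") -> float:
        return r_squared(self, method=method)


def mae(pred: PredictionSet) -> float:
    """Mean absolute error between predicted and chronological age, in years."""
    if len(pred) == 0:
        raise ValidationError("empty prediction set")
    return float(np.mean(np.abs(pred.frame["predicted_age"] - pred.frame["age_years"])))


def r_squared(pred: PredictionSet, method: str = "pearson") -> float:
    """Coefficient of determination of predicted vs chronological age.

    ``method='pearson'`` (default): squared Pearson correlation, the
    regression-through-the-data convention used when R² is read off a simple
    linear regression of predicted on chronological age.  ``method='ss'``:
    1 - SSE/SST about the identity prediction.
    """
    y = pred.frame["age_years"].to_numpy(dtype=float)
    p = pred.frame["predicted_age"].to_numpy(dtype=float)
    if method == "pearson":
        r, _ = pearson_correlation(y, p)
        return float(r**2)
    if method == "ss":
        sst = float(np.sum((y - y.mean()) ** 2))
        if sst == 0:
            raise ValidationError("R² undefined: zero age variance")
        return 1.0 - float(np.sum((y - p) ** 2)) / sst
    raise ValidationError(f"unknown R² method {method!r}")


class AgeModel:
    """Fitted SVR age predictor with its training-set feature scaling."""

    def __init__(self, genes, params, mean, scale, svr):
        self.genes = list(genes)
        self.params = params
        self.mean_ = mean
        self.scale_ = scale
        self._svr = svr

    def predict(self, data) -> np.ndarray:
        """Predict ages for a MethylationDataset or a raw feature matrix."""
        x = data.feature_matrix(self.genes) if isinstance(data, MethylationDataset) else np.asarray(data, float)
        return self._svr.predict((x - self.mean_) / self.scale_)


def _scaler(x: np.ndarray, scale: bool) -> tuple[np.ndarray, np.ndarray]:
    if not scale:
        return np.zeros(x.shape[1]), np.ones(x.shape[1])
    sd = x.std(axis=0)
    return x.mean(axis=0), np.where(sd == 0, 1.0, sd)


def fit_age_model(
    dataset: MethylationDataset,
    params: SvrParams,
    genes: list[str] | None = None,
    scale: bool = True,
) -> AgeModel:
    """Fit an epsilon-SVR (radial kernel) on z-scored methylation features."""
    if len(dataset) < 3:
        raise ValidationError("need at least 3 training samples")
    genes = dataset.genes if genes is None else genes
    x = dataset.feature_matrix(genes)
    y = dataset.ages
    mean, sd = _scaler(x, scale)
    svr = SVR(kernel="rbf", C=params.cost, epsilon=params.epsilon, gamma=params.gamma)
    svr.fit((x - mean) / sd, y)
    return AgeModel(genes, params, mean, sd, svr)


def _grouped_folds(individuals: np.ndarray, k: int, rng: np.random.Generator):
    uniq = np.array(sorted(set(individuals)))
    rng.shuffle(uniq)
    return [set(chunk) for chunk in np.array_split(uniq, k)]


def tune_hyperparameters(
    dataset: MethylationDataset,
    cost_grid=DEFAULT_COST_GRID,
    epsilon_grid=DEFAULT_EPSILON_GRID,
    gammas=DEFAULT_GAMMAS,
    seed: int = 0,
    genes: list[str] | None = None,
    scale: bool = True,
) -> SvrParams:
    """Grid-search SVR hyperparameters by individual-grouped k-fold MAE.

    k = min(10, number of individuals).  Ties are broken towards the
    smallest cost, then smallest epsilon, then smallest gamma; with a fixed
    seed the result is deterministic (fold assignment is the only
    randomness).
    """
    cost_grid, epsilon_grid, gammas = list(cost_grid), list(epsilon_grid), list(gammas)
    if not cost_grid or not epsilon_grid or not gammas:
        raise ValidationError("empty hyperparameter grid")
    genes = dataset.genes if genes is None else genes
    x = dataset.feature_matrix(genes)
    y = dataset.ages
    ind = dataset.individual_ids
    k = min(10, len(set(ind)))
    if k < 2:
        raise ValidationError("grouped tuning needs at least 2 individuals")
    rng = np.random.default_rng(seed)
    splits = []
    for fold in _grouped_folds(ind, k, rng):
        test = np.isin(ind, list(fold))
        train = ~test
        mean, sd = _scaler(x[train], scale)
        splits.append(((x[train] - mean) / sd, y[train], (x[test] - mean) / sd, y[test]))

    best_score, best = np.inf, None
    for cost, eps, gamma in product(sorted(cost_grid), sorted(epsilon_grid), sorted(gammas)):
        errors = []
        for xtr, ytr, xte, yte in splits:
            svr = SVR(kernel="rbf", C=cost, epsilon=eps, gamma=gamma)
            errors.append(np.abs(svr.fit(xtr, ytr).predict(xte) - yte))
        score = float(np.mean(np.concatenate(errors)))
        if score < best_score - 1e-12:  # strict improvement => first (smallest) wins ties
            best_score, best = score, SvrParams(float(cost), float(eps), float(gamma))
    return best


def refit_predictions(
    dataset: MethylationDataset,
    params: SvrParams,
    genes: list[str] | None = None,
    scale: bool = True,
) -> PredictionSet:
    """Fit on all samples and predict them back (training-set performance)."""
    model = fit_age_model(dataset, params, genes=genes, scale=scale)
    frame = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in dataset.records],
            "individual_id": dataset.individual_ids,
            "age_years": dataset.ages,
            "predicted_age": model.predict(dataset),
            "fold_id": "all",
        }
    )
    return PredictionSet(frame, "refit_full")


def loiocv(
    dataset: MethylationDataset,
    cost_grid=DEFAULT_COST_GRID,
    epsilon_grid=DEFAULT_EPSILON_GRID,
    gammas=DEFAULT_GAMMAS,
    seed: int = 0,
    genes: list[str] | None = None,
    scale: bool = True,
    tune_once: bool = False,
    params: SvrParams | None = None,
) -> PredictionSet:
    """Leave-one-individual-out cross-validation.

    For each individual, all of that individual's samples form the test
    fold; the model is tuned (grouped k-fold inside the training remainder,
    unless ``tune_once`` or explicit ``params``) and fitted on everyone
    else, then predicts the held-out samples.  Every sample is predicted
    exactly once and never by a model that saw its individual.
    """
    individuals = dataset.individuals
    if len(individuals) < 2:
        raise ValidationError("LOIOCV needs at least 2 individuals")
    genes = dataset.genes if genes is None else genes
    if params is None and tune_once:
        params = tune_hyperparameters(
            dataset, cost_grid, epsilon_grid, gammas, seed=seed, genes=genes, scale=scale
        )
    ind = dataset.individual_ids
    frames = []
    for i, holdout in enumerate(individuals):
        test = ind == holdout
        train_ds = dataset.subset(~test)
        fold_params = params
        if fold_params is None:
            fold_params = tune_hyperparameters(
                train_ds, cost_grid, epsilon_grid, gammas, seed=seed + i, genes=genes, scale=scale
            )
        model = fit_age_model(train_ds, fold_params, genes=genes, scale=scale)
        test_ds = dataset.subset(test)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": [r.sample_id for r in test_ds.records],
                    "individual_id": test_ds.individual_ids,
                    "age_years": test_ds.ages,
                    "predicted_age": model.predict(test_ds),
                    "fold_id": holdout,
                }
            )
        )
    frame = pd.concat(frames, ignore_index=True)
    return PredictionSet(frame, "loiocv")
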