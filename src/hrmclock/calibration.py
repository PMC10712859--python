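"""PCR-bias standard-curve calibration: Df values <-> methylation rates.

PCR on bisulphite-converted templates preferentially amplifies unmethylated
molecules, so the measured melt-curve signal (Df) is a saturating, not
linear, function of the true methylation rate M (in %).  The standard-curve
model used throughout is

    a * M / (100 - M) = Df / (Dfmax - Df)

where Dfmax is the Df value of the fully methylated (100%) standard and the
coefficient ``a`` captures the amplification bias (a < 1: unmethylated
templates amplify better).  Rearranged to the forward form fitted here:

    Df(M) = Dfmax * r / (1 + r),   r = a * M / (100 - M)

``fit_standard_curve`` estimates ``a`` from a dilution series of known
methylation fractions by least squares on Df; ``df_to_methylation`` inverts
the model for unknown samples.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import ConvergenceError, IllConditionedFitWarning, ValidationError
from .melt import DfValue

__all__ = [
    "StandardSeries",
    "CalibrationFit",
    "fit_standard_curve",
    "df_to_methylation",
    "methylation_to_df",
    "quantify_plate",
]

_A_BOUNDS = (1e-6, 1e6)
_A_STARTS = (0.1, 1.0, 10.0)


@dataclass
class StandardSeries:
    """Dilution series of known methylation fractions with measured Df values."""

    gene_id: str
    points: list[tuple[float, float]]  # (nominal fraction M in %, Df)

    def __post_init__(self):
        fractions = [m for m, _ in self.points]
        if len(set(fractions)) != len(fractions):
            raise ValidationError(f"series {self.gene_id!r}: duplicate nominal fractions")
        if 0.0 not in fractions or 100.0 not in fractions:
            raise ValidationError(
                f"series {self.gene_id!r}: must contain the 0% and 100% anchors"
            )
        for m, _ in self.points:
            if not 0.0 <= m <= 100.0:
                raise ValidationError(
                    f"series {self.gene_id!r}: nominal fraction {m} outside [0, 100]"
                )


@dataclass
class CalibrationFit:
    """Fitted standard-curve parameters for one gene/plate."""

    gene_id: str
    a: float
    dfmax: float
    rss: float
    n_points: int

    def __post_init__(self):
        if self.a <= 0:
            raise ValidationError(f"fit {self.gene_id!r}: coefficient a must be positive")
        if self.dfmax <= 0:
            raise ValidationError(f"fit {self.gene_id!r}: Dfmax must be positive")

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CalibrationFit":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


def _forward(m: np.ndarray, a: float, dfmax: float) -> np.ndarray:
    """Predicted Df for methylation rate m (%) under the bias model."""
    m = np.asarray(m, dtype=float)
    interior = np.where(m >= 100.0, 50.0, m)  # placeholder; overwritten below
    ratio = a * interior / (100.0 - interior)
    return np.where(m >= 100.0, dfmax, dfmax * ratio / (1.0 + ratio))


def fit_standard_curve(
    series: StandardSeries, include_anchors: bool = False
) -> CalibrationFit:
    """Fit the bias coefficient ``a`` to a standard dilution series.

    Dfmax is pinned to the measured Df of the 100% standard (it is defined as
    that measurement, not a free parameter).  By default the 0% and 100%
    anchors are excluded from the residual since the model reproduces them by
    construction.  ``a`` is found by bounded scalar minimization in log space
    with multistart around 0.1, 1 and 10.
    """
    points = dict(series.points)
    dfmax = points[100.0]
    if dfmax <= 0:
        raise ValidationError(f"series {series.gene_id!r}: Df of the 100% standard is <= 0")
    interior = [(m, df) for m, df in series.points if 0.0 < m < 100.0]
    if len(interior) < 3:
        raise ValidationError(
            f"series {series.gene_id!r}: need >=3 interior points, got {len(interior)}"
        )
    fit_points = series.points if include_anchors else interior
    m_arr = np.array([m for m, _ in fit_points])
    df_arr = np.array([df for _, df in fit_points])

    if all(df >= dfmax for _, df in interior):
        warnings.warn(
            f"series {series.gene_id!r}: every interior Df >= Dfmax; "
            "the bias coefficient is ill-determined",
            IllConditionedFitWarning,
            stacklevel=2,
        )

    def sse_log(u: float) -> float:
        resid = df_arr - _forward(m_arr, np.exp(u), dfmax)
        return float(resid @ resid)

    lo, hi = np.log(_A_BOUNDS)
    # multistart: bounded searches on overlapping log-space intervals around
    # each start, so a far-from-1 optimum cannot be missed
    brackets = [(lo, np.log(_A_STARTS[1])), (np.log(0.01), np.log(100.0)), (np.log(_A_STARTS[1]), hi)]
    best = None
    for b_lo, b_hi in brackets:
        res = minimize_scalar(
            sse_log, bounds=(b_lo, b_hi), method="bounded", options={"xatol": 1e-12}
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not best.success:
        raise ConvergenceError(
            f"series {series.gene_id!r}: standard-curve fit did not converge",
            best=None if best is None else float(np.exp(best.x)),
        )
    a = float(np.exp(best.x))
    return CalibrationFit(series.gene_id, a, float(dfmax), float(best.fun), len(fit_points))


def df_to_methylation(df, fit: CalibrationFit):
    """Invert the standard curve: Df -> methylation rate M in [0, 100] %.

    With R = Df/(Dfmax - Df), M = 100 R / (a + R).  Values outside the
    calibrated range are clamped: Df <= 0 -> 0%, Df >= Dfmax -> 100%.
    Accepts scalars or arrays.
    """
    df_arr = np.asarray(df, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = df_arr / (fit.dfmax - df_arr)
        m = 100.0 * ratio / (fit.a + ratio)
    m = np.where(df_arr <= 0.0, 0.0, np.where(df_arr >= fit.dfmax, 100.0, m))
    return float(m) if np.isscalar(df) else m


def methylation_to_df(m, fit: CalibrationFit):
    """Forward model: methylation rate M (%) -> predicted Df.

    Exact inverse of :func:`df_to_methylation` on (0, 100).
    """
    m_arr = np.asarray(m, dtype=float)
    if np.any((m_arr < 0) | (m_arr > 100)):
        raise ValidationError("methylation rate outside [0, 100]")
    out = _forward(m_arr, fit.a, fit.dfmax)
    return float(out) if np.isscalar(m) else out


def quantify_plate(
    sample_dfs: dict[str, DfValue] | dict[str, float], fit: CalibrationFit
) -> pd.DataFrame:
    """Apply the calibrated inversion to each sample's aggregated Df.

    Returns a table with columns ``sample_id, gene, df, methylation_pct,
    clamped``; ``clamped`` marks Df values outside [0, Dfmax] that were
    snapped to the 0/100% anchors.
    """
    rows = []
    for sample_id, dfv in sample_dfs.items():
        df = dfv.df if isinstance(dfv, DfValue) else float(dfv)
        rows.append(
            {
                "sample_id": sample_id,
                "gene": fit.gene_id,
                "df": df,
                "methylation_pct": df_to_methylation(df, fit),
                "clamped": bool(df <= 0.0 or df >= fit.dfmax),
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "gene", "df", "methylation_pct", "clamped"])
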