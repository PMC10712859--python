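"""Raw melt curves to normalized curves, difference curves and Df values.

High-resolution melting (HRM) quantifies the dissociation of a PCR amplicon
as temperature rises: fluorescence of a saturating intercalating dye decays
from a high pre-melt plateau to a low post-melt plateau.  Methylated
(bisulphite-retained C/G) templates melt at a higher temperature than
unmethylated ones, so the shape of the melt transition encodes the
methylation level of the amplicon.

The processing chain implemented here mirrors the Gene-Scanning convention:

1. ``normalize_curve`` — fit straight lines to the raw signal inside a
   pre-melt and a post-melt temperature window and map the signal to a
   0–100 "% helicity" scale between those lines.  No temperature shift is
   applied (the shift threshold is fixed at zero so curve shape is
   preserved).
2. ``difference_curve`` — subtract the normalized curve of the 0%-methylated
   standard (the baseline) from each sample's normalized curve.
3. ``df_value`` — the Df value: the maximum absolute relative signal
   difference over the grid.
4. ``aggregate_replicates`` — average Df over duplicate reactions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateBaselineError,
    ReplicateConcordanceWarning,
    ValidationError,
)

__all__ = [
    "MeltCurve",
    "GeneAssay",
    "NormalizedCurve",
    "DifferenceCurve",
    "DfValue",
    "DEFAULT_ASSAYS",
    "normalize_curve",
    "melt_derivative",
    "difference_curve",
    "df_value",
    "aggregate_replicates",
]


@dataclass
class MeltCurve:
    """One well's raw fluorescence over a strictly increasing temperature grid."""

    well_id: str
    gene_id: str
    temperatures: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperatures.shape != self.fluorescence.shape:
            raise ValidationError(
                f"well {self.well_id!r}: temperature and fluorescence lengths differ"
            )
        if self.temperatures.size < 2:
            raise ValidationError(f"well {self.well_id!r}: fewer than 2 points")
        if not np.all(np.diff(self.temperatures) > 0):
            raise ValidationError(
                f"well {self.well_id!r}: temperatures not strictly increasing"
            )

    def __len__(self):
        return self.temperatures.size


@dataclass(frozen=True)
class GeneAssay:
    """Per-gene HRM analysis settings.

    ``pre_melt_window`` and ``post_melt_window`` are closed intervals in °C
    inside which the raw signal is assumed to sit on its linear plateau.
    ``threshold`` is fixed at 0: the temperature-shift step of curve
    normalization is skipped so the melt-curve shape is preserved.
    """

    gene_id: str
    pre_melt_window: tuple[float, float]
    post_melt_window: tuple[float, float]
    amplicon_length: int | None = None
    n_cpgs: int | None = None
    threshold: float = field(default=0.0)

    def __post_init__(self):
        pre_lo, pre_hi = self.pre_melt_window
        post_lo, post_hi = self.post_melt_window
        if not (pre_lo < pre_hi and post_lo < post_hi):
            raise ValidationError(f"assay {self.gene_id!r}: empty melt window")
        if pre_hi >= post_lo:
            raise ValidationError(
                f"assay {self.gene_id!r}: pre-melt window must lie below post-melt window"
            )
        if self.threshold != 0:
            raise ValidationError(
                f"assay {self.gene_id!r}: only threshold=0 (no temperature shift) is supported"
            )


#: Published assay settings for the two elephant age-responsive loci.
DEFAULT_ASSAYS: dict[str, GeneAssay] = {
    "RALYL": GeneAssay("RALYL", (67.0, 68.0), (82.0, 83.0), amplicon_length=109, n_cpgs=8),
    "TET2": GeneAssay("TET2", (66.0, 67.0), (80.0, 81.0), amplicon_length=202, n_cpgs=6),
}


@dataclass
class NormalizedCurve:
    """Melt curve on the 0–100 %-helicity scale."""

    well_id: str
    gene_id: str
    temperatures: np.ndarray
    normalized_signal: np.ndarray


@dataclass
class DifferenceCurve:
    """Signed relative signal difference, sample minus 0% baseline."""

    well_id: str
    temperatures: np.ndarray
    relative_difference: np.ndarray


@dataclass
class DfValue:
    """Scalar melt-curve summary: max |relative difference| and where it occurs."""

    well_id: str
    df: float
    argmax_temperature: float


def _window_line(curve: MeltCurve, window: tuple[float, float], which: str) -> np.ndarray:
    """Least-squares line through the raw signal inside a closed window.

    Returns the line evaluated on the full grid.
    """
    lo, hi = window
    mask = (curve.temperatures >= lo) & (curve.temperatures <= hi)
    if mask.sum() < 2:
        raise ValidationError(
            f"well {curve.well_id!r}: {which}-melt window [{lo}, {hi}] °C covered by "
            f"{int(mask.sum())} point(s); need at least 2"
        )
    slope, intercept = np.polyfit(curve.temperatures[mask], curve.fluorescence[mask], 1)
    return slope * curve.temperatures + intercept


def normalize_curve(curve: MeltCurve, assay: GeneAssay) -> NormalizedCurve:
    """Map a raw melt curve to the 0–100 % helicity scale.

    ``normalized(T) = 100 * (F(T) - Lpost(T)) / (Lpre(T) - Lpost(T))`` where
    ``Lpre``/``Lpost`` are straight lines fitted to the raw signal inside the
    pre-/post-melt windows.  The result is invariant to any affine transform
    ``a*F + c`` (a > 0) of the raw signal.
    """
    l_pre = _window_line(curve, assay.pre_melt_window, "pre")
    l_post = _window_line(curve, assay.post_melt_window, "post")
    denom = l_pre - l_post
    if np.any(denom <= 0):
        raise DegenerateBaselineError(
            f"well {curve.well_id!r}: pre- and post-melt baseline lines touch or cross "
            "(no dynamic range)"
        )
    signal = 100.0 * (curve.fluorescence - l_post) / denom
    return NormalizedCurve(curve.well_id, curve.gene_id, curve.temperatures.copy(), signal)


def melt_derivative(curve: NormalizedCurve) -> NormalizedCurve:
    """Negative first derivative -dN/dT of a normalized curve (melt-peak view).

    Used by the optional ``difference_mode='derivative'``; the default
    difference plot subtracts normalized curves directly.
    """
    deriv = -np.gradient(curve.normalized_signal, curve.temperatures)
    return NormalizedCurve(curve.well_id, curve.gene_id, curve.temperatures.copy(), deriv)


def difference_curve(sample: NormalizedCurve, baseline: NormalizedCurve) -> DifferenceCurve:
    """Sample minus baseline on the overlap of their grids.

    The baseline is linearly interpolated onto the sample grid; extrapolation
    is forbidden, so the result is restricted to the overlapping temperature
    range.
    """
    if sample.gene_id != baseline.gene_id:
        raise ValidationError(
            f"gene mismatch: sample {sample.gene_id!r} vs baseline {baseline.gene_id!r}"
        )
    lo = max(sample.temperatures[0], baseline.temperatures[0])
    hi = min(sample.temperatures[-1], baseline.temperatures[-1])
    if lo > hi:
        raise ValidationError(
            f"well {sample.well_id!r}: sample and baseline grids do not overlap"
        )
    mask = (sample.temperatures >= lo) & (sample.temperatures <= hi)
    temps = sample.temperatures[mask]
    base = np.interp(temps, baseline.temperatures, baseline.normalized_signal)
    return DifferenceCurve(sample.well_id, temps, sample.normalized_signal[mask] - base)


def df_value(diff: DifferenceCurve) -> DfValue:
    """Df value: maximum absolute relative difference (ties -> lowest T)."""
    if diff.temperatures.size == 0:
        raise ValidationError(f"well {diff.well_id!r}: empty difference curve")
    abs_diff = np.abs(diff.relative_difference)
    idx = int(np.argmax(abs_diff))  # first max = lowest temperature
    return DfValue(diff.well_id, float(abs_diff[idx]), float(diff.temperatures[idx]))


def aggregate_replicates(
    dfs: list[DfValue], concordance_limit: float | None = None
) -> DfValue:
    """Mean Df over duplicate reactions of one sample/gene.

    The reported peak temperature is taken from the replicate whose Df is
    closest to the mean.  If the replicate spread exceeds
    ``concordance_limit`` (typically 20% of Dfmax) a
    :class:`ReplicateConcordanceWarning` is emitted — flagged, not fatal.
    """
    if not dfs:
        raise ValidationError("no replicates to aggregate")
    values = np.array([d.df for d in dfs])
    mean = float(values.mean())
    if concordance_limit is not None and values.max() - values.min() > concordance_limit:
        warnings.warn(
            f"replicates of well {dfs[0].well_id!r} span "
            f"{values.max() - values.min():.3g} > limit {concordance_limit:.3g}",
            ReplicateConcordanceWarning,
            stacklevel=2,
        )
    closest = dfs[int(np.argmin(np.abs(values - mean)))]
    return DfValue(dfs[0].well_id, mean, closest.argmax_temperature)
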