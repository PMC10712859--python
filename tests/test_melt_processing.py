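import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hrmclock import (
    DfValue,
    MeltCurve,
    ValidationError,
    aggregate_replicates,
    df_value,
    difference_curve,
    normalize_curve,
    simulate_melt_curve,
)
from hrmclock.errors import DegenerateBaselineError, ReplicateConcordanceWarning
from hrmclock.melt import NormalizedCurve

TEMPS = np.arange(65.0, 95.0 + 0.25, 0.5)


def piecewise_curve(offset=0.0, slope=0.0):
    """Flat 500 below 75 °C, flat 100 above 80 °C, linear ramp between."""
    f = np.where(
        TEMPS <= 75.0,
        500.0,
        np.where(TEMPS >= 80.0, 100.0, 500.0 - 80.0 * (TEMPS - 75.0)),
    )
    return MeltCurve("W", "RALYL", TEMPS, f + offset + slope * TEMPS)


def test_piecewise_normalization_plateaus_and_midpoint(ralyl_assay):
    nc = normalize_curve(piecewise_curve(), ralyl_assay)
    pre = (TEMPS >= 67.0) & (TEMPS <= 68.0)
    post = (TEMPS >= 82.0) & (TEMPS <= 83.0)
    assert np.allclose(nc.normalized_signal[pre], 100.0, atol=1e-9)
    assert np.allclose(nc.normalized_signal[post], 0.0, atol=1e-9)
    mid = np.searchsorted(TEMPS, 77.5)
    assert nc.normalized_signal[mid] == pytest.approx(50.0, abs=1e-9)


def test_added_global_slope_normalizes_identically(ralyl_assay):
    # The window baselines are lines: F -> F - 2T shifts both lines by -2T,
    # leaving the normalized output unchanged.
    plain = normalize_curve(piecewise_curve(), ralyl_assay)
    sloped = normalize_curve(piecewise_curve(slope=-2.0), ralyl_assay)
    assert np.allclose(plain.normalized_signal, sloped.normalized_signal, atol=1e-9)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(
    scale=st.floats(min_value=0.01, max_value=100.0),
    offset=st.floats(min_value=-1e4, max_value=1e4),
)
def test_normalization_affine_invariance(scale, offset):
    from hrmclock import DEFAULT_ASSAYS

    assay = DEFAULT_ASSAYS["RALYL"]
    base = piecewise_curve()
    transformed = MeltCurve("W", "RALYL", TEMPS, scale * base.fluorescence + offset)
    a = normalize_curve(base, assay).normalized_signal
    b = normalize_curve(transformed, assay).normalized_signal
    assert np.allclose(a, b, atol=1e-6)


def test_constant_curve_is_degenerate(ralyl_assay):
    curve = MeltCurve("W", "RALYL", TEMPS, np.full(TEMPS.size, 300.0))
    with pytest.raises(DegenerateBaselineError):
        normalize_curve(curve, ralyl_assay)


def test_window_not_covered(ralyl_assay):
    temps = np.arange(70.0, 95.0, 0.5)  # misses the 67-68 °C pre window
    curve = MeltCurve("W", "RALYL", temps, np.linspace(500, 100, temps.size))
    with pytest.raises(ValidationError, match="pre-melt"):
        normalize_curve(curve, ralyl_assay)


def test_difference_identity_and_uniform_shift(ralyl_assay):
    nc = normalize_curve(piecewise_curve(), ralyl_assay)
    diff = difference_curve(nc, nc)
    assert np.allclose(diff.relative_difference, 0.0)
    assert df_value(diff).df == 0.0

    shifted = NormalizedCurve("W2", "RALYL", nc.temperatures, nc.normalized_signal + 5.0)
    diff = difference_curve(shifted, nc)
    assert np.allclose(diff.relative_difference, 5.0)
    assert df_value(diff).df == pytest.approx(5.0)


def test_difference_disjoint_grids_error():
    a = NormalizedCurve("A", "G", np.array([65.0, 66.0]), np.array([1.0, 2.0]))
    b = NormalizedCurve("B", "G", np.array([80.0, 81.0]), np.array([1.0, 2.0]))
    with pytest.raises(ValidationError, match="overlap"):
        difference_curve(a, b)


def test_difference_gene_mismatch_error():
    a = NormalizedCurve("A", "G1", np.array([65.0, 66.0]), np.array([1.0, 2.0]))
    b = NormalizedCurve("B", "G2", np.array([65.0, 66.0]), np.array([1.0, 2.0]))
    with pytest.raises(ValidationError, match="gene"):
        difference_curve(a, b)


def test_df_value_examples_and_tie_break():
    from hrmclock.melt import DifferenceCurve

    diff = DifferenceCurve("W", np.array([70.0, 71.0, 72.0, 73.0]), np.array([-1.0, 4.0, -6.0, 2.0]))
    dfv = df_value(diff)
    assert dfv.df == 6.0
    assert dfv.argmax_temperature == 72.0

    tie = DifferenceCurve("W", np.array([70.0, 71.0, 72.0]), np.array([5.0, -5.0, 5.0]))
    assert df_value(tie).argmax_temperature == 70.0  # lowest temperature wins


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.floats(min_value=-50, max_value=50), min_size=1, max_size=40))
def test_df_value_matches_exhaustive_scan(values):
    from hrmclock.melt import DifferenceCurve

    temps = np.arange(len(values), dtype=float) + 65.0
    dfv = df_value(DifferenceCurve("W", temps, np.array(values)))
    brute = max(abs(v) for v in values)
    assert dfv.df == pytest.approx(brute)


def test_df_subadditivity_under_curve_addition():
    rng = np.random.default_rng(4)
    from hrmclock.melt import DifferenceCurve

    temps = np.arange(65.0, 95.0, 0.5)
    for _ in range(20):
        x = rng.normal(size=temps.size)
        y = rng.normal(size=temps.size)
        b = rng.normal(size=temps.size)
        df_xy = df_value(DifferenceCurve("W", temps, (x + y) - b)).df
        df_x = df_value(DifferenceCurve("W", temps, x - b)).df
        df_y = df_value(DifferenceCurve("W", temps, y)).df
        assert df_xy <= df_x + df_y + 1e-12


def test_aggregate_mean_and_identity():
    mk = lambda df: DfValue("W", df, 75.0)
    assert aggregate_replicates([mk(4.0), mk(6.0)]).df == pytest.approx(5.0)
    assert aggregate_replicates([mk(3.2)]).df == pytest.approx(3.2)


def test_aggregate_concordance_warning():
    dfs = [DfValue("W", 1.0, 75.0), DfValue("W", 9.0, 76.0)]
    with pytest.warns(ReplicateConcordanceWarning):
        out = aggregate_replicates(dfs, concordance_limit=2.0)
    assert out.df == pytest.approx(5.0)


def test_noisy_duplicates_aggregate_near_truth(quiet_spec, ralyl_assay):
    """Duplicate Df means stay within a few normalized-scale noise sd of truth."""
    from dataclasses import replace

    sigma_raw = 2.0
    noisy_spec = replace(quiet_spec, noise_sd=sigma_raw)
    baseline = normalize_curve(simulate_melt_curve(quiet_spec, 0.0), ralyl_assay)
    truth_curve = normalize_curve(simulate_melt_curve(quiet_spec, 0.5), ralyl_assay)
    df_true = df_value(difference_curve(truth_curve, baseline)).df
    # raw noise scales to the % scale by 100 / dynamic range (~490 units)
    sigma_norm = 100.0 * sigma_raw / 490.0
    errors = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        reps = []
        for _ in range(2):
            nc = normalize_curve(simulate_melt_curve(noisy_spec, 0.5, rng), ralyl_assay)
            reps.append(df_value(difference_curve(nc, baseline)))
        errors.append(abs(aggregate_replicates(reps).df - df_true))
    # the Df picks a max over the grid, so single errors are mildly
    # heavy-tailed; the median over seeds obeys the Gaussian scaling
    assert np.median(errors) < 3.0 * sigma_norm / np.sqrt(2)


def test_aggregate_empty_error():
    with pytest.raises(ValidationError):
        aggregate_replicates([])
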