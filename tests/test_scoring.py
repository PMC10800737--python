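"""The composite score: formulas, bounds, symmetry, calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from anthrofail.scoring import (
    CalibrationError,
    Classification,
    ScoreParams,
    calibrate_cutoff,
    classify_by_score,
    composite_score,
    max_unscaled_score,
    max_unscaled_sum,
    signed_power,
)

# ---------------------------------------------------------------------------
# Independent oracle: the literal two-branch formulation with the quotient
# power z^(2n-1) / |z^(n-1)|.  Kept test-side, independent of the package's
# single-form implementation.


def literal_quotient_power(z: float, n: int) -> float:
    return z ** (2 * n - 1) / abs(z ** (n - 1))


def literal_branch_score(haz: float, waz: float, whz: float, n: int) -> float:
    scale = 100.0 / (3 * 6**n + 2 * 5**n)
    assert haz != 0 and waz != 0 and whz != 0, "literal quotient undefined at 0"
    hw = literal_quotient_power(haz, n) + literal_quotient_power(waz, n)
    if whz < 0:
        return scale * ((6**n + 5**n) - (hw + literal_quotient_power(whz, n)))
    return scale * ((6**n + 5**n) - (hw - literal_quotient_power(whz, n)))


finite_z = st.floats(-5.0, 5.0, allow_nan=False).filter(lambda z: abs(z) > 1e-3)


# ---------------------------------------------------------------------------
# signed_power


@pytest.mark.parametrize(
    "z,n,expected",
    [(-2, 2, -4), (0, 15, 0), (-3, 3, -27), (2, 3, 8), (-1.5, 2, -2.25)],
)
def test_signed_power_examples(z, n, expected):
    assert signed_power(z, n) == pytest.approx(expected)


def test_signed_power_matches_literal_quotient():
    # (-3)^(2·3-1) / |(-3)^(3-1)| = -243/9 = -27
    assert literal_quotient_power(-3, 3) == -27
    rng = np.random.default_rng(0)
    for _ in range(500):
        z = float(rng.uniform(-5, 5))
        n = int(rng.integers(1, 8))  # quotient overflows for large n; oracle range only
        if z == 0:
            continue
        assert signed_power(z, n) == pytest.approx(literal_quotient_power(z, n), rel=1e-12)


# ---------------------------------------------------------------------------
# composite_score


def test_score_extremes_all_n():
    """Score spans exactly [0, 100]: 100 at (-6,-6,-5), 0 at (+6,+5,0)."""
    for n in range(1, 20):
        params = ScoreParams(n=n)
        assert composite_score(-6, -6, -5, params) == 100.0
        assert composite_score(6, 5, 0, params) == 0.0
    # n = 20: bracket exceeds 2^53, top corner correct to 1 ulp.
    assert composite_score(-6, -6, -5, ScoreParams(n=20)) == pytest.approx(100.0, rel=1e-12)


def test_score_n1_neutral_point():
    # 11/28 of the range at the WHO median child.
    assert composite_score(0, 0, 0, ScoreParams(n=1)) == pytest.approx(100 * 11 / 28)


def test_score_rejects_out_of_box():
    with pytest.raises(ValueError):
        composite_score(-6.5, 0, 0)
    with pytest.raises(ValueError):
        composite_score(0, 5.2, 0)
    with pytest.raises(ValueError):
        composite_score(0, 0, -5.1)


@given(
    haz=st.floats(-6, 6, allow_nan=False),
    waz=st.floats(-6, 5, allow_nan=False),
    whz=st.floats(0, 5, allow_nan=False),
    n=st.sampled_from([1, 2, 3, 15]),
)
@settings(max_examples=300, deadline=None)
def test_score_whz_sign_symmetry_and_bounds(haz, waz, whz, n):
    params = ScoreParams(n=n)
    plus = composite_score(haz, waz, whz, params)
    minus = composite_score(haz, waz, -whz, params)
    assert plus == minus
    assert 0.0 <= plus <= 100.0


@given(
    haz=finite_z, waz=finite_z, whz=finite_z,
    n=st.sampled_from([1, 2, 3, 4, 5, 6, 7]),
)
@settings(max_examples=300, deadline=None)
def test_score_equals_literal_branch_formulas(haz, waz, whz, n):
    """The single-form implementation equals the printed two-branch quotient
    formulas to 1e-9 relative error (away from the 0/0 point)."""
    got = composite_score(haz, waz, whz, ScoreParams(n=n))
    want = literal_branch_score(haz, waz, whz, n)
    assert got == pytest.approx(want, rel=1e-9, abs=1e-9)


@given(
    z1=st.floats(-6, 6, allow_nan=False),
    z2=st.floats(-6, 6, allow_nan=False),
    other=st.floats(-5, 5, allow_nan=False),
    n=st.sampled_from([1, 2, 15]),
)
@settings(max_examples=200, deadline=None)
def test_score_monotonicity(z1, z2, other, n):
    """Non-increasing in HAZ and WAZ; non-decreasing in |WHZ|."""
    params = ScoreParams(n=n)
    lo, hi = sorted([z1, z2])
    waz = max(-6.0, min(5.0, other))
    whz = max(-5.0, min(5.0, other))
    assert composite_score(lo, waz, whz, params) >= composite_score(hi, waz, whz, params)
    wlo, whi = max(lo, -6.0), min(hi, 5.0)
    if wlo <= whi:
        haz = max(-6.0, min(6.0, other))
        assert composite_score(haz, wlo, whz, params) >= composite_score(haz, whi, whz, params)
    alo, ahi = sorted([abs(z1), abs(z2)])
    if ahi <= 5:
        haz = max(-6.0, min(6.0, other))
        assert composite_score(haz, waz, alo, params) <= composite_score(haz, waz, ahi, params)


def test_score_vectorized_matches_scalar():
    rng = np.random.default_rng(1)
    haz = rng.uniform(-6, 6, 50)
    waz = rng.uniform(-6, 5, 50)
    whz = rng.uniform(-5, 5, 50)
    vec = composite_score(haz, waz, whz)
    for i in range(50):
        # numpy's vectorized pow can differ from the scalar path by 1 ulp
        assert vec[i] == pytest.approx(composite_score(haz[i], waz[i], whz[i]), rel=1e-14)


# ---------------------------------------------------------------------------
# brute-force maxima of the n = 1 construction


def test_max_unscaled_sum_is_11():
    assert max_unscaled_sum() == 11.0
    # independent dense-grid cross-check
    assert max_unscaled_sum(grid_step=0.25) == 11.0


def test_max_unscaled_score_is_28_at_worst_corner():
    value, point = max_unscaled_score()
    assert value == 28.0
    assert point == (-6.0, -6.0, -5.0)
    value_grid, point_grid = max_unscaled_score(grid_step=0.25)
    assert (value_grid, point_grid) == (28.0, (-6.0, -6.0, -5.0))


def test_max_unscaled_sum_restricted_box():
    from anthrofail.records import PlausibilityLimits

    # near-degenerate box around the origin: branch sum ≈ 0, unscaled score ≈ 11
    box = PlausibilityLimits(haz_lo=-1e-12, haz_hi=1e-12, waz_lo=-1e-12,
                             waz_hi=1e-12, whz_lo=-1e-12, whz_hi=1e-12)
    assert max_unscaled_sum(box) == pytest.approx(0.0, abs=1e-11)
    value, _ = max_unscaled_score(box)
    assert value == pytest.approx(11.0, abs=1e-11)


# ---------------------------------------------------------------------------
# calibration and classification


def test_calibrate_cutoff_examples():
    calib = calibrate_cutoff([(10, -1.0), (20, -2.2), (30, -3.0)])
    assert calib.cutoff == 20 and calib.qualifying_count == 2
    with pytest.raises(CalibrationError, match="-2.1"):
        calibrate_cutoff([(10, -1.0)])


def test_calibrate_cutoff_matches_filter_then_min_oracle():
    rng = np.random.default_rng(5)
    haz = rng.uniform(-6, 6, 1000)
    scores = rng.uniform(0, 100, 1000)
    calib = calibrate_cutoff(zip(scores, haz))
    oracle = min(s for s, h in zip(scores, haz) if h < -2.10)
    assert calib.cutoff == oracle
    assert calib.qualifying_count == int((haz < -2.10).sum())


def test_classify_by_score_tie_goes_to_failure():
    assert classify_by_score(50, 34) is Classification.FAILURE
    assert classify_by_score(10, 34) is Classification.NO_FAILURE
    assert classify_by_score(34.0, 34.0) is Classification.FAILURE


def test_calibration_guarantee_every_qualifying_record_fails():
    """Any record with HAZ below the threshold scores at or above the
    calibrated cut-off, hence classifies Failure."""
    rng = np.random.default_rng(11)
    haz = rng.uniform(-6, 6, 2000)
    waz = rng.uniform(-6, 5, 2000)
    whz = rng.uniform(-5, 5, 2000)
    scores = composite_score(haz, waz, whz, ScoreParams(n=15))
    calib = calibrate_cutoff(zip(scores, haz))
    for s, h in zip(scores, haz):
        if h < calib.haz_threshold:
            assert classify_by_score(s, calib.cutoff) is Classification.FAILURE


def test_score_params_validation():
    with pytest.raises(ValueError):
        ScoreParams(n=0)
    p = ScoreParams(n=1)
    assert p.offset == 11 and p.denom == 28
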