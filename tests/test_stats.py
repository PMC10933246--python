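"""Repeatability statistics: worked values, identities, invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmikit import (
    RC_FACTOR,
    between_subject_cov,
    bland_altman,
    dynamics_fit,
    repeatability_coefficient,
    repeatability_table,
    within_subject_cov,
)


def test_between_subject_cov_hand_computed():
    assert between_subject_cov([2.0, 4.0, 6.0]) == pytest.approx(50.0, abs=1e-12)


def test_between_subject_cov_constant_is_zero():
    assert between_subject_cov([3.0, 3.0, 3.0]) == 0.0


def test_between_subject_cov_averages_sessions_first():
    values = np.array([[1.0, 3.0], [4.0, 4.0], [5.0, 7.0]])  # subject x session
    assert between_subject_cov(values) == pytest.approx(
        between_subject_cov(values.mean(axis=1))
    )


def test_within_subject_cov_hand_computed():
    assert within_subject_cov(np.array([10.0, 10.0]), np.array([12.0, 8.0])) == pytest.approx(
        20.0, abs=1e-9
    )


def test_within_subject_cov_perfect_repeatability():
    e = np.array([3.0, 5.0, 9.0])
    assert within_subject_cov(e, e) == 0.0


def test_within_subject_cov_symmetric_in_exam_order(rng):
    e1 = rng.random(8) + 1
    e2 = rng.random(8) + 1
    assert within_subject_cov(e1, e2) == pytest.approx(within_subject_cov(e2, e1))


@pytest.mark.parametrize(
    "ws,rc", [(5.4, 15.0), (6.9, 19.1), (15.7, 43.5), (8.9, 24.7), (8.5, 23.6), (0.0, 0.0)]
)
def test_repeatability_coefficient_worked_examples(ws, rc):
    assert repeatability_coefficient(ws) == pytest.approx(rc, abs=0.15)


def test_repeatability_coefficient_rejects_negative():
    with pytest.raises(ValueError):
        repeatability_coefficient(-1.0)


@given(st.floats(0.1, 1e6))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_all_statistics_scale_invariant(c):
    e1 = np.array([10.0, 12.0, 9.0, 11.0])
    e2 = np.array([11.0, 11.5, 8.0, 12.5])
    assert within_subject_cov(c * e1, c * e2) == pytest.approx(
        within_subject_cov(e1, e2), rel=1e-9
    )
    assert between_subject_cov(c * e1) == pytest.approx(between_subject_cov(e1), rel=1e-9)


def test_bland_altman_identical_and_offset():
    e = np.array([4.0, 6.0, 8.0])
    assert bland_altman(e, e) == (0.0, 0.0, 0.0)
    bias, lo, hi = bland_altman(e, e + 1)
    assert (bias, lo, hi) == (1.0, 1.0, 1.0)


def test_bland_altman_antisymmetric(rng):
    e1, e2 = rng.random(6), rng.random(6)
    b1, lo1, hi1 = bland_altman(e1, e2)
    b2, lo2, hi2 = bland_altman(e2, e1)
    assert b2 == pytest.approx(-b1)
    assert lo2 == pytest.approx(-hi1)
    assert hi2 == pytest.approx(-lo1)


def test_dynamics_fit_exact_quadratic():
    t = np.array([0.0, 30.0, 75.0, 120.0, 0.0, 30.0, 75.0, 120.0])
    y = 1 + 2 * t - 0.01 * t**2
    c = dynamics_fit(t, y)
    assert np.allclose(c, [1.0, 2.0, -0.01], atol=1e-9)


def test_dynamics_fit_constant_data():
    t = np.array([0.0, 30.0, 75.0, 120.0])
    c = dynamics_fit(t, np.full(4, 5.0))
    assert np.allclose(c[1:], 0.0, atol=1e-9)


def test_dynamics_fit_matches_normal_equations(rng):
    t = np.repeat([0.0, 30.0, 75.0, 120.0], 3)
    y = 0.5 + 0.03 * t - 1e-4 * t**2 + 0.1 * rng.standard_normal(t.size)
    design = np.stack([np.ones_like(t), t, t * t], axis=1)
    expected = np.linalg.solve(design.T @ design, design.T @ y)
    assert np.allclose(dynamics_fit(t, y), expected, rtol=1e-9)


def test_dynamics_fit_needs_three_distinct_times():
    with pytest.raises(ValueError):
        dynamics_fit(np.array([0.0, 0.0, 30.0]), np.array([1.0, 1.1, 2.0]))


def test_table_rows_satisfy_rc_ratio(rng):
    rows = []
    for subject in range(6):
        for session in range(2):
            for metab in ("water", "glucose"):
                rows.append(
                    dict(subject=subject, session=session, timepoint_min=120.0,
                         region="whole_brain", metabolite=metab,
                         value=10 + rng.random())
                )
    table = repeatability_table(pd.DataFrame(rows))
    valid = table.dropna()
    assert len(valid) == 2
    ratio = valid.repeatability_coefficient_pct / valid.within_subject_cov_pct
    assert np.allclose(ratio, RC_FACTOR, rtol=1e-9)
    assert np.allclose(RC_FACTOR, 2.7719, atol=5e-5)
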