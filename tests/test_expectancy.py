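"""Life-table engine: grid conventions, closed forms, decomposition,
origin weighting."""
import numpy as np
import pandas as pd
import pytest

from conftest import random_matrix_set
from mmle import (
    CovariateProfile,
    HealthState,
    OriginDistribution,
    StateExpectancies,
    TransitionMatrixSet,
    build_matrix_set,
    conditional_expectancies,
    origin_distribution,
    weighted_expectancies,
)

ND, OD, MM, D = (
    HealthState.NO_DISEASE,
    HealthState.ONE_DISEASE,
    HealthState.MULTIMORBID,
    HealthState.DEAD,
)


def _constant_set(P_row_builder, n_intervals=33, start_age=20.0):
    mats = np.zeros((n_intervals, 4, 4))
    for k in range(n_intervals):
        mats[k] = P_row_builder()
    return TransitionMatrixSet(
        start_age=start_age,
        truncation_age=start_age + 2.0 * n_intervals,
        matrices=mats,
    )


def _identity_transient():
    P = np.zeros((4, 4))
    for i in range(4):
        P[i, i] = 1.0
    return P


def test_default_grid_has_33_matrices(fitted_female):
    ms = build_matrix_set(fitted_female, CovariateProfile(0.5))
    assert ms.n_intervals == 33
    assert ms.ages[0] == 20.0 and ms.ages[-1] == 84.0


def test_age40_grid_has_23_matrices(fitted_female):
    ms = build_matrix_set(fitted_female, CovariateProfile(0.5), start_age=40.0)
    assert ms.n_intervals == 23
    assert ms.ages[-1] == 84.0


def test_built_matrices_are_valid(fitted_female):
    ms = build_matrix_set(fitted_female, CovariateProfile(0.5))
    rows = ms.matrices.sum(axis=2)
    assert np.abs(rows - 1).max() < 1e-12
    assert (ms.matrices[:, 1, 0] == 0).all()
    assert (ms.matrices[:, 2, :2] == 0).all()
    assert (ms.matrices[:, 3, :3] == 0).all() and (ms.matrices[:, 3, 3] == 1).all()


def test_no_movement_yields_full_horizon_in_origin_state():
    ms = _constant_set(_identity_transient)
    exp = conditional_expectancies(ms, ND)
    assert exp.total_le == pytest.approx(66.0, abs=1e-12)
    assert exp.years_by_state[ND] == pytest.approx(66.0, abs=1e-12)
    assert exp.years_by_state[OD] == 0.0 and exp.years_by_state[MM] == 0.0


def test_certain_death_credits_the_origin_interval():
    def builder():
        P = np.zeros((4, 4))
        P[:, 3] = 1.0
        P[3] = [0, 0, 0, 1]
        return P

    ms = _constant_set(builder)
    for origin in (ND, OD, MM):
        exp = conditional_expectancies(ms, origin)
        assert exp.total_le == pytest.approx(2.0, abs=1e-12)
        assert exp.years_by_state[origin] == pytest.approx(2.0, abs=1e-12)


def test_geometric_chain_closed_form():
    p = 0.9

    def builder():
        P = np.zeros((4, 4))
        P[0] = [p, 0, 0, 1 - p]
        P[1] = [0, p, 0, 1 - p]
        P[2] = [0, 0, p, 1 - p]
        P[3] = [0, 0, 0, 1]
        return P

    ms = _constant_set(builder)
    expected = 2.0 * (1 - p**33) / (1 - p)
    for origin in (ND, OD, MM):
        exp = conditional_expectancies(ms, origin)
        assert exp.total_le == pytest.approx(expected, abs=1e-9)


def test_forward_and_fundamental_agree_on_random_sets():
    for seed in range(8):
        ms = random_matrix_set(seed)
        for origin in (ND, OD, MM):
            a = conditional_expectancies(ms, origin, method="fundamental")
            b = conditional_expectancies(ms, origin, method="forward")
            for s in (ND, OD, MM):
                assert a.years_by_state[s] == pytest.approx(
                    b.years_by_state[s], abs=1e-9
                )


def test_decomposition_identity_and_bounds():
    for seed in range(8):
        ms = random_matrix_set(seed)
        for origin in (ND, OD, MM):
            exp = conditional_expectancies(ms, origin)
            assert sum(exp.years_by_state.values()) == pytest.approx(
                exp.total_le, abs=1e-9
            )
            assert 0.0 <= exp.total_le <= 2.0 * ms.n_intervals + 1e-9


def test_multimorbid_origin_spends_years_only_in_multimorbidity():
    ms = random_matrix_set(3)
    exp = conditional_expectancies(ms, MM)
    assert exp.years_by_state[ND] == 0.0
    assert exp.years_by_state[OD] == 0.0
    assert exp.total_le == pytest.approx(exp.years_by_state[MM], abs=1e-12)


def test_half_weighted_final_interval_reduces_le():
    ms = random_matrix_set(4)
    full = conditional_expectancies(ms, ND)
    half = conditional_expectancies(ms, ND, final_interval_weight=0.5)
    assert half.total_le < full.total_le


def test_raising_death_probability_never_raises_le():
    for seed in range(5):
        ms = random_matrix_set(seed)
        mats = ms.matrices.copy()
        # shift 5 points of stay probability into death in every row
        for i in range(3):
            delta = np.minimum(mats[:, i, i], 0.05)
            mats[:, i, i] -= delta
            mats[:, i, 3] += delta
        worse = TransitionMatrixSet(
            start_age=ms.start_age,
            truncation_age=ms.truncation_age,
            matrices=mats,
        )
        for origin in (ND, OD, MM):
            le0 = conditional_expectancies(ms, origin).total_le
            le1 = conditional_expectancies(worse, origin).total_le
            assert le1 <= le0 + 1e-12


def test_invalid_matrices_rejected():
    mats = np.zeros((33, 4, 4))
    mats[:, :, 0] = 1.0  # every row jumps to state 0: reverse transitions
    with pytest.raises(ValueError, match="structural zero"):
        TransitionMatrixSet(start_age=20, truncation_age=86, matrices=mats)
    bad = np.zeros((33, 4, 4))
    bad[:, 0, 0] = 0.7  # rows do not sum to one
    with pytest.raises(ValueError, match="sum"):
        TransitionMatrixSet(start_age=20, truncation_age=86, matrices=bad)


def _states_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["person_id", "wave", "age", "sex", "state", "design_weight"],
    )


def test_origin_distribution_hand_computed():
    df = _states_frame(
        [
            (1, 1, 25.0, "female", int(ND), 2.0),
            (2, 1, 22.0, "female", int(MM), 1.0),
        ]
    )
    dist = origin_distribution(df, "female")
    assert dist.weights[ND] == pytest.approx(2 / 3)
    assert dist.weights[OD] == 0.0
    assert dist.weights[MM] == pytest.approx(1 / 3)


def test_origin_distribution_all_disease_free():
    df = _states_frame([(i, 1, 21.0 + i * 0.1, "male", int(ND), 1.0) for i in range(5)])
    dist = origin_distribution(df, "male")
    assert dist.weights[ND] == 1.0


def test_origin_distribution_sums_to_one(derived_states):
    for sex in ("male", "female"):
        dist = origin_distribution(derived_states, sex)
        assert sum(dist.weights.values()) == pytest.approx(1.0, abs=1e-12)


def test_origin_distribution_empty_window_rejected():
    df = _states_frame([(1, 1, 55.0, "male", int(ND), 1.0)])
    with pytest.raises(ValueError, match="no baseline"):
        origin_distribution(df, "male", (20.0, 30.0))


def _three_conditionals():
    def mk(origin, nd, od, mm):
        return StateExpectancies(
            origin=origin,
            years_by_state={ND: nd, OD: od, MM: mm},
            total_le=nd + od + mm,
        )

    return {ND: mk(ND, 30.0, 10.0, 5.0), OD: mk(OD, 0.0, 25.0, 8.0), MM: mk(MM, 0.0, 0.0, 20.0)}


def test_weighted_expectancies_dot_product_oracle():
    cond = _three_conditionals()
    dist = OriginDistribution({ND: 0.5, OD: 0.3, MM: 0.2})
    res = weighted_expectancies(cond, dist)
    assert res.weighted_le == pytest.approx(0.5 * 45 + 0.3 * 33 + 0.2 * 20)
    assert res.mmle == pytest.approx(0.5 * 5 + 0.3 * 8 + 0.2 * 20)
    lows = min(c.total_le for c in cond.values())
    highs = max(c.total_le for c in cond.values())
    assert lows <= res.weighted_le <= highs  # convex combination


def test_point_mass_distribution_recovers_conditional():
    cond = _three_conditionals()
    res = weighted_expectancies(cond, OriginDistribution({ND: 1.0, OD: 0.0, MM: 0.0}))
    assert res.weighted_le == cond[ND].total_le
    assert res.mmle == cond[ND].years_by_state[MM]


def test_weight_on_missing_origin_rejected():
    cond = _three_conditionals()
    del cond[MM]
    with pytest.raises(ValueError, match="MULTIMORBID"):
        weighted_expectancies(cond, OriginDistribution({ND: 0.5, OD: 0.3, MM: 0.2}))
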