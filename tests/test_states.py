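"""State derivation: hypertension rule, condition counts, monotone
coding, exclusion cascade, transition-record construction."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmle import (
    CHRONIC_CONDITIONS,
    ExclusionTally,
    HealthState,
    MultimorbidityDefinition,
    apply_exclusions,
    build_transition_records,
    classify_hypertension,
    count_conditions,
    derive_panel_states,
    derive_state,
    enforce_monotone_states,
)

ND, OD, MM, D = (
    HealthState.NO_DISEASE,
    HealthState.ONE_DISEASE,
    HealthState.MULTIMORBID,
    HealthState.DEAD,
)


@pytest.mark.parametrize(
    "sbp,dbp,expected",
    [
        (150, 95, True),  # all three clauses met
        (139, 95, False),  # systolic cut-off fails
        (140, 130, False),  # difference clause fails despite both cut-offs
        (140, 90, True),  # inclusive boundaries: 140/90 with difference 50
        (150, 89, False),  # diastolic cut-off fails
    ],
)
def test_hypertension_rule_literal(sbp, dbp, expected):
    assert classify_hypertension(sbp, dbp) is expected


def test_hypertension_missing_pressure_is_unknown():
    assert classify_hypertension(float("nan"), 95) is None
    assert classify_hypertension(150, None) is None


def test_hypertension_rejects_nonpositive():
    with pytest.raises(ValueError):
        classify_hypertension(-1, 80)


def test_hypertension_difference_clause_toggle():
    # both cut-offs met but pulse pressure < 15: only the relaxed rule flags
    assert classify_hypertension(140, 130) is False
    assert classify_hypertension(140, 130, require_pulse_gap=False) is True


def test_count_conditions_and_sensitivity_removal():
    obs = {c: False for c in CHRONIC_CONDITIONS}
    obs.update(hypertension=True, diabetes=True)
    full = MultimorbidityDefinition()
    assert count_conditions(obs, full) == 2
    assert count_conditions(obs, full.without("hypertension")) == 1
    assert count_conditions({c: False for c in CHRONIC_CONDITIONS}, full) == 0


def test_count_conditions_from_bp_rule():
    obs = {c: False for c in CHRONIC_CONDITIONS}
    obs.update(sbp_mean=155.0, dbp_mean=96.0)
    defn = MultimorbidityDefinition(hypertension_rule="from_bp")
    assert count_conditions(obs, defn) == 1


def test_unknown_condition_name_rejected():
    with pytest.raises(ValueError, match="gout"):
        MultimorbidityDefinition(included_conditions=frozenset({"gout"}))


def test_threshold_below_two_rejected():
    with pytest.raises(ValueError):
        MultimorbidityDefinition(threshold=1)


@pytest.mark.parametrize(
    "n,alive,expected",
    [(0, True, ND), (1, True, OD), (2, True, MM), (7, True, MM), (7, False, D), (0, False, D)],
)
def test_derive_state(n, alive, expected):
    assert derive_state(n, alive) is expected


@pytest.mark.parametrize(
    "seq,expected",
    [
        ([MM, OD], [MM, MM]),
        ([ND, OD, MM], [ND, OD, MM]),
        ([OD, ND, D], [OD, OD, D]),
        ([ND], [ND]),
        ([D, D], [D, D]),
    ],
)
def test_monotone_repair(seq, expected):
    assert enforce_monotone_states(seq) == expected


def test_dead_then_alive_is_integrity_error():
    with pytest.raises(ValueError, match="death"):
        enforce_monotone_states([OD, D, ND])


@settings(max_examples=200, derandomize=True)
@given(st.lists(st.sampled_from([ND, OD, MM]), min_size=1, max_size=8))
def test_monotone_repair_properties(seq):
    out = enforce_monotone_states(seq)
    assert all(b >= a for a, b in zip(out, out[1:]))  # non-decreasing
    assert all(o >= s for o, s in zip(out, seq))  # never below observed
    assert enforce_monotone_states(out) == out  # idempotent


def _mini_panel(rows):
    cols = ["person_id", "wave", "age", "alive"]
    df = pd.DataFrame(rows, columns=cols + ["n_dis"])
    for i, c in enumerate(CHRONIC_CONDITIONS):
        df[c] = [
            (np.nan if pd.isna(nd) else float(i < nd)) if a else np.nan
            for nd, a in zip(df["n_dis"], df["alive"])
        ]
    df["sbp_mean"] = np.nan
    df["dbp_mean"] = np.nan
    df["sex"] = "female"
    df["race"] = "African"
    df["education"] = "secondary"
    df["residence"] = "urban"
    df["design_weight"] = 1.0
    return df.drop(columns="n_dis")


def test_exclusions_empty_panel():
    out, tally = apply_exclusions(pd.DataFrame())
    assert out.empty and tally.final_n == 0 and tally.initial_n == 0


def test_exclusion_cascade_counts():
    rows = [
        # kept: two complete waves
        (1, 1, 30.0, 1, 0), (1, 2, 32.0, 1, 1),
        # single wave -> excluded
        (2, 1, 40.0, 1, 0),
        # two waves but one invalid disease block -> nonresponse
        (3, 1, 50.0, 1, np.nan), (3, 2, 52.0, 1, np.nan),
        # kept: alive then death report
        (4, 1, 60.0, 1, 2), (4, 2, 62.0, 0, 0),
    ]
    df = _mini_panel(rows)
    df.loc[df["person_id"] == 4, "wave"] = [1, 2]
    # person 5: complete but missing education -> missing-essential
    extra = _mini_panel([(5, 1, 35.0, 1, 0), (5, 2, 37.0, 1, 0)])
    extra["education"] = np.nan
    df = pd.concat([df, extra], ignore_index=True)
    out, tally = apply_exclusions(df)
    assert tally.to_dict() == {
        "initial_n": 5,
        "excluded_single_wave": 1,
        "excluded_nonresponse": 1,
        "excluded_missing": 1,
        "final_n": 2,
    }
    assert set(out["person_id"]) == {1, 4}


def test_tally_arithmetic_enforced():
    with pytest.raises(ValueError):
        ExclusionTally(10, 1, 1, 1, 8)


def test_complete_panel_has_no_exclusions(small_panel):
    from mmle import GenerativeConfig, generate_panel

    cfg = GenerativeConfig(n_individuals=300, seed=3, attrition_prob=0.0)
    frame = generate_panel(cfg).frame
    out, tally = apply_exclusions(frame)
    assert tally.excluded_single_wave == 0
    assert tally.excluded_nonresponse == 0
    assert tally.excluded_missing == 0
    assert len(out) == len(frame)


def test_transition_record_counts_match_waves_observed(derived_states):
    rec = build_transition_records(derived_states)
    waves = derived_states.groupby("person_id")["wave"].size()
    per_person = rec.groupby("person_id").size()
    # one baseline pseudo-transition plus one record per consecutive pair
    assert per_person.equals(waves.loc[per_person.index])
    assert rec["is_baseline_pseudo"].sum() == derived_states["person_id"].nunique()


def test_two_wave_individual_yields_two_records():
    df = _mini_panel([(1, 1, 30.0, 1, 0), (1, 2, 32.0, 1, 1)])
    states = derive_panel_states(df)
    rec = build_transition_records(states)
    assert len(rec) == 2
    real = rec[~rec["is_baseline_pseudo"]]
    assert real.iloc[0]["origin_state"] == int(ND)
    assert real.iloc[0]["destination_state"] == int(OD)


def test_death_report_becomes_dead_destination():
    df = _mini_panel([(1, 1, 30.0, 1, 1), (1, 2, 32.0, 1, 1), (1, 3, 34.0, 0, 0)])
    states = derive_panel_states(df)
    rec = build_transition_records(states)
    last = rec.sort_values("age_at_origin").iloc[-1]
    assert last["destination_state"] == int(D)
    # no record ever originates from death
    assert (rec["origin_state"] != int(D)).all()


def test_single_observation_individual_rejected():
    df = _mini_panel([(1, 1, 30.0, 1, 0)])
    states = derive_panel_states(df)
    with pytest.raises(ValueError, match="excluded"):
        build_transition_records(states)


def test_gapped_pairs_dropped_when_requested():
    df = _mini_panel([(1, 1, 30.0, 1, 0), (1, 3, 34.0, 1, 1), (1, 4, 36.0, 1, 1)])
    states = derive_panel_states(df)
    full = build_transition_records(states, include_baseline_pseudo=False)
    assert len(full) == 2
    strict = build_transition_records(
        states, include_baseline_pseudo=False, drop_gapped=True
    )
    assert len(strict) == 1  # only the wave 3->4 pair remains


def test_definition_narrowing_never_raises_states(derived_states, small_panel):
    """Removing a condition can only lower each person-wave state."""
    panel, _ = apply_exclusions(small_panel.frame)
    narrow = derive_panel_states(
        panel, MultimorbidityDefinition().without("hypertension")
    )
    full = derived_states
    merged = full.merge(
        narrow[["person_id", "wave", "state"]],
        on=["person_id", "wave"],
        suffixes=("_full", "_narrow"),
    )
    assert (merged["state_narrow"] <= merged["state_full"]).all()


def test_reversal_noise_is_repaired(small_panel):
    from mmle import inject_reversal_noise

    noisy = inject_reversal_noise(small_panel, rate=0.3, seed=9)
    panel, _ = apply_exclusions(noisy.frame)
    states = derive_panel_states(panel)
    rec = build_transition_records(states)
    assert (rec["destination_state"] >= rec["origin_state"]).all()
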