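"""Four-state chronic-disease state space and panel state derivation.

The state space has three transient states ordered by disease burden --
no disease, one disease, multimorbidity (two or more chronic conditions)
-- and one absorbing state, death.  Reverse transitions are disallowed:
chronic conditions are treated as permanent, so an individual's state is
non-decreasing over time and death, once entered, persists.

This module turns raw person-wave panel observations (disease flags,
blood-pressure means, vital status) into health states, applies the
sample-exclusion cascade, and builds the origin->destination transition
records that the multinomial-logit transition model is fitted to.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HealthState",
    "TRANSIENT_STATES",
    "ADMISSIBLE_DESTINATIONS",
    "CHRONIC_CONDITIONS",
    "MultimorbidityDefinition",
    "ExclusionTally",
    "classify_hypertension",
    "count_conditions",
    "derive_state",
    "enforce_monotone_states",
    "derive_panel_states",
    "apply_exclusions",
    "build_transition_records",
]


class HealthState(IntEnum):
    """Health states, totally ordered so that monotone coding is a cummax."""

    NO_DISEASE = 0
    ONE_DISEASE = 1
    MULTIMORBID = 2
    DEAD = 3

    @property
    def label(self) -> str:
        return _LABELS[self]


_LABELS = {
    HealthState.NO_DISEASE: "no disease",
    HealthState.ONE_DISEASE: "one disease",
    HealthState.MULTIMORBID: "multimorbidity",
    HealthState.DEAD: "dead",
}

TRANSIENT_STATES: tuple[HealthState, ...] = (
    HealthState.NO_DISEASE,
    HealthState.ONE_DISEASE,
    HealthState.MULTIMORBID,
)

#: Destinations reachable from each transient origin.  The first entry is
#: always "remain in the same state", used as the reference category of the
#: multinomial logit.  Reverse transitions are structurally impossible.
ADMISSIBLE_DESTINATIONS: dict[HealthState, tuple[HealthState, ...]] = {
    HealthState.NO_DISEASE: (
        HealthState.NO_DISEASE,
        HealthState.ONE_DISEASE,
        HealthState.MULTIMORBID,
        HealthState.DEAD,
    ),
    HealthState.ONE_DISEASE: (
        HealthState.ONE_DISEASE,
        HealthState.MULTIMORBID,
        HealthState.DEAD,
    ),
    HealthState.MULTIMORBID: (
        HealthState.MULTIMORBID,
        HealthState.DEAD,
    ),
}

#: The 14 chronic conditions entering the multimorbidity count.
CHRONIC_CONDITIONS: tuple[str, ...] = (
    "alzheimers",
    "arthritis",
    "asthma",
    "cancer",
    "diabetes",
    "emphysema",
    "epilepsy",
    "heart_problems",
    "hiv",
    "hypertension",
    "kidney_problems",
    "psychiatric",
    "stroke",
    "tuberculosis",
)


def classify_hypertension(
    sbp_mean: float,
    dbp_mean: float,
    *,
    require_pulse_gap: bool = True,
) -> bool | None:
    """Classify hypertension from per-wave mean blood pressures.

    An individual is hypertensive when the mean systolic pressure is
    >= 140 mmHg, the mean diastolic pressure is >= 90 mmHg, and the
    difference between the two is >= 15 mmHg.  The difference clause can
    be disabled via ``require_pulse_gap`` for sensitivity checks.

    Returns ``None`` (condition unknown) when either pressure is missing,
    so the record can be routed to the missing-data exclusion path rather
    than silently classified as normotensive.
    """
    if sbp_mean is None or dbp_mean is None:
        return None
    if isinstance(sbp_mean, float) and math.isnan(sbp_mean):
        return None
    if isinstance(dbp_mean, float) and math.isnan(dbp_mean):
        return None
    if sbp_mean <= 0 or dbp_mean <= 0 or not (math.isfinite(sbp_mean) and math.isfinite(dbp_mean)):
        raise ValueError("blood pressures must be positive and finite")
    ok = sbp_mean >= 140.0 and dbp_mean >= 90.0
    if require_pulse_gap:
        ok = ok and (sbp_mean - dbp_mean) >= 15.0
    return ok


@dataclass(frozen=True)
class MultimorbidityDefinition:
    """Which conditions count towards multimorbidity and how.

    Parameters
    ----------
    included_conditions
        Names of the conditions entering the count; defaults to all 14.
    threshold
        Minimum number of co-occurring conditions that constitutes
        multimorbidity (>= 2).
    hypertension_rule
        ``"from_flag"`` reads the hypertension indicator column directly;
        ``"from_bp"`` derives it from the systolic/diastolic means via
        :func:`classify_hypertension`.
    require_pulse_gap
        Whether the >=15 mmHg systolic-diastolic difference clause of the
        blood-pressure rule is enforced.
    """

    included_conditions: frozenset[str] = frozenset(CHRONIC_CONDITIONS)
    threshold: int = 2
    hypertension_rule: str = "from_flag"
    require_pulse_gap: bool = True

    def __post_init__(self) -> None:
        if self.threshold < 2:
            raise ValueError("multimorbidity threshold must be >= 2")
        if not self.included_conditions:
            raise ValueError("included_conditions must be non-empty")
        unknown = set(self.included_conditions) - set(CHRONIC_CONDITIONS)
        if unknown:
            raise ValueError(f"unknown condition name(s): {sorted(unknown)}")
        if self.hypertension_rule not in ("from_flag", "from_bp"):
            raise ValueError("hypertension_rule must be 'from_flag' or 'from_bp'")

    def without(self, *conditions: str) -> "MultimorbidityDefinition":
        """Return a copy with the given conditions removed (sensitivity)."""
        missing = set(conditions) - set(self.included_conditions)
        if missing:
            raise ValueError(f"cannot remove conditions not included: {sorted(missing)}")
        return MultimorbidityDefinition(
            included_conditions=self.included_conditions - set(conditions),
            threshold=self.threshold,
            hypertension_rule=self.hypertension_rule,
            require_pulse_gap=self.require_pulse_gap,
        )


def count_conditions(
    obs: Mapping[str, object],
    defn: MultimorbidityDefinition = MultimorbidityDefinition(),
) -> int:
    """Count the included chronic conditions flagged in one observation.

    ``obs`` maps condition names to flags (plus optionally ``sbp_mean`` /
    ``dbp_mean`` when the definition derives hypertension from blood
    pressure).  Raises when a flag needed by the definition is missing.
    """
    total = 0
    for cond in defn.included_conditions:
        if cond == "hypertension" and defn.hypertension_rule == "from_bp":
            flag = classify_hypertension(
                obs.get("sbp_mean", float("nan")),  # type: ignore[arg-type]
                obs.get("dbp_mean", float("nan")),  # type: ignore[arg-type]
                require_pulse_gap=defn.require_pulse_gap,
            )
            if flag is None:
                raise ValueError("hypertension unknown: missing blood pressure")
        else:
            if cond not in obs:
                raise ValueError(f"observation missing condition flag: {cond}")
            raw = obs[cond]
            if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                raise ValueError(f"condition flag missing (NaN): {cond}")
            flag = bool(raw)
        total += int(flag)
    return total


def derive_state(
    n_conditions: int,
    alive: bool,
    defn: MultimorbidityDefinition = MultimorbidityDefinition(),
) -> HealthState:
    """Map a condition count and vital status to a health state."""
    if n_conditions < 0:
        raise ValueError("n_conditions must be non-negative")
    if not alive:
        return HealthState.DEAD
    if n_conditions >= defn.threshold:
        return HealthState.MULTIMORBID
    if n_conditions == 1:
        return HealthState.ONE_DISEASE
    return HealthState.NO_DISEASE


def enforce_monotone_states(states: Sequence[HealthState]) -> list[HealthState]:
    """Repair apparent recoveries by carrying the highest state forward.

    output[k] = max(input[0..k]) under the state order, so the returned
    sequence is non-decreasing and chronic states persist.  A living state
    observed *after* death is unrepairable and raises.
    """
    out: list[HealthState] = []
    current = HealthState.NO_DISEASE
    seen_dead = False
    for s in states:
        s = HealthState(s)
        if seen_dead and s != HealthState.DEAD:
            raise ValueError("living state observed after death: data integrity error")
        if s == HealthState.DEAD:
            seen_dead = True
        current = max(current, s)
        out.append(current)
    return out


# ---------------------------------------------------------------------------
# Frame-level operations
# ---------------------------------------------------------------------------

def _counts_and_missing(
    df: pd.DataFrame, defn: MultimorbidityDefinition
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised condition counts plus a mask of rows with unknown counts."""
    conds = sorted(defn.included_conditions)
    n = len(df)
    counts = np.zeros(n, dtype=float)
    missing = np.zeros(n, dtype=bool)
    for cond in conds:
        if cond == "hypertension" and defn.hypertension_rule == "from_bp":
            sbp = df["sbp_mean"].to_numpy(dtype=float)
            dbp = df["dbp_mean"].to_numpy(dtype=float)
            col_missing = np.isnan(sbp) | np.isnan(dbp)
            flag = (sbp >= 140.0) & (dbp >= 90.0)
            if defn.require_pulse_gap:
                flag &= (sbp - dbp) >= 15.0
            flag = np.where(col_missing, False, flag)
        else:
            raw = df[cond].to_numpy(dtype=float)
            col_missing = np.isnan(raw)
            flag = np.where(col_missing, False, raw > 0)
        counts += flag
        missing |= col_missing
    return counts.astype(int), missing


def derive_panel_states(
    panel: pd.DataFrame,
    defn: MultimorbidityDefinition = MultimorbidityDefinition(),
) -> pd.DataFrame:
    """Derive monotone health states for every person-wave.

    Expects the long panel schema (``person_id``, ``wave``, ``age``,
    ``alive``, one column per condition, ``sbp_mean``/``dbp_mean``,
    covariates).  Rows whose disease block is incomplete while alive are
    dropped (that wave contributes no transition; flanking waves pair up).
    Apparent reversals are repaired by carry-forward of the highest state.
    """
    df = panel.sort_values(["person_id", "wave"], kind="mergesort").reset_index(drop=True)
    alive = df["alive"].to_numpy(dtype=float) > 0
    counts, missing = _counts_and_missing(df, defn)
    state = np.where(alive, np.minimum(counts, defn.threshold), int(HealthState.DEAD))
    state = np.where(alive & (counts >= defn.threshold), int(HealthState.MULTIMORBID), state)
    state = np.where(alive & (counts == 1), int(HealthState.ONE_DISEASE), state)
    state = np.where(alive & (counts == 0), int(HealthState.NO_DISEASE), state)
    df["state"] = state
    # a dead row never has a missing state; alive rows with incomplete
    # disease blocks are unknowable and dropped
    keep = ~(missing & alive)
    df = df.loc[keep].reset_index(drop=True)

    # integrity: death must be terminal within each person
    pid = df["person_id"].to_numpy()
    st = df["state"].to_numpy()
    same_person = pid[1:] == pid[:-1]
    if np.any(same_person & (st[:-1] == int(HealthState.DEAD)) & (st[1:] != int(HealthState.DEAD))):
        raise ValueError("living state observed after death: data integrity error")

    # carry-forward maximum within person (monotone coding)
    df["state"] = df.groupby("person_id", sort=False)["state"].cummax()
    return df


@dataclass(frozen=True)
class ExclusionTally:
    """Bookkeeping of the sample-exclusion cascade."""

    initial_n: int
    excluded_single_wave: int
    excluded_nonresponse: int
    excluded_missing: int
    final_n: int

    def __post_init__(self) -> None:
        expected = (
            self.initial_n
            - self.excluded_single_wave
            - self.excluded_nonresponse
            - self.excluded_missing
        )
        if self.final_n != expected:
            raise ValueError(
                f"tally inconsistent: {self.initial_n} - {self.excluded_single_wave}"
                f" - {self.excluded_nonresponse} - {self.excluded_missing}"
                f" != {self.final_n}"
            )

    def to_dict(self) -> dict[str, int]:
        return {
            "initial_n": self.initial_n,
            "excluded_single_wave": self.excluded_single_wave,
            "excluded_nonresponse": self.excluded_nonresponse,
            "excluded_missing": self.excluded_missing,
            "final_n": self.final_n,
        }


_ESSENTIAL_FIELDS = ("sex", "race", "education", "residence", "design_weight")


def apply_exclusions(panel: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionTally]:
    """Apply the exclusion cascade to a raw long panel.

    Sequentially removes (a) individuals present at only one wave,
    (b) individuals with fewer than two valid adult interviews (an alive
    row with a complete disease block, or a death report), and
    (c) individuals missing essential socio-demographic or mortality
    fields.  Returns the filtered panel and the tally.
    """
    if panel.empty:
        return panel.copy(), ExclusionTally(0, 0, 0, 0, 0)
    df = panel.sort_values(["person_id", "wave"], kind="mergesort").reset_index(drop=True)
    initial = df["person_id"].nunique()

    sizes = df.groupby("person_id", sort=False)["wave"].size()
    single = set(sizes.index[sizes < 2])
    df = df[~df["person_id"].isin(single)]

    # valid interview: alive with complete disease block, or a death report
    alive = df["alive"].to_numpy(dtype=float) > 0
    flags = df[list(CHRONIC_CONDITIONS)].to_numpy(dtype=float)
    complete = ~np.isnan(flags).any(axis=1)
    valid = (~alive) | complete
    nvalid = pd.Series(valid, index=df.index).groupby(df["person_id"], sort=False).sum()
    nonresp = set(nvalid.index[nvalid < 2])
    df = df[~df["person_id"].isin(nonresp)]

    essential = df[list(_ESSENTIAL_FIELDS) + ["alive"]]
    bad = essential.isna().any(axis=1)
    missing_ids = set(df.loc[bad, "person_id"].unique())
    df = df[~df["person_id"].isin(missing_ids)]

    final = df["person_id"].nunique()
    tally = ExclusionTally(
        initial_n=initial,
        excluded_single_wave=len(single),
        excluded_nonresponse=len(nonresp),
        excluded_missing=len(missing_ids),
        final_n=final,
    )
    return df.reset_index(drop=True), tally


def build_transition_records(
    states: pd.DataFrame,
    *,
    include_baseline_pseudo: bool = True,
    drop_gapped: bool = False,
) -> pd.DataFrame:
    """Build origin->destination transition records from a derived panel.

    Per individual: one baseline pseudo-transition (the first observed
    state counted as a self-transition, reflecting pre-survey chronic
    status) plus one record per consecutive pair of observed waves.  Each
    record carries the exact age at origin, the individual's covariates
    and design weight.  Pairs spanning a missed wave are treated as a
    single biennial transition unless ``drop_gapped`` is set.
    """
    df = states.sort_values(["person_id", "wave"], kind="mergesort").reset_index(drop=True)
    sizes = df.groupby("person_id", sort=False)["wave"].size()
    if (sizes < 2).any():
        bad = sizes.index[sizes < 2][:5].tolist()
        raise ValueError(
            f"individuals with <2 observations present (should be excluded): {bad}"
        )
    pid = df["person_id"].to_numpy()
    wave = df["wave"].to_numpy()
    age = df["age"].to_numpy(dtype=float)
    st = df["state"].to_numpy(dtype=int)
    covs = {c: df[c].to_numpy() for c in _ESSENTIAL_FIELDS}

    same = pid[1:] == pid[:-1]
    pair_ok = same & (st[:-1] != int(HealthState.DEAD))
    if drop_gapped:
        pair_ok &= (wave[1:] - wave[:-1]) == 1
    i = np.flatnonzero(pair_ok)

    parts = [
        pd.DataFrame(
            {
                "person_id": pid[i],
                "origin_state": st[i],
                "destination_state": st[i + 1],
                "age_at_origin": age[i],
                "is_baseline_pseudo": False,
                **{c: covs[c][i] for c in _ESSENTIAL_FIELDS},
            }
        )
    ]
    if include_baseline_pseudo:
        first = np.r_[True, ~same]
        j = np.flatnonzero(first & (st != int(HealthState.DEAD)))
        parts.insert(
            0,
            pd.DataFrame(
                {
                    "person_id": pid[j],
                    "origin_state": st[j],
                    "destination_state": st[j],
                    "age_at_origin": age[j],
                    "is_baseline_pseudo": True,
                    **{c: covs[c][j] for c in _ESSENTIAL_FIELDS},
                }
            ),
        )
    rec = pd.concat(parts, ignore_index=True)
    if (rec["destination_state"].to_numpy() < rec["origin_state"].to_numpy()).any():
        raise ValueError("reverse transition found in records; states not monotone")
    return rec
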