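"""Published headline estimates packaged as a numeric fixture.

The original study fits restricted survey microdata, so its headline
life-expectancy table cannot be recomputed here; what *can* be verified
exactly is the internal arithmetic of the published numbers.  This
module packages the printed table of weighted LE, MMLE, and percentage
of LE with multimorbidity (by model, stratum and sex) together with the
printed sample-exclusion counts, and recomputes from those cells every
derived quantity quoted in the accompanying text: the MMLE sex gaps per
race and education group, and the educational gains in LE and MMLE
within each racial group.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import pandas as pd

from .pipeline import group_gap, percent_of_le
from .states import ExclusionTally

__all__ = [
    "EXCLUSION_COUNTS",
    "FixtureCheck",
    "load_table2",
    "exclusion_tally",
    "check_table2_fixture",
]

#: Printed sample-construction counts: initial pooled adult sample and
#: the three sequential exclusions (single wave, questionnaire
#: non-response, missing essential information).
EXCLUSION_COUNTS = {
    "initial_n": 28237,
    "excluded_single_wave": 9340,
    "excluded_nonresponse": 447,
    "excluded_missing": 420,
    "final_n": 18030,
}


def load_table2() -> pd.DataFrame:
    """Load the published expectancy table keyed by (model, stratum, sex)."""
    with importlib.resources.files("mmle.data").joinpath("table2.csv").open() as fh:
        df = pd.read_csv(fh)
    return df


def exclusion_tally() -> ExclusionTally:
    """The printed exclusion cascade as a validated tally (the
    :class:`~mmle.states.ExclusionTally` constructor enforces the
    arithmetic identity)."""
    return ExclusionTally(**EXCLUSION_COUNTS)


@dataclass(frozen=True)
class FixtureCheck:
    """One recomputed quantity compared against its printed value."""

    name: str
    computed: float
    expected: float
    tolerance: float = 0.0

    @property
    def passed(self) -> bool:
        return abs(self.computed - self.expected) <= self.tolerance + 1e-12


def _cell(df: pd.DataFrame, model: str, stratum: str, sex: str, col: str) -> float:
    row = df[(df["model"] == model) & (df["stratum"] == stratum) & (df["sex"] == sex)]
    if len(row) != 1:
        raise ValueError(f"fixture row not found: {model}/{stratum}/{sex}")
    return float(row.iloc[0][col])


def check_table2_fixture(fixture: pd.DataFrame | None = None) -> list[FixtureCheck]:
    """Recompute every derived quantity quoted in the published text.

    Returns one :class:`FixtureCheck` per quantity: the per-row identity
    pct = round(100 * MMLE / LE) (integer-rounding tolerance +-1), the
    exclusion-cascade arithmetic, the MMLE sex gaps by race and by
    education, and the educational differences in LE and MMLE by race
    and sex.
    """
    df = load_table2() if fixture is None else fixture
    checks: list[FixtureCheck] = []

    for _, r in df.iterrows():
        checks.append(
            FixtureCheck(
                name=f"pct_identity:{r['model']}/{r['stratum']}/{r['sex']}",
                computed=float(percent_of_le(r["mmle"], r["weighted_le"])),
                expected=float(r["pct_mm"]),
                tolerance=1.0,
            )
        )

    tally = exclusion_tally()
    checks.append(
        FixtureCheck(
            name="exclusion_cascade_final_n",
            computed=float(
                tally.initial_n
                - tally.excluded_single_wave
                - tally.excluded_nonresponse
                - tally.excluded_missing
            ),
            expected=float(tally.final_n),
        )
    )

    def gap(name: str, a: float, b: float, expected: float) -> None:
        checks.append(FixtureCheck(name=name, computed=group_gap(a, b), expected=expected))

    # MMLE sex gaps (female - male) by race
    m2 = {"African": 7.5, "Asian/Indian": 8.1, "Coloured": 8.3, "white": 7.5}
    for race, exp in m2.items():
        gap(
            f"sex_gap_mmle:{race}",
            _cell(df, "M2", race, "female", "mmle"),
            _cell(df, "M2", race, "male", "mmle"),
            exp,
        )

    # MMLE sex gaps by education
    m3 = {"less than secondary": 7.9, "secondary": 7.4, "post-secondary": 7.2}
    for edu, exp in m3.items():
        gap(
            f"sex_gap_mmle:{edu}",
            _cell(df, "M3", edu, "female", "mmle"),
            _cell(df, "M3", edu, "male", "mmle"),
            exp,
        )

    # educational gains in LE (secondary-or-more minus less-than-secondary)
    le_gains = {
        ("Coloured", "male"): 10.3,
        ("African", "male"): 1.7,
        ("white", "male"): 1.3,
        ("Coloured", "female"): 8.7,
        ("African", "female"): 0.9,
        ("white", "female"): 0.1,
    }
    for (race, sex), exp in le_gains.items():
        gap(
            f"educ_gain_le:{race}/{sex}",
            _cell(df, "M4", f"{race} x secondary or more", sex, "weighted_le"),
            _cell(df, "M4", f"{race} x less than secondary", sex, "weighted_le"),
            exp,
        )

    # educational differences in MMLE (sign: more educated minus less)
    mmle_diffs = {
        ("African", "male"): -1.5,
        ("white", "male"): -6.2,
        ("Coloured", "male"): 4.9,
        ("Coloured", "female"): 4.5,
        ("African", "female"): -2.3,
        ("white", "female"): -7.7,
    }
    for (race, sex), exp in mmle_diffs.items():
        gap(
            f"educ_diff_mmle:{race}/{sex}",
            _cell(df, "M4", f"{race} x secondary or more", sex, "mmle"),
            _cell(df, "M4", f"{race} x less than secondary", sex, "mmle"),
            exp,
        )

    return checks
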