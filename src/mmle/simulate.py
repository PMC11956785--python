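"""Synthetic household-panel generator with known transition dynamics.

Emulates the structure of a biennial national household panel (five
waves, adults aged 20+, household-reported deaths, wave-on-wave
attrition, design weights) while generating every trajectory from a
*known* multinomial-logit transition model.  Because the generative
coefficients are known, parameter recovery and confidence-interval
coverage of the downstream estimators can be verified against ground
truth.

The default generative coefficients are calibrated so that, at the
reference profile (age 42, half urban), the implied biennial transition
probabilities equal realistic sex-specific fractions for a middle-income
population with a heavy chronic-disease burden (e.g. roughly 12 per cent
of one-disease person-waves progress to multimorbidity per biennium),
with log-odds of death rising at 0.085 per year of age and disease
progression rising more gently.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .model import ModelSpec, TransitionCoefficients
from .states import ADMISSIBLE_DESTINATIONS, CHRONIC_CONDITIONS, HealthState, TRANSIENT_STATES

__all__ = [
    "GenerativeConfig",
    "Panel",
    "default_true_coefficients",
    "generate_panel",
    "inject_reversal_noise",
]

_REFERENCE_AGE = 42.0
_REFERENCE_URBAN = 0.5

# Biennial transition probabilities at the reference profile.  Stay
# probabilities are the complements within each origin row.
_REFERENCE_PROBS: dict[str, dict[HealthState, dict[HealthState, float]]] = {
    "male": {
        HealthState.NO_DISEASE: {
            HealthState.ONE_DISEASE: 0.082,
            HealthState.MULTIMORBID: 0.011,
            HealthState.DEAD: 0.022,
        },
        HealthState.ONE_DISEASE: {
            HealthState.MULTIMORBID: 0.113,
            HealthState.DEAD: 0.056,
        },
        HealthState.MULTIMORBID: {HealthState.DEAD: 0.112},
    },
    "female": {
        HealthState.NO_DISEASE: {
            HealthState.ONE_DISEASE: 0.096,
            HealthState.MULTIMORBID: 0.016,
            HealthState.DEAD: 0.015,
        },
        HealthState.ONE_DISEASE: {
            HealthState.MULTIMORBID: 0.122,
            HealthState.DEAD: 0.033,
        },
        HealthState.MULTIMORBID: {HealthState.DEAD: 0.063},
    },
}

# Log-odds slopes per year of age and urban-residence effects, by
# destination kind: progression to more disease vs death.
_AGE_SLOPES = {"progress": 0.035, "death": 0.085}
_URBAN_EFFECTS = {"progress": 0.05, "death": -0.10}

# Relative chances that a newly acquired condition is each disease,
# echoing the prevalence ranking seen in South African panel data
# (hypertension by far the most common, then tuberculosis and diabetes).
_DISEASE_WEIGHTS: dict[str, float] = {
    "hypertension": 0.40,
    "tuberculosis": 0.12,
    "diabetes": 0.11,
    "arthritis": 0.08,
    "asthma": 0.07,
    "heart_problems": 0.06,
    "hiv": 0.05,
    "stroke": 0.03,
    "psychiatric": 0.03,
    "cancer": 0.02,
    "kidney_problems": 0.015,
    "epilepsy": 0.01,
    "emphysema": 0.01,
    "alzheimers": 0.005,
}


def default_true_coefficients(sex: str) -> TransitionCoefficients:
    """Generative truth on the M1 design (const, age, urban).

    Intercepts solve alpha = log(p_dest/p_stay) - beta_age*42 -
    beta_urban*0.5 so the reference-profile probabilities hit the
    calibration targets exactly.
    """
    spec = ModelSpec("M1")
    coef: dict[HealthState, np.ndarray] = {}
    for origin in TRANSIENT_STATES:
        targets = _REFERENCE_PROBS[sex][origin]
        p_stay = 1.0 - sum(targets.values())
        rows = []
        for dest in ADMISSIBLE_DESTINATIONS[origin][1:]:
            kind = "death" if dest == HealthState.DEAD else "progress"
            b_age = _AGE_SLOPES[kind]
            b_urb = _URBAN_EFFECTS[kind]
            alpha = (
                np.log(targets[dest] / p_stay)
                - b_age * _REFERENCE_AGE
                - b_urb * _REFERENCE_URBAN
            )
            rows.append([alpha, b_age, b_urb])
        coef[origin] = np.asarray(rows, dtype=float)
    return TransitionCoefficients(spec=spec, sex=sex, coef=coef)


@dataclass
class GenerativeConfig:
    """Study conditions for the synthetic panel.

    Defaults mirror the target survey: ~18,030 adults aged 20+, five
    biennial waves, household-reported deaths, independent per-wave
    attrition, lognormal design weights, and covariate margins matching
    the published baseline composition.
    """

    n_individuals: int = 18030
    n_waves: int = 5
    wave_spacing_years: float = 2.0
    baseline_age_range: tuple[float, float] = (20.0, 90.0)
    true_coefficients: dict[str, TransitionCoefficients] | None = None
    baseline_state_distribution: tuple[float, float, float] = (0.697, 0.223, 0.080)
    covariate_mix: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "sex": {"male": 0.401, "female": 0.599},
            "race": {
                "African": 0.799,
                "Asian/Indian": 0.012,
                "Coloured": 0.148,
                "white": 0.041,
            },
            "education": {
                "less than secondary": 0.462,
                "secondary": 0.416,
                "post-secondary": 0.122,
            },
            "residence": {"urban": 0.502, "rural": 0.498},
        }
    )
    design_weight_sigma: float = 0.5
    attrition_prob: float = 0.15
    attrition_state_multiplier: dict[int, float] | None = None
    age_jitter: float = 0.5
    item_nonresponse_prob: float = 0.0
    missing_demographics_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_coefficients is None:
            self.true_coefficients = {
                s: default_true_coefficients(s) for s in ("male", "female")
            }
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.n_waves < 2:
            raise ValueError("n_waves must be >= 2 (no transitions observable)")
        if self.wave_spacing_years <= 0:
            raise ValueError("wave_spacing_years must be positive")
        lo, hi = self.baseline_age_range
        if not (20.0 <= lo < hi):
            raise ValueError("baseline_age_range must satisfy 20 <= min < max")
        dist = np.asarray(self.baseline_state_distribution, dtype=float)
        if dist.shape != (3,) or (dist < 0).any() or abs(dist.sum() - 1.0) > 1e-12:
            raise ValueError(
                "baseline_state_distribution must be 3 non-negative "
                "probabilities summing to 1 within 1e-12"
            )
        for p in (self.attrition_prob, self.item_nonresponse_prob, self.missing_demographics_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for name, mix in self.covariate_mix.items():
            tot = sum(mix.values())
            if abs(tot - 1.0) > 1e-9 or any(v < 0 for v in mix.values()):
                raise ValueError(f"covariate_mix[{name!r}] must be a probability vector")

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "n_individuals",
                "n_waves",
                "wave_spacing_years",
                "design_weight_sigma",
                "attrition_prob",
                "age_jitter",
                "item_nonresponse_prob",
                "missing_demographics_prob",
                "seed",
            )
        }
        d["baseline_age_range"] = list(self.baseline_age_range)
        d["baseline_state_distribution"] = list(self.baseline_state_distribution)
        d["covariate_mix"] = self.covariate_mix
        d["true_coefficients"] = {
            s: c.to_dict() for s, c in self.true_coefficients.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GenerativeConfig":
        d = dict(d)
        if "true_coefficients" in d and d["true_coefficients"] is not None:
            d["true_coefficients"] = {
                s: TransitionCoefficients.from_dict(c)
                for s, c in d["true_coefficients"].items()
            }
        if "baseline_age_range" in d:
            d["baseline_age_range"] = tuple(d["baseline_age_range"])
        if "baseline_state_distribution" in d:
            d["baseline_state_distribution"] = tuple(d["baseline_state_distribution"])
        return cls(**d)


@dataclass
class Panel:
    """A generated panel: long person-wave frame plus generative truth."""

    frame: pd.DataFrame
    config: GenerativeConfig

    @property
    def truth(self) -> dict[str, TransitionCoefficients]:
        return self.config.true_coefficients

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def write_truth_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({s: c.to_dict() for s, c in self.truth.items()}, fh, indent=1)

    def individuals(self):
        """Iterate per-person sub-frames ordered by wave."""
        for pid, grp in self.frame.groupby("person_id", sort=True):
            yield pid, grp.sort_values("wave")


def _sample_categorical(rng: np.random.Generator, mix: dict[str, float], n: int) -> np.ndarray:
    cats = np.array(list(mix.keys()), dtype=object)
    probs = np.array(list(mix.values()), dtype=float)
    probs = probs / probs.sum()
    return cats[rng.choice(len(cats), size=n, p=probs)]


def generate_panel(config: GenerativeConfig) -> Panel:
    """Generate a panel from the configured transition dynamics.

    Each individual draws a baseline state, then evolves wave to wave via
    the multinomial-logit probabilities implied by the true coefficients
    evaluated at the current exact age.  Death between waves is recorded
    at the next wave (household-report convention) and terminates the
    trajectory; interviews are missed independently per wave with the
    attrition probability.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    lo, hi = config.baseline_age_range

    sex = _sample_categorical(rng, config.covariate_mix["sex"], n)
    race = _sample_categorical(rng, config.covariate_mix["race"], n)
    education = _sample_categorical(rng, config.covariate_mix["education"], n)
    residence = _sample_categorical(rng, config.covariate_mix["residence"], n)
    urban = (residence == "urban").astype(float)
    weight = rng.lognormal(mean=0.0, sigma=config.design_weight_sigma, size=n)
    base_age = rng.uniform(lo, hi, size=n)
    state = rng.choice(
        3, size=n, p=np.asarray(config.baseline_state_distribution, dtype=float)
    )

    # weighted-without-replacement disease acquisition order per person
    dweights = np.array([_DISEASE_WEIGHTS[c] for c in CHRONIC_CONDITIONS])
    keys = np.log(dweights)[None, :] + rng.gumbel(size=(n, len(CHRONIC_CONDITIONS)))
    disease_order = np.argsort(-keys, axis=1)  # (n, 14)
    n_acquired = np.where(state == 2, 2, state).astype(int)

    female = sex == "female"
    coefs = {s: config.true_coefficients[s] for s in ("male", "female")}

    rows: list[pd.DataFrame] = []
    alive = np.ones(n, dtype=bool)
    death_pending = np.zeros(n, dtype=bool)  # died since last wave, report due
    done = np.zeros(n, dtype=bool)  # death already reported

    for t in range(config.n_waves):
        age = base_age + t * config.wave_spacing_years
        if t > 0 and config.age_jitter > 0:
            age = age + rng.uniform(-config.age_jitter, config.age_jitter, size=n)
        # interview response this wave
        miss = np.zeros(n, dtype=bool)
        if t > 0:
            p_attr = np.full(n, config.attrition_prob)
            if config.attrition_state_multiplier:
                for s, m in config.attrition_state_multiplier.items():
                    p_attr = np.where(state == int(s), np.clip(p_attr * m, 0, 1), p_attr)
            miss = rng.random(n) < p_attr
        # death reports come from the household and are not subject to
        # individual interview non-response
        observed = (~done) & (death_pending | ((~miss) & alive))

        idx = np.flatnonzero(observed)
        if idx.size:
            obs_alive = alive[idx] & ~death_pending[idx]
            flags = np.zeros((idx.size, len(CHRONIC_CONDITIONS)), dtype=float)
            rowpos = np.arange(idx.size)
            for k in range(int(n_acquired[idx].max(initial=0))):
                m = obs_alive & (n_acquired[idx] > k)
                flags[rowpos[m], disease_order[idx[m], k]] = 1.0
            flags[~obs_alive] = np.nan
            # item non-response wipes the disease block of some interviews
            if config.item_nonresponse_prob > 0:
                wipe = rng.random(idx.size) < config.item_nonresponse_prob
                flags[wipe & obs_alive] = np.nan
            hyp_col = CHRONIC_CONDITIONS.index("hypertension")
            has_hyp = flags[:, hyp_col] == 1.0
            dbp = np.where(
                has_hyp,
                92.0 + 18.0 * rng.random(idx.size),
                65.0 + 23.0 * rng.random(idx.size),
            )
            sbp = np.where(
                has_hyp,
                np.maximum(140.0, dbp + 15.0) + 25.0 * rng.random(idx.size),
                100.0 + 38.0 * rng.random(idx.size),
            )
            sbp = np.where(obs_alive, sbp, np.nan)
            dbp = np.where(obs_alive, dbp, np.nan)
            block = pd.DataFrame(
                {
                    "person_id": idx,
                    "wave": t + 1,
                    "age": age[idx],
                    "alive": obs_alive.astype(int),
                }
            )
            for k, cond in enumerate(CHRONIC_CONDITIONS):
                block[cond] = flags[:, k]
            block["sbp_mean"] = sbp
            block["dbp_mean"] = dbp
            block["sex"] = sex[idx]
            block["race"] = race[idx]
            block["education"] = education[idx]
            block["residence"] = residence[idx]
            block["design_weight"] = weight[idx]
            rows.append(block)

        done |= death_pending & observed
        death_pending &= ~observed  # unreported deaths stay pending

        if t == config.n_waves - 1:
            break

        # evolve the living to the next wave
        live = np.flatnonzero(alive & ~done & ~death_pending)
        if live.size:
            nxt = state.copy()
            for s in ("male", "female"):
                grp = live[(sex[live] == s)]
                if grp.size == 0:
                    continue
                tc = coefs[s]
                for origin in TRANSIENT_STATES:
                    sub = grp[state[grp] == int(origin)]
                    if sub.size == 0:
                        continue
                    X = np.column_stack(
                        [np.ones(sub.size), age[sub], urban[sub]]
                    )
                    extra = len(tc.spec.columns) - 3
                    if extra:
                        raise NotImplementedError(
                            "generative truth must use the M1 design"
                        )
                    eta = X @ tc.coef[origin].T  # (m, K)
                    eta = np.column_stack([np.zeros(sub.size), eta])
                    eta -= eta.max(axis=1, keepdims=True)
                    p = np.exp(eta)
                    p /= p.sum(axis=1, keepdims=True)
                    u = rng.random(sub.size)
                    pick = (u[:, None] > np.cumsum(p, axis=1)).sum(axis=1)
                    dests = np.array(
                        [int(d) for d in ADMISSIBLE_DESTINATIONS[origin]]
                    )
                    pick = np.minimum(pick, len(dests) - 1)
                    nxt[sub] = dests[pick]
            newly_dead = (nxt == int(HealthState.DEAD)) & (
                state != int(HealthState.DEAD)
            )
            upgraded = (nxt > state) & (nxt < int(HealthState.DEAD))
            # acquire enough named conditions to justify the new state
            need = np.where(nxt == 2, 2, nxt)
            n_acquired = np.where(
                upgraded, np.maximum(n_acquired, need), n_acquired
            ).astype(int)
            alive = alive & ~newly_dead
            death_pending |= newly_dead
            state = nxt

    frame = pd.concat(rows, ignore_index=True)
    if config.missing_demographics_prob > 0:
        persons = frame["person_id"].unique()
        hit = persons[rng.random(persons.size) < config.missing_demographics_prob]
        frame.loc[frame["person_id"].isin(hit), "education"] = np.nan
    frame = frame.sort_values(["person_id", "wave"], kind="mergesort").reset_index(
        drop=True
    )
    return Panel(frame=frame, config=config)


def inject_reversal_noise(panel: Panel, rate: float, seed: int = 0) -> Panel:
    """Create apparent recoveries for testing the monotone-coding repair.

    With probability ``rate``, each alive follow-up observation has its
    disease count downgraded below the previous wave's count (flags of
    the most recently acquired conditions are cleared), producing state
    reversals that downstream derivation must repair.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    if rate == 0.0:
        return Panel(frame=panel.frame.copy(), config=panel.config)
    rng = np.random.default_rng(seed)
    df = panel.frame.copy()
    conds = list(CHRONIC_CONDITIONS)
    flags = df[conds].to_numpy(dtype=float)
    counts = np.nansum(flags, axis=1)
    alive = df["alive"].to_numpy() > 0
    pid = df["person_id"].to_numpy()
    first = np.r_[True, pid[1:] != pid[:-1]]
    eligible = alive & ~first & (counts > 0)
    hit = eligible & (rng.random(len(df)) < rate)
    for i in np.flatnonzero(hit):
        target = max(int(counts[i]) - 1, 0)
        on = np.flatnonzero(flags[i] == 1.0)
        # drop flags until only `target` remain; keep lower-indexed on the
        # principle that earlier-acquired chronic conditions persist
        for col in on[target:]:
            flags[i, col] = 0.0
    df[conds] = flags
    return Panel(frame=df, config=panel.config)
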