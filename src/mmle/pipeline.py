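"""End-to-end orchestration: simulate/load -> derive -> fit -> expectancies.

Runs the full estimation pipeline for a chosen covariate model and
multimorbidity-definition variant, producing one table row per sex and
stratum (weighted LE with CI, MMLE with CI, percentage of LE with
multimorbidity) in the layout of the published expectancy table.
Sensitivity variants re-derive states from the raw disease flags, since
removing a disease changes counts at source.
"""
from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expectancy import (
    ExpectancyResult,
    build_matrix_set,
    conditional_expectancies,
    origin_distribution,
    weighted_expectancies,
)
from .model import (
    EDUCATION_LEVELS,
    RACES,
    CovariateProfile,
    ModelSpec,
    TransitionModel,
)
from .simulate import GenerativeConfig, generate_panel
from .states import (
    MultimorbidityDefinition,
    TRANSIENT_STATES,
    apply_exclusions,
    build_transition_records,
    derive_panel_states,
)

__all__ = [
    "DEFINITION_VARIANTS",
    "RunConfig",
    "PipelineReport",
    "definition_variant",
    "percent_of_le",
    "group_gap",
    "strata_for_model",
    "run_pipeline",
]

logger = logging.getLogger("mmle")

DEFINITION_VARIANTS = (
    "full",
    "no_hypertension",
    "no_tb",
    "no_hypertension_no_tb",
)


def definition_variant(
    name: str, base: MultimorbidityDefinition | None = None
) -> MultimorbidityDefinition:
    """Multimorbidity definition for a named sensitivity variant."""
    base = base or MultimorbidityDefinition()
    if name == "full":
        return base
    if name == "no_hypertension":
        return base.without("hypertension")
    if name == "no_tb":
        return base.without("tuberculosis")
    if name == "no_hypertension_no_tb":
        return base.without("hypertension", "tuberculosis")
    raise ValueError(f"unknown definition variant: {name!r}")


def percent_of_le(mmle: float, le: float) -> int:
    """Percentage of LE spent with multimorbidity, rounded half away
    from zero to the nearest integer (display convention)."""
    if le <= 0:
        raise ValueError("life expectancy must be positive")
    if not 0 <= mmle <= le:
        raise ValueError("MMLE must lie between 0 and LE")
    x = 100.0 * mmle / le
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def group_gap(value_a: float, value_b: float) -> float:
    """Between-group difference in years, rounded to one decimal."""
    if not (math.isfinite(value_a) and math.isfinite(value_b)):
        raise ValueError("inputs must be finite")
    return round(value_a - value_b, 1)


def strata_for_model(model_id: str) -> list[CovariateProfile]:
    """The covariate profiles at which a model's table rows are computed.

    The urban proportion is filled in at run time from the sample.
    """
    if model_id == "M1":
        return [CovariateProfile()]
    if model_id == "M2":
        return [CovariateProfile(race=r) for r in RACES]
    if model_id == "M3":
        return [CovariateProfile(education=e) for e in EDUCATION_LEVELS]
    if model_id == "M4":
        out = []
        for r in ("African", "Coloured", "white"):
            for e in ("less than secondary", "secondary"):
                out.append(CovariateProfile(race=r, education=e))
        return out
    raise ValueError(f"unknown model_id: {model_id!r}")


def _stratum_label(model_id: str, profile: CovariateProfile) -> str:
    if model_id == "M4":
        edu = "secondary or more" if profile.education != "less than secondary" else profile.education
        return f"{profile.race} x {edu}"
    return profile.label


@dataclass
class RunConfig:
    """Configuration of one end-to-end pipeline run."""

    generative: GenerativeConfig | None = None
    input_panel_path: str | Path | None = None
    model_ids: tuple[str, ...] = ("M1",)
    definition_variant: str = "full"
    hypertension_rule: str = "from_flag"
    start_age: float = 20.0
    truncation_age: float = 85.0
    alpha: float = 0.05
    seed: int = 0
    include_baseline_pseudo: bool = True
    drop_gapped: bool = False
    compute_cis: bool = True
    output_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if (self.generative is None) == (self.input_panel_path is None):
            raise ValueError(
                "exactly one of generative config or input_panel_path is required"
            )
        if self.start_age >= self.truncation_age:
            raise ValueError("start_age must be below truncation_age")
        if self.definition_variant not in DEFINITION_VARIANTS:
            raise ValueError(f"unknown definition variant: {self.definition_variant!r}")
        for m in self.model_ids:
            ModelSpec(m)  # validates

    @property
    def origin_age_window(self) -> tuple[float, float]:
        """Origin-state weights come from the decade above the start age
        (ages 20-29 for the age-20 analysis, 40-49 for age 40)."""
        return (self.start_age, self.start_age + 10.0)


@dataclass
class PipelineReport:
    """Collected outputs of one pipeline run."""

    results: list[ExpectancyResult]
    table: pd.DataFrame
    exclusion_tally: object
    timings: dict[str, float] = field(default_factory=dict)
    files: list[Path] = field(default_factory=list)


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Execute all stages and return the expectancy table.

    Stages: obtain panel (simulate or load CSV), apply the exclusion
    cascade, derive monotone states under the configured multimorbidity
    definition, build transition records, fit the sex-stratified
    multinomial logits, assemble age-indexed matrices per stratum and
    compute origin-weighted expectancies with delta-method intervals.
    Deterministic given the config and seed.
    """
    from .uncertainty import delta_method_ci  # deferred: avoids cycle at import

    timings: dict[str, float] = {}

    def _stage(name):
        logger.info("stage %s", name)
        return time.perf_counter()

    t0 = _stage("panel")
    if config.generative is not None:
        gen = config.generative
        if gen.seed != config.seed:
            from dataclasses import replace as _replace

            gen = _replace(gen, seed=config.seed)
        panel = generate_panel(gen).frame
    else:
        panel = pd.read_csv(config.input_panel_path)
    timings["panel"] = time.perf_counter() - t0

    t0 = _stage("exclusions")
    panel, tally = apply_exclusions(panel)
    logger.info("exclusion tally: %s", tally.to_dict())
    timings["exclusions"] = time.perf_counter() - t0

    t0 = _stage("states")
    defn = definition_variant(config.definition_variant)
    defn = MultimorbidityDefinition(
        included_conditions=defn.included_conditions,
        threshold=defn.threshold,
        hypertension_rule=config.hypertension_rule,
    )
    states = derive_panel_states(panel, defn)
    records = build_transition_records(
        states,
        include_baseline_pseudo=config.include_baseline_pseudo,
        drop_gapped=config.drop_gapped,
    )
    logger.info("%d transition records from %d individuals",
                len(records), records["person_id"].nunique())
    timings["states"] = time.perf_counter() - t0

    urban_prop = float((panel["residence"] == "urban").mean())
    results: list[ExpectancyResult] = []
    for model_id in config.model_ids:
        t0 = _stage(f"fit:{model_id}")
        spec = ModelSpec(model_id)
        for sex in ("male", "female"):
            fitted = TransitionModel(records, spec=spec, sex=sex).fit()
            dist = origin_distribution(states, sex, config.origin_age_window)
            for profile in strata_for_model(model_id):
                profile = CovariateProfile(
                    urban_proportion=urban_prop,
                    race=profile.race,
                    education=profile.education,
                )
                ms = build_matrix_set(
                    fitted,
                    profile,
                    start_age=config.start_age,
                    truncation_age=config.truncation_age,
                )
                cond = {
                    o: conditional_expectancies(ms, o) for o in TRANSIENT_STATES
                }
                res = weighted_expectancies(
                    cond,
                    dist,
                    model_id=model_id,
                    sex=sex,
                    stratum=_stratum_label(model_id, profile),
                )
                if config.compute_cis:
                    ci_le = delta_method_ci(
                        fitted,
                        "weighted_le",
                        profile,
                        dist,
                        alpha=config.alpha,
                        start_age=config.start_age,
                        truncation_age=config.truncation_age,
                    )
                    ci_mm = delta_method_ci(
                        fitted,
                        "mmle",
                        profile,
                        dist,
                        alpha=config.alpha,
                        start_age=config.start_age,
                        truncation_age=config.truncation_age,
                    )
                    res.ci_weighted_le = (ci_le.lower, ci_le.upper)
                    res.ci_mmle = (ci_mm.lower, ci_mm.upper)
                results.append(res)
        timings[f"fit:{model_id}"] = time.perf_counter() - t0

    rows = []
    for r in results:
        rows.append(
            {
                "model": r.model_id,
                "stratum": r.stratum,
                "sex": r.sex,
                "weighted_le": round(r.weighted_le, 1),
                "le_lo": round(r.ci_weighted_le[0], 1) if r.ci_weighted_le else None,
                "le_hi": round(r.ci_weighted_le[1], 1) if r.ci_weighted_le else None,
                "mmle": round(r.mmle, 1),
                "mmle_lo": round(r.ci_mmle[0], 1) if r.ci_mmle else None,
                "mmle_hi": round(r.ci_mmle[1], 1) if r.ci_mmle else None,
                "pct_mm": percent_of_le(r.mmle, r.weighted_le),
            }
        )
    table = pd.DataFrame(rows)

    files: list[Path] = []
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        tag = f"{config.definition_variant}_age{int(config.start_age)}"
        tpath = out / f"expectancies_{tag}.csv"
        table.to_csv(tpath, index=False)
        meta = {
            "model_ids": list(config.model_ids),
            "definition_variant": config.definition_variant,
            "start_age": config.start_age,
            "truncation_age": config.truncation_age,
            "alpha": config.alpha,
            "seed": config.seed,
            "exclusions": tally.to_dict(),
            "n_records": int(len(records)),
            "timings": timings,
        }
        mpath = out / f"expectancies_{tag}.meta.json"
        with open(mpath, "w") as fh:
            json.dump(meta, fh, indent=1)
        files += [tpath, mpath]

    return PipelineReport(
        results=results,
        table=table,
        exclusion_tally=tally,
        timings=timings,
        files=files,
    )
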