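"""Sex-stratified, design-weighted multinomial-logit transition models.

For each transient origin state the biennial probability of moving to
each admissible destination j is modelled as

    log(p_ij / p_ii) = alpha_ij + beta1_ij * Age + beta2_ij * Urban + gamma_ij' Cov

with "remain in the same state" as the reference destination.  Reverse
transitions are structural zeros and never appear on the right-hand
side.  Four nested covariate sets are supported:

    M1  age + residence
    M2  M1 + race
    M3  M1 + education
    M4  M1 + race x dichotomised education (Asian/Indian excluded)

Fitting maximises the design-weighted log-likelihood by Newton-Raphson
with analytic score and Hessian.  The default variance-covariance is the
weight-robust (sandwich) estimator appropriate for pseudo-likelihood
estimation with survey design weights; a model-based information option
is available.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.linalg import block_diag

from .states import ADMISSIBLE_DESTINATIONS, HealthState, TRANSIENT_STATES

__all__ = [
    "RACES",
    "EDUCATION_LEVELS",
    "ModelSpec",
    "CovariateProfile",
    "TransitionCoefficients",
    "TransitionModel",
    "TransitionModelResults",
    "ConvergenceError",
    "BoundaryWarning",
    "fit_transition_models",
]

RACES: tuple[str, ...] = ("African", "Asian/Indian", "Coloured", "white")
EDUCATION_LEVELS: tuple[str, ...] = (
    "less than secondary",
    "secondary",
    "post-secondary",
)
SEXES: tuple[str, ...] = ("male", "female")


class ConvergenceError(RuntimeError):
    """Raised when a multinomial-logit fit cannot be identified."""


class BoundaryWarning(UserWarning):
    """Emitted when an origin has no observed transitions into a
    destination (typically zero deaths), so that destination's
    probability degenerates to zero."""


def _education_high(education: object) -> float:
    """Dichotomise education: secondary school or more vs less."""
    return float(education in ("secondary", "post-secondary"))


@dataclass(frozen=True)
class ModelSpec:
    """Covariate specification of one of the nested models M1-M4."""

    model_id: str = "M1"

    def __post_init__(self) -> None:
        if self.model_id not in ("M1", "M2", "M3", "M4"):
            raise ValueError(f"unknown model_id: {self.model_id!r}")

    @property
    def columns(self) -> tuple[str, ...]:
        base = ("const", "age", "urban")
        if self.model_id == "M1":
            return base
        if self.model_id == "M2":
            return base + tuple(f"race[{r}]" for r in RACES[1:])
        if self.model_id == "M3":
            return base + tuple(f"education[{e}]" for e in EDUCATION_LEVELS[1:])
        # M4: race x dichotomised education, Asian/Indian excluded
        return base + (
            "race[Coloured]",
            "race[white]",
            "educ_high",
            "race[Coloured]:educ_high",
            "race[white]:educ_high",
        )

    @property
    def required_profile_fields(self) -> tuple[str, ...]:
        return {
            "M1": (),
            "M2": ("race",),
            "M3": ("education",),
            "M4": ("race", "education"),
        }[self.model_id]

    def admissible_records(self, records: pd.DataFrame) -> pd.DataFrame:
        """Drop records outside the model's support (M4 drops Asian/Indian)."""
        if self.model_id == "M4":
            return records[records["race"] != "Asian/Indian"]
        return records

    def design_matrix(self, records: pd.DataFrame) -> np.ndarray:
        """Design matrix for transition records (one row per record)."""
        n = len(records)
        urban = (records["residence"].to_numpy() == "urban").astype(float)
        cols = [np.ones(n), records["age_at_origin"].to_numpy(dtype=float), urban]
        if self.model_id == "M2":
            race = records["race"].to_numpy()
            cols += [(race == r).astype(float) for r in RACES[1:]]
        elif self.model_id == "M3":
            edu = records["education"].to_numpy()
            cols += [(edu == e).astype(float) for e in EDUCATION_LEVELS[1:]]
        elif self.model_id == "M4":
            race = records["race"].to_numpy()
            if (race == "Asian/Indian").any():
                raise ValueError("M4 requires Asian/Indian records to be dropped first")
            high = np.array([_education_high(e) for e in records["education"]])
            col_c = (race == "Coloured").astype(float)
            col_w = (race == "white").astype(float)
            cols += [col_c, col_w, high, col_c * high, col_w * high]
        return np.column_stack(cols)

    def design_row(self, profile: "CovariateProfile", age: float) -> np.ndarray:
        """Covariate row for prediction at a given exact age."""
        for f in self.required_profile_fields:
            if getattr(profile, f) is None:
                raise ValueError(
                    f"profile missing covariate required by {self.model_id}: {f}"
                )
        row = [1.0, float(age), float(profile.urban_proportion)]
        if self.model_id == "M2":
            row += [float(profile.race == r) for r in RACES[1:]]
        elif self.model_id == "M3":
            row += [float(profile.education == e) for e in EDUCATION_LEVELS[1:]]
        elif self.model_id == "M4":
            if profile.race == "Asian/Indian":
                raise ValueError("M4 excludes the Asian/Indian group")
            high = _education_high(profile.education)
            c = float(profile.race == "Coloured")
            w = float(profile.race == "white")
            row += [c, w, high, c * high, w * high]
        return np.asarray(row, dtype=float)


@dataclass(frozen=True)
class CovariateProfile:
    """Covariate values at which transition probabilities are predicted.

    Residence enters as the sample proportion urban (a fraction, not a
    0/1 indicator); categorical covariates are set to a specific group.
    """

    urban_proportion: float = 0.5
    race: str | None = None
    education: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.urban_proportion <= 1.0:
            raise ValueError("urban_proportion must lie in [0, 1]")
        if self.race is not None and self.race not in RACES:
            raise ValueError(f"unknown race: {self.race!r}")
        if self.education is not None and self.education not in EDUCATION_LEVELS:
            raise ValueError(f"unknown education: {self.education!r}")

    @property
    def label(self) -> str:
        bits = [b for b in (self.race, self.education) if b is not None]
        return " x ".join(bits) if bits else "overall"


@dataclass
class TransitionCoefficients:
    """Per-origin multinomial-logit coefficients on a common design.

    ``coef[origin]`` has one row per non-reference admissible destination
    (in the order of :data:`ADMISSIBLE_DESTINATIONS` minus the first,
    stay, entry) and one column per design column.  The reference (stay)
    destination's coefficients are identically zero and not stored.
    """

    spec: ModelSpec
    sex: str
    coef: dict[HealthState, np.ndarray]

    def __post_init__(self) -> None:
        p = len(self.spec.columns)
        for origin in TRANSIENT_STATES:
            arr = np.asarray(self.coef[origin], dtype=float)
            k = len(ADMISSIBLE_DESTINATIONS[origin]) - 1
            if arr.shape != (k, p):
                raise ValueError(
                    f"coef[{origin.name}] must have shape ({k}, {p}), got {arr.shape}"
                )
            self.coef[origin] = arr

    def destinations(self, origin: HealthState) -> tuple[HealthState, ...]:
        return ADMISSIBLE_DESTINATIONS[HealthState(origin)]

    def predict_row_from_x(self, origin: HealthState, x: np.ndarray) -> np.ndarray:
        """Probability vector over the four states from design row ``x``."""
        origin = HealthState(origin)
        if origin == HealthState.DEAD:
            raise ValueError("origin must be a transient state")
        eta = self.coef[origin] @ x
        expeta = np.exp(np.concatenate(([0.0], eta)) - max(0.0, eta.max(initial=0.0)))
        probs = expeta / expeta.sum()
        row = np.zeros(4)
        for dest, p in zip(self.destinations(origin), probs):
            row[int(dest)] = p
        return row

    def predict_row(
        self, origin: HealthState, profile: CovariateProfile, age: float
    ) -> np.ndarray:
        """Destination-state probabilities at a covariate profile and age.

        Inadmissible destinations (reverse transitions) carry probability
        exactly zero; the row sums to one.
        """
        x = self.spec.design_row(profile, age)
        return self.predict_row_from_x(origin, x)

    # -- flat parameter vector, used by the delta method ------------------
    def flatten(self) -> np.ndarray:
        return np.concatenate(
            [self.coef[o].ravel() for o in TRANSIENT_STATES]
        )

    def with_flat(self, theta: np.ndarray) -> "TransitionCoefficients":
        out: dict[HealthState, np.ndarray] = {}
        pos = 0
        for o in TRANSIENT_STATES:
            size = self.coef[o].size
            out[o] = theta[pos : pos + size].reshape(self.coef[o].shape).copy()
            pos += size
        if pos != theta.size:
            raise ValueError("theta has wrong length")
        return TransitionCoefficients(spec=self.spec, sex=self.sex, coef=out)

    def param_names(self) -> list[str]:
        names = []
        for o in TRANSIENT_STATES:
            dests = self.destinations(o)[1:]
            for d in dests:
                for c in self.spec.columns:
                    names.append(f"{o.name}->{d.name}:{c}")
        return names

    def to_dict(self) -> dict:
        return {
            "model_id": self.spec.model_id,
            "sex": self.sex,
            "columns": list(self.spec.columns),
            "coef": {o.name: self.coef[o].tolist() for o in TRANSIENT_STATES},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TransitionCoefficients":
        spec = ModelSpec(d["model_id"])
        coef = {
            HealthState[name]: np.asarray(v, dtype=float)
            for name, v in d["coef"].items()
        }
        return cls(spec=spec, sex=d["sex"], coef=coef)


def predict_probability_row(
    model: "TransitionCoefficients | TransitionModelResults",
    origin: HealthState,
    profile: CovariateProfile,
    age: float,
) -> np.ndarray:
    """Functional wrapper around :meth:`TransitionCoefficients.predict_row`."""
    coefs = model.coefficients if isinstance(model, TransitionModelResults) else model
    return coefs.predict_row(origin, profile, age)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _fit_origin(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    n_cat: int,
    origin: HealthState,
    dests: tuple[HealthState, ...],
    maxiter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, list[int]]:
    """Newton-Raphson for one weighted multinomial logit.

    Returns (B, bread_inv=I^{-1}, meat, loglik, degenerate destination
    indices).  ``y`` holds category indices 0..n_cat-1 with 0 = reference
    (stay).  Destinations with zero observed (weighted) records are held
    at a large negative intercept and excluded from the optimisation.
    """
    n, p = X.shape
    K = n_cat - 1  # free categories
    Y = np.zeros((n, K))
    for j in range(K):
        Y[:, j] = y == (j + 1)

    observed = [j for j in range(K) if Y[:, j].sum() > 0]
    degenerate = [j for j in range(K) if j not in observed]
    if len(observed) == 0:
        stay = dests[0].name
        raise ConvergenceError(
            f"all records from origin {origin.name} share destination {stay}; "
            "model not identified"
        )

    B = np.zeros((K, p))
    for j in degenerate:
        B[j, 0] = -30.0  # probability numerically zero

    free = np.array(observed, dtype=int)

    def probs(Bcur: np.ndarray) -> np.ndarray:
        eta = X @ Bcur.T  # (n, K)
        eta = np.column_stack([np.zeros(n), eta])
        eta -= eta.max(axis=1, keepdims=True)
        e = np.exp(eta)
        return e / e.sum(axis=1, keepdims=True)  # (n, K+1)

    def loglik(Bcur: np.ndarray) -> float:
        P = probs(Bcur)
        idx = np.arange(n)
        return float(np.sum(w * np.log(np.clip(P[idx, y], 1e-300, None))))

    ll = loglik(B)
    kf = len(free)
    for _ in range(maxiter):
        P = probs(B)
        resid = Y[:, free] - P[:, free + 1]  # (n, kf)
        g = (X.T @ (w[:, None] * resid)).T.ravel()  # (kf*p,)
        H = np.zeros((kf * p, kf * p))
        for a, j in enumerate(free):
            for b, l in enumerate(free):
                pj = P[:, j + 1]
                pl = P[:, l + 1]
                wjl = w * (pj * (1.0 * (j == l)) - pj * pl)
                H[a * p : (a + 1) * p, b * p : (b + 1) * p] = X.T @ (wjl[:, None] * X)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                f"singular information matrix for origin {origin.name} "
                f"(possible separation)"
            ) from exc
        # step-halving line search
        scale = 1.0
        for _half in range(30):
            Bnew = B.copy()
            Bnew[free] = B[free] + scale * step.reshape(kf, p)
            llnew = loglik(Bnew)
            if llnew >= ll - 1e-10:
                break
            scale *= 0.5
        B, ll_prev, ll = Bnew, ll, llnew
        if np.max(np.abs(g)) < tol * (1.0 + abs(ll)) and ll - ll_prev < 1e-9:
            break
    else:
        if np.max(np.abs(g)) > 1e-4 * (1.0 + abs(ll)):
            dnames = ", ".join(d.name for d in dests[1:])
            raise ConvergenceError(
                f"Newton iteration did not converge for origin {origin.name} "
                f"(destinations {dnames}); possible separation"
            )

    # information and sandwich meat on the free block
    P = probs(B)
    H = np.zeros((kf * p, kf * p))
    for a, j in enumerate(free):
        for b, l in enumerate(free):
            pj = P[:, j + 1]
            pl = P[:, l + 1]
            wjl = w * (pj * (1.0 * (j == l)) - pj * pl)
            H[a * p : (a + 1) * p, b * p : (b + 1) * p] = X.T @ (wjl[:, None] * X)
    resid = Y[:, free] - P[:, free + 1]
    S = (w[:, None] * resid)[:, :, None] * X[:, None, :]  # (n, kf, p)
    S = S.reshape(n, kf * p)
    meat = S.T @ S
    bread_inv = np.linalg.inv(H)

    # expand to the full (K*p) parameter block, zeros for degenerate rows
    full_bread = np.zeros((K * p, K * p))
    full_meat = np.zeros((K * p, K * p))
    for a, j in enumerate(free):
        for b, l in enumerate(free):
            full_bread[j * p : (j + 1) * p, l * p : (l + 1) * p] = bread_inv[
                a * p : (a + 1) * p, b * p : (b + 1) * p
            ]
            full_meat[j * p : (j + 1) * p, l * p : (l + 1) * p] = meat[
                a * p : (a + 1) * p, b * p : (b + 1) * p
            ]
    return B, full_bread, full_meat, ll, degenerate


class TransitionModel:
    """Weighted multinomial-logit model of state transitions for one sex.

    Parameters
    ----------
    records
        Transition records (one row per origin->destination move) as
        produced by :func:`mmle.states.build_transition_records`.
    spec
        Covariate specification (M1-M4).
    sex
        Stratum to fit; records of the other sex are dropped.

    Examples
    --------
    >>> model = TransitionModel(records, ModelSpec("M1"), sex="female")
    >>> res = model.fit()
    >>> res.predict_row(HealthState.NO_DISEASE, CovariateProfile(0.5), age=40)
    """

    def __init__(
        self,
        records: pd.DataFrame,
        spec: ModelSpec = ModelSpec("M1"),
        sex: str = "female",
    ) -> None:
        if sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {sex!r}")
        self.spec = spec
        self.sex = sex
        rec = records[records["sex"] == sex]
        rec = spec.admissible_records(rec)
        if rec.empty:
            raise ValueError(f"no records for sex={sex!r}")
        self.records = rec.reset_index(drop=True)

    @classmethod
    def from_panel(
        cls,
        panel: pd.DataFrame,
        defn=None,
        spec: ModelSpec = ModelSpec("M1"),
        sex: str = "female",
        **record_kwargs,
    ) -> "TransitionModel":
        """Build the model straight from a derived-state panel."""
        from .states import MultimorbidityDefinition, build_transition_records

        if defn is None:
            defn = MultimorbidityDefinition()
        rec = build_transition_records(panel, **record_kwargs)
        return cls(rec, spec=spec, sex=sex)

    def fit(
        self,
        cov_type: str = "sandwich",
        maxiter: int = 100,
        tol: float = 1e-10,
    ) -> "TransitionModelResults":
        """Fit per-origin multinomial logits by maximum weighted likelihood.

        ``cov_type`` is ``"sandwich"`` (robust, default) or
        ``"information"`` (inverse weighted information with weights
        normalised to mean one).
        """
        if cov_type not in ("sandwich", "information"):
            raise ValueError("cov_type must be 'sandwich' or 'information'")
        coef: dict[HealthState, np.ndarray] = {}
        vcov_blocks: list[np.ndarray] = []
        loglik = 0.0
        n_by_origin: dict[HealthState, int] = {}
        for origin in TRANSIENT_STATES:
            sub = self.records[self.records["origin_state"] == int(origin)]
            if sub.empty:
                raise ValueError(
                    f"no records with origin {origin.name} in sex={self.sex!r}"
                )
            dests = ADMISSIBLE_DESTINATIONS[origin]
            X = self.spec.design_matrix(sub)
            w = sub["design_weight"].to_numpy(dtype=float)
            if cov_type == "information":
                w = w / w.mean()
            dest_idx = {int(d): k for k, d in enumerate(dests)}
            y = np.array([dest_idx[int(d)] for d in sub["destination_state"]])
            B, bread_inv, meat, ll, degenerate = _fit_origin(
                X, y, w, len(dests), origin, dests, maxiter, tol
            )
            for j in degenerate:
                warnings.warn(
                    f"origin {origin.name}: no observed transitions to "
                    f"{dests[j + 1].name}; its probability degenerates to zero",
                    BoundaryWarning,
                    stacklevel=2,
                )
            coef[origin] = B
            if cov_type == "sandwich":
                vcov_blocks.append(bread_inv @ meat @ bread_inv)
            else:
                vcov_blocks.append(bread_inv)
            loglik += ll
            n_by_origin[origin] = len(sub)
        coefficients = TransitionCoefficients(spec=self.spec, sex=self.sex, coef=coef)
        vcov = block_diag(*vcov_blocks)
        vcov = 0.5 * (vcov + vcov.T)
        return TransitionModelResults(
            model=self,
            coefficients=coefficients,
            cov_params=vcov,
            loglik=loglik,
            nobs=len(self.records),
            n_by_origin=n_by_origin,
            cov_type=cov_type,
        )


@dataclass
class TransitionModelResults:
    """Fitted transition model: estimates, vcov, prediction, summary."""

    model: TransitionModel | None
    coefficients: TransitionCoefficients
    cov_params: np.ndarray
    loglik: float
    nobs: int
    n_by_origin: dict[HealthState, int]
    cov_type: str = "sandwich"

    def __post_init__(self) -> None:
        k = self.coefficients.flatten().size
        if self.cov_params.shape != (k, k):
            raise ValueError("cov_params dimensions inconsistent with coefficients")
        if not np.allclose(self.cov_params, self.cov_params.T, atol=1e-8):
            raise ValueError("cov_params must be symmetric")

    @property
    def spec(self) -> ModelSpec:
        return self.coefficients.spec

    @property
    def sex(self) -> str:
        return self.coefficients.sex

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.coefficients.flatten(), index=self.coefficients.param_names())

    @property
    def bse(self) -> pd.Series:
        se = np.sqrt(np.clip(np.diag(self.cov_params), 0.0, None))
        return pd.Series(se, index=self.coefficients.param_names())

    def predict_row(
        self, origin: HealthState, profile: CovariateProfile, age: float
    ) -> np.ndarray:
        return self.coefficients.predict_row(origin, profile, age)

    def with_coef_vector(self, theta: np.ndarray) -> "TransitionModelResults":
        """Copy of the results with the flat coefficient vector replaced
        (used for finite-difference variance propagation)."""
        return replace(self, coefficients=self.coefficients.with_flat(theta))

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        p = self.params
        se = self.bse
        return pd.DataFrame({"lower": p - z * se, "upper": p + z * se})

    def summary(self) -> str:
        lines = [
            f"Transition model {self.spec.model_id} ({self.sex}), "
            f"n={self.nobs}, loglik={self.loglik:.1f}, cov={self.cov_type}",
            f"{'parameter':<42}{'coef':>10}{'se':>10}",
        ]
        for name, c, s in zip(self.params.index, self.params, self.bse):
            lines.append(f"{name:<42}{c:>10.4f}{s:>10.4f}")
        return "\n".join(lines)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.params, "se": self.bse})

    # -- serialisation ----------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "coefficients": self.coefficients.to_dict(),
            "cov_params": self.cov_params.tolist(),
            "loglik": self.loglik,
            "nobs": self.nobs,
            "n_by_origin": {o.name: n for o, n in self.n_by_origin.items()},
            "cov_type": self.cov_type,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TransitionModelResults":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            model=None,
            coefficients=TransitionCoefficients.from_dict(d["coefficients"]),
            cov_params=np.asarray(d["cov_params"], dtype=float),
            loglik=d["loglik"],
            nobs=d["nobs"],
            n_by_origin={HealthState[k]: v for k, v in d["n_by_origin"].items()},
            cov_type=d["cov_type"],
        )


def fit_transition_models(
    records: pd.DataFrame,
    spec: ModelSpec = ModelSpec("M1"),
    sexes: Iterable[str] = SEXES,
    **fit_kwargs,
) -> dict[str, TransitionModelResults]:
    """Fit one model per sex stratum and return them keyed by sex."""
    return {
        sex: TransitionModel(records, spec=spec, sex=sex).fit(**fit_kwargs)
        for sex in sexes
    }
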