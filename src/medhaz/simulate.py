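"""Synthetic cohort generator with a known causal structure, and the
ground-truth effect decomposition it implies.

The generator emulates a pooled 1997-2014 health-interview cohort with
mortality follow-up through the end of 2015:

* covariates: sex, age at survey (scaled Beta on [18, 85]), education and
  marital status with race-specific probabilities, survey year (uniform
  integers 1997-2014);
* exposure: race/ethnicity with fixed marginal probabilities;
* mediators: four categorized lifestyle factors, each drawn from a
  baseline-category multinomial logit on race, age, education, marital
  status and survey year (mediators conditionally independent given
  exposure and covariates);
* mortality: additive hazard on the age timescale,
  ``lambda(a) = lambda0_sex(a) + beta_race + sum_k (gamma_k[M_k] +
  delta_race,k[M_k]) + covariate effects``, with a piecewise-constant
  Gompertz-like baseline per 1-year age bin, administrative censoring at
  age-at-survey + (2016 - survey year), and a hard cap at age 100.

Because every effect enters the hazard additively with known
coefficients, the implied differential-exposure / differential-
vulnerability decomposition is available in closed form
(:func:`true_decomposition`), which is what makes the whole estimation
pipeline testable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from ._util import substream
from .cohort import (
    MEDIATOR_LEVELS,
    MEDIATORS,
    Cohort,
    validate_cohort,
)
from .exceptions import DomainError, GenerationError
from .mediators import PredictorSpec, softmax_probs

__all__ = [
    "MediatorLaw",
    "HazardParams",
    "GeneratorParams",
    "TrueDecomposition",
    "default_params",
    "generate_cohort",
    "sample_event_age",
    "true_decomposition",
]

SCALE = 10_000.0  # effects reported per 10,000 person-years


def short_name(mediator_column: str) -> str:
    """'alcohol_category' -> 'alcohol', etc."""
    return mediator_column.removesuffix("_category")


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class MediatorLaw:
    """Baseline-category logit law of one mediator given exposure+covariates.

    ``coef`` has one row per non-reference level (levels[1:]) and one
    column per predictor of the accompanying :class:`PredictorSpec`.
    """

    name: str  # mediator column name
    levels: list  # reference level first
    coef: np.ndarray  # (n_levels - 1, n_predictors)

    def probs(self, X: np.ndarray) -> np.ndarray:
        """Category probabilities (n, n_levels), reference level first."""
        return softmax_probs(X, np.asarray(self.coef, dtype=float))


@dataclass
class HazardParams:
    """Additive mortality hazard: piecewise-constant baseline plus
    constant offsets per exposure, mediator level and covariate.

    Rates are per person-year. Reference levels carry coefficient 0 and
    are omitted from the dictionaries.
    """

    age_edges: np.ndarray  # bin edges, e.g. 18..100
    baseline_rates: np.ndarray  # one rate per bin (reference sex)
    sex_factor: dict  # sex -> multiplier on the baseline
    beta_direct: dict  # race -> rate offset
    gamma: dict  # mediator column -> {level: rate offset}
    delta: dict  # race -> mediator column -> {level: rate offset}
    covariate_effects: dict  # predictor name (e.g. 'edu_high') -> rate offset


@dataclass
class GeneratorParams:
    """Full specification of the synthetic-cohort law."""

    n: int
    races: list  # reference ('white') first
    race_probs: list
    sex_probs: dict  # sex -> probability
    age_beta: tuple  # (a, b) of the Beta age law scaled to [age_min, age_max]
    age_range: tuple  # (18.0, 85.0)
    education_probs: dict  # race -> (low, medium, high)
    married_prob: dict  # race -> probability
    year_range: tuple  # inclusive integer range (1997, 2014)
    mediator_laws: dict  # sex -> [MediatorLaw] * 4
    hazard: HazardParams
    predictor_spec: "PredictorSpec" = None
    admin_end_year: float = 2016.0
    max_age: float = 100.0

    def laws_for(self, sex: str):
        return self.mediator_laws[sex]

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if dataclasses.is_dataclass(obj):
                return clean(dataclasses.asdict(obj))
            return obj

        return clean(dataclasses.asdict(self))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorParams":
        d = dict(d)
        d["mediator_laws"] = {
            sex: [
                MediatorLaw(law["name"], list(law["levels"]), np.asarray(law["coef"], float))
                for law in laws
            ]
            for sex, laws in d["mediator_laws"].items()
        }
        hz = dict(d["hazard"])
        hz["age_edges"] = np.asarray(hz["age_edges"], float)
        hz["baseline_rates"] = np.asarray(hz["baseline_rates"], float)
        d["hazard"] = HazardParams(**hz)
        spec = d.get("predictor_spec")
        if isinstance(spec, dict):
            spec = dict(spec)
            spec["race_levels"] = tuple(spec["race_levels"])
            d["predictor_spec"] = PredictorSpec(**spec)
        for key in ("age_beta", "age_range", "year_range"):
            d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class TrueDecomposition:
    """Ground-truth effect components implied by :class:`GeneratorParams`.

    ``components[(sex, race)]`` maps component names (``total``,
    ``direct``, ``net_indirect``, ``exposure_<m>``, ``vulnerability_<m>``)
    to deaths per 10,000 person-years; ``mc_se`` holds Monte-Carlo
    standard errors where the value was simulated (None in closed form).
    """

    components: dict
    mc_se: dict | None = None
    mode: str = "closed_form"

    def for_contrast(self, sex: str, race: str) -> dict:
        return self.components[(sex, race)]


# ---------------------------------------------------------------------------
# default parameters
# ---------------------------------------------------------------------------

# Mediator-category prevalences (fractions) loosely matched to published
# unweighted survey descriptives, per sex and race; used only to place
# the default logit intercepts and race shifts at realistic values.
_PREV = {
    "men": {
        "alcohol_category": {  # cat_i, never, former, cat_ii, cat_iii
            "white": (0.67, 0.19, 0.09, 0.03, 0.03) ,
            "black": (0.56, 0.31, 0.09, 0.02, 0.02),
            "hispanic": (0.63, 0.26, 0.07, 0.02, 0.02),
            "other": (0.59, 0.34, 0.05, 0.01, 0.01),
        },
        "smoking_category": {  # never, former, someday, everyday
            "white": (0.46, 0.30, 0.04, 0.20),
            "black": (0.53, 0.19, 0.07, 0.21),
            "hispanic": (0.59, 0.20, 0.08, 0.13),
            "other": (0.60, 0.20, 0.05, 0.15),
        },
        "bmi_category": {  # normal, underweight, overweight, obese
            "white": (0.31, 0.01, 0.43, 0.25),
            "black": (0.30, 0.01, 0.39, 0.30),
            "hispanic": (0.27, 0.01, 0.46, 0.27)  ,
            "other": (0.48, 0.02, 0.37, 0.14),
        },
        "activity_category": {  # active, somewhat, sedentary
            "white": (0.52, 0.16, 0.33),
            "black": (0.44, 0.14, 0.42),
            "hispanic": (0.41, 0.13, 0.46),
            "other": (0.51, 0.17, 0.32),
        },
    },
    "women": {
        "alcohol_category": {
            "white": (0.60, 0.30, 0.06, 0.03, 0.01),
            "black": (0.43, 0.49, 0.05, 0.02, 0.01),
            "hispanic": (0.42, 0.53, 0.04, 0.008, 0.004),
            "other": (0.40, 0.55, 0.03, 0.01, 0.004),
        },
        "smoking_category": {
            "white": (0.55, 0.23, 0.04, 0.18),
            "black": (0.67, 0.13, 0.05, 0.15),
            "hispanic": (0.78, 0.11, 0.04, 0.08),
            "other": (0.80, 0.09, 0.03, 0.08),
        },
        "bmi_category": {
            "white": (0.46, 0.02, 0.27, 0.24),
            "black": (0.27, 0.02, 0.31, 0.41),
            "hispanic": (0.36, 0.02, 0.33, 0.30),
            "other": (0.59, 0.06, 0.21, 0.13),
        },
        "activity_category": {
            "white": (0.44, 0.21, 0.35),
            "black": (0.31, 0.18, 0.51),
            "hispanic": (0.32, 0.16, 0.52),
            "other": (0.41, 0.22, 0.38),
        },
    },
}

# Small covariate effects (on the logit scale) per mediator level; keys
# are (mediator, level, predictor). These make the mediator laws depend
# on covariates, as in real cohorts.
_LAW_COVARIATE_LOGITS = {
    ("alcohol_category", "never", "age_s"): 0.15,
    ("alcohol_category", "former", "age_s"): 0.35,
    ("alcohol_category", "cat_iii", "age_s"): 0.05,
    ("alcohol_category", "cat_iii", "edu_high"): -0.30,
    ("alcohol_category", "cat_iii", "married"): -0.25,
    ("smoking_category", "former", "age_s"): 0.45,
    ("smoking_category", "someday", "age_s"): -0.10,
    ("smoking_category", "everyday", "age_s"): 0.05,
    ("smoking_category", "everyday", "edu_medium"): -0.20,
    ("smoking_category", "everyday", "edu_high"): -0.50,
    ("smoking_category", "everyday", "married"): -0.15,
    ("smoking_category", "everyday", "year_s"): -0.25,
    ("bmi_category", "underweight", "age_s"): -0.10,
    ("bmi_category", "overweight", "age_s"): 0.15,
    ("bmi_category", "obese", "age_s"): 0.10,
    ("bmi_category", "obese", "edu_high"): -0.25,
    ("bmi_category", "obese", "year_s"): 0.20,
    ("activity_category", "somewhat", "age_s"): 0.05,
    ("activity_category", "sedentary", "age_s"): 0.30,
    ("activity_category", "sedentary", "edu_medium"): -0.15,
    ("activity_category", "sedentary", "edu_high"): -0.40,
    ("activity_category", "sedentary", "year_s"): -0.10,
}

# Mediator-level hazard offsets (per person-year), reference levels 0.
_DEFAULT_GAMMA = {
    "alcohol_category": {"never": 0.0006, "former": 0.0018, "cat_ii": 0.0009, "cat_iii": 0.0028},
    "smoking_category": {"former": 0.0010, "someday": 0.0022, "everyday": 0.0042},
    "bmi_category": {"underweight": 0.0028, "overweight": 0.0001, "obese": 0.0011},
    "activity_category": {"somewhat": 0.0009, "sedentary": 0.0024},
}

# Exposure x mediator additive interactions (differential vulnerability).
_DEFAULT_DELTA = {
    "black": {
        "alcohol_category": {"never": -0.0002, "former": -0.0006, "cat_ii": -0.0004, "cat_iii": -0.0012},
        "smoking_category": {"former": 0.0002, "someday": 0.0005, "everyday": 0.0009},
        "bmi_category": {"underweight": 0.0004, "overweight": -0.0001, "obese": -0.0005},
        "activity_category": {"somewhat": -0.0002, "sedentary": -0.0004},
    },
    "hispanic": {
        "alcohol_category": {"never": -0.0001, "former": -0.0003, "cat_ii": -0.0002, "cat_iii": -0.0008},
        "smoking_category": {"former": 0.0002, "someday": 0.0006, "everyday": 0.0011},
        "bmi_category": {"underweight": 0.0002, "overweight": 0.0001, "obese": 0.0003},
        "activity_category": {"somewhat": -0.0003, "sedentary": -0.0007},
    },
    "other": {m: {} for m in MEDIATORS},
}

_DEFAULT_BETA_DIRECT = {"black": 0.0020, "hispanic": -0.0003, "other": -0.0001}

_DEFAULT_EDUCATION = {
    "white": (0.39, 0.31, 0.30),
    "black": (0.53, 0.31, 0.16),
    "hispanic": (0.67, 0.22, 0.11),
    "other": (0.30, 0.25, 0.45),
}
_DEFAULT_MARRIED = {"white": 0.56, "black": 0.33, "hispanic": 0.56, "other": 0.57}
_DEFAULT_RACE_PROBS = {"white": 0.63, "black": 0.15, "hispanic": 0.17, "other": 0.05}


def default_params(n: int = 20_000, races=("white", "black")) -> GeneratorParams:
    """Ship-with generator parameters.

    Marginal prevalences, race mix, age law and hazard magnitudes are
    loosely calibrated to published unweighted descriptives of the
    emulated survey (illustrative realism, not estimates). ``races``
    selects the exposure levels (reference first), e.g.
    ``("white", "black")`` or ``("white", "black", "hispanic")``.
    """
    races = list(races)
    if races[0] != "white":
        raise DomainError("the reference exposure level must be 'white'")
    spec = PredictorSpec(race_levels=tuple(races[1:]))
    probs = np.array([_DEFAULT_RACE_PROBS[r] for r in races], dtype=float)
    probs = probs / probs.sum()

    laws = {}
    for sex in ("men", "women"):
        sex_laws = []
        for med in MEDIATORS:
            levels = MEDIATOR_LEVELS[med]
            prev = _PREV[sex][med]
            pref = np.array(prev["white"], dtype=float)
            pref = pref / pref.sum()
            coef = np.zeros((len(levels) - 1, len(spec.names())))
            logit_ref = np.log(pref[1:] / pref[0])
            coef[:, 0] = logit_ref
            for j, race in enumerate(races[1:]):
                pr = np.array(prev[race], dtype=float)
                pr = pr / pr.sum()
                coef[:, 1 + j] = np.log(pr[1:] / pr[0]) - logit_ref
            names = spec.names()
            for li, level in enumerate(levels[1:]):
                for pi, pname in enumerate(names):
                    extra = _LAW_COVARIATE_LOGITS.get((med, level, pname))
                    if extra is not None:
                        coef[li, pi] += extra
            sex_laws.append(MediatorLaw(med, list(levels), coef))
        laws[sex] = sex_laws

    age_edges = np.arange(18.0, 101.0)
    mid = 0.5 * (age_edges[:-1] + age_edges[1:])
    baseline = 9e-4 + 2.0e-3 * np.exp(0.085 * (mid - 40.0))
    hazard = HazardParams(
        age_edges=age_edges,
        baseline_rates=baseline,
        sex_factor={"men": 1.0, "women": 0.6},
        beta_direct={r: _DEFAULT_BETA_DIRECT[r] for r in races[1:]},
        gamma={m: dict(_DEFAULT_GAMMA[m]) for m in MEDIATORS},
        delta={r: {m: dict(_DEFAULT_DELTA[r][m]) for m in MEDIATORS} for r in races[1:]},
        covariate_effects={
            "edu_medium": -0.0001,
            "edu_high": -0.0002,
            "married": -0.0001,
            "year_s": -0.00005,
        },
    )
    return GeneratorParams(
        n=n,
        races=races,
        race_probs=probs.tolist(),
        sex_probs={"men": 0.45, "women": 0.55},
        age_beta=(1.3, 1.8),
        age_range=(18.0, 85.0),
        education_probs={r: _DEFAULT_EDUCATION[r] for r in races},
        married_prob={r: _DEFAULT_MARRIED[r] for r in races},
        year_range=(1997, 2014),
        mediator_laws=laws,
        hazard=hazard,
        predictor_spec=spec,
    )


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _sample_covariates(params: GeneratorParams, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw (sex, race, age, education, married, year) from the generator laws."""
    sexes = list(params.sex_probs)
    sex = rng.choice(sexes, size=n, p=[params.sex_probs[s] for s in sexes])
    race = rng.choice(params.races, size=n, p=params.race_probs)
    a, b = params.age_beta
    lo, hi = params.age_range
    age = lo + (hi - lo) * rng.beta(a, b, size=n)
    y0, y1 = params.year_range
    year = rng.integers(y0, y1 + 1, size=n)
    education = np.empty(n, dtype=object)
    married = np.zeros(n, dtype=int)
    for r in params.races:
        m = race == r
        if not m.any():
            continue
        education[m] = rng.choice(
            ["low", "medium", "high"], size=int(m.sum()), p=np.asarray(params.education_probs[r], float)
        )
        married[m] = rng.random(int(m.sum())) < params.married_prob[r]
    return pd.DataFrame(
        {
            "sex": sex,
            "race_ethnicity": race,
            "age_at_survey": age,
            "education": education,
            "married": married,
            "survey_year": year,
        }
    )


def _sample_mediators(params: GeneratorParams, cov: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the four mediator categories given covariates and exposure."""
    spec = params.predictor_spec
    out = {}
    for med in MEDIATORS:
        out[med] = np.empty(len(cov), dtype=object)
    for sex in cov["sex"].unique():
        m = (cov["sex"] == sex).to_numpy()
        X = spec.build(cov.loc[m])
        for law in params.laws_for(sex):
            P = law.probs(X)
            u = rng.random(int(m.sum()))
            idx = (P.cumsum(axis=1) < u[:, None]).sum(axis=1)
            out[law.name][m] = np.asarray(law.levels, dtype=object)[idx]
    return cov.assign(**out)


def _hazard_offsets(params: GeneratorParams, df: pd.DataFrame) -> np.ndarray:
    """Constant per-subject additive hazard offset (everything but the baseline)."""
    hz = params.hazard
    n = len(df)
    off = np.zeros(n)
    race = df["race_ethnicity"].to_numpy()
    for r, b in hz.beta_direct.items():
        off[race == r] += b
    for med in MEDIATORS:
        levels = df[med].to_numpy()
        for lev, g in hz.gamma.get(med, {}).items():
            off[levels == lev] += g
        for r, med_map in hz.delta.items():
            dmap = med_map.get(med, {})
            if dmap:
                rm = race == r
                for lev, d in dmap.items():
                    off[rm & (levels == lev)] += d
    spec = params.predictor_spec
    names = spec.names()
    X = spec.build(df)
    for pname, c in hz.covariate_effects.items():
        off += c * X[:, names.index(pname)]
    return off


def sample_event_age(entry_age, rates, age_edges, u=None, rng=None):
    """Invert the piecewise-constant cumulative hazard to draw event ages.

    ``rates`` is (n, n_bins) (or (n_bins,) broadcast) of nonnegative
    per-year rates over the age bins defined by ``age_edges``; the
    cumulative hazard is accumulated from each subject's ``entry_age``
    and the exponential quantile ``-log(u)`` is inverted through it.
    Returns +inf where the total hazard to the last edge is insufficient
    (the subject outlives the supported range).
    """
    entry = np.atleast_1d(np.asarray(entry_age, dtype=float))
    edges = np.asarray(age_edges, dtype=float)
    R = np.atleast_2d(np.asarray(rates, dtype=float))
    if R.shape[0] == 1 and entry.shape[0] > 1:
        R = np.broadcast_to(R, (entry.shape[0], R.shape[1]))
    if np.any(R < 0):
        raise DomainError("hazard rates must be nonnegative")
    if np.any(entry < edges[0]) or np.any(entry >= edges[-1]):
        raise DomainError("entry age outside the supported age range")
    if u is None:
        u = (rng or np.random.default_rng()).random(entry.shape[0])
    u = np.atleast_1d(np.asarray(u, dtype=float))
    target = -np.log(u)

    # width of each bin clipped to start at the subject's entry age
    widths = np.clip(edges[1:][None, :] - np.maximum(edges[:-1][None, :], entry[:, None]), 0.0, None)
    cum = np.cumsum(R * widths, axis=1)
    # first bin where the cumulative hazard reaches the target
    k = (cum < target[:, None]).sum(axis=1)
    out = np.full(entry.shape[0], np.inf)
    hit = k < R.shape[1]
    kk = k[hit]
    prev = np.where(kk > 0, cum[hit, np.maximum(kk - 1, 0)], 0.0)
    start = np.maximum(edges[kk], entry[hit])
    rate = R[hit, kk]
    with np.errstate(divide="ignore", invalid="ignore"):
        out[hit] = start + (target[hit] - prev) / rate
    scalar = np.asarray(entry_age).ndim == 0
    return float(out[0]) if scalar else out


def generate_cohort(params: GeneratorParams, seed: int) -> Cohort:
    """Draw a full synthetic cohort; deterministic given ``seed``.

    Raises :class:`GenerationError` if assembling the additive hazard
    clips a >= 1% fraction of (subject, age-bin) rates at zero.
    """
    rng = substream(seed, "generator")
    cov = _sample_covariates(params, params.n, rng)
    df = _sample_mediators(params, cov, rng)
    off = _hazard_offsets(params, df)

    hz = params.hazard
    edges = np.asarray(hz.age_edges, dtype=float)
    base = np.asarray(hz.baseline_rates, dtype=float)
    entry = df["age_at_survey"].to_numpy()
    event_age = np.empty(len(df))
    clipped = 0
    considered = 0
    for sex in df["sex"].unique():
        m = (df["sex"] == sex).to_numpy()
        rates = hz.sex_factor[sex] * base[None, :] + off[m, None]
        in_range = edges[1:][None, :] > entry[m, None]  # bins after entry
        clipped += int(((rates < 0) & in_range).sum())
        considered += int(in_range.sum())
        rates = np.clip(rates, 0.0, None)
        event_age[m] = sample_event_age(entry[m], rates, edges, u=rng.random(int(m.sum())))
    clip_fraction = clipped / max(considered, 1)
    if clip_fraction >= 0.01:
        raise GenerationError(
            f"{clip_fraction:.1%} of assembled hazard rates were negative and clipped; "
            "reduce the magnitude of negative offsets or raise the baseline"
        )

    censor_age = np.minimum(
        entry + (params.admin_end_year - df["survey_year"].to_numpy()), params.max_age
    )
    event = (event_age <= censor_age).astype(int)
    exit_age = np.minimum(event_age, censor_age)

    out = df.assign(
        subject_id=np.arange(len(df)),
        entry_age=entry,
        exit_age=exit_age,
        event=event,
    )
    cohort = validate_cohort(out)
    cohort.report.dropped["hazard_clip_fraction"] = clip_fraction
    return cohort


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def _component_arrays(params, cov_sex, sex, race, spec):
    """Per-draw closed-form contributions for one (sex, race) contrast.

    Returns dict of arrays over the covariate sample whose means are the
    true components (per person-year)."""
    hz = params.hazard
    X0 = spec.build(cov_sex, race_override=params.races[0])
    X1 = spec.build(cov_sex, race_override=race)
    out = {}
    direct = np.full(len(cov_sex), hz.beta_direct.get(race, 0.0))
    for law in params.laws_for(sex):
        med = law.name
        gam = np.array([hz.gamma.get(med, {}).get(lev, 0.0) for lev in law.levels])
        dlt = np.array([hz.delta.get(race, {}).get(med, {}).get(lev, 0.0) for lev in law.levels])
        P0 = law.probs(X0)
        P1 = law.probs(X1)
        out[f"exposure_{short_name(med)}"] = (P1 - P0) @ gam
        out[f"vulnerability_{short_name(med)}"] = (P1 - P0) @ dlt
        # interaction evaluated at the reference-group mediator law is
        # part of the (pure) direct effect
        direct = direct + P0 @ dlt
    out["direct"] = direct
    return out


def true_decomposition(
    params: GeneratorParams,
    mode: str = "closed_form",
    mc_size: int = 200_000,
    seed: int = 0,
) -> TrueDecomposition:
    """True effect components implied by the generator, per sex and contrast.

    The decomposition follows the natural-effects convention of the
    estimation pipeline: the *direct* effect is the pure direct effect
    (exposure effect with every mediator held at its reference-exposure
    distribution, so it includes the exposure-mediator interaction
    evaluated at that distribution); *differential exposure* for mediator
    k is the pure indirect effect through k; *differential vulnerability*
    is the mediated-interaction component. All components marginalize
    over the covariate distribution of the whole simulated sample (both
    exposure groups) and satisfy
    ``total = direct + sum_k (exposure_k + vulnerability_k)`` exactly.

    ``closed_form`` averages exact per-draw expectations over a large
    covariate sample; ``monte_carlo`` additionally draws the mediators
    and evaluates the same contrasts by simulation, attaching Monte-Carlo
    standard errors. Values are deaths per 10,000 person-years.
    """
    if mode not in ("closed_form", "monte_carlo"):
        raise DomainError(f"unknown mode {mode!r}")
    if mode == "monte_carlo" and mc_size < 10_000:
        import warnings

        warnings.warn("mc_size < 10,000 gives noisy Monte-Carlo truths", stacklevel=2)
    rng = substream(seed, f"truth-{mode}")
    spec = params.predictor_spec
    cov = _sample_covariates(params, mc_size, rng)

    components: dict = {}
    mc_se: dict = {}
    for sex in params.sex_probs:
        cov_sex = cov[cov["sex"] == sex]
        for race in params.races[1:]:
            arrays = _component_arrays(params, cov_sex, sex, race, spec)
            if mode == "monte_carlo":
                arrays = _mc_component_arrays(params, cov_sex, sex, race, spec, rng)
            comp = {k: SCALE * float(np.mean(v)) for k, v in arrays.items()}
            comp["net_indirect"] = sum(
                v for k, v in comp.items() if k.startswith(("exposure_", "vulnerability_"))
            )
            comp["total"] = comp["direct"] + comp["net_indirect"]
            components[(sex, race)] = comp
            if mode == "monte_carlo":
                se = {
                    k: SCALE * float(np.std(v, ddof=1) / np.sqrt(len(v)))
                    for k, v in arrays.items()
                }
                mc_se[(sex, race)] = se
    return TrueDecomposition(components, mc_se or None, mode=mode)


def _mc_component_arrays(params, cov_sex, sex, race, spec, rng):
    """Monte-Carlo analogue of :func:`_component_arrays`: draws mediators
    under each counterfactual exposure instead of using expectations."""
    hz = params.hazard
    X0 = spec.build(cov_sex, race_override=params.races[0])
    X1 = spec.build(cov_sex, race_override=race)
    out = {}
    direct = np.full(len(cov_sex), hz.beta_direct.get(race, 0.0))
    for law in params.laws_for(sex):
        med = law.name
        gam = np.array([hz.gamma.get(med, {}).get(lev, 0.0) for lev in law.levels])
        dlt = np.array([hz.delta.get(race, {}).get(med, {}).get(lev, 0.0) for lev in law.levels])
        draws = {}
        for tag, X in (("0", X0), ("1", X1)):
            P = law.probs(X)
            u = rng.random(len(P))
            draws[tag] = (P.cumsum(axis=1) < u[:, None]).sum(axis=1)
        out[f"exposure_{short_name(med)}"] = gam[draws["1"]] - gam[draws["0"]]
        out[f"vulnerability_{short_name(med)}"] = dlt[draws["1"]] - dlt[draws["0"]]
        direct = direct + dlt[draws["0"]]
    out["direct"] = direct
    return out
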