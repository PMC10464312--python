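"""End-to-end decomposition of exposure effects on mortality into direct,
differential-exposure and differential-vulnerability components.

Pipeline per sex stratum: fit one multinomial model per mediator ->
expand the cohort over counterfactual auxiliary exposures -> compute and
truncate the marginal-structural weights -> fit the weighted additive-
hazards natural-effect model with age as timescale -> read the
components off the coefficients:

* direct effect            = coefficient of the observed exposure R,
* differential exposure_k  = coefficient of the auxiliary exposure R*_k,
* differential vulnerability_k = coefficient of the R x R*_k interaction,
* net indirect             = sum over mediators of the last two,
* total                    = direct + net indirect (exact by construction).

Everything is reported as additional deaths per 10,000 person-years.
Confidence intervals come either from the cluster sandwich (fast,
treating weights as known) or from a subject-level nonparametric
bootstrap that reruns the entire pipeline per replicate (primary,
because the weights are estimated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._fast import StratumEngine
from ._util import round_half_away, substream
from .cohort import MAIN_RACE_LEVELS, MEDIATORS, Cohort
from .exceptions import DomainError, MedhazError, SchemaError
from .expand import ExpandedData, compute_weights, expand_cohort, truncate_weights
from .hazard import SurvivalDesign, cluster_sandwich_vcov, fit_additive_hazard
from .mediators import PredictorSpec, fit_mediator_model
from .simulate import SCALE, short_name

__all__ = [
    "DecompositionConfig",
    "DecompositionResult",
    "build_msm_design",
    "run_decomposition",
    "bootstrap_ci",
    "report_table",
    "simulation_study",
]

logger = logging.getLogger(__name__)

Z975 = 1.959963984540054


@dataclass
class DecompositionConfig:
    """Structural options of a decomposition run."""

    covariate_set: str = "full"  # "full" | "no_education"
    truncation_percentile: float = 99.5
    exposure_levels: list | None = None  # None: infer (white first) from the data
    mediators: list = field(default_factory=lambda: list(MEDIATORS))
    sexes: list | None = None  # None: every sex present
    scale: float = SCALE
    normalize_weights: bool = False  # stabilize by mean weight per replicate pattern

    def predictor_spec(self, exposure_levels) -> PredictorSpec:
        return PredictorSpec(
            race_levels=tuple(exposure_levels[1:]),
            include_education=self.covariate_set == "full",
        )


def component_names(exposure_levels, mediators=MEDIATORS) -> list:
    meds = [short_name(m) for m in mediators]
    out = ["total", "direct", "net_indirect"]
    for m in meds:
        out += [f"exposure_{m}", f"vulnerability_{m}"]
    return out


@dataclass
class DecompositionResult:
    """Point estimates, uncertainty and provenance of one decomposition.

    ``estimates[(sex, race)]`` maps component name -> deaths per 10,000
    person-years; ``ci`` holds (low, high) tuples on the same scale and
    ``se`` standard errors where available (sandwich method).
    """

    estimates: dict
    ci: dict
    se: dict
    ci_method: str
    metadata: dict

    def contrasts(self):
        return list(self.estimates)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (sex, race), comps in self.estimates.items():
            for name, est in comps.items():
                lo, hi = self.ci[(sex, race)].get(name, (np.nan, np.nan))
                rows.append(
                    {
                        "sex": sex,
                        "contrast": f"{race} vs white",
                        "component": name,
                        "estimate": est,
                        "ci_low": lo,
                        "ci_high": hi,
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_msm_design(expanded: ExpandedData, covariate_set: str = "full") -> SurvivalDesign:
    """Design matrix of the natural-effect (marginal structural) model.

    Columns: observed-exposure dummies (direct effect), auxiliary-
    exposure dummies per mediator (differential exposure), observed x
    auxiliary interaction dummies per mediator (differential
    vulnerability), then the adjustment covariates (education dummies
    unless ``covariate_set == "no_education"``, married, scaled survey
    year). Age enters only as the timescale. Rows are clustered by
    subject.
    """
    if covariate_set not in ("full", "no_education"):
        raise DomainError(f"unknown covariate_set {covariate_set!r}")
    df = expanded.data
    if "w" not in df.columns:
        raise SchemaError("expanded data has no weights; run compute_weights first")
    levels = expanded.exposure_levels
    nonref = levels[1:]
    race = df["race_ethnicity"].to_numpy()
    cols, names = [], []
    for r in nonref:
        cols.append((race == r).astype(float))
        names.append(f"race_{r}")
    for med in expanded.mediators:
        rs = df[f"rstar_{short_name(med)}"].to_numpy()
        for r in nonref:
            cols.append((rs == r).astype(float))
            names.append(f"rstar_{short_name(med)}_{r}")
    for med in expanded.mediators:
        rs = df[f"rstar_{short_name(med)}"].to_numpy()
        for r_obs in nonref:
            for r_star in nonref:
                cols.append(((race == r_obs) & (rs == r_star)).astype(float))
                names.append(f"race_{r_obs}_x_rstar_{short_name(med)}_{r_star}")
    if covariate_set == "full":
        if "education" not in df.columns:
            raise SchemaError("covariate_set 'full' requires an education column")
        edu = df["education"].to_numpy()
        cols += [(edu == "medium").astype(float), (edu == "high").astype(float)]
        names += ["edu_medium", "edu_high"]
    cols.append(df["married"].to_numpy(float))
    names.append("married")
    cols.append((df["survey_year"].to_numpy(float) - 2005.5) / 10.0)
    names.append("year_s")
    return SurvivalDesign(
        entry=df["entry_age"].to_numpy(float),
        exit=df["exit_age"].to_numpy(float),
        event=df["event"].to_numpy(int),
        Z=np.column_stack(cols),
        names=names,
        weights=df["w"].to_numpy(float),
        cluster=df["subject_id"].to_numpy(),
    )


def _component_lincombs(names, exposure_levels, mediators):
    """Linear combinations mapping fitted coefficients to components,
    one dict per non-reference exposure level."""
    p = len(names)
    idx = {nm: j for j, nm in enumerate(names)}
    out = {}
    for r in exposure_levels[1:]:
        combs = {}
        v = np.zeros(p)
        v[idx[f"race_{r}"]] = 1.0
        combs["direct"] = v
        net = np.zeros(p)
        for med in mediators:
            m = short_name(med)
            e = np.zeros(p)
            e[idx[f"rstar_{m}_{r}"]] = 1.0
            combs[f"exposure_{m}"] = e
            g = np.zeros(p)
            g[idx[f"race_{r}_x_rstar_{m}_{r}"]] = 1.0
            combs[f"vulnerability_{m}"] = g
            net += e + g
        combs["net_indirect"] = net
        combs["total"] = combs["direct"] + net
        out[r] = combs
    return out


# ---------------------------------------------------------------------------
# single-stratum pipeline
# ---------------------------------------------------------------------------

def _decompose_stratum(df: pd.DataFrame, config: DecompositionConfig, levels, warm=None):
    """Run the full pipeline on one sex stratum.

    Returns (fit, lincombs, models, expanded). ``warm`` optionally maps
    mediator name -> starting coefficients (bootstrap warm starts).
    """
    spec = config.predictor_spec(levels)
    models = {}
    for med in config.mediators:
        coef0 = None if warm is None else warm.get(med)
        models[med] = fit_mediator_model(df, med, spec, coef0=coef0)
    expanded = expand_cohort(Cohort(df), levels, config.mediators)
    expanded = compute_weights(expanded, models)
    if config.truncation_percentile < 100.0:
        expanded = truncate_weights(expanded, config.truncation_percentile)
    if config.normalize_weights:
        dat = expanded.data
        mean_w = dat.groupby("replicate_id")["w"].transform("mean")
        expanded = ExpandedData(
            dat.assign(w=dat["w"] / mean_w), expanded.exposure_levels,
            expanded.mediators, expanded.truncation,
        )
    design = build_msm_design(expanded, config.covariate_set)
    fit = fit_additive_hazard(design)
    lincombs = _component_lincombs(design.names, levels, config.mediators)
    return fit, lincombs, models, expanded, design


def _infer_levels(df: pd.DataFrame, config: DecompositionConfig):
    if config.exposure_levels is not None:
        return list(config.exposure_levels)
    present = [r for r in MAIN_RACE_LEVELS if (df["race_ethnicity"] == r).any()]
    if present[0] != "white" or len(present) < 2:
        raise DomainError("decomposition needs 'white' (reference) plus >= 1 contrast group")
    return present


def run_decomposition(cohort: Cohort, config: DecompositionConfig | None = None) -> DecompositionResult:
    """Point estimates with cluster-sandwich confidence intervals.

    The cohort is restricted to the main-analysis exposure groups,
    stratified by sex, and each stratum is pushed through the whole
    pipeline. Any stage failure is re-raised with the stage and stratum
    named.
    """
    config = config or DecompositionConfig()
    data = cohort.main_analysis().data
    levels = _infer_levels(data, config)
    sexes = config.sexes or [s for s in ("men", "women") if (data["sex"] == s).any()]
    estimates, cis, ses = {}, {}, {}
    metadata = {
        "n": {},
        "events": {},
        "person_years": {},
        "weights": {},
        "covariate_set": config.covariate_set,
        "exposure_levels": levels,
        "truncation_percentile": config.truncation_percentile,
        "marginal_total": {},
    }
    for sex in sexes:
        sdf = data[data["sex"] == sex].reset_index(drop=True)
        if not len(sdf):
            raise DomainError(f"no rows for sex stratum {sex!r}")
        try:
            fit, lincombs, models, expanded, design = _decompose_stratum(sdf, config, levels)
            V = cluster_sandwich_vcov(fit, design)
        except MedhazError as exc:
            raise type(exc)(f"[stratum {sex}] {exc}") from exc
        metadata["n"][sex] = len(sdf)
        metadata["events"][sex] = int(sdf["event"].sum())
        metadata["person_years"][sex] = float((sdf["exit_age"] - sdf["entry_age"]).sum())
        metadata["weights"][sex] = expanded.weight_diagnostics()
        metadata["marginal_total"][sex] = _marginal_total(sdf, levels, config)
        for race, combs in lincombs.items():
            est, ci, se = {}, {}, {}
            for name, v in combs.items():
                point = float(v @ fit.beta) * config.scale
                s = float(np.sqrt(v @ V @ v)) * config.scale
                est[name] = point
                se[name] = s
                ci[name] = (point - Z975 * s, point + Z975 * s)
            estimates[(sex, race)] = est
            cis[(sex, race)] = ci
            ses[(sex, race)] = se
    return DecompositionResult(estimates, cis, ses, "sandwich", metadata)


def _marginal_total(sdf: pd.DataFrame, levels, config: DecompositionConfig) -> dict:
    """Diagnostic: unweighted, unexpanded adjusted total effect of the
    exposure (race + covariates only)."""
    cols, names = [], []
    race = sdf["race_ethnicity"].to_numpy()
    for r in levels[1:]:
        cols.append((race == r).astype(float))
        names.append(f"race_{r}")
    if config.covariate_set == "full":
        edu = sdf["education"].to_numpy()
        cols += [(edu == "medium").astype(float), (edu == "high").astype(float)]
        names += ["edu_medium", "edu_high"]
    cols.append(sdf["married"].to_numpy(float))
    names.append("married")
    cols.append((sdf["survey_year"].to_numpy(float) - 2005.5) / 10.0)
    names.append("year_s")
    design = SurvivalDesign(
        entry=sdf["entry_age"].to_numpy(float),
        exit=sdf["exit_age"].to_numpy(float),
        event=sdf["event"].to_numpy(int),
        Z=np.column_stack(cols),
        names=names,
        weights=None,
        cluster=sdf["subject_id"].to_numpy(),
    )
    fit = fit_additive_hazard(design)
    return {
        r: float(fit.beta[names.index(f"race_{r}")]) * config.scale for r in levels[1:]
    }


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_ci(
    cohort: Cohort,
    config: DecompositionConfig | None = None,
    B: int = 200,
    seed: int = 0,
    max_failure_fraction: float = 0.10,
) -> DecompositionResult:
    """Subject-level nonparametric bootstrap of the whole pipeline.

    Subjects are resampled with replacement within each sex stratum and
    the entire pipeline (mediator fits, expansion, weights, truncation,
    weighted fit) is rerun per replicate; 95% CIs are percentile-based.
    Deterministic given ``seed``. Replicate failures above
    ``max_failure_fraction`` abort with the collected failure log.
    """
    if B < 50:
        raise DomainError("B must be at least 50 for percentile intervals")
    config = config or DecompositionConfig()
    data = cohort.main_analysis().data
    levels = _infer_levels(data, config)
    sexes = config.sexes or [s for s in ("men", "women") if (data["sex"] == s).any()]
    point = run_decomposition(cohort, config)
    cis = {k: dict(v) for k, v in point.ci.items()}
    meta = dict(point.metadata)
    meta["bootstrap_B"] = B
    meta["bootstrap_seed"] = seed
    comp_names = component_names(levels, config.mediators)
    for sex in sexes:
        sdf = data[data["sex"] == sex].reset_index(drop=True)
        rng = substream(seed, f"bootstrap-{sex}")
        engine = StratumEngine(sdf, config, levels)
        lincombs = _component_lincombs(engine.names, levels, config.mediators)
        draws = {race: [] for race in levels[1:]}
        failures = []
        n = len(sdf)
        for b in range(B):
            idx = rng.integers(0, n, size=n)
            try:
                beta = engine.fit(idx)
            except MedhazError as exc:
                failures.append(f"rep {b}: {exc}")
                continue
            for race, combs in lincombs.items():
                draws[race].append(
                    [float(combs[nm] @ beta) * config.scale for nm in comp_names]
                )
        if len(failures) > max_failure_fraction * B:
            raise MedhazError(
                f"[stratum {sex}] {len(failures)}/{B} bootstrap replicates failed:\n"
                + "\n".join(failures[:10])
            )
        if failures:
            logger.warning("stratum %s: %d/%d bootstrap replicates failed", sex, len(failures), B)
        for race in levels[1:]:
            arr = np.asarray(draws[race])
            lo = np.percentile(arr, 2.5, axis=0)
            hi = np.percentile(arr, 97.5, axis=0)
            cis[(sex, race)] = {nm: (float(l), float(h)) for nm, l, h in zip(comp_names, lo, hi)}
        meta.setdefault("bootstrap_failures", {})[sex] = len(failures)
    return DecompositionResult(point.estimates, cis, point.se, "bootstrap", meta)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

_ROW_LABELS = [
    ("total", "Effect of race/ethnicity (ref = White)"),
    ("direct", "'Direct' effect of race/ethnicity (ref = White)"),
    ("net_indirect", "Net indirect effect of race/ethnicity (ref = White)"),
    ("exposure_alcohol", "Alcohol use: differential exposure"),
    ("vulnerability_alcohol", "Alcohol use: differential vulnerability"),
    ("exposure_smoking", "Smoking: differential exposure"),
    ("vulnerability_smoking", "Smoking: differential vulnerability"),
    ("exposure_bmi", "BMI: differential exposure"),
    ("vulnerability_bmi", "BMI: differential vulnerability"),
    ("exposure_activity", "Physical inactivity: differential exposure"),
    ("vulnerability_activity", "Physical inactivity: differential vulnerability"),
]


def report_table(result: DecompositionResult):
    """Decomposition table in the published layout.

    Returns ``(df, text)``: a tidy DataFrame (one formatted cell per
    contrast x sex) and its aligned text rendering. Values are deaths
    per 10,000 person-years, rounded to one decimal half-away-from-zero,
    with 95% CIs in parentheses.
    """
    races = sorted({race for (_, race) in result.estimates}, key=lambda r: ["black", "hispanic", "other"].index(r) if r in ("black", "hispanic", "other") else 99)
    sexes = [s for s in ("men", "women") if any(sx == s for (sx, _) in result.estimates)]
    columns = [(race, sex) for race in races for sex in sexes if (sex, race) in result.estimates]
    table = {}
    for key, label in _ROW_LABELS:
        row = {}
        for race, sex in columns:
            est = result.estimates[(sex, race)].get(key)
            if est is None:
                continue
            lo, hi = result.ci[(sex, race)][key]
            row[f"{race} {sex}"] = (
                f"{round_half_away(est, 1):.1f} "
                f"({round_half_away(lo, 1):.1f}, {round_half_away(hi, 1):.1f})"
            )
        table[label] = row
    df = pd.DataFrame(table).T
    df.index.name = "Additional deaths per 10,000 py (95% CI)"
    text = df.to_string()
    return df, text


# ---------------------------------------------------------------------------
# simulation study
# ---------------------------------------------------------------------------

def simulation_study(
    params,
    n_reps: int,
    seed: int = 0,
    config: DecompositionConfig | None = None,
    ci_method: str = "bootstrap",
    B: int = 100,
    truth=None,
    truth_size: int = 200_000,
) -> pd.DataFrame:
    """Repeated generate -> decompose recovery experiment.

    Per component and contrast: true value, mean estimate, bias,
    empirical SE, RMSE and 95% CI coverage against the generator's
    closed-form truth. Deterministic given ``seed``.
    """
    from .simulate import generate_cohort, true_decomposition

    config = config or DecompositionConfig(exposure_levels=list(params.races))
    if truth is None:
        truth = true_decomposition(params, "closed_form", mc_size=truth_size, seed=seed)
    rng = substream(seed, "simulation-study")
    rows = {}
    for rep in range(n_reps):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        cohort = generate_cohort(params, seed=rep_seed)
        if ci_method == "bootstrap":
            res = bootstrap_ci(cohort, config, B=B, seed=rep_seed)
        else:
            res = run_decomposition(cohort, config)
        for contrast, comps in res.estimates.items():
            for name, est in comps.items():
                lo, hi = res.ci[contrast][name]
                tr = truth.for_contrast(*contrast)[name]
                rows.setdefault((contrast, name), []).append(
                    (est, lo <= tr <= hi, lo <= 0.0 <= hi)
                )
    out = []
    for ((sex, race), name), vals in rows.items():
        est = np.array([v[0] for v in vals])
        cover = np.array([v[1] for v in vals])
        cover0 = np.array([v[2] for v in vals])
        tr = truth.for_contrast(sex, race)[name]
        out.append(
            {
                "sex": sex,
                "contrast": race,
                "component": name,
                "true": tr,
                "mean_estimate": est.mean(),
                "bias": est.mean() - tr,
                "empirical_se": est.std(ddof=1) if len(est) > 1 else np.nan,
                "rmse": float(np.sqrt(np.mean((est - tr) ** 2))),
                "ci_coverage": float(cover.mean()),
                "ci_covers_zero": float(cover0.mean()),
                "n_reps": len(est),
            }
        )
    return pd.DataFrame(out)
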