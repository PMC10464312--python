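"""Person-level cohort data model and lifestyle-factor harmonization.

The cohort emulates a pooled cross-sectional health interview survey
(1997-2014) linked to a national death index: one row per adult with
race/ethnicity (the exposure), four categorized lifestyle factors (the
mediators: alcohol use, smoking, body-mass index, leisure-time physical
activity), covariates (sex, age at survey, education, marital status,
survey year) and mortality follow-up on the age timescale (entry age =
age at survey, exit age = age at death or censoring).

Harmonization follows WHO-style conventions:

* alcohol: past-year frequency x quantity converted to grams of pure
  ethanol per day at 14 g per drink, then sex-specific consumption
  categories with never/former drinker statuses;
* smoking: never / former / current-someday / current-everyday from the
  100-cigarette lifetime screen plus current status;
* BMI: weight/height^2 in WHO classes (right-open boundaries);
* physical activity: weekly moderate-equivalent minutes (1 vigorous
  minute counts as 2 moderate minutes), classed sedentary (exactly 0),
  somewhat active (<150) and active (>=150).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DomainError, InconsistencyError, InputError, SchemaError

__all__ = [
    "RACE_LEVELS",
    "MAIN_RACE_LEVELS",
    "SEX_LEVELS",
    "EDUCATION_LEVELS",
    "ALCOHOL_LEVELS",
    "SMOKING_LEVELS",
    "BMI_LEVELS",
    "ACTIVITY_LEVELS",
    "MEDIATORS",
    "MEDIATOR_LEVELS",
    "GRAMS_PER_DRINK",
    "Cohort",
    "ValidationReport",
    "alcohol_grams_per_day",
    "categorize_alcohol",
    "categorize_smoking",
    "categorize_bmi",
    "categorize_activity",
    "harmonize_raw_lifestyle",
    "validate_cohort",
    "read_cohort",
    "write_cohort",
]

# Reference level of every categorical is listed first.
RACE_LEVELS = ["white", "black", "hispanic", "other"]
MAIN_RACE_LEVELS = ["white", "black", "hispanic"]  # "other" kept for descriptives only
SEX_LEVELS = ["men", "women"]
EDUCATION_LEVELS = ["low", "medium", "high"]
ALCOHOL_LEVELS = ["cat_i", "never", "former", "cat_ii", "cat_iii"]
SMOKING_LEVELS = ["never", "former", "someday", "everyday"]
BMI_LEVELS = ["normal", "underweight", "overweight", "obese"]
ACTIVITY_LEVELS = ["active", "somewhat", "sedentary"]

MEDIATORS = ["alcohol_category", "smoking_category", "bmi_category", "activity_category"]
MEDIATOR_LEVELS = {
    "alcohol_category": ALCOHOL_LEVELS,
    "smoking_category": SMOKING_LEVELS,
    "bmi_category": BMI_LEVELS,
    "activity_category": ACTIVITY_LEVELS,
}

GRAMS_PER_DRINK = 14.0  # grams of pure ethanol per standard drink

AGE_MIN, AGE_MAX = 18.0, 85.0
YEAR_MIN, YEAR_MAX = 1997, 2014

#: canonical column set of a harmonized cohort table
COHORT_COLUMNS = [
    "subject_id",
    "race_ethnicity",
    "sex",
    "age_at_survey",
    "education",
    "married",
    "survey_year",
    "alcohol_category",
    "smoking_category",
    "bmi_category",
    "activity_category",
    "entry_age",
    "exit_age",
    "event",
]

_CATEGORICAL_LEVELS = {
    "race_ethnicity": RACE_LEVELS,
    "sex": SEX_LEVELS,
    "education": EDUCATION_LEVELS,
    **MEDIATOR_LEVELS,
}

_RAW_COLUMNS = [
    "drinking_days_per_year",
    "drinks_per_occasion",
    "lifetime_12plus",
    "past_year_any",
    "smoked_100",
    "current_smoking",
    "height_m",
    "weight_kg",
    "vigorous_min_wk",
    "moderate_min_wk",
]


# ---------------------------------------------------------------------------
# categorization rules
# ---------------------------------------------------------------------------

def _as_array(x):
    arr = np.asarray(x)
    return arr, arr.ndim == 0


def alcohol_grams_per_day(drinking_days_per_year, drinks_per_occasion):
    """Grams of pure alcohol per day from past-year frequency and quantity.

    days/year x drinks/occasion x 14 g per drink, averaged over a
    365-day year.
    """
    days, scalar = _as_array(drinking_days_per_year)
    drinks, _ = _as_array(drinks_per_occasion)
    days = days.astype(float)
    drinks = drinks.astype(float)
    if np.any(days < 0) or np.any(drinks < 0):
        raise DomainError("drinking frequency and quantity must be nonnegative")
    if np.any(days > 366):
        raise DomainError("drinking days per year cannot exceed 366")
    gpd = days * drinks * GRAMS_PER_DRINK / 365.0
    return float(gpd) if scalar else gpd


#: sex-specific grams/day cut points for consumption categories I/II/III,
#: half-open on the left: category I is (0, c1], II is (c1, c2], III is (c2, inf)
ALCOHOL_CUTS = {"men": (40.0, 60.0), "women": (20.0, 40.0)}


def categorize_alcohol(gpd, sex, lifetime_12plus, past_year_any):
    """WHO-style drinking category from grams/day and drinking history.

    Never drinkers reported no past-year drinks and fewer than 12 drinks
    in any year of their life; former drinkers reported no past-year
    drinks but at least 12 in some year. Current drinkers fall in
    sex-specific consumption categories I (reference), II, III with
    half-open (low, high] boundaries. A current drinker whose computed
    consumption rounds to exactly 0 g/day is placed in category I.
    """
    gpd_a, scalar = _as_array(gpd)
    gpd_a = gpd_a.astype(float)
    sex_a = np.broadcast_to(np.asarray(sex, dtype=object), gpd_a.shape).ravel()
    life = np.broadcast_to(np.asarray(lifetime_12plus, dtype=bool), gpd_a.shape).ravel()
    past = np.broadcast_to(np.asarray(past_year_any, dtype=bool), gpd_a.shape).ravel()
    flat = gpd_a.ravel()
    if np.any(flat < 0):
        raise DomainError("grams/day must be nonnegative")
    if np.any((flat > 0) & ~past):
        raise InconsistencyError("positive grams/day with no past-year drinking reported")
    bad_sex = ~np.isin(sex_a.astype(str), SEX_LEVELS)
    if np.any(bad_sex):
        raise DomainError(f"unknown sex level(s): {set(sex_a[bad_sex])}")

    out = np.empty(flat.shape, dtype=object)
    out[~past & ~life] = "never"
    out[~past & life] = "former"
    cur = past
    for s in SEX_LEVELS:
        c1, c2 = ALCOHOL_CUTS[s]
        m = cur & (sex_a == s)
        out[m & (flat <= c1)] = "cat_i"
        out[m & (flat > c1) & (flat <= c2)] = "cat_ii"
        out[m & (flat > c2)] = "cat_iii"
    out = out.reshape(gpd_a.shape)
    return str(out.item()) if scalar else out


def categorize_smoking(smoked_100, current_smoking):
    """Smoking status from the lifetime 100-cigarette screen and current use."""
    s100, scalar = _as_array(smoked_100)
    s100 = np.atleast_1d(s100).astype(bool)
    cur = np.broadcast_to(np.asarray(current_smoking, dtype=object), s100.shape).ravel()
    cur = cur.astype(str)
    valid = {"none", "someday", "everyday"}
    bad = ~np.isin(cur, sorted(valid))
    if np.any(bad):
        raise DomainError(f"unknown current-smoking level(s): {set(cur[bad])}")
    if np.any(~s100 & (cur != "none")):
        raise InconsistencyError(
            "current smoker reported without having smoked 100 lifetime cigarettes"
        )
    out = np.where(~s100, "never", np.where(cur == "none", "former", cur)).astype(object)
    return str(out[0]) if scalar else out


BMI_CUTS = (18.5, 25.0, 30.0)  # right-open class boundaries


def categorize_bmi(weight_kg, height_m):
    """WHO BMI class from measured weight and height.

    Classes are right-open: [0, 18.5) underweight, [18.5, 25) normal,
    [25, 30) overweight (pre-obesity), [30, inf) obese.
    """
    w, scalar = _as_array(weight_kg)
    h, _ = _as_array(height_m)
    w = w.astype(float)
    h = h.astype(float)
    if np.any(w <= 0) or np.any(h <= 0):
        raise DomainError("weight and height must be positive")
    bmi = w / h**2
    out = np.select(
        [bmi < BMI_CUTS[0], bmi < BMI_CUTS[1], bmi < BMI_CUTS[2]],
        ["underweight", "normal", "overweight"],
        default="obese",
    ).astype(object)
    return str(out.item()) if scalar else out


ACTIVITY_RECOMMENDED_MIN = 150.0  # moderate-equivalent minutes/week
VIGOROUS_EQUIVALENCE = 2.0  # 1 vigorous minute counts as 2 moderate minutes


def categorize_activity(vigorous_min_wk, moderate_min_wk):
    """Physical-activity class from weekly vigorous and moderate minutes.

    Total moderate-equivalent minutes = 2 x vigorous + moderate.
    Sedentary means exactly 0 minutes; somewhat active is (0, 150);
    active is >= 150.
    """
    v, scalar = _as_array(vigorous_min_wk)
    m, _ = _as_array(moderate_min_wk)
    v = v.astype(float)
    m = m.astype(float)
    if np.any(v < 0) or np.any(m < 0):
        raise DomainError("activity minutes must be nonnegative")
    total = VIGOROUS_EQUIVALENCE * v + m
    out = np.select(
        [total == 0, total < ACTIVITY_RECOMMENDED_MIN],
        ["sedentary", "somewhat"],
        default="active",
    ).astype(object)
    return str(out.item()) if scalar else out


def harmonize_raw_lifestyle(df: pd.DataFrame) -> pd.DataFrame:
    """Derive the four mediator categories from raw lifestyle measures.

    Expects the raw columns ``drinking_days_per_year, drinks_per_occasion,
    lifetime_12plus, past_year_any, smoked_100, current_smoking, height_m,
    weight_kg, vigorous_min_wk, moderate_min_wk`` plus ``sex``; returns a
    copy with the ``*_category`` columns appended.
    """
    missing = [c for c in _RAW_COLUMNS + ["sex"] if c not in df.columns]
    if missing:
        raise SchemaError(f"raw lifestyle columns missing: {missing}")
    out = df.copy()
    gpd = alcohol_grams_per_day(
        df["drinking_days_per_year"].to_numpy(), df["drinks_per_occasion"].to_numpy()
    )
    # frequency/quantity of non-drinkers may be coded 0 without harm
    gpd = np.where(df["past_year_any"].to_numpy(dtype=bool), gpd, 0.0)
    out["alcohol_category"] = categorize_alcohol(
        gpd,
        df["sex"].to_numpy(),
        df["lifetime_12plus"].to_numpy(dtype=bool),
        df["past_year_any"].to_numpy(dtype=bool),
    )
    out["smoking_category"] = categorize_smoking(
        df["smoked_100"].to_numpy(dtype=bool), df["current_smoking"].to_numpy()
    )
    out["bmi_category"] = categorize_bmi(
        df["weight_kg"].to_numpy(), df["height_m"].to_numpy()
    )
    out["activity_category"] = categorize_activity(
        df["vigorous_min_wk"].to_numpy(), df["moderate_min_wk"].to_numpy()
    )
    return out


# ---------------------------------------------------------------------------
# cohort container and validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Counts of records dropped per validation rule."""

    n_input: int = 0
    n_retained: int = 0
    dropped: dict = field(default_factory=dict)
    n_excluded_race_other: int = 0  # retained, but outside the main analyses

    @property
    def n_dropped(self) -> int:
        return int(sum(self.dropped.values()))


@dataclass
class Cohort:
    """Validated person-level cohort.

    ``data`` holds one row per subject with the canonical columns; the
    ``other`` race/ethnicity stratum is retained for descriptives and
    excluded from the decomposition (see :meth:`main_analysis`).
    """

    data: pd.DataFrame
    report: ValidationReport | None = None

    def __len__(self) -> int:
        return len(self.data)

    @property
    def person_years(self) -> float:
        return float((self.data["exit_age"] - self.data["entry_age"]).sum())

    @property
    def n_events(self) -> int:
        return int(self.data["event"].sum())

    def main_analysis(self) -> "Cohort":
        """Subset to the race/ethnicity groups included in the decomposition."""
        sub = self.data[self.data["race_ethnicity"].isin(MAIN_RACE_LEVELS)]
        return Cohort(sub.reset_index(drop=True), self.report)

    def stratum(self, sex: str) -> "Cohort":
        sub = self.data[self.data["sex"] == sex]
        return Cohort(sub.reset_index(drop=True), self.report)


def validate_cohort(data: pd.DataFrame | Cohort) -> Cohort:
    """Complete-case validation of a cohort table.

    Drops (and counts, per rule) records with missing values, ages
    outside [18, 85] at survey, survey years outside 1997-2014,
    non-listed categorical levels, non-binary flags, or nonpositive
    follow-up (exit age <= entry age). Idempotent: validating the
    retained subset again changes nothing.
    """
    df = data.data if isinstance(data, Cohort) else data
    df = df.copy()
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"cohort table missing mandatory columns: {missing_cols}")
    df = df[COHORT_COLUMNS]
    report = ValidationReport(n_input=len(df))

    def drop(mask: pd.Series, reason: str):
        nonlocal df
        n = int(mask.sum())
        if n:
            report.dropped[reason] = report.dropped.get(reason, 0) + n
            df = df[~mask]

    drop(df.isna().any(axis=1), "missing_values")
    for col in ("age_at_survey", "entry_age", "exit_age"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["survey_year"] = pd.to_numeric(df["survey_year"], errors="coerce")
    drop(df[["age_at_survey", "entry_age", "exit_age", "survey_year"]].isna().any(axis=1),
         "non_numeric")
    drop((df["age_at_survey"] < AGE_MIN) | (df["age_at_survey"] > AGE_MAX), "age_out_of_range")
    drop((df["survey_year"] < YEAR_MIN) | (df["survey_year"] > YEAR_MAX), "year_out_of_range")
    for col, levels in _CATEGORICAL_LEVELS.items():
        drop(~df[col].astype(str).isin(levels), f"invalid_level_{col}")
    drop(~df["married"].isin([0, 1, True, False]), "invalid_married")
    drop(~df["event"].isin([0, 1, True, False]), "invalid_event")
    drop(df["exit_age"] <= df["entry_age"], "nonpositive_followup")

    df = df.assign(
        married=df["married"].astype(int),
        event=df["event"].astype(int),
        survey_year=df["survey_year"].astype(int),
    ).reset_index(drop=True)
    report.n_retained = len(df)
    report.n_excluded_race_other = int((df["race_ethnicity"] == "other").sum())
    return Cohort(df, report)


def read_cohort(path, schema: dict | None = None) -> Cohort:
    """Read and validate a cohort CSV.

    ``schema`` maps canonical field names to file column names for any
    columns whose header differs from the canonical one. If the file
    carries raw lifestyle measures instead of pre-categorized mediators,
    the categories are derived via :func:`harmonize_raw_lifestyle`.
    ``entry_age`` defaults to ``age_at_survey``; ``exit_age`` may instead
    be given as ``follow_up_years`` (added to entry age).
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"empty cohort file: {path}") from exc
    if len(df) == 0:
        raise InputError(f"cohort file has a header but no rows: {path}")
    if schema:
        rename = {file_col: canon for canon, file_col in schema.items()}
        missing = [c for c in rename if c not in df.columns]
        if missing:
            raise SchemaError(f"schema refers to absent file columns: {missing}")
        df = df.rename(columns=rename)
    if "entry_age" not in df.columns and "age_at_survey" in df.columns:
        df["entry_age"] = df["age_at_survey"]
    if "exit_age" not in df.columns and "follow_up_years" in df.columns:
        df["exit_age"] = df["entry_age"] + df["follow_up_years"]
    if not all(m in df.columns for m in MEDIATORS):
        if all(c in df.columns for c in _RAW_COLUMNS):
            df = harmonize_raw_lifestyle(df)
        else:
            missing = [m for m in MEDIATORS if m not in df.columns]
            raise SchemaError(
                f"mediator columns missing and raw lifestyle columns absent: {missing}"
            )
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file missing mandatory columns: {missing}")
    return validate_cohort(df)


def write_cohort(cohort: Cohort, path) -> None:
    """Write the canonical cohort columns as UTF-8 CSV with header."""
    cohort.data[COHORT_COLUMNS].to_csv(path, index=False)
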