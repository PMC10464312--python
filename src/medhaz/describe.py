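"""Descriptive outputs: prevalence tables, person-years, and
left-truncated survival on the age timescale.

Survival uses the product-limit (Kaplan-Meier) estimator with delayed
entry: a subject enters the risk set only at their age at survey, so the
curves describe survival as a function of age, not of follow-up time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .cohort import Cohort, MEDIATORS

__all__ = [
    "SurvivalCurve",
    "km_left_truncated",
    "median_survival_age",
    "prevalence_table",
    "plot_survival",
]


@dataclass
class SurvivalCurve:
    """One group's product-limit survival curve on the age timescale."""

    label: str
    ages: np.ndarray
    survival: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    at_risk: np.ndarray
    n: int
    n_events: int
    flagged_delayed_start: bool = False

    def __call__(self, age):
        age = np.asarray(age, dtype=float)
        idx = np.searchsorted(self.ages, age, side="right") - 1
        out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, len(self.survival) - 1)])
        return float(out) if out.ndim == 0 else out


def km_left_truncated(cohort: Cohort, group_by=("sex", "race_ethnicity")) -> dict:
    """Kaplan-Meier curves with delayed entry, one per group.

    The risk set at age a is {i : entry_i < a <= exit_i}. Groups without
    events raise; a group whose curve cannot start at the minimum entry
    age (empty early risk set) is flagged.
    """
    df = cohort.data
    group_by = [group_by] if isinstance(group_by, str) else list(group_by)
    curves = {}
    for key, g in df.groupby(group_by, observed=True):
        key = key if len(group_by) > 1 else (key,)
        kmf = KaplanMeierFitter()
        kmf.fit(
            durations=g["exit_age"],
            event_observed=g["event"],
            entry=g["entry_age"],
            label=" ".join(map(str, key)),
        )
        sf = kmf.survival_function_
        ci = kmf.confidence_interval_survival_function_
        ages = sf.index.to_numpy(dtype=float)
        surv = sf.iloc[:, 0].to_numpy()
        label = " ".join(map(str, key))
        # risk-set sizes at each knot
        entry = g["entry_age"].to_numpy()
        exit_ = g["exit_age"].to_numpy()
        at_risk = np.array([(np.sum((entry < a) & (exit_ >= a))) for a in ages])
        flagged = bool(at_risk[1] == 0) if len(at_risk) > 1 else False
        curves[key] = SurvivalCurve(
            label=label,
            ages=ages,
            survival=surv,
            ci_low=ci.iloc[:, 0].to_numpy(),
            ci_high=ci.iloc[:, 1].to_numpy(),
            at_risk=at_risk,
            n=len(g),
            n_events=int(g["event"].sum()),
            flagged_delayed_start=flagged,
        )
    return curves


def median_survival_age(curve: SurvivalCurve):
    """Median survival age with a log-log (Greenwood) 95% CI.

    The median is the first age where S(age) <= 0.5. The CI collects the
    ages where the pointwise log-log band still contains 0.5: its lower
    bound is where the lower survival limit first drops to 0.5 (it
    crosses earliest), the upper bound where the upper limit does.
    Returns (median, (lo, hi)); values are ``inf`` ("not reached") where
    the corresponding curve never crosses 0.5.
    """

    def first_crossing(values):
        below = np.nonzero(values <= 0.5)[0]
        return float(curve.ages[below[0]]) if len(below) else float("inf")

    return first_crossing(curve.survival), (
        first_crossing(curve.ci_low),
        first_crossing(curve.ci_high),
    )


def prevalence_table(cohort: Cohort, strata=("sex", "race_ethnicity")) -> pd.DataFrame:
    """Unweighted descriptives per stratum, mirroring a participants table.

    Per stratum: n, mean age (SD), mean follow-up (SD), person-years,
    deaths (n, crude %), percentage in each level of every mediator,
    education and marital status. Empty strata yield zero rows (flagged
    with n = 0).
    """
    df = cohort.data
    strata = [strata] if isinstance(strata, str) else list(strata)
    rows = []
    for key, g in df.groupby(strata, observed=True):
        key = key if len(strata) > 1 else (key,)
        rec = dict(zip(strata, key))
        rec["n"] = len(g)
        fu = g["exit_age"] - g["entry_age"]
        rec["age_mean"] = g["age_at_survey"].mean()
        rec["age_sd"] = g["age_at_survey"].std()
        rec["followup_mean"] = fu.mean()
        rec["followup_sd"] = fu.std()
        rec["person_years"] = fu.sum()
        rec["deaths"] = int(g["event"].sum())
        rec["deaths_pct"] = 100.0 * g["event"].mean()
        for var in MEDIATORS + ["education"]:
            counts = g[var].value_counts(normalize=True)
            for level, frac in counts.items():
                rec[f"{var}:{level}_pct"] = 100.0 * frac
        rec["married_pct"] = 100.0 * g["married"].mean()
        rows.append(rec)
    return pd.DataFrame(rows).fillna(0.0)


def plot_survival(curves: dict, path=None, title="Survival by group (age timescale)"):
    """Step plot of the curves; written to ``path`` if given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for curve in curves.values():
        ax.step(curve.ages, curve.survival, where="post", label=curve.label)
    ax.set_xlabel("Age (years)")
    ax.set_ylabel("Survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
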