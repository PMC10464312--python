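"""Counterfactual data expansion and marginal-structural weights.

Each subject is replicated once per joint assignment of *auxiliary
exposures* R*_1..R*_K (one per mediator, each ranging over all exposure
levels). The replicate whose auxiliary exposures all equal the observed
exposure is the identity replicate and carries weight exactly 1; every
other replicate is weighted by the likelihood ratio

    W_i(r*) = prod_k  P_k(m_ki | R = r*_k, C_i) / P_k(m_ki | R = r_i, C_i)

so that, in the weighted data, mediator k behaves as if it had been
drawn under exposure r*_k. A weighted additive-hazards regression of the
survival outcome on (R, R*_1..R*_K, R x R*_k, covariates) then reads off
the natural-effect decomposition directly from its coefficients.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import MEDIATORS
from .exceptions import DomainError, PositivityError, SchemaError

__all__ = [
    "ExpandedData",
    "expand_cohort",
    "compute_weights",
    "truncate_weights",
    "effective_sample_size",
]

RSTAR_COLUMNS = [f"rstar_{m.removesuffix('_category')}" for m in MEDIATORS]


@dataclass
class ExpandedData:
    """Counterfactual replicates of a (sex-stratified) cohort.

    ``data`` holds one row per subject x auxiliary-exposure assignment,
    with the observed exposure in ``race_ethnicity``, auxiliary
    exposures in ``rstar_alcohol`` .. ``rstar_activity``, survival
    fields copied unchanged, and (after :func:`compute_weights`) the
    weight column ``w``.
    """

    data: pd.DataFrame
    exposure_levels: list
    mediators: list = field(default_factory=lambda: list(MEDIATORS))
    truncation: dict | None = None  # set by truncate_weights

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    @property
    def replicates_per_subject(self) -> int:
        return len(self.exposure_levels) ** len(self.mediators)

    def weight_diagnostics(self) -> dict:
        w = self.data["w"].to_numpy()
        return {
            "max_weight": float(w.max()),
            "mean_weight": float(w.mean()),
            "effective_sample_size": effective_sample_size(w),
            "truncation": self.truncation,
        }


def expand_cohort(cohort, exposure_levels, mediators=None) -> ExpandedData:
    """Cartesian-product expansion over auxiliary exposure assignments.

    With L exposure levels and K mediators each subject yields L^K
    replicates; survival fields are copied unchanged and weights are not
    yet attached.
    """
    df = cohort.data if hasattr(cohort, "data") else cohort
    mediators = list(mediators or MEDIATORS)
    missing = [m for m in mediators if m not in df.columns]
    if missing:
        raise SchemaError(f"mediator columns absent from cohort: {missing}")
    levels = list(exposure_levels)
    obs_races = set(df["race_ethnicity"])
    if not obs_races <= set(levels):
        raise SchemaError(
            f"cohort contains exposure levels outside the expansion set: "
            f"{sorted(obs_races - set(levels))}"
        )
    K = len(mediators)
    patterns = np.array(list(itertools.product(range(len(levels)), repeat=K)), dtype=int)
    R = len(patterns)  # L^K
    n = len(df)

    expanded = df.loc[df.index.repeat(R)].reset_index(drop=True)
    expanded["replicate_id"] = np.tile(np.arange(R), n)
    level_arr = np.asarray(levels, dtype=object)
    for k, med in enumerate(mediators):
        expanded[f"rstar_{med.removesuffix('_category')}"] = np.tile(
            level_arr[patterns[:, k]], n
        )
    return ExpandedData(expanded, levels, mediators)


def compute_weights(expanded: ExpandedData, models, min_prob: float = 1e-12) -> ExpandedData:
    """Attach the marginal-structural weight to every replicate.

    ``models`` maps mediator column name -> fitted
    :class:`~medhaz.mediators.MediatorModel` (an iterable in mediator
    order is also accepted). Weights are unstabilized likelihood ratios;
    the identity replicate gets weight exactly 1 by construction.
    Denominator probabilities below ``min_prob`` raise
    :class:`PositivityError` naming the subject and mediator.
    """
    if not isinstance(models, dict):
        models = {m.mediator_name: m for m in models}
    df = expanded.data
    mediators = expanded.mediators
    levels = expanded.exposure_levels
    R = expanded.replicates_per_subject
    n = len(df) // R
    base = df.iloc[::R]  # one row per subject, any replicate carries C_i
    obs_race = base["race_ethnicity"].to_numpy()

    # ratio[k][l] = P_k(m_i | R = level_l, C_i) / P_k(m_i | r_i, C_i), per subject
    ratios = {}
    for med in mediators:
        model = models[med]
        lut = {lev: i for i, lev in enumerate(model.levels)}
        m_idx = base[med].astype(str).map(lut).to_numpy()
        p_by_level = {}
        for lev in levels:
            P = model.predict_probs(base, race_override=lev)
            p_by_level[lev] = P[np.arange(n), m_idx]
        denom = np.empty(n)
        for lev in levels:
            denom[obs_race == lev] = p_by_level[lev][obs_race == lev]
        low = denom < min_prob
        if low.any():
            sid = base["subject_id"].to_numpy()[low][0]
            raise PositivityError(
                f"denominator probability below {min_prob:g} for subject {sid!r}, "
                f"mediator {med!r}"
            )
        med_ratios = {}
        for lev in levels:
            r = p_by_level[lev] / denom
            r[obs_race == lev] = 1.0  # exact identity where r* equals the observed exposure
            med_ratios[lev] = r
        ratios[med] = med_ratios

    w = np.ones(len(df))
    subj = np.repeat(np.arange(n), R)
    for med in mediators:
        rstar = df[f"rstar_{med.removesuffix('_category')}"].to_numpy()
        col = np.empty(len(df))
        for lev in levels:
            m = rstar == lev
            col[m] = ratios[med][lev][subj[m]]
        w *= col
    out = df.assign(w=w)
    return ExpandedData(out, expanded.exposure_levels, expanded.mediators, expanded.truncation)


def truncate_weights(expanded: ExpandedData, upper_percentile: float = 99.5) -> ExpandedData:
    """Cap weights at the given percentile of the weight distribution.

    Percentile 100 is the identity. The number of capped replicates and
    the weight mass removed are recorded in ``truncation``.
    """
    if not (50.0 < upper_percentile <= 100.0):
        raise DomainError("truncation percentile must lie in (50, 100]")
    df = expanded.data
    if "w" not in df.columns:
        raise SchemaError("weights not yet computed; call compute_weights first")
    w = df["w"].to_numpy()
    cap = float(np.percentile(w, upper_percentile))
    clipped = w > cap
    info = {
        "percentile": upper_percentile,
        "cap": cap,
        "n_clipped": int(clipped.sum()),
        "mass_removed": float((w[clipped] - cap).sum()),
    }
    out = df.assign(w=np.minimum(w, cap))
    return ExpandedData(out, expanded.exposure_levels, expanded.mediators, info)


def effective_sample_size(w: np.ndarray) -> float:
    """Kish effective sample size (sum w)^2 / sum w^2."""
    w = np.asarray(w, dtype=float)
    return float(w.sum() ** 2 / (w**2).sum())
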