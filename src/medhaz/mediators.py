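"""Per-mediator baseline-category multinomial logistic models.

These models, P(M_k = m | race, covariates), supply the numerator and
denominator probabilities of the marginal-structural weights. Fitting is
Newton-Raphson on the full multinomial log-likelihood with optional warm
starts, which keeps the subject-level bootstrap (thousands of refits)
cheap. A tiny ridge fallback is applied only on (quasi-)separation and
is logged prominently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConvergenceError, DegenerateDataError, DomainError

__all__ = [
    "PredictorSpec",
    "MediatorModel",
    "softmax_probs",
    "fit_mediator_model",
    "predict_category_probs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PredictorSpec:
    """Design of the mediator-model linear predictor.

    Columns: intercept, one dummy per non-reference exposure level,
    centered/scaled age ((age - 50)/10), optionally two education
    dummies, the married indicator, and centered/scaled survey year
    ((year - 2005.5)/10). Age and year enter linearly; centering keeps
    the Newton iterations well conditioned without changing the model.
    """

    race_levels: tuple  # non-reference exposure levels, in order
    include_education: bool = True
    age_center: float = 50.0
    age_scale: float = 10.0
    year_center: float = 2005.5
    year_scale: float = 10.0

    def names(self) -> list:
        cols = ["intercept"] + [f"race_{r}" for r in self.race_levels] + ["age_s"]
        if self.include_education:
            cols += ["edu_medium", "edu_high"]
        cols += ["married", "year_s"]
        return cols

    def build(self, df: pd.DataFrame, race_override=None) -> np.ndarray:
        """Design matrix for ``df``; ``race_override`` (a single level or
        an array) replaces the observed exposure column, which is how
        counterfactual probabilities are evaluated."""
        n = len(df)
        race = (
            np.broadcast_to(np.asarray(race_override, dtype=object), (n,))
            if race_override is not None
            else df["race_ethnicity"].to_numpy()
        )
        cols = [np.ones(n)]
        for r in self.race_levels:
            cols.append((race == r).astype(float))
        cols.append((df["age_at_survey"].to_numpy(float) - self.age_center) / self.age_scale)
        if self.include_education:
            edu = df["education"].to_numpy()
            cols.append((edu == "medium").astype(float))
            cols.append((edu == "high").astype(float))
        cols.append(df["married"].to_numpy(float))
        cols.append((df["survey_year"].to_numpy(float) - self.year_center) / self.year_scale)
        return np.column_stack(cols)


def softmax_probs(X: np.ndarray, coef: np.ndarray) -> np.ndarray:
    """Baseline-category softmax: returns (n, L) probabilities with the
    reference level first; ``coef`` is (L-1, p)."""
    return softmax_probs_eta(X @ coef.T)


def softmax_probs_eta(eta: np.ndarray) -> np.ndarray:
    """Softmax over [0, eta]: the reference category has linear predictor 0."""
    n, Lm1 = eta.shape
    m = np.maximum(eta.max(axis=1, keepdims=True), 0.0)
    P = np.empty((n, Lm1 + 1))
    np.exp(-m[:, 0], out=P[:, 0])
    np.exp(eta - m, out=P[:, 1:])
    P /= P.sum(axis=1, keepdims=True)
    return P


@dataclass
class MediatorModel:
    """Fitted baseline-category logit for one mediator."""

    mediator_name: str
    levels: list  # reference level first
    coef: np.ndarray  # (n_levels-1, n_predictors)
    spec: PredictorSpec
    converged: bool
    log_likelihood: float
    vcov: np.ndarray | None = None  # ((L-1)*p, (L-1)*p), row-major over (level, predictor)
    ridge_used: bool = False
    n_obs: int = 0

    def se(self) -> np.ndarray:
        """Standard errors shaped like ``coef``."""
        if self.vcov is None:
            raise ValueError("no variance available")
        return np.sqrt(np.diag(self.vcov)).reshape(self.coef.shape)

    def predict_probs(self, df: pd.DataFrame, race_override=None) -> np.ndarray:
        X = self.spec.build(df, race_override=race_override)
        return softmax_probs(X, self.coef)


def _multinomial_hessian(X, Pn, ridge=0.0):
    """Observed information of the multinomial log-likelihood.

    Block (j, k) is sum_i P_ij (delta_jk - P_ik) x_i x_i'; assembled per
    block as X' diag(w_jk) X, which keeps everything in BLAS."""
    n, p = X.shape
    Lm1 = Pn.shape[1]
    H = np.empty((Lm1, p, Lm1, p))
    for j in range(Lm1):
        for k in range(j, Lm1):
            w = Pn[:, j] * ((1.0 if j == k else 0.0) - Pn[:, k])
            blk = X.T @ (w[:, None] * X)
            H[j, :, k, :] = blk
            if k != j:
                H[k, :, j, :] = blk
    H = H.reshape(Lm1 * p, Lm1 * p)
    if ridge:
        H = H + ridge * np.eye(Lm1 * p)
    return H


def _newton_multinomial(X, y_idx, L, coef0=None, tol=1e-8, max_iter=60, ridge=0.0):
    """Maximize the multinomial log-likelihood; returns (coef, loglik,
    converged, hessian_inv). ``y_idx`` codes categories 0..L-1 with 0 the
    reference."""
    n, p = X.shape
    B = np.zeros((L - 1, p)) if coef0 is None else coef0.copy()
    Y = np.zeros((n, L - 1))
    for j in range(1, L):
        Y[:, j - 1] = y_idx == j
    def penalized_ll(Bm):
        P = softmax_probs(X, Bm)
        with np.errstate(divide="ignore"):
            ll = float(np.log(P[np.arange(n), y_idx]).sum())
        return ll - ridge * float((Bm * Bm).sum()) / 2.0, P

    converged = False
    H = None
    ll, P = penalized_ll(B)
    for _ in range(max_iter):
        Pn = P[:, 1:]  # non-reference probs
        G = (Y - Pn).T @ X - ridge * B  # (L-1, p)
        if np.max(np.abs(G)) < tol:
            converged = True
            break
        H = _multinomial_hessian(X, Pn, ridge)
        try:
            step = np.linalg.solve(H, G.ravel()).reshape(L - 1, p)
        except np.linalg.LinAlgError:
            return B, ll, False, None
        # step-halving keeps the likelihood monotone
        t = 1.0
        for _ in range(30):
            ll_new, P_new = penalized_ll(B + t * step)
            if ll_new >= ll - 1e-12:
                break
            t /= 2.0
        B = B + t * step
        ll, P = ll_new, P_new
    # observed information at the final coefficients, for the vcov
    H = _multinomial_hessian(X, P[:, 1:], ridge)
    try:
        Hinv = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        Hinv = None
    return B, ll, converged, Hinv


def fit_mediator_model(
    cohort,
    mediator_name: str,
    spec: PredictorSpec,
    levels=None,
    coef0: np.ndarray | None = None,
    tol: float = 1e-8,
) -> MediatorModel:
    """Fit the baseline-category logit of one mediator.

    The cohort is expected to be sex-stratified upstream. Every mediator
    level must be observed within every exposure group (otherwise the
    counterfactual weights would be driven by pure extrapolation); the
    offending empty cell is named in the error.
    """
    df = cohort.data if hasattr(cohort, "data") else cohort
    if mediator_name not in df.columns:
        raise DomainError(f"no such mediator column: {mediator_name}")
    obs = df[mediator_name].astype(str)
    if levels is None:
        from .cohort import MEDIATOR_LEVELS

        levels = [l for l in MEDIATOR_LEVELS[mediator_name] if l in set(obs)]
    if len(levels) < 2:
        raise DegenerateDataError(
            f"mediator {mediator_name!r} has a single observed level: {levels}"
        )
    races = [r for r in ["white", *spec.race_levels] if (df["race_ethnicity"] == r).any()]
    cell = pd.crosstab(df["race_ethnicity"], obs)
    for r in races:
        for lev in levels:
            if r not in cell.index or lev not in cell.columns or cell.loc[r, lev] == 0:
                raise DegenerateDataError(
                    f"mediator {mediator_name!r} level {lev!r} unobserved in exposure "
                    f"group {r!r}"
                )
    X = spec.build(df)
    lut = {lev: i for i, lev in enumerate(levels)}
    y_idx = obs.map(lut).to_numpy()
    L = len(levels)
    coef, ll, converged, Hinv = _newton_multinomial(X, y_idx, L, coef0=coef0, tol=tol)
    ridge_used = False
    if not converged or not np.all(np.isfinite(coef)) or np.max(np.abs(coef)) > 30:
        # (quasi-)separation: refit with a tiny ridge
        logger.warning(
            "mediator model %r: separation suspected, refitting with ridge 1e-6",
            mediator_name,
        )
        coef, ll, converged, Hinv = _newton_multinomial(
            X, y_idx, L, coef0=None, tol=tol, ridge=1e-6
        )
        ridge_used = True
        if not converged:
            raise ConvergenceError(
                f"mediator model {mediator_name!r} did not converge even with ridge"
            )
    return MediatorModel(
        mediator_name=mediator_name,
        levels=list(levels),
        coef=coef,
        spec=spec,
        converged=converged,
        log_likelihood=ll,
        vcov=Hinv,
        ridge_used=ridge_used,
        n_obs=len(df),
    )


def predict_category_probs(model: MediatorModel, covariates: pd.DataFrame, exposure_value):
    """Predicted category probabilities at a fixed counterfactual exposure.

    Returns an (n, L) array ordered like ``model.levels``; rows are
    strictly positive and sum to 1.
    """
    valid = {"white", *model.spec.race_levels}
    vals = np.unique(np.asarray(exposure_value, dtype=object))
    unknown = [v for v in vals if v not in valid]
    if unknown:
        raise DomainError(f"unknown exposure level(s): {unknown}")
    return model.predict_probs(covariates, race_override=exposure_value)
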