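"""Weighted additive-hazards regression with delayed entry on the age
timescale.

The model is the semiparametric additive hazards model with constant
(time-invariant) covariate effects and an unspecified baseline:

    lambda_i(t) = lambda_0(t) + Z_i' beta,

estimated from possibly weighted, possibly clustered survival data with
left truncation (each subject is at risk on the half-open age interval
(entry_i, exit_i]). The estimator solves the closed-form estimating
equation

    [ sum_i w_i int Y_i(t) (Z_i - Zbar_w(t)) (Z_i - Zbar_w(t))' dt ] beta
        = sum_i w_i int (Z_i - Zbar_w(t)) dN_i(t),

where Zbar_w(t) is the weighted mean of Z over the risk set at t. All
integrals are evaluated exactly by decomposing time into the intervals
between consecutive distinct entry/exit ages, so the fit is deterministic
and free of discretization error. beta is in events per person-year.

Ties: exact ties among event ages are aggregated; a subject whose exit
(event or censoring) coincides with an event age is in the risk set at
that age ("events first"), a subject entering exactly at an event age is
not. No jitter is applied.

``brute_force_estimating_equation`` re-evaluates the same equation by
explicit enumeration on tiny datasets and exists solely as an
independent oracle for the fast implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DomainError, RankError

__all__ = [
    "SurvivalDesign",
    "AdditiveHazardFit",
    "BaselineCumulativeHazard",
    "fit_additive_hazard",
    "brute_force_estimating_equation",
    "estimate_baseline",
    "cluster_sandwich_vcov",
]


@dataclass
class SurvivalDesign:
    """Design for one additive-hazards fit.

    ``Z`` is (n_rows, p); ``cluster`` identifies the independent sampling
    unit (the subject, when rows are counterfactual replicates).
    """

    entry: np.ndarray
    exit: np.ndarray
    event: np.ndarray
    Z: np.ndarray
    names: list
    weights: np.ndarray | None = None
    cluster: np.ndarray | None = None

    def __post_init__(self):
        self.entry = np.asarray(self.entry, dtype=float)
        self.exit = np.asarray(self.exit, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        if self.Z.shape[0] != self.entry.shape[0]:
            self.Z = self.Z.T
        if self.weights is None:
            self.weights = np.ones_like(self.entry)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.exit <= self.entry):
            raise DomainError("every row needs exit > entry")
        if np.any(self.weights < 0):
            raise DomainError("weights must be nonnegative")

    @property
    def n_rows(self) -> int:
        return len(self.entry)


@dataclass
class BaselineCumulativeHazard:
    """Baseline cumulative hazard as a right-continuous step/drift function.

    ``ages`` are the evaluation knots (interval breakpoints), ``values``
    the cumulative hazard just after each knot (jumps at event ages plus
    the -Zbar' beta drift between them).
    """

    ages: np.ndarray
    values: np.ndarray

    def __call__(self, age):
        age = np.asarray(age, dtype=float)
        idx = np.searchsorted(self.ages, age, side="right") - 1
        out = np.where(idx < 0, 0.0, self.values[np.clip(idx, 0, len(self.values) - 1)])
        return float(out) if out.ndim == 0 else out


@dataclass
class AdditiveHazardFit:
    """Constant hazard differences (per person-year) with covariance."""

    beta: np.ndarray
    names: list
    A: np.ndarray  # integrated information matrix (LHS of the equation)
    b: np.ndarray  # RHS
    vcov_naive: np.ndarray  # A^-1 [sum (Z-Zbar)^{x2} w^2 dN] A^-1
    n_events: float
    person_years: float
    vcov_cluster: np.ndarray | None = None

    def summary(self, scale: float = 1.0, vcov: str = "naive") -> pd.DataFrame:
        V = self.vcov_cluster if (vcov == "cluster" and self.vcov_cluster is not None) else self.vcov_naive
        se = np.sqrt(np.diag(V))
        return pd.DataFrame(
            {
                "term": self.names,
                "estimate": self.beta * scale,
                "se": se * scale,
                "ci_low": (self.beta - 1.959963984540054 * se) * scale,
                "ci_high": (self.beta + 1.959963984540054 * se) * scale,
            }
        )


def _risk_structure(design: SurvivalDesign):
    """Interval decomposition of the risk process.

    Returns (u, entry_idx, exit_idx, S0, S1, dt):
    ``u`` the sorted distinct entry/exit ages (len K+1); row i is at risk
    on intervals entry_idx[i] .. exit_idx[i]-1, where interval k is
    (u[k], u[k+1]]; S0 (K,) and S1 (K, p) are the weighted risk-set size
    and covariate sum per interval; dt the interval lengths.
    """
    u = np.unique(np.concatenate([design.entry, design.exit]))
    K = len(u) - 1
    entry_idx = np.searchsorted(u, design.entry)
    exit_idx = np.searchsorted(u, design.exit)
    w = design.weights
    p = design.Z.shape[1]
    d0 = np.bincount(entry_idx, weights=w, minlength=K + 1) - np.bincount(
        exit_idx, weights=w, minlength=K + 1
    )
    S0 = np.cumsum(d0)[:K]
    S1 = np.empty((K, p))
    for j in range(p):
        wz = w * design.Z[:, j]
        d1 = np.bincount(entry_idx, weights=wz, minlength=K + 1) - np.bincount(
            exit_idx, weights=wz, minlength=K + 1
        )
        S1[:, j] = np.cumsum(d1)[:K]
    dt = np.diff(u)
    return u, entry_idx, exit_idx, S0, S1, dt


def _assemble_equation(design: SurvivalDesign):
    u, entry_idx, exit_idx, S0, S1, dt = _risk_structure(design)
    w = design.weights
    Z = design.Z
    dur = design.exit - design.entry

    # A = int S2 dt - int S1 S1'/S0 dt ; the first term collapses to a matmul
    A = (Z * (w * dur)[:, None]).T @ Z
    pos = S0 > 0
    M = S1[pos] * np.sqrt(dt[pos] / S0[pos])[:, None]
    A -= M.T @ M

    # b = sum_events w (Z - Zbar(exit))
    ev = design.event.astype(bool)
    iv = exit_idx[ev] - 1  # the interval ending at the event age
    Zbar_ev = S1[iv] / S0[iv][:, None]
    wev = w[ev]
    b = (Z[ev] * wev[:, None]).sum(axis=0) - (Zbar_ev * wev[:, None]).sum(axis=0)

    # middle matrix of the naive sandwich: sum w^2 (Z-Zbar)^{x2} dN
    resid = Z[ev] - Zbar_ev
    Bmat = (resid * (wev**2)[:, None]).T @ resid
    return A, b, Bmat, (u, entry_idx, exit_idx, S0, S1, dt)


def _solve_or_raise(A: np.ndarray, b: np.ndarray, names):
    # A is PSD by construction: a vanishing diagonal entry means the
    # column has no variation on the risk sets at all
    d = np.diag(A)
    dead = d <= max(d.max(), 0.0) * 1e-12
    if dead.any():
        cols = [names[j] for j in np.nonzero(dead)[0]]
        raise RankError(f"integrated design matrix is singular; degenerate columns: {cols}")
    scale = np.sqrt(d)
    cond = np.linalg.cond(A / np.outer(scale, scale))
    if not np.isfinite(cond) or cond > 1e10:
        # name the columns involved in the (near-)null space
        _, s, VT = np.linalg.svd(A / np.outer(scale, scale))
        null = VT[s < s.max() * 1e-10]
        cols = sorted({names[j] for v in null for j in np.nonzero(np.abs(v) > 1e-6)[0]})
        raise RankError(f"integrated design matrix is singular; collinear columns: {cols or names}")
    return np.linalg.solve(A, b)


def fit_additive_hazard(design: SurvivalDesign) -> AdditiveHazardFit:
    """Fit the weighted constant-coefficient additive hazards model."""
    if design.event.sum() < 1:
        raise DomainError("no events in the design; the model is not estimable")
    A, b, Bmat, _ = _assemble_equation(design)
    beta = _solve_or_raise(A, b, design.names)
    Ainv = np.linalg.inv(A)
    vcov = Ainv @ Bmat @ Ainv
    return AdditiveHazardFit(
        beta=beta,
        names=list(design.names),
        A=A,
        b=b,
        vcov_naive=vcov,
        n_events=float((design.weights * design.event).sum()),
        person_years=float((design.weights * (design.exit - design.entry)).sum()),
    )


def brute_force_estimating_equation(design: SurvivalDesign) -> np.ndarray:
    """Solve the estimating equation by explicit enumeration (test oracle).

    Loops over every inter-breakpoint interval and every event age,
    recomputing risk sets from scratch. Limited to 50 rows; exists only
    to validate :func:`fit_additive_hazard` on small instances.
    """
    if design.n_rows > 50:
        raise DomainError("brute-force oracle is limited to 50 rows")
    entry, exit_, event = design.entry, design.exit, design.event
    Z, w = design.Z, design.weights
    p = Z.shape[1]
    times = np.unique(np.concatenate([entry, exit_]))
    A = np.zeros((p, p))
    for t0, t1 in zip(times[:-1], times[1:]):
        at_risk = (entry <= t0) & (exit_ >= t1)
        if not at_risk.any() or w[at_risk].sum() == 0:
            continue
        zb = np.average(Z[at_risk], axis=0, weights=w[at_risk])
        for i in np.nonzero(at_risk)[0]:
            d = Z[i] - zb
            A += w[i] * np.outer(d, d) * (t1 - t0)
    b = np.zeros(p)
    for i in np.nonzero(event)[0]:
        t = exit_[i]
        at_risk = (entry < t) & (exit_ >= t)
        zb = np.average(Z[at_risk], axis=0, weights=w[at_risk])
        b += w[i] * (Z[i] - zb)
    return _solve_or_raise(A, b, design.names)


def estimate_baseline(fit: AdditiveHazardFit, design: SurvivalDesign) -> BaselineCumulativeHazard:
    """Breslow-type baseline cumulative hazard for the fitted model.

    Jumps sum(w dN)/S0 at event ages minus the drift int Zbar' beta dt
    between them; with beta = 0 this is exactly the (weighted)
    Nelson-Aalen estimator with delayed entry.
    """
    u, entry_idx, exit_idx, S0, S1, dt = _risk_structure(design)
    K = len(dt)
    ev = design.event.astype(bool)
    iv = exit_idx[ev] - 1
    if np.any(S0[iv] <= 0):
        raise DomainError("empty risk set at an event age")
    jumps = np.bincount(iv, weights=design.weights[ev], minlength=K)
    with np.errstate(invalid="ignore", divide="ignore"):
        jump_term = np.where(S0 > 0, jumps / np.where(S0 > 0, S0, 1.0), 0.0)
        drift = np.where(S0 > 0, (S1 @ fit.beta) / np.where(S0 > 0, S0, 1.0), 0.0) * dt
    values = np.cumsum(jump_term - drift)
    return BaselineCumulativeHazard(ages=u[1:], values=values)


def cluster_sandwich_vcov(fit: AdditiveHazardFit, design: SurvivalDesign) -> np.ndarray:
    """Sandwich covariance with scores summed within cluster.

    The per-row score is the integrated martingale-residual process

        U_i = w_i [ (Z_i - Zbar(T_i)) dN_i
                    - int Y_i (Z_i - Zbar(t)) dLambda0_hat(t)
                    - int Y_i (Z_i - Zbar(t)) (Z_i - Zbar(t))' beta_hat dt ];

    rows sharing a cluster id (replicates of one subject) are summed
    before the outer product. Requires at least two clusters.
    """
    if design.cluster is None:
        raise DomainError("design has no cluster ids")
    cl, cl_idx = np.unique(design.cluster, return_inverse=True)
    if len(cl) < 2:
        raise DomainError("a single cluster cannot support a sandwich variance; bootstrap instead")

    u, entry_idx, exit_idx, S0, S1, dt = _risk_structure(design)
    K = len(dt)
    w, Z, beta = design.weights, design.Z, fit.beta
    p = Z.shape[1]
    ev = design.event.astype(bool)
    iv_all = exit_idx - 1  # interval ending at each row's exit age

    with np.errstate(invalid="ignore", divide="ignore"):
        Zbar = np.where(S0[:, None] > 0, S1 / np.where(S0 > 0, S0, 1.0)[:, None], 0.0)

    # --- event part: w (Z - Zbar(T)) dN -----------------------------------
    U = np.zeros((len(w), p))
    U[ev] = (Z[ev] - Zbar[iv_all[ev]]) * w[ev][:, None]

    # --- compensator jump part: int Y_i (Z_i - Zbar) dLambda0-jumps -------
    jumps = np.bincount(iv_all[ev], weights=w[ev], minlength=K)
    q = np.where(S0 > 0, jumps / np.where(S0 > 0, S0, 1.0), 0.0)  # per-interval jump mass
    cumQ1 = np.concatenate([[0.0], np.cumsum(q)])
    cumQZ = np.concatenate([np.zeros((1, p)), np.cumsum(Zbar * q[:, None], axis=0)])
    dQ1 = cumQ1[exit_idx] - cumQ1[entry_idx]
    dQZ = cumQZ[exit_idx] - cumQZ[entry_idx]
    U -= w[:, None] * (Z * dQ1[:, None] - dQZ)

    # --- regression drift part: int Y_i (Z-Zbar)(Z-Zbar)' beta dt ---------
    zb_beta = Zbar @ beta  # per-interval Zbar' beta
    c1 = np.concatenate([[0.0], np.cumsum(zb_beta * dt)])
    c2 = np.concatenate([np.zeros((1, p)), np.cumsum(Zbar * dt[:, None], axis=0)])
    c3 = np.concatenate([np.zeros((1, p)), np.cumsum(Zbar * (zb_beta * dt)[:, None], axis=0)])
    dC1 = c1[exit_idx] - c1[entry_idx]
    dC2 = c2[exit_idx] - c2[entry_idx]
    dC3 = c3[exit_idx] - c3[entry_idx]
    dur = design.exit - design.entry
    zbeta = Z @ beta
    drift = Z * (zbeta * dur - dC1)[:, None] - dC2 * zbeta[:, None] + dC3
    U -= w[:, None] * drift

    # --- cluster sums and sandwich ----------------------------------------
    Uc = np.zeros((len(cl), p))
    np.add.at(Uc, cl_idx, U)
    Ainv = np.linalg.inv(fit.A)
    V = Ainv @ (Uc.T @ Uc) @ Ainv
    fit.vcov_cluster = V
    return V
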