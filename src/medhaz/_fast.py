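"""Vectorized bootstrap engine for the decomposition pipeline.

The subject-level bootstrap reruns the whole pipeline (mediator fits,
counterfactual expansion, weights, truncation, weighted additive-hazards
fit) hundreds of times per stratum. This module implements the identical
computation on preassembled numpy arrays, exploiting two structural
facts: the replicate pattern matrix is the same for every subject, and
all replicates of a subject share one survival interval, so every
risk-set sum and every block of the integrated information matrix of the
expanded data collapses to subject-level aggregates — the L^K-fold
expanded design is never materialized. The estimating equation solved is
algebraically the one of the public path (the test suite pins the two to
machine precision); only the bookkeeping differs.
"""

from __future__ import annotations

import itertools

import numpy as np

from .exceptions import ConvergenceError, MedhazError
from .mediators import (
    _multinomial_hessian,
    _newton_multinomial,
    fit_mediator_model,
    softmax_probs_eta,
)

__all__ = ["StratumEngine"]


def _fit_warm(X, Y, y_idx, L, coef0, tol=1e-8, max_iter=12):
    """Warm-started Newton refit with the same convergence criterion as
    the point fit (max |gradient| < tol).

    Bootstrap replicates sit close to the point estimate, so plain
    Newton steps without line search converge in a few iterations; on
    any sign of trouble the safeguarded full fit takes over."""
    B = coef0
    prev = np.inf
    for _ in range(max_iter):
        P = softmax_probs_eta(X @ B.T)
        G = (Y - P[:, 1:]).T @ X
        g = np.max(np.abs(G))
        if g < tol:
            return B
        if not np.isfinite(g) or g > 10.0 * prev:
            break
        prev = g
        H = _multinomial_hessian(X, P[:, 1:])
        try:
            B = B + np.linalg.solve(H, G.ravel()).reshape(B.shape)
        except np.linalg.LinAlgError:
            break
    B, _, converged, _ = _newton_multinomial(X, y_idx, L, coef0=coef0, tol=tol)
    if not converged:
        raise ConvergenceError("mediator refit did not converge in bootstrap replicate")
    return B


class StratumEngine:
    """Reruns the single-stratum pipeline on bootstrap index vectors.

    Built once per (sex stratum, configuration); ``fit(idx)`` returns
    the fitted natural-effect coefficients for the resampled subjects
    ``idx`` (``idx = arange(n)`` reproduces the point fit exactly).
    """

    def __init__(self, df, config, levels):
        self.levels = list(levels)
        self.L = len(levels)
        self.mediators = list(config.mediators)
        self.K = len(self.mediators)
        self.truncation_percentile = config.truncation_percentile
        self.normalize = config.normalize_weights
        spec = config.predictor_spec(levels)
        self.spec = spec
        n = len(df)
        self.n = n

        X = spec.build(df)
        names = spec.names()
        self.race_cols = [names.index(f"race_{r}") for r in levels[1:]]
        self.X = X
        X0 = X.copy()
        X0[:, self.race_cols] = 0.0
        self.X0 = X0
        race = df["race_ethnicity"].to_numpy()
        self.race_idx = np.array([self.levels.index(r) for r in race])

        # per-mediator category codes, indicators and point fits
        self.y_idx = {}
        self.Yind = {}
        self.Lk = {}
        self.warm = {}
        for med in self.mediators:
            model = fit_mediator_model(df, med, spec)
            lut = {lev: i for i, lev in enumerate(model.levels)}
            y = df[med].astype(str).map(lut).to_numpy()
            self.y_idx[med] = y
            Lk = len(model.levels)
            self.Lk[med] = Lk
            self.Yind[med] = np.column_stack([(y == j).astype(float) for j in range(1, Lk)])
            self.warm[med] = model.coef

        # survival times and adjustment covariates
        self.entry = df["entry_age"].to_numpy(float)
        self.exit = df["exit_age"].to_numpy(float)
        self.event = df["event"].to_numpy(int)
        cov_cols = []
        self.cov_names = []
        if config.covariate_set == "full":
            edu = df["education"].to_numpy()
            cov_cols += [(edu == "medium").astype(float), (edu == "high").astype(float)]
            self.cov_names += ["edu_medium", "edu_high"]
        cov_cols.append(df["married"].to_numpy(float))
        cov_cols.append((df["survey_year"].to_numpy(float) - 2005.5) / 10.0)
        self.cov_names += ["married", "year_s"]
        self.cov = np.column_stack(cov_cols)

        # replicate patterns (R, K), ordered like expand_cohort
        self.patterns = np.array(
            list(itertools.product(range(self.L), repeat=self.K)), dtype=int
        )
        self.R = len(self.patterns)
        # pattern dummies per mediator: (R, L-1)
        self.pat = [
            np.column_stack([(self.patterns[:, k] == l).astype(float) for l in range(1, self.L)])
            for k in range(self.K)
        ]

        # design column layout identical to build_msm_design
        Lm1 = self.L - 1
        self.names = [f"race_{r}" for r in levels[1:]]
        for med in self.mediators:
            m = med.removesuffix("_category")
            self.names += [f"rstar_{m}_{r}" for r in levels[1:]]
        for med in self.mediators:
            m = med.removesuffix("_category")
            for r_obs in levels[1:]:
                self.names += [f"race_{r_obs}_x_rstar_{m}_{r_star}" for r_star in levels[1:]]
        self.names += self.cov_names
        self.p = len(self.names)
        # column index helpers
        self._rc = list(range(Lm1))
        self._rs = [[Lm1 + k * Lm1 + l for l in range(Lm1)] for k in range(self.K)]
        base = Lm1 * (1 + self.K)
        self._it = [
            [[base + k * Lm1 * Lm1 + lo * Lm1 + ls for ls in range(Lm1)] for lo in range(Lm1)]
            for k in range(self.K)
        ]
        self._cv = list(range(base + self.K * Lm1 * Lm1, self.p))

    # ------------------------------------------------------------------
    def _mediator_ratios(self, idx, refit=True):
        """{mediator: (L, n) array of P(m_i | r*, C_i)/P(m_i | r_i, C_i)}."""
        ratios = {}
        n = len(idx)
        rows = np.arange(n)
        race_idx = self.race_idx[idx]
        Xb0 = self.X0[idx]
        for med in self.mediators:
            Lk = self.Lk[med]
            y = self.y_idx[med][idx]
            if refit:
                B = _fit_warm(self.X[idx], self.Yind[med][idx], y, Lk, self.warm[med])
            else:
                B = self.warm[med]
            eta_base = Xb0 @ B.T  # linear predictor at the reference exposure
            p_lev = np.empty((self.L, n))
            for l in range(self.L):
                eta = eta_base if l == 0 else eta_base + B[:, self.race_cols[l - 1]]
                P = softmax_probs_eta(eta)
                p_lev[l] = P[rows, y]
            denom = p_lev[race_idx, rows]
            rat = p_lev / denom
            rat[race_idx, rows] = 1.0  # identity replicate is exact
            ratios[med] = rat
        return ratios

    def _weights(self, idx, ratios):
        """(n, R) weight matrix with percentile truncation applied."""
        n = len(idx)
        w = np.ones((n, self.R))
        for k, med in enumerate(self.mediators):
            w *= ratios[med][self.patterns[:, k], :].T
        if self.truncation_percentile < 100.0:
            cap = np.percentile(w, self.truncation_percentile)
            np.minimum(w, cap, out=w)
        if self.normalize:
            w = w / w.mean(axis=0, keepdims=True)
        return w

    # ------------------------------------------------------------------
    def _subject_aggregates(self, race_d, cov, w, scale):
        """G = sum_a (scale_a-weighted) z_ia per subject, for a (n, R)
        weight-like matrix ``w`` scaled per subject by ``scale``."""
        n = w.shape[0]
        ws = w * scale[:, None] if scale is not None else w
        g = ws.sum(axis=1)
        q = [ws @ self.pat[k] for k in range(self.K)]  # (n, L-1) each
        G = np.empty((n, self.p))
        Lm1 = self.L - 1
        for l in range(Lm1):
            G[:, self._rc[l]] = race_d[:, l] * g
        for k in range(self.K):
            for l in range(Lm1):
                G[:, self._rs[k][l]] = q[k][:, l]
        for k in range(self.K):
            for lo in range(Lm1):
                for ls in range(Lm1):
                    G[:, self._it[k][lo][ls]] = race_d[:, lo] * q[k][:, ls]
        for j, c in enumerate(self._cv):
            G[:, c] = cov[:, j] * g
        return g, G

    def _information_matrix(self, race_d, cov, Wd):
        """sum_i sum_a Wd_ia z_ia z_ia' assembled block-wise; Wd is the
        (n, R) matrix of duration-scaled weights."""
        Lm1 = self.L - 1
        p = self.p
        A = np.zeros((p, p))
        s = Wd.sum(axis=1)  # (n,)
        colWd = Wd.sum(axis=0)  # (R,)
        rWd = race_d.T @ Wd  # (L-1, R)
        rsum = race_d.T @ s  # (L-1,)
        qd = [Wd @ self.pat[k] for k in range(self.K)]  # (n, L-1)
        rqd = [race_d.T @ qd[k] for k in range(self.K)]  # (L-1, L-1)

        def put(i, j, v):
            A[i, j] = v
            A[j, i] = v

        # race x race (dummies are mutually exclusive)
        for lo in range(Lm1):
            A[self._rc[lo], self._rc[lo]] = rsum[lo]
        # race x rstar and race x interaction
        for k in range(self.K):
            for lo in range(Lm1):
                for ls in range(Lm1):
                    put(self._rc[lo], self._rs[k][ls], rqd[k][lo, ls])
                    put(self._rc[lo], self._it[k][lo][ls], rqd[k][lo, ls])
        # rstar x rstar, rstar x interaction, interaction x interaction
        for j in range(self.K):
            for k in range(j, self.K):
                blk = (self.pat[j].T * colWd) @ self.pat[k]  # (L-1, L-1)
                rblk = [
                    (self.pat[j].T * rWd[lo]) @ self.pat[k] for lo in range(Lm1)
                ]
                for lj in range(Lm1):
                    for lk in range(Lm1):
                        if k > j or lk >= lj:
                            put(self._rs[j][lj], self._rs[k][lk], blk[lj, lk])
                        for lo in range(Lm1):
                            put(self._it[j][lo][lj], self._rs[k][lk], rblk[lo][lj, lk])
                            if k > j:
                                put(self._rs[j][lj], self._it[k][lo][lk], rblk[lo][lj, lk])
                            if k > j or lk >= lj:
                                put(self._it[j][lo][lj], self._it[k][lo][lk], rblk[lo][lj, lk])
        # covariate blocks
        scov = cov * s[:, None]
        A[np.ix_(self._cv, self._cv)] = cov.T @ scov
        crace = cov.T @ (race_d * s[:, None])  # (q, L-1)
        for lo in range(Lm1):
            for j, c in enumerate(self._cv):
                put(c, self._rc[lo], crace[j, lo])
        for k in range(self.K):
            cq = cov.T @ qd[k]  # (q, L-1)
            for ls in range(Lm1):
                for j, c in enumerate(self._cv):
                    put(c, self._rs[k][ls], cq[j, ls])
            for lo in range(Lm1):
                cqi = cov.T @ (race_d[:, lo][:, None] * qd[k])
                for ls in range(Lm1):
                    for j, c in enumerate(self._cv):
                        put(c, self._it[k][lo][ls], cqi[j, ls])
        return A

    # ------------------------------------------------------------------
    def fit(self, idx, refit_mediators=True):
        """Full pipeline on the resampled subjects; returns beta."""
        idx = np.asarray(idx)
        ratios = self._mediator_ratios(idx, refit=refit_mediators)
        w = self._weights(idx, ratios)  # (n, R)

        race_idx = self.race_idx[idx]
        race_d = np.column_stack([(race_idx == l).astype(float) for l in range(1, self.L)])
        cov = self.cov[idx]
        entry, exit_, event = self.entry[idx], self.exit[idx], self.event[idx]
        dur = exit_ - entry

        A = self._information_matrix(race_d, cov, w * dur[:, None])
        g, G = self._subject_aggregates(race_d, cov, w, None)

        # subject-level risk structure (replicates share intervals)
        u = np.unique(np.concatenate([entry, exit_]))
        Kiv = len(u) - 1
        entry_idx = np.searchsorted(u, entry)
        exit_idx = np.searchsorted(u, exit_)
        d0 = np.bincount(entry_idx, weights=g, minlength=Kiv + 1) - np.bincount(
            exit_idx, weights=g, minlength=Kiv + 1
        )
        S0 = np.cumsum(d0)[:Kiv]
        S1 = np.empty((Kiv, self.p))
        for j in range(self.p):
            d1 = np.bincount(entry_idx, weights=G[:, j], minlength=Kiv + 1) - np.bincount(
                exit_idx, weights=G[:, j], minlength=Kiv + 1
            )
            S1[:, j] = np.cumsum(d1)[:Kiv]
        dt = np.diff(u)
        pos = S0 > 0
        M = S1[pos] * np.sqrt(dt[pos] / S0[pos])[:, None]
        A -= M.T @ M

        ev = event.astype(bool)
        iv = exit_idx[ev] - 1
        Zbar_ev = S1[iv] / S0[iv][:, None]
        b = G[ev].sum(axis=0) - (Zbar_ev * g[ev][:, None]).sum(axis=0)

        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:
            raise MedhazError(f"singular design in bootstrap replicate: {exc}") from exc
        if not np.all(np.isfinite(beta)):
            raise MedhazError("non-finite coefficients in bootstrap replicate")
        return beta
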