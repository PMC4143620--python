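"""Two-stage region association for longitudinal family phenotypes.

Stage 1 summarizes the genotypes of a candidate region per individual:

* an empirical-Bayes (EB) genetic load — genotypes are standardized per
  marker, modeled with a one-way random-effects model
  ``z_im = b_i + eps_im`` fitted by maximum likelihood, and the individual
  effect is predicted by its BLUP, ``EB_i = m_i s2b / (m_i s2b + s2e) * zbar_i``;
* a rare-variant burden — the summed minor-allele dosage over region markers
  with MAF below a rarity threshold.

Stage 2 fits, per region, the longitudinal linear mixed model

    y_ijt = b0 + b_age * age_ijt + b_smoke * smoke_ijt
            + beta2 * EB_ij + beta3 * s_ij + u_ij + e_ijt

where for family ``i`` the vector of individual effects ``u_i`` is
``MVN(0, sigma_u^2 * R_i)`` with ``R_i`` the coefficient-of-relationship
block, and the residuals of one individual's T repeated measurements are
``MVN(0, Sigma_e)`` with an unstructured T x T covariance. Fixed effects are
profiled by GLS and the variance components maximized numerically
(log-Cholesky parameterization). The region effect is tested by a 2-df Wald
statistic on (beta2, beta3).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Stage 1: EB summaries and rare burdens
# ---------------------------------------------------------------------------

@dataclass
class EBSummary:
    """Per-individual empirical-Bayes genetic load for one region."""

    region_id: str
    eb: pd.Series                # indexed by individual id; 0 where m_obs = 0
    m_obs: pd.Series             # non-missing markers used per individual
    sigma2_b: float
    sigma2_e: float
    boundary: bool               # True when the between-individual variance hit 0


@dataclass
class RareBurden:
    """Per-individual rare-allele count (expected dosage allowed)."""

    region_id: str
    rare_maf_max: float
    s: pd.Series
    n_rare_markers: int


def _standardize(genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardize genotype/dosage columns to z = (g - 2p)/sqrt(2p(1-p)).

    Missing values (negative or NaN) become NaN. Monomorphic columns are
    dropped by the caller (their z is NaN everywhere).
    """
    g = np.asarray(genotypes, dtype=float)
    g = np.where(g < 0, np.nan, g)
    p = np.nanmean(g, axis=0) / 2.0
    denom = np.sqrt(2.0 * p * (1.0 - p))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (g - 2.0 * p) / denom
    z[:, (p <= 0.0) | (p >= 1.0)] = np.nan
    return z, p


def _oneway_ml(zbar: np.ndarray, m: np.ndarray, wss: np.ndarray) -> tuple[float, float]:
    """ML of the zero-mean one-way random-effects model from sufficient stats.

    Per individual i with m_i observations: within-SS ``wss_i`` and mean
    ``zbar_i``; the likelihood splits into a within part depending on s2e and
    a mean part with variance s2b + s2e/m_i. Optimized over log variances.
    """
    use = m > 0
    m, zbar, wss = m[use], zbar[use], wss[use]
    n_within = float((m - 1).sum())
    W = float(wss.sum())

    def nll(theta):
        s2b, s2e = np.maximum(np.exp(np.clip(theta, -700, 700)), 1e-300)
        v = s2b + s2e / m
        return 0.5 * (n_within * math.log(s2e) + W / s2e
                      + np.log(v).sum() + (zbar ** 2 / v).sum())

    s2e0 = max(W / max(n_within, 1.0), 1e-8)
    v0 = max(float((zbar ** 2).mean()), 1e-8)
    s2b0 = max(v0 - s2e0 / float(m.mean()), 1e-8)
    res = optimize.minimize(nll, np.log([s2b0, s2e0]), method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
    s2b, s2e = np.exp(res.x)
    # boundary: between-variance indistinguishable from 0
    if s2b < 1e-8 * max(s2e, 1e-12):
        s2b = 0.0
    return float(s2b), float(s2e)


def eb_summarize(genotypes: np.ndarray, marker_idx: Sequence[int],
                 ids: Sequence[str], region_id: str = "region") -> EBSummary:
    """Empirical-Bayes genetic load of a region for every individual.

    ``genotypes`` is individuals x markers (hard calls or dosages; negatives
    and NaN are missing); ``marker_idx`` selects the region's columns. Raises
    if the region holds no polymorphic marker. When the between-individual
    variance estimate hits 0 the EB loads are all 0 and the summary is
    flagged.
    """
    sub = np.asarray(genotypes, dtype=float)[:, list(marker_idx)]
    z, p = _standardize(sub)
    poly = (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError(f"region {region_id!r} has no polymorphic marker")
    z = z[:, poly]
    m = (~np.isnan(z)).sum(axis=1)
    zsum = np.nansum(z, axis=1)  # direct sum avoids nanmean warnings on all-missing rows
    zbar = np.where(m > 0, zsum / np.maximum(m, 1), 0.0)
    wss = np.nansum((z - zbar[:, None]) ** 2, axis=1)

    s2b, s2e = _oneway_ml(zbar.copy(), m.astype(float), wss)
    boundary = s2b == 0.0
    if boundary:
        shrink = np.zeros_like(zbar)
    else:
        shrink = m * s2b / (m * s2b + s2e)
    eb = np.where(m > 0, shrink * zbar, 0.0)
    return EBSummary(region_id=region_id,
                     eb=pd.Series(eb, index=list(ids)),
                     m_obs=pd.Series(m, index=list(ids)),
                     sigma2_b=s2b, sigma2_e=s2e, boundary=boundary)


def rare_count(genotypes: np.ndarray, marker_idx: Sequence[int],
               ids: Sequence[str], rare_maf_max: float = 0.01,
               region_id: str = "region") -> RareBurden:
    """Summed minor-allele dosage over the region's rare markers.

    A marker is rare when its sample MAF is positive and below
    ``rare_maf_max``. Hard calls give integer counts, dosages reals. A
    missing genotype contributes the marker's mean minor-allele dosage
    (logged).
    """
    sub = np.asarray(genotypes, dtype=float)[:, list(marker_idx)]
    sub = np.where(sub < 0, np.nan, sub)
    p = np.nanmean(sub, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    rare = (maf > 0) & (maf < rare_maf_max)
    minor = np.where(p[rare] <= 0.5, sub[:, rare], 2.0 - sub[:, rare])
    n_missing = int(np.isnan(minor).sum())
    if n_missing:
        logger.info("rare_count %s: %d missing genotypes imputed by marker mean",
                    region_id, n_missing)
        col_mean = np.nanmean(minor, axis=0)
        minor = np.where(np.isnan(minor), col_mean, minor)
    s = minor.sum(axis=1) if minor.shape[1] else np.zeros(sub.shape[0])
    return RareBurden(region_id=region_id, rare_maf_max=rare_maf_max,
                      s=pd.Series(s, index=list(ids)), n_rare_markers=int(rare.sum()))


# ---------------------------------------------------------------------------
# Stage 2: kinship-structured longitudinal LMM
# ---------------------------------------------------------------------------

@dataclass
class LMMFit:
    """Maximum-likelihood fit of the longitudinal family mixed model."""

    beta: pd.Series
    cov_beta: pd.DataFrame
    sigma_u2: float
    se_sigma_u2: float
    sigma_e: np.ndarray          # T x T residual covariance
    loglik: float
    converged: bool
    boundary_sigma_u2: bool
    n_obs: int
    n_individuals: int
    method: str = "ml"


class _FamilyBlocks:
    """Per-family covariance structure, batched by block size for speed.

    Families with the same number of observed rows are stacked so the
    Cholesky factorizations and triangular solves run as one batched LAPACK
    call; with a shared family template this removes the Python loop from
    every likelihood evaluation.
    """

    def __init__(self, df: pd.DataFrame, X: np.ndarray, y: np.ndarray,
                 R: pd.DataFrame, T: int):
        self.T = T
        blocks = []
        self.balanced = self._try_balanced(df, X, y, R, T)
        for _, fam in df.groupby("family_id", sort=True):
            inds = pd.unique(fam["individual_id"])
            ind_pos = {iid: k for k, iid in enumerate(inds)}
            rows = fam.index.to_numpy()
            r_ind = fam["individual_id"].map(ind_pos).to_numpy()
            t_idx = fam["_t"].to_numpy()
            Rsub = R.loc[list(inds), list(inds)].to_numpy()
            A = Rsub[np.ix_(r_ind, r_ind)]                      # kinship part
            same = (r_ind[:, None] == r_ind[None, :])
            blocks.append((X[rows], y[rows], A, same,
                           t_idx[:, None], t_idx[None, :]))
        self.blocks = blocks
        self.groups = []
        by_size: dict[int, list] = {}
        for b in blocks:
            by_size.setdefault(len(b[1]), []).append(b)
        for size, bs in sorted(by_size.items()):
            Xs = np.stack([b[0] for b in bs])
            ys = np.stack([b[1] for b in bs])
            As = np.stack([b[2] for b in bs])
            Ss = np.stack([b[3] for b in bs])
            ti = np.stack([np.broadcast_to(b[4], (size, size)) for b in bs])
            tj = np.stack([np.broadcast_to(b[5], (size, size)) for b in bs])
            self.groups.append((Xs, ys, As, Ss, ti, tj))

    def _try_balanced(self, df, X, y, R, T):
        """Spectral precomputation for complete balanced data.

        When every individual is observed at all T ordered time points, the
        family covariance sigma_u^2 (R_i o J) + I o Sigma_e diagonalizes per
        family through R_i = Q Lam Q': in the rotated basis it is
        block-diagonal with T x T blocks sigma_u^2 lam_k J + Sigma_e, so one
        likelihood evaluation is a batched T x T Cholesky over all
        individuals. The rotation of X and y is parameter-free and done once.
        """
        lam_all, Xr_all, yr_all = [], [], []
        for _, fam in df.groupby("family_id", sort=True):
            inds = pd.unique(fam["individual_id"])
            n_i = len(inds)
            if len(fam) != n_i * T:
                return None
            t_seq = fam["_t"].to_numpy().reshape(n_i, T)
            if not np.all(t_seq == np.arange(T)):
                return None
            if not (fam["individual_id"].to_numpy().reshape(n_i, T)
                    == np.asarray(inds)[:, None]).all():
                return None
            Rsub = R.loc[list(inds), list(inds)].to_numpy()
            lam, Q = np.linalg.eigh(Rsub)
            rows = fam.index.to_numpy()
            yb = y[rows].reshape(n_i, T)
            Xb = X[rows].reshape(n_i, T, -1)
            lam_all.append(lam)
            yr_all.append(np.einsum("ij,it->jt", Q, yb))
            Xr_all.append(np.einsum("ij,itp->jtp", Q, Xb))
        return (np.concatenate(lam_all), np.concatenate(yr_all),
                np.concatenate(Xr_all))

    def _nll_balanced(self, s2u, sigma_e, reml):
        lam, yr, Xr = self.balanced
        T = self.T
        J = np.ones((T, T))
        V = s2u * lam[:, None, None] * J + sigma_e[None, :, :]
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return np.inf, None, None
        logdet = 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum()
        wy = np.linalg.solve(L, yr[..., None])[..., 0]
        wX = np.linalg.solve(L, Xr)
        XtViX = np.einsum("ktp,ktq->pq", wX, wX)
        XtViy = np.einsum("ktp,kt->p", wX, wy)
        ytViy = float((wy * wy).sum())
        try:
            beta = np.linalg.solve(XtViX, XtViy)
        except np.linalg.LinAlgError:
            return np.inf, None, None
        quad = ytViy - beta @ XtViy
        nll = 0.5 * (logdet + yr.size * math.log(2.0 * math.pi) + quad)
        if reml:
            sign, ld = np.linalg.slogdet(XtViX)
            if sign <= 0:
                return np.inf, None, None
            nll += 0.5 * ld
        return nll, beta, XtViX

    def nll(self, s2u: float, sigma_e: np.ndarray, reml: bool = False):
        """Profile negative log-likelihood; returns (nll, beta, XtViX)."""
        if self.balanced is not None:
            return self._nll_balanced(s2u, sigma_e, reml)
        p = self.blocks[0][0].shape[1]
        XtViX = np.zeros((p, p))
        XtViy = np.zeros(p)
        ytViy = 0.0
        logdet = 0.0
        N = 0
        for Xs, ys, As, Ss, ti, tj in self.groups:
            V = s2u * As + sigma_e[ti, tj] * Ss
            try:
                L = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                return np.inf, None, None
            logdet += 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum()
            wy = solve_triangular_batched(L, ys[..., None])[..., 0]
            wX = solve_triangular_batched(L, Xs)
            XtViX += np.einsum("fnp,fnq->pq", wX, wX)
            XtViy += np.einsum("fnp,fn->p", wX, wy)
            ytViy += float((wy * wy).sum())
            N += ys.size
        try:
            beta = np.linalg.solve(XtViX, XtViy)
        except np.linalg.LinAlgError:
            return np.inf, None, None
        quad = ytViy - beta @ XtViy
        nll = 0.5 * (logdet + N * math.log(2.0 * math.pi) + quad)
        if reml:
            sign, ld = np.linalg.slogdet(XtViX)
            if sign <= 0:
                return np.inf, None, None
            nll += 0.5 * ld
        return nll, beta, XtViX


def solve_triangular_batched(L: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve L w = B for a batch of lower-triangular L via forward substitution.

    Uses LAPACK's batched generic solve, which is exact for triangular
    systems and avoids a Python-level loop over families.
    """
    return np.linalg.solve(L, B)


def _chol_params_to_cov(theta: np.ndarray, T: int) -> np.ndarray:
    """Log-Cholesky vector -> SPD T x T matrix (diagonal entries logged)."""
    L = np.zeros((T, T))
    k = 0
    for i in range(T):
        for j in range(i + 1):
            L[i, j] = math.exp(theta[k]) if i == j else theta[k]
            k += 1
    return L @ L.T


def _cov_to_chol_params(S: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(S)
    out = []
    for i in range(S.shape[0]):
        for j in range(i + 1):
            out.append(math.log(max(L[i, j], 1e-10)) if i == j else L[i, j])
    return np.array(out)


def fit_lmm(pheno: pd.DataFrame, R: pd.DataFrame,
            eb: Mapping[str, float] | pd.Series | None = None,
            s: Mapping[str, float] | pd.Series | None = None,
            covariates: Sequence[str] = ("age", "smoke"),
            response: str = "dbp",
            n_timepoints: int = 4,
            method: str = "ml",
            sigma_e_structure: str = "unstructured",
            constrain_sigma_u2: float | None = None,
            gtol: float = 1e-6, maxiter: int = 500,
            max_restarts: int = 5) -> LMMFit:
    """Fit the longitudinal family LMM by (RE)ML with profiled fixed effects.

    ``pheno`` is long-format with columns ``family_id``, ``individual_id``,
    ``timepoint`` (1..T), the response, and covariates; rows with a missing
    response or covariate are dropped (missing-at-random row deletion).
    ``R`` is the coefficient-of-relationship matrix covering every phenotyped
    individual. ``eb`` and ``s`` add the region load and rare-burden
    covariates (beta2, beta3); omit ``s`` for the beta2-only model.

    The marginal covariance of family i is
    ``sigma_u^2 (R_i o J_T) + I o Sigma_e`` restricted to observed rows.
    Sigma_e is unstructured (log-Cholesky) by default, or ``"iso"`` for
    sigma^2 I; ``constrain_sigma_u2`` fixes the family variance (e.g. 0).
    Starts from method-of-moments values with perturbed restarts on failure.
    """
    if method not in ("ml", "reml"):
        raise ValueError("method must be 'ml' or 'reml'")
    Rv = R.to_numpy()
    if np.any(np.linalg.eigvalsh((Rv + Rv.T) / 2) < -1e-8):
        raise ValueError("relationship matrix is not positive semidefinite")

    df = pheno.copy()
    cols = ["family_id", "individual_id", "timepoint", response, *covariates]
    df = df[cols].dropna().reset_index(drop=True)
    df["_t"] = df["timepoint"].astype(int) - 1
    T = n_timepoints
    if df["_t"].max() >= T:
        raise ValueError("timepoint exceeds n_timepoints")

    names = ["intercept", *covariates]
    Xcols = [np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in covariates]
    if eb is not None:
        names.append("eb")
        Xcols.append(df["individual_id"].map(pd.Series(eb)).to_numpy(dtype=float))
    if s is not None:
        names.append("s")
        Xcols.append(df["individual_id"].map(pd.Series(s)).to_numpy(dtype=float))
    X = np.column_stack(Xcols)
    y = df[response].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("covariate or region summary missing for some individuals")

    if len(pd.unique(df["family_id"])) < 2:
        raise ValueError("need at least 2 families")
    blocks = _FamilyBlocks(df, X, y, R, T)
    reml = method == "reml"

    # method-of-moments starting values from OLS residuals
    bols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ bols
    df["_r"] = resid
    wide = df.pivot_table(index="individual_id", columns="_t", values="_r")
    emp = wide.cov().reindex(index=range(T), columns=range(T)).to_numpy()
    var0 = float(np.var(resid))
    emp = np.where(np.isnan(emp), 0.0, emp)
    emp = emp + emp.T - np.diag(np.diag(emp))
    np.fill_diagonal(emp, np.maximum(np.diag(emp), 0.1 * var0))
    # regularize toward a diagonal and floor eigenvalues to ensure SPD
    Se0 = 0.8 * emp + 0.2 * var0 * np.eye(T)
    w, Q = np.linalg.eigh((Se0 + Se0.T) / 2)
    Se0 = (Q * np.maximum(w, 0.05 * var0)) @ Q.T
    fam_means = df.groupby("family_id")["_r"].mean()
    s2u0 = float(max(fam_means.var(), 0.05 * var0, 1e-6))

    free_u = constrain_sigma_u2 is None

    def unpack(theta):
        k = 0
        if free_u:
            s2u = math.exp(theta[0])
            k = 1
        else:
            s2u = float(constrain_sigma_u2)
        if sigma_e_structure == "iso":
            Se = math.exp(theta[k]) * np.eye(T)
        else:
            Se = _chol_params_to_cov(theta[k:], T)
        return s2u, Se

    def obj(theta):
        s2u, Se = unpack(theta)
        val, _, _ = blocks.nll(s2u, Se, reml)
        return val if np.isfinite(val) else 1e12

    theta0_parts = []
    if free_u:
        theta0_parts.append([math.log(s2u0)])
    if sigma_e_structure == "iso":
        theta0_parts.append([math.log(var0)])
    else:
        theta0_parts.append(list(_cov_to_chol_params(Se0)))
    theta0 = np.concatenate(theta0_parts)

    rng = np.random.default_rng(0)
    best = None
    converged = False
    for attempt in range(max_restarts + 1):
        start = theta0 if attempt == 0 else theta0 + rng.normal(0, 0.3, size=theta0.size)
        res = optimize.minimize(obj, start, method="L-BFGS-B",
                                options={"gtol": gtol, "maxiter": maxiter})
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        if res.success and np.isfinite(res.fun):
            converged = True
            break
    if not converged:
        logger.warning("fit_lmm: optimizer did not report convergence after "
                       "%d restarts (flagged)", max_restarts)

    s2u, Se = unpack(best.x)
    nll, beta, XtViX = blocks.nll(s2u, Se, reml)
    cov_beta = np.linalg.inv(XtViX)

    # SE of sigma_u2 by observed information on log scale + delta method
    se_s2u = float("nan")
    boundary = free_u and s2u < 1e-6 * max(var0, 1e-12)
    if free_u and not boundary:
        h = 1e-4
        t = best.x.copy()
        f0 = obj(t)
        tp = t.copy(); tp[0] += h
        tm = t.copy(); tm[0] -= h
        d2 = (obj(tp) - 2 * f0 + obj(tm)) / h ** 2
        if d2 > 0:
            se_s2u = s2u / math.sqrt(d2)   # delta method from log sigma_u2

    return LMMFit(
        beta=pd.Series(beta, index=names),
        cov_beta=pd.DataFrame(cov_beta, index=names, columns=names),
        sigma_u2=float(s2u), se_sigma_u2=se_s2u, sigma_e=Se,
        loglik=float(-nll), converged=converged,
        boundary_sigma_u2=bool(boundary),
        n_obs=len(y), n_individuals=df["individual_id"].nunique(),
        method=method,
    )


def loglik_at(pheno: pd.DataFrame, R: pd.DataFrame, beta: Mapping[str, float],
              sigma_u2: float, sigma_e: np.ndarray,
              eb=None, s=None, covariates: Sequence[str] = ("age", "smoke"),
              response: str = "dbp", n_timepoints: int = 4) -> float:
    """Log-likelihood of the LMM at fully specified parameter values.

    Used for generative/inferential sanity checks (e.g. the ML solution must
    dominate the generating truth).
    """
    fit_cols = ["intercept", *covariates] + (["eb"] if eb is not None else []) \
        + (["s"] if s is not None else [])
    df = pheno.copy()
    df = df[["family_id", "individual_id", "timepoint", response, *covariates]].dropna()
    df = df.reset_index(drop=True)
    df["_t"] = df["timepoint"].astype(int) - 1
    Xcols = [np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in covariates]
    if eb is not None:
        Xcols.append(df["individual_id"].map(pd.Series(eb)).to_numpy(dtype=float))
    if s is not None:
        Xcols.append(df["individual_id"].map(pd.Series(s)).to_numpy(dtype=float))
    X = np.column_stack(Xcols)
    y = df[response].to_numpy(dtype=float)
    b = np.array([beta[c] for c in fit_cols])
    blocks = _FamilyBlocks(df, X, y, R, n_timepoints)
    ll = 0.0
    for Xf, yf, A, same, ti, tj in blocks.blocks:
        V = sigma_u2 * A + np.asarray(sigma_e)[ti, tj] * same
        L = np.linalg.cholesky(V)
        rf = yf - Xf @ b
        w = solve_triangular(L, rf, lower=True)
        ll -= 0.5 * (2 * np.log(np.diag(L)).sum() + len(yf) * math.log(2 * math.pi) + w @ w)
    return float(ll)


def wald_2df(beta_hat: np.ndarray, cov: np.ndarray) -> tuple[float, float]:
    """2-df Wald test of H0: beta2 = beta3 = 0.

    W = beta' cov^{-1} beta referred to chi-square with 2 df
    (p = exp(-W/2)). Raises on a singular covariance, advising the
    beta2-only model.
    """
    beta_hat = np.asarray(beta_hat, dtype=float)
    cov = np.asarray(cov, dtype=float)
    eig = np.linalg.eigvalsh((cov + cov.T) / 2)
    if eig.min() <= 0 or eig.min() / eig.max() < 1e-12:
        raise np.linalg.LinAlgError(
            "singular covariance of (beta2, beta3); consider the beta2-only model")
    W = float(beta_hat @ np.linalg.solve(cov, beta_hat))
    p = float(stats.chi2.sf(W, df=2))
    return W, p


@dataclass
class AssociationResult:
    """Per-region association summary (one row of a Table-4-style output)."""

    region_id: str
    beta2: float = float("nan")
    se_beta2: float = float("nan")
    beta3: float = float("nan")
    se_beta3: float = float("nan")
    p_beta2: float = float("nan")
    p_beta3: float = float("nan")
    wald: float = float("nan")
    p_joint: float = float("nan")
    p_beta2_only: float = float("nan")
    sigma_u2: float = float("nan")
    se_sigma_u2: float = float("nan")
    n_rare_markers: int = 0
    converged: bool = False
    flagged: str = ""


def test_regions(regions, pheno: pd.DataFrame, genotypes: np.ndarray,
                 panel: pd.DataFrame, ids: Sequence[str], R: pd.DataFrame,
                 rare_maf_max: float = 0.01, with_rare: bool = True,
                 **fit_kwargs) -> pd.DataFrame:
    """Stage-1 + stage-2 association for every region; Table-4-shaped output.

    For each region the EB load and (optionally) the rare burden are computed
    from ``genotypes`` over the markers whose bp fall inside the region, the
    LMM is fitted with and without the rare-count covariate, and the
    per-coefficient and joint 2-df Wald p-values are reported. Regions whose
    stage fails are emitted as flagged rows, never dropped silently.
    """
    bp = panel["bp"].to_numpy()
    rows = []
    for r in regions:
        rid = f"{r.chrom}:{r.start_bp}-{r.end_bp}"
        out = AssociationResult(region_id=rid)
        idx = np.flatnonzero((bp >= r.start_bp) & (bp <= r.end_bp))
        try:
            ebs = eb_summarize(genotypes, idx, ids, region_id=rid)
            burden = rare_count(genotypes, idx, ids, rare_maf_max, region_id=rid)
            out.n_rare_markers = burden.n_rare_markers
            use_s = with_rare and burden.s.var() > 0
            fit = fit_lmm(pheno, R, eb=ebs.eb, s=burden.s if use_s else None,
                          **fit_kwargs)
            out.beta2 = float(fit.beta["eb"])
            out.se_beta2 = math.sqrt(float(fit.cov_beta.loc["eb", "eb"]))
            out.p_beta2 = float(stats.chi2.sf((out.beta2 / out.se_beta2) ** 2, 1))
            out.sigma_u2 = fit.sigma_u2
            out.se_sigma_u2 = fit.se_sigma_u2
            out.converged = fit.converged
            if use_s:
                out.beta3 = float(fit.beta["s"])
                out.se_beta3 = math.sqrt(float(fit.cov_beta.loc["s", "s"]))
                out.p_beta3 = float(stats.chi2.sf((out.beta3 / out.se_beta3) ** 2, 1))
                sub = fit.cov_beta.loc[["eb", "s"], ["eb", "s"]].to_numpy()
                out.wald, out.p_joint = wald_2df(np.array([out.beta2, out.beta3]), sub)
                fit2 = fit_lmm(pheno, R, eb=ebs.eb, s=None, **fit_kwargs)
                b2 = float(fit2.beta["eb"])
                se2 = math.sqrt(float(fit2.cov_beta.loc["eb", "eb"]))
                out.p_beta2_only = float(stats.chi2.sf((b2 / se2) ** 2, 1))
            else:
                out.p_beta2_only = out.p_beta2
                out.wald = (out.beta2 / out.se_beta2) ** 2
                out.p_joint = float("nan")
                if with_rare:
                    out.flagged = "no polymorphic rare burden; beta2-only model"
        except (ValueError, np.linalg.LinAlgError) as exc:
            out.flagged = str(exc)
        rows.append(out.__dict__.copy())
    cols = list(AssociationResult("x").__dict__)
    return pd.DataFrame(rows, columns=cols)


def bonferroni_alpha(alpha: float, n_regions: int) -> tuple[float, float]:
    """Per-region significance level alpha / n_regions.

    Returns the exact level and its one-significant-figure presentation
    (e.g. 0.05 over 7 regions -> 0.0071428..., presented as 7e-3).
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    exact = alpha / n_regions
    mag = 10.0 ** math.floor(math.log10(exact))
    presented = round(exact / mag) * mag
    return exact, presented
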