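"""REML variance-component estimation for animal models with named kernels.

The model is ``y = X b + sum_k u_k + e`` with ``u_k ~ N(0, K_k sigma2_k)``
for each named relationship kernel (the pedigree matrix A, the microbial
matrix M, or both jointly) and ``e ~ N(0, I sigma2_e)``.  Estimation is by
restricted maximum likelihood:

* a single kernel is fit by profiling the REML log-likelihood over the
  variance ratio ``delta = sigma2_e / sigma2_k`` after one eigendecomposition
  of the kernel (exact, fast, and robust at the boundary);
* two or more kernels are fit by average-information (AI) REML with
  expectation-maximization fallback steps whenever an AI update would leave
  the parameter space or decrease the likelihood.

Standard errors come from the inverse average-information matrix; variance
ratios (h2 = sigma2_a / sigma2_p, m2 = sigma2_m / sigma2_p) get delta-method
standard errors.  The REML log-likelihood convention is
``-0.5 * (log|V| + log|X' V^-1 X| + y' P y)`` throughout, so the two fitting
routes are directly comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .kernels import Kernel

WILMINK_K = 0.065
#: lower bound on each variance component, as a fraction of the initial
#: phenotypic variance
BOUND_FRACTION = 1e-6
MAX_ITER = 200
LOGLIK_TOL = 1e-8


# ---------------------------------------------------------------------------
# fixed-effect design


def _dummies(values, prefix: str):
    levels = sorted(pd.unique(np.asarray(values, dtype=object)), key=str)
    cols, names = [], []
    for lev in levels[1:]:  # first level is the reference
        cols.append((np.asarray(values, dtype=object) == lev).astype(float))
        names.append(f"{prefix}[{lev}]")
    return cols, names


def build_design(metadata, wilmink_k: float = WILMINK_K,
                 include_herd: bool = True, include_batch: bool = False):
    """Fixed-effect design matrix for the animal model.

    Columns: intercept, herd and parity dummies (first level reference),
    optionally sequencing batch nested within platform, days in milk (dim)
    and the Wilmink early-lactation term ``exp(-k * dim)``.

    Returns ``(X, names)``.  Raises on rank deficiency, naming the aliased
    columns; warns when dim falls outside [1, 350].
    """
    md = pd.DataFrame(metadata)
    n = len(md)
    cols = [np.ones(n)]
    names = ["intercept"]
    if include_herd:
        if "herd" not in md:
            raise ValueError("metadata lacks a 'herd' column")
        c, nm = _dummies(md["herd"], "herd")
        cols += c
        names += nm
    if "parity" not in md:
        raise ValueError("metadata lacks a 'parity' column")
    c, nm = _dummies(md["parity"], "parity")
    cols += c
    names += nm
    if include_batch:
        if "batch" not in md:
            raise ValueError("metadata lacks a 'batch' column")
        if "platform" in md:
            lab = (md["platform"].astype(str) + ":" + md["batch"].astype(str))
        else:
            lab = md["batch"].astype(str)
        c, nm = _dummies(lab.to_numpy(object), "batch")
        cols += c
        names += nm
    if "dim" not in md:
        raise ValueError("metadata lacks a 'dim' column")
    dim = md["dim"].to_numpy(float)
    if ((dim < 1) | (dim > 350)).any():
        warnings.warn("days-in-milk values outside [1, 350]", stacklevel=2)
    cols.append(dim)
    names.append("dim")
    cols.append(np.exp(-wilmink_k * dim))
    names.append("wilmink")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns via pivoted QR
        _, _, piv = linalg.qr(X, mode="economic", pivoting=True)
        aliased = sorted(names[j] for j in piv[rank:])
        raise ValueError(f"design matrix is rank deficient; aliased columns: "
                         f"{aliased}")
    return X, names


# ---------------------------------------------------------------------------
# results container


@dataclass
class VarianceEstimate:
    """REML variance components, ratios, and uncertainty."""

    components: dict[str, float]          # kernel name -> sigma2, + "residual"
    se: dict[str, float]
    ratios: dict[str, float]              # kernel name -> sigma2_k / sigma2_p
    ratio_se: dict[str, float]
    loglik: float
    converged: bool
    n_iter: int
    method: str
    kernel_names: tuple[str, ...]
    cov: np.ndarray | None = None         # inverse AI matrix (component order)

    @property
    def sigma2_p(self) -> float:
        return float(sum(self.components.values()))

    @property
    def h2(self) -> float | None:
        return self.ratios.get("A")

    @property
    def m2(self) -> float | None:
        return self.ratios.get("M")

    def to_series(self) -> pd.Series:
        d: dict[str, float] = {}
        for k, v in self.components.items():
            d[f"sigma2_{k}"] = v
            d[f"se_sigma2_{k}"] = self.se.get(k, np.nan)
        for k, v in self.ratios.items():
            d[f"ratio_{k}"] = v
            d[f"se_ratio_{k}"] = self.ratio_se.get(k, np.nan)
        d["loglik"] = self.loglik
        d["converged"] = self.converged
        d["n_iter"] = self.n_iter
        return pd.Series(d)


@dataclass
class MixedModelSpec:
    """A response, its metadata, and named kernels, ready to fit.

    ``kernels`` maps names (conventionally "A" and "M") to :class:`Kernel`
    objects; they are aligned to ``ids`` before fitting.
    """

    response: np.ndarray
    metadata: pd.DataFrame
    kernels: dict[str, Kernel]
    ids: list[str]
    include_herd: bool = True
    include_batch: bool = False
    wilmink_k: float = WILMINK_K

    def fit(self, **kwargs) -> VarianceEstimate:
        X, _ = build_design(self.metadata, self.wilmink_k,
                            self.include_herd, self.include_batch)
        mats = {name: k.subset(self.ids).values
                for name, k in self.kernels.items()}
        return fit_reml(np.asarray(self.response, float), X, mats, **kwargs)


# ---------------------------------------------------------------------------
# internal numerics


def _as_matrix(k) -> np.ndarray:
    if isinstance(k, Kernel):
        return k.values
    return np.asarray(k, dtype=float)


def _loglik_at(y, X, Ks, theta):
    """REML log-likelihood at a component vector (cheap: no full inverse)."""
    n = len(y)
    V = theta[-1] * np.eye(n)
    for t, K in zip(theta[:-1], Ks):
        V += t * K
    cf = linalg.cho_factor(V, lower=True)
    ldV = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Viy = linalg.cho_solve(cf, y)
    ViX = linalg.cho_solve(cf, X)
    XtViX = X.T @ ViX
    cfc = linalg.cho_factor(XtViX)
    ldC = 2.0 * np.sum(np.log(np.diag(cfc[0])))
    XtViy = X.T @ Viy
    b = linalg.cho_solve(cfc, XtViy)
    yPy = float(y @ Viy - XtViy @ b)
    return -0.5 * (ldV + ldC + yPy)


def _ai_iteration(y, X, Ks, theta):
    """One full AI-REML evaluation: loglik, scores, AI matrix, traces."""
    n = len(y)
    q = len(Ks)
    V = theta[-1] * np.eye(n)
    for t, K in zip(theta[:-1], Ks):
        V += t * K
    cf = linalg.cho_factor(V, lower=True)
    ldV = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Vinv = linalg.cho_solve(cf, np.eye(n))
    ViX = Vinv @ X
    XtViX = X.T @ ViX
    cfc = linalg.cho_factor(XtViX)
    ldC = 2.0 * np.sum(np.log(np.diag(cfc[0])))
    P = Vinv - ViX @ linalg.cho_solve(cfc, ViX.T)
    Py = P @ y
    ll = -0.5 * (ldV + ldC + float(y @ Py))
    # per-component quantities (residual kernel is the identity)
    T = np.empty((n, q + 1))
    trPK = np.empty(q + 1)
    for k, K in enumerate(Ks):
        T[:, k] = K @ Py
        trPK[k] = float(np.sum(P * K))
    T[:, q] = Py
    trPK[q] = float(np.trace(P))
    yPKPy = T.T @ Py
    score = -0.5 * (trPK - yPKPy)
    AI = 0.5 * (T.T @ (P @ T))
    return ll, score, AI, trPK, yPKPy


def _em_update(theta, trPK, yPKPy, n):
    return (theta ** 2 * yPKPy + theta * n - theta ** 2 * trPK) / n


def _fit_ai(y, X, Ks, names, max_iter=MAX_ITER, tol=LOGLIK_TOL,
            theta0=None):
    n, p = X.shape
    # initial phenotypic variance from OLS residuals
    b0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ b0
    varp0 = float(resid @ resid) / max(n - p, 1)
    bound = BOUND_FRACTION * varp0
    q = len(Ks)
    theta = (np.asarray(theta0, float) if theta0 is not None
             else np.full(q + 1, varp0 / (q + 1)))
    ll_prev = None
    converged = False
    it = 0
    AI = None
    for it in range(1, max_iter + 1):
        ll, score, AI, trPK, yPKPy = _ai_iteration(y, X, Ks, theta)
        if ll_prev is not None and abs(ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll
        em = np.maximum(_em_update(theta, trPK, yPKPy, n), bound)
        if it == 1:
            theta = em
            continue
        # active-set Newton direction: components pinned at the bound with
        # a negative score are frozen out of the AI solve
        pinned = (theta <= bound * (1 + 1e-9)) & (score < 0)
        free = ~pinned
        delta = np.zeros_like(theta)
        try:
            delta[free] = np.linalg.solve(AI[np.ix_(free, free)], score[free])
        except np.linalg.LinAlgError:
            theta = em
            continue
        # project AI proposals onto the bound; halve the step while the
        # loglik would drop, then fall back on the monotone EM update
        accepted = False
        for _ in range(8):
            prop = np.maximum(theta + delta, bound)
            if _loglik_at(y, X, Ks, prop) >= ll - 1e-10:
                accepted = True
                break
            delta = 0.5 * delta
        theta = prop if accepted else em
    if not converged:
        warnings.warn(f"AI-REML did not converge in {max_iter} iterations",
                      stacklevel=2)
    return theta, ll, AI, converged, it


def _se_from_ai(AI, theta):
    """Component SEs and the full covariance from the AI matrix."""
    try:
        cov = np.linalg.inv(AI)
        if (np.diag(cov) < 0).any():
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("singular average-information matrix; "
                      "standard errors unavailable", stacklevel=3)
        return None, np.full(len(theta), np.nan)
    return cov, np.sqrt(np.diag(cov))


def _ratio_se(theta, cov):
    """Delta-method SEs for ratios theta_k / sum(theta)."""
    tot = theta.sum()
    q1 = len(theta)
    if cov is None:
        return np.full(q1, np.nan)
    ses = np.empty(q1)
    for k in range(q1):
        g = -theta[k] / tot ** 2 * np.ones(q1)
        g[k] += 1.0 / tot
        ses[k] = np.sqrt(max(float(g @ cov @ g), 0.0))
    return ses


def _package(theta, ses, cov, names, ll, converged, n_iter, method):
    all_names = list(names) + ["residual"]
    tot = theta.sum()
    rse = _ratio_se(theta, cov)
    return VarianceEstimate(
        components=dict(zip(all_names, map(float, theta))),
        se=dict(zip(all_names, map(float, ses))),
        ratios={nm: float(theta[k] / tot) for k, nm in enumerate(names)},
        ratio_se={nm: float(rse[k]) for k, nm in enumerate(names)},
        loglik=float(ll),
        converged=bool(converged),
        n_iter=int(n_iter),
        method=method,
        kernel_names=tuple(names),
        cov=cov,
    )


# -- single-kernel eigendecomposition route ---------------------------------


def _profile_negll(log_delta, S, yr, Xr):
    n, p = Xr.shape
    w = S + np.exp(log_delta)
    if w.min() <= 0:
        return np.inf
    Xw = Xr / w[:, None]
    XtWX = Xr.T @ Xw
    sign, ldC = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(XtWX, Xw.T @ yr)
    r = yr - Xr @ beta
    rss = float(np.sum(r * r / w))
    sig_g = rss / (n - p)
    return 0.5 * ((n - p) * np.log(sig_g) + np.sum(np.log(w)) + ldC + (n - p))


def _single_ai_rotated(S, yr, Xr, sig_g, sig_e):
    """AI matrix for (sigma2_k, sigma2_e) in the rotated (diagonal) space."""
    v = sig_g * S + sig_e
    Xv = Xr / v[:, None]
    C = Xr.T @ Xv
    Cinv = np.linalg.inv(C)

    def Pdot(t):
        return t / v - Xv @ (Cinv @ (Xv.T @ t))

    Py = Pdot(yr)
    t_g = S * Py
    t_e = Py
    AI = 0.5 * np.array([
        [t_g @ Pdot(t_g), t_g @ Pdot(t_e)],
        [t_e @ Pdot(t_g), t_e @ Pdot(t_e)],
    ])
    return AI


def _fit_single_rotated(S, yr, Xr, name):
    """Profile-likelihood REML fit given pre-rotated data."""
    n, p = Xr.shape
    grid = np.linspace(np.log(1e-6), np.log(1e8), 57)
    vals = np.array([_profile_negll(g, S, yr, Xr) for g in grid])
    j = int(np.argmin(vals))
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        _profile_negll, bounds=(lo, hi), args=(S, yr, Xr), method="bounded",
        options={"xatol": 1e-10})
    log_delta = float(res.x)
    if vals[j] < res.fun:  # guard: keep the better of grid vs refine
        log_delta = float(grid[j])
    delta = np.exp(log_delta)
    w = S + delta
    Xw = Xr / w[:, None]
    XtWX = Xr.T @ Xw
    beta = np.linalg.solve(XtWX, Xw.T @ yr)
    r = yr - Xr @ beta
    sig_g = float(np.sum(r * r / w)) / (n - p)
    sig_e = delta * sig_g
    ll = -_profile_negll(log_delta, S, yr, Xr)
    theta = np.array([sig_g, sig_e])
    AI = _single_ai_rotated(S, yr, Xr, sig_g, sig_e)
    cov, ses = _se_from_ai(AI, theta)
    n_eval = int(res.nfev) + len(grid)
    return _package(theta, ses, cov, [name], ll, True, n_eval, "eigen")


def _fit_null(y, X):
    """Residual-only (fixed effects only) REML fit."""
    n, p = X.shape
    b, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ b
    rss = float(r @ r)
    sig_e = rss / (n - p)
    sign, ldXtX = np.linalg.slogdet(X.T @ X)
    ll = -0.5 * ((n - p) * np.log(sig_e) + ldXtX + (n - p))
    se = sig_e * np.sqrt(2.0 / (n - p))
    return VarianceEstimate(
        components={"residual": sig_e}, se={"residual": se},
        ratios={}, ratio_se={}, loglik=ll, converged=True, n_iter=0,
        method="closed-form", kernel_names=())


def fit_reml(y, X, kernels: dict, method: str = "auto",
             max_iter: int = MAX_ITER, tol: float = LOGLIK_TOL,
             theta0=None) -> VarianceEstimate:
    """REML fit of a mixed model with any number of named kernels.

    Parameters
    ----------
    y, X : response vector and full-rank fixed-effect design.
    kernels : mapping of name -> n x n relationship matrix (or Kernel).
    method : "auto" (eigendecomposition profile for one kernel, AI-REML for
        several), "eigen" (single kernel only) or "ai".
    """
    y = np.asarray(y, dtype=float)
    names = list(kernels.keys())
    Ks = [_as_matrix(kernels[nm]) for nm in names]
    n = len(y)
    for nm, K in zip(names, Ks):
        if K.shape != (n, n):
            raise ValueError(f"kernel {nm!r} has shape {K.shape}, expected "
                             f"({n}, {n})")
    if X.shape[0] != n:
        raise ValueError("design and response dimensions differ")
    if len(Ks) == 0:
        return _fit_null(y, X)
    if method == "eigen" and len(Ks) != 1:
        raise ValueError("eigen method supports exactly one kernel")
    if len(Ks) == 1 and method in ("auto", "eigen"):
        S, U = np.linalg.eigh(Ks[0])
        S = np.clip(S, 0.0, None)
        return _fit_single_rotated(S, U.T @ y, U.T @ X, names[0])
    theta, ll, AI, converged, n_iter = _fit_ai(
        y, X, Ks, names, max_iter=max_iter, tol=tol, theta0=theta0)
    cov, ses = _se_from_ai(AI, theta)
    return _package(theta, ses, cov, names, ll, converged, n_iter, "ai")


# ---------------------------------------------------------------------------
# inference helpers


@dataclass
class LrtResult:
    statistic: float
    p_value: float
    df: int = 1


def likelihood_ratio_test(null: VarianceEstimate,
                          full: VarianceEstimate) -> LrtResult:
    """Boundary likelihood-ratio test for one extra variance component.

    The null distribution is the 50:50 mixture of a point mass at zero and a
    chi-square with 1 df, because the component is tested on the boundary of
    its parameter space.
    """
    null_set = set(null.kernel_names)
    full_set = set(full.kernel_names)
    if not (null_set < full_set and len(full_set - null_set) == 1):
        raise ValueError(
            f"models are not nested with one extra component: "
            f"{null.kernel_names} vs {full.kernel_names}")
    stat = max(0.0, 2.0 * (full.loglik - null.loglik))
    p = 1.0 if stat <= 0 else 0.5 * float(stats.chi2.sf(stat, df=1))
    return LrtResult(statistic=stat, p_value=p)


def wald_interval(estimate: float, se: float, level: float = 0.95):
    """Normal-approximation confidence interval estimate +/- z * SE."""
    if not np.isfinite(se) or se <= 0:
        raise ValueError("standard error must be positive and finite")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return estimate - z * se, estimate + z * se


def wald_pvalue(estimate: float, se: float) -> float:
    """Two-sided normal p-value for estimate / SE."""
    if not np.isfinite(se) or se <= 0:
        raise ValueError("standard error must be positive and finite")
    return 2.0 * float(stats.norm.sf(abs(estimate) / se))


# ---------------------------------------------------------------------------
# per-taxon heritability scan


def taxon_heritability_scan(abund, metadata, A: Kernel,
                            include_batch: bool = True,
                            fdr_level: float = 0.15,
                            level: float = 0.95) -> pd.DataFrame:
    """Animal-model heritability of each taxon's log abundance.

    ``abund`` is an :class:`~microbiability.microbiome.AbundanceMatrix` of
    log-transformed relative abundances (samples x taxa).  Each taxon is fit
    as the response of the animal model with herd, parity, dim, the Wilmink
    term and (by default) sequencing batch nested in platform as fixed
    effects, and the pedigree kernel A as the single random effect.  Returns
    one row per taxon with h2, its SE, Wald CI and p-value, and
    Benjamini-Hochberg q-value.  Taxa whose fit fails are flagged
    (converged=False) and the scan continues.
    """
    from .association import bh_fdr  # local import avoids a cycle

    samples = list(abund.sample_ids)
    Asub = A.subset(samples)
    X, _ = build_design(metadata, include_herd=True,
                        include_batch=include_batch)
    if X.shape[0] != len(samples):
        raise ValueError("metadata rows do not match abundance samples")
    S, U = np.linalg.eigh(Asub.values)
    S = np.clip(S, 0.0, None)
    Xr = U.T @ X
    Yr = U.T @ abund.values
    rows = []
    for t, taxon in enumerate(abund.taxon_ids):
        try:
            est = _fit_single_rotated(S, Yr[:, t], Xr, "A")
            h2 = est.ratios["A"]
            se = est.ratio_se["A"]
            if np.isfinite(se) and se > 0:
                lo, hi = wald_interval(h2, se, level)
                p = wald_pvalue(h2, se)
            else:
                lo = hi = p = np.nan
            rows.append((taxon, est.components["A"], est.components["residual"],
                         h2, se, lo, hi, p, True))
        except Exception as exc:  # pragma: no cover - defensive path
            warnings.warn(f"taxon {taxon!r} failed: {exc}", stacklevel=2)
            rows.append((taxon, *[np.nan] * 7, False))
    df = pd.DataFrame(rows, columns=[
        "taxon_id", "sigma2_a", "sigma2_e", "h2", "se", "ci_low", "ci_high",
        "p", "converged"])
    ok = df["p"].notna()
    df["q"] = np.nan
    if ok.any():
        df.loc[ok, "q"] = bh_fdr(df.loc[ok, "p"].to_numpy(),
                                 q_level=fdr_level).qvalues
    return df
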