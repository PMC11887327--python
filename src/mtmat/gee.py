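"""Marginal (GEE) regression engine with small-sample-robust tests.

For one node covariate x (the GEE response, stacked over subjects and
visits) the marginal model is

    E(x | Z, y) = Z a + y b,    var(x | Z, y) = Sigma,

with Sigma block-diagonal over subjects and per-subject blocks
Sigma_i = sigma * D_i^{1/2} R_i D_i^{1/2}, where R_i is a working
correlation matrix (identity, compound symmetry, AR1, or unstructured) and
sigma an overdispersion scalar.  The association null H0: b = 0 is tested
with the generalized score statistic (score evaluated at the null GLS fit,
robust variance) and the robust Wald statistic, each with an optional
Mancl-DeRouen-style leverage correction that inflates per-subject residuals
by (I - P_ii)^{-1} to undo the small-sample downward bias of the sandwich.

Coefficient estimation iterates generalized least squares with moment
re-estimation of sigma and the correlation parameters from Pearson
residuals.  Subjects are grouped by their visit pattern so that all linear
algebra is batched; per-subject blocks are tiny (N_i <= a handful of
visits).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

__all__ = [
    "DesignData",
    "WorkingCorrelation",
    "CovarianceModel",
    "GeeFit",
    "fit_null",
    "score_test",
    "wald_test",
]

WC_STRUCTURES = ("identity", "CS", "AR1", "UN")

_TOL = 1e-8
_MAX_ITER = 200


class GeeError(RuntimeError):
    """Numerical failure inside the GEE engine."""


@dataclass
class WorkingCorrelation:
    """Working within-subject correlation structure.

    ``params`` holds the fitted parameters after estimation: a scalar rho for
    CS/AR1, a full matrix for UN, nothing for identity.
    """

    structure: str = "identity"
    params: object = None

    def __post_init__(self):
        if self.structure not in WC_STRUCTURES:
            raise ValueError(f"unknown working correlation {self.structure!r}")


@dataclass
class CovarianceModel:
    sigma_kk: float
    wc: WorkingCorrelation
    visit_variances: np.ndarray | None = None  # per-visit var when modelled


@dataclass
class GeeFit:
    alpha_hat: np.ndarray
    beta_hat: float | None
    cov: CovarianceModel
    V_hat: float | None = None
    T: float | None = None
    p: float | None = None
    df: int = 1
    converged: bool = True
    n_iter: int = 0
    # intermediates kept for validation against direct matrix oracles
    U: np.ndarray | None = None
    H: np.ndarray | None = None
    B: np.ndarray | None = None
    B_adj: np.ndarray | None = None


class DesignData:
    """Stacked per-sample data with contiguous, visit-ordered subject blocks.

    Parameters
    ----------
    x : response vector (the node covariate), length sum(N_i)
    Z : covariate design matrix including the intercept, shape (n, p)
    y : phenotype / exposure vector, length n
    subjects : subject label per row
    visits : integer visit index per row (1-based, ascending within subject)
    """

    def __init__(self, x, Z, y, subjects, visits=None):
        x = np.asarray(x, dtype=float)
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[0] != x.size:
            Z = Z.T
        y = np.asarray(y, dtype=float)
        subjects = np.asarray(subjects)
        n = x.size
        if not (Z.shape[0] == y.size == subjects.size == n):
            raise ValueError("row counts of x, Z, y, subjects disagree")
        if visits is None:
            # consecutive visits within each subject, in input order
            visits = np.zeros(n, dtype=int)
            seen: dict = {}
            for i, s in enumerate(subjects):
                seen[s] = seen.get(s, 0) + 1
                visits[i] = seen[s]
        visits = np.asarray(visits, dtype=int)

        # sort rows: subjects in first-appearance order, visits ascending
        first = {s: i for i, s in reversed(list(enumerate(subjects)))}
        order = np.lexsort((visits, [first[s] for s in subjects]))
        self.x = x[order]
        self.Z = Z[order]
        self.y = y[order]
        self.subjects = subjects[order]
        self.visits = visits[order]

        if np.linalg.matrix_rank(self.Z) < self.Z.shape[1]:
            raise ValueError("design matrix Z is rank deficient")

        # contiguous block slices per subject
        self.block_slices = []
        start = 0
        for i in range(1, n + 1):
            if i == n or self.subjects[i] != self.subjects[start]:
                self.block_slices.append(slice(start, i))
                start = i
        self.n_subjects = len(self.block_slices)
        self.n_obs = n
        self.p = self.Z.shape[1]

        # group subjects by visit pattern for batched linear algebra
        groups: dict = {}
        for sl in self.block_slices:
            key = tuple(self.visits[sl])
            groups.setdefault(key, []).append(sl)
        self._groups = [
            (np.array(key), np.array([[s.start + j for j in range(len(key))] for s in sls]))
            for key, sls in groups.items()
        ]

    @property
    def balanced_grid(self) -> np.ndarray | None:
        """Common visit grid if every subject shares one, else None."""
        if len(self._groups) == 1:
            return self._groups[0][0]
        return None


def _corr_matrix(structure: str, params, visits: np.ndarray) -> np.ndarray:
    n = visits.size
    if structure == "identity" or n == 1:
        return np.eye(n)
    if structure == "CS":
        rho = 0.0 if params is None else float(params)
        R = np.full((n, n), rho)
        np.fill_diagonal(R, 1.0)
        return R
    if structure == "AR1":
        rho = 0.0 if params is None else float(params)
        lag = np.abs(visits[:, None] - visits[None, :])
        return rho ** lag.astype(float)
    if structure == "UN":
        if params is None:
            return np.eye(n)
        return np.asarray(params)
    raise ValueError(structure)


def _estimate_params(data: DesignData, resid: np.ndarray, p_mean: int,
                     structure: str, visit_var: bool):
    """Moment estimators of sigma, correlation parameters and (optionally)
    per-visit variances from raw residuals."""
    n = data.n_obs
    dof = max(n - p_mean - 1, 1)
    sigma = float(resid @ resid) / dof
    if sigma <= 0 or not np.isfinite(sigma):
        raise GeeError("zero residual variance; covariate is degenerate")

    dvals = None
    e = resid.copy()
    if visit_var:
        grid = np.unique(data.visits)
        dvals = np.ones(grid.max() + 1)
        for v in grid:
            m = data.visits == v
            dvals[v] = max(resid[m].var(), 1e-12)
        e = resid / np.sqrt(dvals[data.visits])
        sigma = float(e @ e) / dof
    e = e / np.sqrt(sigma)

    params = None
    if structure == "CS":
        num = 0.0
        cnt = 0
        for _, idx in data._groups:
            ni = idx.shape[1]
            if ni < 2:
                continue
            eb = e[idx]  # (B, ni)
            tot = eb.sum(axis=1)
            num += float((tot**2 - (eb**2).sum(axis=1)).sum()) / 2.0
            cnt += idx.shape[0] * ni * (ni - 1) // 2
        params = num / cnt if cnt else 0.0
        nmax = max(idx.shape[1] for _, idx in data._groups)
        lo = -1.0 / (nmax - 1) + 1e-3 if nmax > 1 else -0.99
        params = float(np.clip(params, lo, 0.99))
    elif structure == "AR1":
        num = 0.0
        cnt = 0
        for visits, idx in data._groups:
            if visits.size < 2:
                continue
            lag1 = np.where(np.diff(visits) == 1)[0]
            if lag1.size == 0:
                continue
            eb = e[idx]
            num += float((eb[:, lag1] * eb[:, lag1 + 1]).sum())
            cnt += idx.shape[0] * lag1.size
        params = float(np.clip(num / cnt if cnt else 0.0, -0.99, 0.99))
    elif structure == "UN":
        grid = data.balanced_grid
        if grid is None:
            raise GeeError("unstructured correlation requires balanced data")
        eb = e[data._groups[0][1]]  # (N, n)
        C = eb.T @ eb / eb.shape[0]
        d = np.sqrt(np.clip(np.diag(C), 1e-12, None))
        R = C / np.outer(d, d)
        # ensure positive definiteness by eigenvalue clipping
        w, V = np.linalg.eigh(R)
        if w.min() < 1e-6:
            w = np.clip(w, 1e-6, None)
            R = V @ np.diag(w) @ V.T
            d = np.sqrt(np.diag(R))
            R = R / np.outer(d, d)
        params = R
    return sigma, params, dvals


def _group_weights(data: DesignData, structure: str, params, sigma: float,
                   dvals) -> list:
    """Per-group inverse covariance blocks W = Sigma_i^{-1} (shared within a
    visit-pattern group when D = I, per-subject otherwise)."""
    out = []
    for visits, idx in data._groups:
        R = _corr_matrix(structure, params, visits)
        if dvals is None:
            W = np.linalg.inv(R) / sigma  # (n, n), shared
            out.append((idx, W, False))
        else:
            d = np.sqrt(dvals[visits])
            Sig = sigma * (d[:, None] * R * d[None, :])
            W = np.linalg.inv(Sig)
            out.append((idx, W, False))
    return out


def _gls_fit(data: DesignData, M: np.ndarray, structure: str,
             visit_var: bool) -> tuple:
    """Iterated GLS of x on mean-design M with moment covariance updates.

    Returns (coef, sigma, params, dvals, n_iter, converged).
    """
    q = M.shape[1]
    coef = np.linalg.lstsq(M, data.x, rcond=None)[0]
    sigma, params, dvals = _estimate_params(
        data, data.x - M @ coef, data.p, structure, visit_var)
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        wblocks = _group_weights(data, structure, params, sigma, dvals)
        A = np.zeros((q, q))
        b = np.zeros(q)
        for idx, W, _ in wblocks:
            Mg = M[idx]          # (B, n, q)
            xg = data.x[idx]     # (B, n)
            WM = np.einsum("nm,bmq->bnq", W, Mg)
            A += np.einsum("bnq,bnr->qr", Mg, WM)
            b += np.einsum("bnq,bn->q", WM, xg)
        try:
            new = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:
            raise GeeError(f"singular GLS system: {exc}") from None
        est_sigma, est_params, est_dvals = _estimate_params(
            data, data.x - M @ new, data.p, structure, visit_var)
        # damped update of the covariance parameters: the plain fixed-point
        # map can enter a 2-cycle on small samples; averaging halves the map
        # without moving its fixed point.  The unstructured matrix is frozen
        # at its initial estimate — with O(n^2) free entries the joint
        # iteration with the mean fit can diverge at small N, and the
        # sandwich keeps inference valid under any fixed working correlation
        new_sigma = 0.5 * (sigma + est_sigma)
        dp = 0.0
        new_params = est_params
        if structure in ("CS", "AR1"):
            new_params = 0.5 * ((params or 0.0) + (est_params or 0.0))
            dp = abs(new_params - (params or 0.0))
        elif structure == "UN":
            new_params = params
        new_dvals = est_dvals
        if visit_var and dvals is not None:
            new_dvals = 0.5 * (dvals + est_dvals)
        delta = float(np.abs(new - coef).max())
        dp = max(dp, abs(new_sigma - sigma))
        coef, sigma, params, dvals = new, new_sigma, new_params, new_dvals
        if delta < _TOL and dp < _TOL:
            converged = True
            break
    if not converged:
        raise GeeError(f"GLS iteration did not converge in {_MAX_ITER} steps")
    return coef, sigma, params, dvals, it, converged


def fit_null(data: DesignData, wc: WorkingCorrelation,
             visit_variances: bool = False):
    """Fit the null mean model E(x) = Z a (b fixed at 0) by iterated GLS.

    Returns (alpha_hat, CovarianceModel) with the correlation parameters and
    overdispersion estimated from the null residuals.
    """
    coef, sigma, params, dvals, n_iter, _ = _gls_fit(
        data, data.Z, wc.structure, visit_variances)
    cov = CovarianceModel(
        sigma_kk=sigma,
        wc=WorkingCorrelation(wc.structure, params),
        visit_variances=dvals,
    )
    return coef, cov


def _default_contrast(p: int) -> np.ndarray:
    L = np.zeros((1, p + 1))
    L[0, -1] = 1.0
    return L


def score_test(data: DesignData, wc: WorkingCorrelation,
               small_sample: bool = True, L: np.ndarray | None = None,
               visit_variances: bool = False) -> GeeFit:
    """Generalized score test of H0: b = 0 (or H0: L theta = 0).

    The score U is evaluated at the null GLS fit (a = a_hat, b = 0); the
    statistic is

        T = U' H^-1 L' (L H^-1 B H^-1 L')^-1 L H^-1 U  ~  chi2(c)

    with H the quasi-information of the joint design D_i = [Z_i y_i] and B
    the empirical (robust) score covariance.  With ``small_sample`` the
    per-subject scores are built from leverage-inflated residuals
    (I - P_ii)^{-1} S_i, with the leverage computed under the
    null-constrained information.
    """
    alpha, cov = fit_null(data, wc, visit_variances)
    sigma, params, dvals = cov.sigma_kk, cov.wc.params, cov.visit_variances
    p = data.p
    if L is None:
        L = _default_contrast(p)
    L = np.atleast_2d(np.asarray(L, dtype=float))
    c = L.shape[0]

    wblocks = _group_weights(data, wc.structure, params, sigma, dvals)
    q = p + 1
    H = np.zeros((q, q))
    U = np.zeros(q)
    Ui_all = []   # per-subject scores, per group
    Dg_all = []
    Sg_all = []
    Wg_all = []
    for idx, W, _ in wblocks:
        Dg = np.concatenate([data.Z[idx], data.y[idx][:, :, None]], axis=2)
        Sg = data.x[idx] - np.einsum("bnp,p->bn", data.Z[idx], alpha)
        WD = np.einsum("nm,bmq->bnq", W, Dg)
        H += np.einsum("bnq,bnr->qr", Dg, WD)
        Ug = np.einsum("bnq,bn->bq", WD, Sg)
        U += Ug.sum(axis=0)
        Ui_all.append(Ug)
        Dg_all.append(Dg)
        Sg_all.append(Sg)
        Wg_all.append(W)

    try:
        Hinv = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise GeeError(f"singular quasi-information: {exc}") from None

    B = np.zeros((q, q))
    if not small_sample:
        for Ug in Ui_all:
            B += np.einsum("bq,br->qr", Ug, Ug)
    else:
        # null-constrained covariance of the estimator: H^-1 projected off L
        LH = L @ Hinv
        Mc = Hinv - LH.T @ np.linalg.solve(LH @ L.T, LH)
        for Dg, Sg, W in zip(Dg_all, Sg_all, Wg_all):
            ni = Dg.shape[1]
            DMD = np.einsum("bnq,qr,bmr->bnm", Dg, Mc, Dg)
            P = DMD @ W  # (B, n, n) leverage blocks
            try:
                Sadj = np.linalg.solve(np.eye(ni)[None] - P, Sg[:, :, None])[..., 0]
            except np.linalg.LinAlgError as exc:
                raise GeeError(f"singular leverage factor: {exc}") from None
            Uadj = np.einsum("nm,bmq,bn->bq", W, Dg, Sadj)
            B += np.einsum("bq,br->qr", Uadj, Uadj)

    LHU = L @ (Hinv @ U)
    mid = L @ Hinv @ B @ Hinv @ L.T
    try:
        T = float(LHU @ np.linalg.solve(mid, LHU))
    except np.linalg.LinAlgError:
        raise GeeError("degenerate variance in score statistic") from None
    if T < 0 or not np.isfinite(T):
        raise GeeError("degenerate variance in score statistic")
    return GeeFit(
        alpha_hat=alpha, beta_hat=None, cov=cov, T=T, df=c,
        p=float(chi2.sf(T, df=c)), U=U, H=H, B=B,
        B_adj=B if small_sample else None,
    )


def wald_test(data: DesignData, wc: WorkingCorrelation,
              small_sample: bool = True,
              visit_variances: bool = False) -> GeeFit:
    """Robust Wald test of H0: b = 0 from the joint GLS fit of (a, b).

    b_hat solves the quasi-score equations jointly with a_hat; its variance
    is the sandwich V = c^-1 B c^-1 with c = sum_i y_i' Sigma_i^-1 y_i and B
    built from the robust per-subject covariance of x_i, leverage-corrected
    by (I - P_ii)^{-1} when ``small_sample`` is on.  T = b_hat^2 / V ~ chi2(1).
    """
    if np.ptp(data.y) == 0:
        raise GeeError("phenotype has no variance")
    M = np.column_stack([data.Z, data.y])
    coef, sigma, params, dvals, n_iter, _ = _gls_fit(
        data, M, wc.structure, visit_variances)
    alpha, beta = coef[:-1], float(coef[-1])
    cov = CovarianceModel(sigma_kk=sigma,
                          wc=WorkingCorrelation(wc.structure, params),
                          visit_variances=dvals)

    # The sandwich for beta_hat needs the phenotype with the Z-covariates
    # partialled out under the working metric (Frisch-Waugh): with the raw
    # y the scalar y' Sigma^-1 y overstates the information about beta and
    # the Wald test is anticonservative by roughly the phenotype's R^2 on Z.
    wblocks = _group_weights(data, wc.structure, params, sigma, dvals)
    ZWZ = np.zeros((data.p, data.p))
    ZWy = np.zeros(data.p)
    for idx, W, _ in wblocks:
        Zg = data.Z[idx]
        WZ = np.einsum("nm,bmq->bnq", W, Zg)
        ZWZ += np.einsum("bnq,bnr->qr", Zg, WZ)
        ZWy += np.einsum("bnq,bn->q", WZ, data.y[idx])
    ytilde = data.y - data.Z @ np.linalg.solve(ZWZ, ZWy)

    cscal = 0.0
    for idx, W, _ in wblocks:
        yg = ytilde[idx]
        cscal += float(np.einsum("bn,nm,bm->", yg, W, yg))
    if cscal <= 0:
        raise GeeError("phenotype has no variance under the weight metric")

    B = 0.0
    for idx, W, _ in wblocks:
        yg = ytilde[idx]
        eg = data.x[idx] - np.einsum("bnp,p->bn", data.Z[idx], alpha)
        if small_sample:
            ni = yg.shape[1]
            # P_ii = y_i (sum y'Wy)^-1 y_i' W
            P = (yg[:, :, None] * yg[:, None, :] / cscal) @ W
            eg = np.linalg.solve(np.eye(ni)[None] - P, eg[:, :, None])[..., 0]
        a = np.einsum("bn,nm,bm->b", yg, W, eg)
        B += float((a * a).sum())

    V = B / cscal**2
    if V <= 0 or not np.isfinite(V):
        raise GeeError("degenerate Wald variance")
    T = beta**2 / V
    return GeeFit(
        alpha_hat=alpha, beta_hat=beta, cov=cov, V_hat=V, T=float(T), df=1,
        p=float(chi2.sf(T, df=1)), n_iter=n_iter, B=np.array([[B]]),
        B_adj=np.array([[B]]) if small_sample else None,
    )
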