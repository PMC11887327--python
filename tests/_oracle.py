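"""Direct dense-matrix transcription of the GEE score/Wald formulas.

This is the independent oracle for the engine in ``mtmat.gee``: every
quantity is assembled literally from the printed estimating equations using
full stacked matrices, block-diagonal covariance built subject by subject,
and plain ``np.linalg.inv`` — no batching, no grouping, no shared code with
the implementation.  The moment estimators for the overdispersion and the
working-correlation parameters follow the same definitions (Pearson
residual moments with n - p - 1 degrees of freedom) so both routes iterate
to the same fixed point.
"""

import numpy as np

TOL = 1e-8
MAX_ITER = 200


def subject_blocks(subjects):
    """Index arrays per subject, in order of first appearance."""
    order = list(dict.fromkeys(subjects))
    return [np.where(np.asarray(subjects) == s)[0] for s in order]


def corr_matrix(structure, params, visits):
    n = len(visits)
    if structure == "identity" or n == 1:
        return np.eye(n)
    if structure == "CS":
        rho = 0.0 if params is None else params
        return np.eye(n) * (1 - rho) + rho * np.ones((n, n))
    if structure == "AR1":
        rho = 0.0 if params is None else params
        R = np.empty((n, n))
        for a in range(n):
            for b in range(n):
                R[a, b] = rho ** abs(visits[a] - visits[b])
        return R
    if structure == "UN":
        return np.eye(n) if params is None else np.asarray(params)
    raise ValueError(structure)


def estimate_params(resid, blocks, visits_list, p, structure):
    n = resid.size
    sigma = float(resid @ resid) / max(n - p - 1, 1)
    e = resid / np.sqrt(sigma)
    params = None
    if structure == "CS":
        num, cnt = 0.0, 0
        for blk in blocks:
            eb = e[blk]
            for a in range(len(blk)):
                for b in range(a + 1, len(blk)):
                    num += eb[a] * eb[b]
                    cnt += 1
        params = num / cnt if cnt else 0.0
        nmax = max(len(b) for b in blocks)
        lo = -1.0 / (nmax - 1) + 1e-3 if nmax > 1 else -0.99
        params = float(np.clip(params, lo, 0.99))
    elif structure == "AR1":
        num, cnt = 0.0, 0
        for blk, vis in zip(blocks, visits_list):
            eb = e[blk]
            for a in range(len(blk) - 1):
                if vis[a + 1] - vis[a] == 1:
                    num += eb[a] * eb[a + 1]
                    cnt += 1
        params = float(np.clip(num / cnt if cnt else 0.0, -0.99, 0.99))
    elif structure == "UN":
        sizes = {len(b) for b in blocks}
        if len(sizes) != 1:
            raise ValueError("UN needs balanced data")
        E = np.vstack([e[blk] for blk in blocks])
        C = E.T @ E / E.shape[0]
        d = np.sqrt(np.clip(np.diag(C), 1e-12, None))
        R = C / np.outer(d, d)
        w, V = np.linalg.eigh(R)
        if w.min() < 1e-6:
            w = np.clip(w, 1e-6, None)
            R = V @ np.diag(w) @ V.T
            d = np.sqrt(np.diag(R))
            R = R / np.outer(d, d)
        params = R
    return sigma, params


def big_sigma(blocks, visits_list, structure, params, sigma, n):
    S = np.zeros((n, n))
    for blk, vis in zip(blocks, visits_list):
        S[np.ix_(blk, blk)] = sigma * corr_matrix(structure, params, vis)
    return S


def gls_iterate(x, M, blocks, visits_list, p, structure):
    """Iterated GLS with moment re-estimation; same fixed-point map as the
    engine, assembled densely."""
    coef = np.linalg.lstsq(M, x, rcond=None)[0]
    sigma, params = estimate_params(x - M @ coef, blocks, visits_list, p, structure)
    n = x.size
    for _ in range(MAX_ITER):
        S = big_sigma(blocks, visits_list, structure, params, sigma, n)
        Sinv = np.linalg.inv(S)
        new = np.linalg.inv(M.T @ Sinv @ M) @ (M.T @ Sinv @ x)
        est_sigma, est_params = estimate_params(
            x - M @ new, blocks, visits_list, p, structure)
        # damped parameter update, averaging with the previous iterate (the
        # same halved fixed-point map as the engine); the unstructured
        # matrix stays frozen at its initial estimate
        new_sigma = 0.5 * (sigma + est_sigma)
        dp = 0.0
        new_params = est_params
        if structure in ("CS", "AR1"):
            new_params = 0.5 * ((params or 0.0) + (est_params or 0.0))
            dp = abs(new_params - (params or 0.0))
        elif structure == "UN":
            new_params = params
        delta = float(np.abs(new - coef).max())
        dp = max(dp, abs(new_sigma - sigma))
        coef, sigma, params = new, new_sigma, new_params
        if delta < TOL and dp < TOL:
            return coef, sigma, params
    raise RuntimeError("oracle GLS did not converge")


def score_oracle(x, Z, y, subjects, visits, structure, small_sample):
    """Null fit, then the generalized score statistic with literal formulas.

    Returns dict with alpha, H, B, T.
    """
    x = np.asarray(x, float)
    Z = np.asarray(Z, float)
    y = np.asarray(y, float)
    n, p = Z.shape
    blocks = subject_blocks(subjects)
    visits_list = [list(np.asarray(visits)[blk]) for blk in blocks]
    alpha, sigma, params = gls_iterate(x, Z, blocks, visits_list, p, structure)

    S = big_sigma(blocks, visits_list, structure, params, sigma, n)
    D = np.column_stack([Z, y])
    L = np.zeros((1, p + 1))
    L[0, -1] = 1.0

    H = np.zeros((p + 1, p + 1))
    U = np.zeros(p + 1)
    Ui = []
    for blk in blocks:
        Si = S[np.ix_(blk, blk)]
        Di = D[blk]
        ri = x[blk] - Z[blk] @ alpha
        ui = Di.T @ np.linalg.inv(Si) @ ri
        H += Di.T @ np.linalg.inv(Si) @ Di
        U += ui
        Ui.append((blk, Si, Di, ri, ui))

    Hinv = np.linalg.inv(H)
    if not small_sample:
        B = sum(np.outer(u, u) for _, _, _, _, u in Ui)
    else:
        Mc = Hinv - Hinv @ L.T @ np.linalg.inv(L @ Hinv @ L.T) @ L @ Hinv
        B = np.zeros((p + 1, p + 1))
        for blk, Si, Di, ri, _ in Ui:
            Sinv_i = np.linalg.inv(Si)
            P = Di @ Mc @ Di.T @ Sinv_i
            A = np.linalg.inv(np.eye(len(blk)) - P)
            u = Di.T @ Sinv_i @ A @ ri
            B += np.outer(u, u)

    mid = L @ Hinv @ B @ Hinv @ L.T
    lhu = L @ Hinv @ U
    T = float(lhu @ np.linalg.inv(mid) @ lhu)
    return {"alpha": alpha, "H": H, "B": B, "T": T,
            "sigma": sigma, "params": params}


def wald_oracle(x, Z, y, subjects, visits, structure, small_sample):
    """Joint fit, then beta_hat and the leverage-corrected sandwich."""
    x = np.asarray(x, float)
    Z = np.asarray(Z, float)
    y = np.asarray(y, float)
    n, p = Z.shape
    blocks = subject_blocks(subjects)
    visits_list = [list(np.asarray(visits)[blk]) for blk in blocks]
    M = np.column_stack([Z, y])
    coef, sigma, params = gls_iterate(x, M, blocks, visits_list, p, structure)
    alpha, beta = coef[:-1], float(coef[-1])

    S = big_sigma(blocks, visits_list, structure, params, sigma, n)
    Sinv = np.linalg.inv(S)
    # phenotype with Z partialled out under the working metric
    yt = y - Z @ (np.linalg.inv(Z.T @ Sinv @ Z) @ (Z.T @ Sinv @ y))
    c = 0.0
    for blk in blocks:
        Si = S[np.ix_(blk, blk)]
        c += float(yt[blk] @ np.linalg.inv(Si) @ yt[blk])

    B = 0.0
    for blk in blocks:
        Si = S[np.ix_(blk, blk)]
        Sinv_i = np.linalg.inv(Si)
        ei = x[blk] - Z[blk] @ alpha
        if small_sample:
            P = np.outer(yt[blk], yt[blk]) @ Sinv_i / c
            ei = np.linalg.inv(np.eye(len(blk)) - P) @ ei
        a = float(yt[blk] @ Sinv_i @ ei)
        B += a * a
    V = B / c**2
    return {"beta": beta, "V": V, "T": beta**2 / V, "alpha": alpha}
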