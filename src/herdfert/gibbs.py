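"""Gibbs sampler for multi-trait linear/threshold animal models.

One compiled kernel runs the whole chain so a single seeded random stream
governs every draw (bitwise reproducibility under a fixed seed).  Per cycle:

1. data augmentation — latent liabilities of binary records are drawn from
   truncated normals on the side of the zero threshold given their observed
   category (1 = below, 2 = above); missing trait values are drawn from
   their conditional Gaussians given the record's other traits;
2. location effects (fixed effects, additive values, permanent-environment
   effects) are drawn from Gaussian full conditionals by single-site sweeps
   over the sparse mixed-model structure;
3. the additive covariance G0 is drawn from an inverse-Wishart with scale
   a' A^-1 a, and the permanent-environment covariance P0 from pe' pe;
4. the residual covariance R0 is drawn from an inverse-Wishart on e' e when
   all traits are linear.  When threshold traits are present their residual
   variances are fixed at 1 (liability identifiability) and their residual
   covariances with each other at 0; the free elements — the linear block
   and the linear-threshold covariances — are drawn exactly from the
   conjugate regression factorization e_linear | e_threshold ~
   N(Gamma' e_threshold, Omega) with Omega inverse-Wishart and Gamma
   matrix-normal, and R0 is reassembled as
   [[Omega + Gamma' Gamma, Gamma'], [Gamma, I]].

The kernel aborts with the cycle index if a scale matrix loses positive
definiteness.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_chain", "GibbsError"]


class GibbsError(RuntimeError):
    pass


@njit(cache=True)
def _std_tnorm_lower(b):
    """z ~ N(0,1) conditional on z > b (Robert's exponential rejection in the tail)."""
    if b < 0.4:
        while True:
            z = np.random.standard_normal()
            if z > b:
                return z
    lam = 0.5 * (b + np.sqrt(b * b + 4.0))
    while True:
        z = b - np.log(np.random.random()) / lam
        if np.random.random() <= np.exp(-0.5 * (z - lam) * (z - lam)):
            return z


@njit(cache=True)
def _inv_wishart(df, S):
    """Draw from InvWishart(df, S) by the Bartlett decomposition."""
    t = S.shape[0]
    Sinv = np.linalg.inv(S)
    L = np.linalg.cholesky(0.5 * (Sinv + Sinv.T))
    A = np.zeros((t, t))
    for i in range(t):
        A[i, i] = np.sqrt(np.random.chisquare(df - i))
        for j in range(i):
            A[i, j] = np.random.standard_normal()
    LA = L @ A
    W = LA @ LA.T
    X = np.linalg.inv(W)
    return 0.5 * (X + X.T)


@njit(cache=True)
def _min_eig(S):
    return np.linalg.eigvalsh(0.5 * (S + S.T))[0]


@njit(cache=True)
def _gibbs_kernel(
    y,
    status,
    eff_trait,
    eff_offset,
    eff_levels,
    cov_trait,
    cov_x,
    rec_animal,
    an_indptr,
    an_recs,
    pe_indptr,
    pe_recs,
    pe_traits,
    ai_indptr,
    ai_indices,
    ai_data,
    is_thresh,
    G0,
    P0,
    R0,
    nu_g,
    S_g,
    nu_p,
    S_p,
    nu_r,
    S_r,
    n_iter,
    burn_in,
    thin,
    seed,
    save_G,
    save_P,
    save_R,
):
    np.random.seed(seed)
    n, t = y.shape
    q = an_indptr.shape[0] - 1
    npe = pe_indptr.shape[0] - 1
    tpe = pe_traits.shape[0]
    n_eff = eff_trait.shape[0]
    n_cov = cov_trait.shape[0]

    beta = np.zeros(eff_offset[n_eff] if n_eff > 0 else 0)
    betac = np.zeros(n_cov)
    a = np.zeros((q, t))
    pe = np.zeros((npe, tpe)) if tpe > 0 else np.zeros((1, 1))
    e = y.copy()
    slot = 0

    for it in range(1, n_iter + 1):
        rinv = np.linalg.inv(R0)

        # --- 1. augmentation (missing values and liabilities) -------------
        for i in range(n):
            for k in range(t):
                st = status[i, k]
                if st == 0:
                    continue
                s = 0.0
                for m in range(t):
                    s += rinv[k, m] * e[i, m]
                cm = e[i, k] - s / rinv[k, k]
                sd = 1.0 / np.sqrt(rinv[k, k])
                mu = y[i, k] - e[i, k]
                if st == 1:
                    enew = cm + sd * np.random.standard_normal()
                elif st == 2:  # category 1 = no: liability below 0
                    enew = cm - sd * _std_tnorm_lower((cm + mu) / sd)
                else:  # category 2 = yes: liability above 0
                    enew = cm + sd * _std_tnorm_lower((-mu - cm) / sd)
                y[i, k] = mu + enew
                e[i, k] = enew

        # --- 2. fixed-effect factors (block per factor) --------------------
        for j in range(n_eff):
            k = eff_trait[j]
            off = eff_offset[j]
            L = eff_offset[j + 1] - off
            num = np.zeros(L)
            cnt = np.zeros(L)
            for i in range(n):
                l = eff_levels[j, i]
                if l < 0:
                    continue
                e[i, k] += beta[off + l]
                s = 0.0
                for m in range(t):
                    s += rinv[k, m] * e[i, m]
                num[l] += s
                cnt[l] += 1.0
            for l in range(L):
                if cnt[l] > 0.0:
                    prec = cnt[l] * rinv[k, k]
                    beta[off + l] = num[l] / prec + np.random.standard_normal() / np.sqrt(prec)
            for i in range(n):
                l = eff_levels[j, i]
                if l >= 0:
                    e[i, k] -= beta[off + l]

        # --- covariates -----------------------------------------------------
        for c in range(n_cov):
            k = cov_trait[c]
            num = 0.0
            den = 0.0
            for i in range(n):
                x = cov_x[c, i]
                if x == 0.0:
                    continue
                e[i, k] += x * betac[c]
                s = 0.0
                for m in range(t):
                    s += rinv[k, m] * e[i, m]
                num += x * s
                den += x * x
            if den > 0.0:
                prec = den * rinv[k, k]
                betac[c] = num / prec + np.random.standard_normal() / np.sqrt(prec)
            for i in range(n):
                x = cov_x[c, i]
                if x != 0.0:
                    e[i, k] -= x * betac[c]

        # --- 3. additive effects (single site, sparse A^-1 prior) ----------
        ginv = np.linalg.inv(G0)
        rowdot = np.zeros(t)
        for j in range(q):
            aii = 0.0
            for m in range(t):
                rowdot[m] = 0.0
            for idx in range(ai_indptr[j], ai_indptr[j + 1]):
                l = ai_indices[idx]
                w = ai_data[idx]
                if l == j:
                    aii = w
                for m in range(t):
                    rowdot[m] += w * a[l, m]
            nj = an_indptr[j + 1] - an_indptr[j]
            for k in range(t):
                num = 0.0
                for rr in range(an_indptr[j], an_indptr[j + 1]):
                    i = an_recs[rr]
                    e[i, k] += a[j, k]
                    s = 0.0
                    for m in range(t):
                        s += rinv[k, m] * e[i, m]
                    num += s
                pnum = 0.0
                for m in range(t):
                    pnum += ginv[k, m] * rowdot[m]
                pnum -= ginv[k, k] * aii * a[j, k]
                lhs = nj * rinv[k, k] + ginv[k, k] * aii
                anew = (num - pnum) / lhs + np.random.standard_normal() / np.sqrt(lhs)
                rowdot[k] += aii * (anew - a[j, k])
                a[j, k] = anew
                for rr in range(an_indptr[j], an_indptr[j + 1]):
                    e[an_recs[rr], k] -= anew

        # --- permanent environment -----------------------------------------
        if tpe > 0:
            pinv = np.linalg.inv(P0)
            for j in range(npe):
                nj = pe_indptr[j + 1] - pe_indptr[j]
                for kp in range(tpe):
                    k = pe_traits[kp]
                    num = 0.0
                    for rr in range(pe_indptr[j], pe_indptr[j + 1]):
                        i = pe_recs[rr]
                        e[i, k] += pe[j, kp]
                        s = 0.0
                        for m in range(t):
                            s += rinv[k, m] * e[i, m]
                        num += s
                    pnum = 0.0
                    for mp in range(tpe):
                        pnum += pinv[kp, mp] * pe[j, mp]
                    pnum -= pinv[kp, kp] * pe[j, kp]
                    lhs = nj * rinv[k, k] + pinv[kp, kp]
                    penew = (num - pnum) / lhs + np.random.standard_normal() / np.sqrt(lhs)
                    pe[j, kp] = penew
                    for rr in range(pe_indptr[j], pe_indptr[j + 1]):
                        e[pe_recs[rr], k] -= penew

        # --- 4. covariance matrices ----------------------------------------
        Sg = S_g.copy()
        for j in range(q):
            for idx in range(ai_indptr[j], ai_indptr[j + 1]):
                l = ai_indices[idx]
                w = ai_data[idx]
                for k in range(t):
                    for m in range(t):
                        Sg[k, m] += w * a[j, k] * a[l, m]
        if _min_eig(Sg) <= 0.0:
            return it
        G0[:, :] = _inv_wishart(nu_g + q, Sg)

        if tpe > 0:
            Sp = S_p.copy()
            for j in range(npe):
                for kp in range(tpe):
                    for mp in range(tpe):
                        Sp[kp, mp] += pe[j, kp] * pe[j, mp]
            if _min_eig(Sp) <= 0.0:
                return it
            P0[:, :] = _inv_wishart(nu_p + npe, Sp)

        # --- residual covariance ---------------------------------------------
        n_th = 0
        for k in range(t):
            if is_thresh[k] != 0:
                n_th += 1
        if n_th == 0:
            Sr = S_r.copy()
            for i in range(n):
                for k in range(t):
                    for m in range(t):
                        Sr[k, m] += e[i, k] * e[i, m]
            if _min_eig(Sr) <= 0.0:
                return it
            R0[:, :] = _inv_wishart(nu_r + n, Sr)
        elif n_th < t:
            # regression factorization: e_lin | e_thresh, thresholds N(0, I)
            n_lin = t - n_th
            lin = np.empty(n_lin, dtype=np.int64)
            th = np.empty(n_th, dtype=np.int64)
            il = 0
            ith = 0
            for k in range(t):
                if is_thresh[k] != 0:
                    th[ith] = k
                    ith += 1
                else:
                    lin[il] = k
                    il += 1
            DtD = np.zeros((n_th, n_th))
            DtY = np.zeros((n_th, n_lin))
            YtY = np.zeros((n_lin, n_lin))
            for i in range(n):
                for u in range(n_th):
                    eu = e[i, th[u]]
                    for v in range(n_th):
                        DtD[u, v] += eu * e[i, th[v]]
                    for w in range(n_lin):
                        DtY[u, w] += eu * e[i, lin[w]]
                for w in range(n_lin):
                    ew = e[i, lin[w]]
                    for w2 in range(n_lin):
                        YtY[w, w2] += ew * e[i, lin[w2]]
            if _min_eig(DtD) <= 0.0:
                return it
            Gam_hat = np.linalg.solve(DtD, DtY)  # (n_th, n_lin)
            Som = YtY - Gam_hat.T @ DtY
            for w in range(n_lin):
                for w2 in range(n_lin):
                    Som[w, w2] += S_r[lin[w], lin[w2]]
            if _min_eig(Som) <= 0.0:
                return it
            Om = _inv_wishart(nu_r + n - n_th, Som)
            Ld = np.linalg.cholesky(np.linalg.inv(DtD))
            Lo = np.linalg.cholesky(Om)
            Z = np.empty((n_th, n_lin))
            for u in range(n_th):
                for w in range(n_lin):
                    Z[u, w] = np.random.standard_normal()
            Gam = Gam_hat + Ld @ Z @ Lo.T
            Rll = Om + Gam.T @ Gam
            for w in range(n_lin):
                for w2 in range(n_lin):
                    R0[lin[w], lin[w2]] = Rll[w, w2]
                for u in range(n_th):
                    R0[lin[w], th[u]] = Gam[u, w]
                    R0[th[u], lin[w]] = Gam[u, w]
            for u in range(n_th):
                for v in range(n_th):
                    R0[th[u], th[v]] = 1.0 if u == v else 0.0
        # else: all traits are thresholds -> R0 stays fixed at the identity

        # --- 6. save ---------------------------------------------------------
        if it > burn_in and (it - burn_in) % thin == 0:
            save_G[slot] = G0
            save_R[slot] = R0
            if tpe > 0:
                save_P[slot] = P0
            slot += 1
    return 0


def run_chain(design, G0, P0, R0, priors, n_iter, burn_in, thin, seed):
    """Run one chain on a prepared design; returns (G, P, R) sample arrays.

    ``design`` is the dict produced by :meth:`AnimalModel._build_design`.
    Raises :class:`GibbsError` (with the cycle index) if a scale matrix is
    not positive definite at some cycle.
    """
    if burn_in >= n_iter:
        raise ValueError("burn_in must be smaller than the chain length")
    if thin < 1:
        raise ValueError("thinning interval must be >= 1")
    t = design["y"].shape[1]
    tpe = len(design["pe_traits"])
    n_save = (n_iter - burn_in) // thin
    if n_save < 1:
        raise ValueError("chain configuration saves no samples")
    save_G = np.empty((n_save, t, t))
    save_R = np.empty((n_save, t, t))
    save_P = np.empty((n_save, max(tpe, 1), max(tpe, 1)))
    y = design["y"].copy()
    G0 = np.array(G0, dtype=float, copy=True)
    R0 = np.array(R0, dtype=float, copy=True)
    # initial R0 must respect the threshold structure (unit variance,
    # zero residual covariance among threshold traits)
    th = np.flatnonzero(design["is_thresh"])
    for u in th:
        for v in th:
            R0[u, v] = 1.0 if u == v else 0.0
    P0 = np.array(P0, dtype=float, copy=True) if tpe > 0 else np.ones((1, 1))
    nu_g, S_g, nu_p, S_p, nu_r, S_r = priors
    code = _gibbs_kernel(
        y,
        design["status"],
        design["eff_trait"],
        design["eff_offset"],
        design["eff_levels"],
        design["cov_trait"],
        design["cov_x"],
        design["rec_animal"],
        design["an_indptr"],
        design["an_recs"],
        design["pe_indptr"],
        design["pe_recs"],
        design["pe_traits"],
        design["ai_indptr"],
        design["ai_indices"],
        design["ai_data"],
        design["is_thresh"],
        G0,
        P0,
        R0,
        float(nu_g),
        np.asarray(S_g, dtype=float),
        float(nu_p),
        np.asarray(S_p, dtype=float) if tpe > 0 else np.ones((1, 1)),
        float(nu_r),
        np.asarray(S_r, dtype=float),
        int(n_iter),
        int(burn_in),
        int(thin),
        int(seed),
        save_G,
        save_P,
        save_R,
    )
    if code != 0:
        raise GibbsError(f"non-positive-definite scale matrix at cycle {code}")
    return save_G, (save_P if tpe > 0 else None), save_R
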