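"""Average-information REML for all-linear multi-trait animal models.

A dense-likelihood implementation intended as the deterministic cross-check
for the Gibbs sampler at desk scale: the phenotypic covariance
``V = A_rec (x) G0 + Pe (x) P0 + I (x) R0`` is formed explicitly (records x
traits), so the method is limited to a few thousand record-trait cells.
Updates are Newton steps with the average-information matrix, with
step-halving back into the parameter space when a step leaves it; the
asymptotic covariance of the estimates is the inverse AI matrix at
convergence.

Threshold (categorical) traits are not supported here — that is exactly the
limitation that motivates the Gibbs path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

__all__ = ["ai_reml", "REMLFit", "REMLError"]


class REMLError(RuntimeError):
    pass


@dataclass
class REMLFit:
    """Variance-component estimates from AI-REML.

    ``param_names`` orders the free parameters (upper triangles of G0, P0,
    R0); ``param_cov`` is their asymptotic covariance (inverse AI).
    """

    G0: np.ndarray
    P0: np.ndarray | None
    R0: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    param_names: list
    param_cov: np.ndarray
    warnings: list = field(default_factory=list)

    def se(self, comp: str, k: int, l: int) -> float:
        i = self.param_names.index((comp, min(k, l), max(k, l)))
        return float(np.sqrt(max(self.param_cov[i, i], 0.0)))


def _tri_indices(t):
    return [(k, l) for k in range(t) for l in range(k, t)]


def _pack(G0, P0, R0):
    th = [G0[k, l] for k, l in _tri_indices(G0.shape[0])]
    names = [("G0", k, l) for k, l in _tri_indices(G0.shape[0])]
    if P0 is not None:
        th += [P0[k, l] for k, l in _tri_indices(P0.shape[0])]
        names += [("P0", k, l) for k, l in _tri_indices(P0.shape[0])]
    th += [R0[k, l] for k, l in _tri_indices(R0.shape[0])]
    names += [("R0", k, l) for k, l in _tri_indices(R0.shape[0])]
    return np.array(th), names


def _unpack(theta, t, tpe, with_pe):
    def mat(vals, tt):
        M = np.zeros((tt, tt))
        for (k, l), v in zip(_tri_indices(tt), vals):
            M[k, l] = M[l, k] = v
        return M

    ng = t * (t + 1) // 2
    G0 = mat(theta[:ng], t)
    pos = ng
    P0 = None
    if with_pe:
        npp = tpe * (tpe + 1) // 2
        P0 = mat(theta[pos : pos + npp], tpe)
        pos += npp
    R0 = mat(theta[pos:], t)
    return G0, P0, R0


def _is_pd(M, tol=1e-10):
    return M is None or np.linalg.eigvalsh(0.5 * (M + M.T))[0] > tol * max(np.trace(M), 1.0)


def ai_reml(
    y,
    X,
    Arec,
    G0,
    R0,
    P0=None,
    Pemat=None,
    pe_traits=None,
    max_iter=50,
    tol=1e-8,
    max_cells=8000,
):
    """AI-REML estimates of (G0, P0, R0) on complete multi-trait records.

    Parameters
    ----------
    y : (n, t) response matrix, no missing values.
    X : (n*t, p) dense fixed-effect design in record-major layout.
    Arec : (n, n) additive relationships among the records' animals.
    G0, R0 : starting covariance matrices (t x t).
    P0, Pemat, pe_traits : permanent-environment start (tpe x tpe), the
        (n, n) same-animal indicator among records, and the trait indices
        that carry a pe effect; all three or none.
    """
    y = np.asarray(y, dtype=float)
    n, t = y.shape
    if n * t > max_cells:
        raise REMLError(
            f"dense REML limited to {max_cells} record-trait cells, got {n * t}"
        )
    if np.isnan(y).any():
        raise REMLError("REML path requires complete records (no missing traits)")
    with_pe = P0 is not None
    tpe = 0 if not with_pe else P0.shape[0]
    pe_traits = np.asarray(pe_traits if pe_traits is not None else range(t), dtype=int)
    yv = y.reshape(-1)
    nt = n * t
    Idx = np.arange(n)
    warnings = []

    def build_V(G0, P0, R0):
        V4 = Arec[:, None, :, None] * G0[None, :, None, :]
        if with_pe:
            P0full = np.zeros((t, t))
            P0full[np.ix_(pe_traits, pe_traits)] = P0
            V4 += Pemat[:, None, :, None] * P0full[None, :, None, :]
        V4[Idx, :, Idx, :] += R0
        return V4.reshape(nt, nt)

    def loglik_and_P(G0, P0, R0):
        V = build_V(G0, P0, R0)
        cf = sla.cho_factor(V, lower=True, check_finite=False)
        logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
        Vinv = sla.cho_solve(cf, np.eye(nt), check_finite=False)
        XtVi = X.T @ Vinv
        C = XtVi @ X
        sign, logdetC = np.linalg.slogdet(C)
        if sign <= 0:
            raise REMLError("X'V^-1X singular: fixed effects not estimable")
        P = Vinv - XtVi.T @ np.linalg.solve(C, XtVi)
        Py = P @ yv
        ll = -0.5 * (logdetV + logdetC + yv @ Py)
        return ll, P, Py

    theta, names = _pack(G0, P0, R0)
    npar = len(theta)
    ll, P, Py = loglik_and_P(G0, P0, R0)
    it = 0
    converged = False
    AI = np.eye(npar)
    for it in range(1, max_iter + 1):
        P4 = P.reshape(n, t, n, t)
        U = Py.reshape(n, t)
        AU = Arec @ U
        trG = np.einsum("ikjl,ij->kl", P4, Arec)
        qG = U.T @ AU
        trR = np.einsum("ikil->kl", P4)
        qR = U.T @ U
        if with_pe:
            PU = Pemat @ U
            trPm = np.einsum("ikjl,ij->kl", P4, Pemat)
            qP = U.T @ PU

        score = np.zeros(npar)
        Fs = np.zeros((n, t, npar))
        pos = 0
        for k, l in _tri_indices(t):
            sym = 1 if k == l else 2
            trv = trG[k, l] if k == l else trG[k, l] + trG[l, k]
            qv = qG[k, l] if k == l else qG[k, l] + qG[l, k]
            score[pos] = -0.5 * (trv - qv)
            Fs[:, k, pos] += AU[:, l]
            if k != l:
                Fs[:, l, pos] += AU[:, k]
            pos += 1
        if with_pe:
            P0full_idx = pe_traits
            for kp, lp in _tri_indices(tpe):
                k, l = P0full_idx[kp], P0full_idx[lp]
                trv = trPm[k, l] if k == l else trPm[k, l] + trPm[l, k]
                qv = qP[k, l] if k == l else qP[k, l] + qP[l, k]
                score[pos] = -0.5 * (trv - qv)
                Fs[:, k, pos] += PU[:, l]
                if k != l:
                    Fs[:, l, pos] += PU[:, k]
                pos += 1
        for k, l in _tri_indices(t):
            trv = trR[k, l] if k == l else trR[k, l] + trR[l, k]
            qv = qR[k, l] if k == l else qR[k, l] + qR[l, k]
            score[pos] = -0.5 * (trv - qv)
            Fs[:, k, pos] += U[:, l]
            if k != l:
                Fs[:, l, pos] += U[:, k]
            pos += 1

        Fmat = Fs.reshape(nt, npar)
        AI = 0.5 * (Fmat.T @ (P @ Fmat))
        AI = 0.5 * (AI + AI.T)
        cond = np.linalg.cond(AI)
        if not np.isfinite(cond) or cond > 1e10:
            warnings.append(
                "average-information matrix is near-singular: some variance "
                "components are at the boundary or not identifiable"
            )
            delta = np.linalg.lstsq(AI, score, rcond=1e-10)[0]
        else:
            delta = np.linalg.solve(AI, score)

        accepted = False
        for half in range(30):
            cand = theta + delta
            G0n, P0n, R0n = _unpack(cand, t, tpe, with_pe)
            if _is_pd(G0n) and _is_pd(P0n) and _is_pd(R0n):
                try:
                    lln, Pn, Pyn = loglik_and_P(G0n, P0n, R0n)
                except (np.linalg.LinAlgError, REMLError):
                    lln = -np.inf
                if np.isfinite(lln) and lln >= ll - 1e-10:
                    accepted = True
                    break
            delta = 0.5 * delta
        if not accepted:
            warnings.append("step-halving exhausted; returning last estimates")
            break
        rel = abs(lln - ll) / (abs(ll) + 1.0)
        theta, ll, P, Py = cand, lln, Pn, Pyn
        G0, P0, R0 = G0n, P0n, R0n
        if rel < tol:
            converged = True
            break

    if not converged and it >= max_iter:
        warnings.append(f"no convergence in {max_iter} iterations")
    try:
        cov = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(AI)
    fit = REMLFit(
        G0=G0,
        P0=P0,
        R0=R0,
        loglik=float(ll),
        n_iter=it,
        converged=converged,
        param_names=names,
        param_cov=cov,
        warnings=warnings,
    )
    if not converged and not warnings:
        raise REMLError("AI-REML failed to converge")
    return fit
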