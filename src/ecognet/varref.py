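"""Reference VAR-route spectral conditional Granger causality.

An independent computational route used to cross-check the state-space
implementation in :mod:`ecognet.ssgc`: starting from known VAR coefficients,
the exact process autocovariance sequence is obtained from the companion-form
Lyapunov equation, the reduced (source-omitting) model is fitted by an
explicit multivariate Yule-Walker regression truncated at a high lag order,
and Geweke's spectral decomposition is evaluated from the two VAR transfer
functions. No subspace identification and no Riccati equation are involved.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg as sla


def var_autocov(coeffs: np.ndarray, Sigma: np.ndarray, n_lags: int) -> np.ndarray:
    """Autocovariance sequence Gamma(0..n_lags) of a stable VAR.

    ``Gamma(h) = E[y_t y_{t-h}^T]``; Gamma(0..p-1) come from the
    companion-form discrete Lyapunov equation and higher lags from the
    Yule-Walker recursion ``Gamma(k) = sum_j A_j Gamma(k - j)``.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    p, n, _ = coeffs.shape
    comp = np.zeros((n * p, n * p))
    comp[:n, :] = np.concatenate(list(coeffs), axis=1)
    if p > 1:
        comp[n:, : n * (p - 1)] = np.eye(n * (p - 1))
    Q = np.zeros((n * p, n * p))
    Q[:n, :n] = Sigma
    G_big = sla.solve_discrete_lyapunov(comp, Q)
    # state z_t = (y_t, ..., y_{t-p+1}); block (0, b) = E[y_t y_{t-b}^T]
    gammas = [G_big[:n, b * n : (b + 1) * n] for b in range(p)]
    for k in range(p, n_lags + 1):
        g = np.zeros((n, n))
        for j in range(1, p + 1):
            g += coeffs[j - 1] @ _gamma(gammas, k - j)
        gammas.append(g)
    return np.stack(gammas[: n_lags + 1])


def _gamma(gammas: list, h: int) -> np.ndarray:
    return gammas[h] if h >= 0 else gammas[-h].T


def yule_walker_fit(
    gammas: np.ndarray, idx: np.ndarray, p_fit: int
) -> tuple[np.ndarray, np.ndarray]:
    """VAR(p_fit) of the subprocess ``idx`` from exact autocovariances.

    Solves the multivariate Yule-Walker (normal) equations of the truncated
    autoregression — the population version of an explicit least-squares
    regression of the subset on its own past — and returns the coefficient
    stack (p_fit, ns, ns) and residual covariance.
    """
    idx = np.asarray(idx)
    sub = [g[np.ix_(idx, idx)] for g in gammas]
    ns = len(idx)

    def G(h):
        return sub[h] if h >= 0 else sub[-h].T

    M = np.empty((p_fit * ns, p_fit * ns))
    for j in range(1, p_fit + 1):
        for i in range(1, p_fit + 1):
            M[(j - 1) * ns : j * ns, (i - 1) * ns : i * ns] = G(i - j)
    rhs = np.concatenate([G(i) for i in range(1, p_fit + 1)], axis=1)
    B_flat = np.linalg.solve(M.T, rhs.T).T  # solves B M = rhs
    B = np.stack([B_flat[:, (j - 1) * ns : j * ns] for j in range(1, p_fit + 1)])
    Sig = G(0).copy()
    for j in range(1, p_fit + 1):
        Sig -= B[j - 1] @ G(j).T
    return B, 0.5 * (Sig + Sig.T)


def var_transfer(coeffs: np.ndarray, fs: float, freqs) -> np.ndarray:
    """VAR transfer function ``H(f) = (I - sum_j A_j z^{-j})^{-1}``; (F, n, n)."""
    coeffs = np.asarray(coeffs, dtype=float)
    p, n, _ = coeffs.shape
    freqs = np.asarray(freqs, dtype=float)
    z = np.exp(-2j * np.pi * freqs / fs)
    Az = np.eye(n)[None, :, :] - np.einsum(
        "fj,jkl->fkl", z[:, None] ** np.arange(1, p + 1)[None, :], coeffs
    )
    return np.linalg.inv(Az)


def var_spectral_cgc(
    coeffs: np.ndarray,
    Sigma: np.ndarray,
    fs: float,
    freqs,
    p_trunc: int = 128,
    n_lags: int | None = None,
) -> np.ndarray:
    """Geweke spectral conditional GC for all ordered pairs, VAR route.

    For each source ``j``, the reduced model on the remaining channels is the
    truncated Yule-Walker autoregression of order ``p_trunc`` computed from
    the exact autocovariances; causality follows from
    ``G(f) = H_R(f)^{-1} H_full[R, :](f)`` and the partialled source
    innovations variance, exactly as in Geweke's formulation.

    Returns ``values[j, i, f]`` (source -> target), diagonal NaN.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    n = coeffs.shape[1]
    freqs = np.asarray(freqs, dtype=float)
    n_lags = n_lags or p_trunc + coeffs.shape[0] + 1
    gammas = var_autocov(coeffs, Sigma, n_lags)
    H_full = var_transfer(coeffs, fs, freqs)
    out = np.full((n, n, len(freqs)), np.nan)
    for j in range(n):
        keep = np.array([i for i in range(n) if i != j])
        B_r, Sig_r = yule_walker_fit(gammas, keep, p_trunc)
        H_r = var_transfer(B_r, fs, freqs)
        G = np.linalg.solve(H_r, H_full[:, keep, :])
        Su = np.einsum("fik,kl,fjl->fij", G, Sigma, G.conj())
        Srr = Sigma[np.ix_(keep, keep)]
        sj = Sigma[j, keep]
        sig_cond = Sigma[j, j] - sj @ np.linalg.solve(Srr, sj)
        num = np.real(np.einsum("fii->fi", Su))
        den = num - (np.abs(G[:, :, j]) ** 2) * sig_cond
        vals = np.log(np.maximum(num, 1e-300) /
                      np.maximum(den, 1e-300))
        for a_pos, a in enumerate(keep):
            out[j, a, :] = np.clip(vals[:, a_pos], 0.0, None)
    return out


def var_time_domain_cgc(
    coeffs: np.ndarray, Sigma: np.ndarray, p_trunc: int = 128
) -> np.ndarray:
    """Time-domain conditional GC, VAR route: ``ln(Sigma^R_ii / Sigma_ii)``."""
    coeffs = np.asarray(coeffs, dtype=float)
    n = coeffs.shape[1]
    gammas = var_autocov(coeffs, Sigma, p_trunc + coeffs.shape[0] + 1)
    out = np.full((n, n), np.nan)
    for j in range(n):
        keep = np.array([i for i in range(n) if i != j])
        _, Sig_r = yule_walker_fit(gammas, keep, p_trunc)
        for a_pos, a in enumerate(keep):
            out[j, a] = np.log(Sig_r[a_pos, a_pos] / Sigma[a, a])
    return out
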