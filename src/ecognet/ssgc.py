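"""Innovations-form state-space modeling and spectral conditional Granger
causality (CGC).

The observed multichannel signal :math:`y_t` is modeled in innovations form

.. math::

    x_{t+1} &= A x_t + K \\varepsilon_t  \\\\
    y_t     &= C x_t + \\varepsilon_t

with latent state :math:`x_t` of order ``m``, steady-state Kalman gain ``K``
and innovations covariance ``Sigma``. The model is identified from trial
ensembles by a canonical-variate (CVA) subspace method; the model order can be
chosen as the number of principal angles between past and future data
subspaces that are significantly below :math:`\\pi/2`.

Directed influence is quantified by Geweke's spectral conditional Granger
causality: for an ordered channel pair ``j -> i`` conditioned on all remaining
modeled channels, the reduced model that omits the source ``j`` is obtained by
solving the discrete algebraic Riccati equation (DARE) for the subsystem
observation, and the causality at frequency ``f`` is the log ratio of the
target's reduced-model spectral power to its intrinsic (source-partialled)
power.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import linalg as sla

from ecognet.bands import BandSet, CGC_BANDS
from ecognet.containers import Epochs

logger = logging.getLogger(__name__)

#: Default spectral grid: 0-50 Hz inclusive at 0.5 Hz (the analysis ceiling).
def default_freqs(fmax: float = 50.0, df: float = 0.5) -> np.ndarray:
    return np.arange(0.0, fmax + df / 2, df)


class FactorizationError(RuntimeError):
    """Raised when the spectral factorization / DARE solution is unusable."""


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------

@dataclass
class StateSpaceModel:
    """Innovations-form state-space model (A, C, K, Sigma)."""

    A: np.ndarray
    C: np.ndarray
    K: np.ndarray
    Sigma: np.ndarray
    fs: float
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        self.K = np.atleast_2d(np.asarray(self.K, dtype=float))
        self.Sigma = np.atleast_2d(np.asarray(self.Sigma, dtype=float))
        if not self.labels:
            self.labels = [f"ch{i}" for i in range(self.n_channels)]

    @property
    def order(self) -> int:
        return self.A.shape[0]

    @property
    def n_channels(self) -> int:
        return self.C.shape[0]

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.A)))) if self.order else 0.0

    def minphase_radius(self) -> float:
        if self.order == 0:
            return 0.0
        return float(np.max(np.abs(np.linalg.eigvals(self.A - self.K @ self.C))))

    def validate(self) -> None:
        if self.spectral_radius() >= 1.0:
            raise ValueError("model is unstable: spectral radius(A) >= 1")
        if self.minphase_radius() >= 1.0:
            raise ValueError("model is not minimum phase: rho(A - K C) >= 1")
        if np.any(np.linalg.eigvalsh(self.Sigma) <= 0):
            raise ValueError("Sigma must be symmetric positive definite")

    @classmethod
    def from_var(cls, coeffs: np.ndarray, Sigma: np.ndarray, fs: float,
                 labels: list[str] | None = None) -> "StateSpaceModel":
        """Exact innovations-form embedding of a VAR(p).

        With state ``x_t = (y_{t-1}, ..., y_{t-p})``, the companion matrix is
        the state transition, ``C = (A_1 ... A_p)`` and ``K = (I, 0, ..., 0)^T``.
        """
        coeffs = np.asarray(coeffs, dtype=float)
        p, n, _ = coeffs.shape
        A = np.zeros((n * p, n * p))
        A[:n, :] = np.concatenate(list(coeffs), axis=1)
        if p > 1:
            A[n:, : n * (p - 1)] = np.eye(n * (p - 1))
        C = np.concatenate(list(coeffs), axis=1)
        K = np.zeros((n * p, n))
        K[:n, :] = np.eye(n)
        return cls(A, C, K, np.asarray(Sigma, dtype=float), fs,
                   labels or [f"ch{i}" for i in range(n)])


@dataclass
class SpectralMatrices:
    """Transfer functions and cross-spectral densities on a frequency grid."""

    freqs: np.ndarray
    H: np.ndarray  # (F, c, c) complex
    S: np.ndarray  # (F, c, c) complex


@dataclass
class CGCSpectrum:
    """Spectral conditional GC: ``values[j, i, f]`` is source j -> target i
    (nats), conditioned on all remaining modeled channels; diagonal is NaN."""

    values: np.ndarray
    freqs: np.ndarray
    labels: list[str]
    conditioning: str = "all remaining channels"

    def pair(self, source, target) -> np.ndarray:
        j = self.labels.index(source) if isinstance(source, str) else source
        i = self.labels.index(target) if isinstance(target, str) else target
        return self.values[j, i]


# ---------------------------------------------------------------------------
# Spectral evaluation
# ---------------------------------------------------------------------------

def transfer_function(A, C, K, fs, freqs) -> np.ndarray:
    """H(f) = I + C (z I - A)^{-1} K with z = exp(i 2 pi f / fs); (F, c, c)."""
    A = np.atleast_2d(A)
    C = np.atleast_2d(C)
    K = np.atleast_2d(K)
    freqs = np.asarray(freqs, dtype=float)
    c = C.shape[0]
    z = np.exp(2j * np.pi * freqs / fs)
    if A.shape[0] == 0:
        return np.broadcast_to(np.eye(c), (len(freqs), c, c)).copy()
    try:
        d, V = np.linalg.eig(A)
        CV = C @ V
        VK = np.linalg.solve(V, K)
        cond = np.linalg.cond(V)
    except np.linalg.LinAlgError:
        cond = np.inf
    if np.isfinite(cond) and cond < 1e10:
        # H_f = I + CV diag(1/(z-d)) VK, vectorised over f
        rz = 1.0 / (z[:, None] - d[None, :])  # (F, m)
        H = np.einsum("ck,fk,kl->fcl", CV, rz, VK)
    else:  # defective A: solve per frequency
        m = A.shape[0]
        H = np.empty((len(freqs), c, c), dtype=complex)
        for fi, zf in enumerate(z):
            H[fi] = C @ np.linalg.solve(zf * np.eye(m) - A, K)
    return H + np.eye(c)[None, :, :]


def spectral_matrices(model: StateSpaceModel, freqs=None) -> SpectralMatrices:
    """Transfer function and CSD: ``S(f) = H(f) Sigma H(f)*``."""
    if freqs is None:
        freqs = default_freqs(model.fs / 2)
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs < 0) or np.any(freqs > model.fs / 2 + 1e-9):
        raise ValueError("freqs must lie in [0, fs/2]")
    H = transfer_function(model.A, model.C, model.K, model.fs, freqs)
    S = np.einsum("fij,jk,flk->fil", H, model.Sigma, H.conj())
    return SpectralMatrices(freqs, H, S)


# ---------------------------------------------------------------------------
# Reduced models via the DARE
# ---------------------------------------------------------------------------

def _dare_residual(A, C, Q, R, S, P) -> float:
    M = C @ P @ C.T + R
    G = A @ P @ C.T + S
    resid = A @ P @ A.T - P - G @ np.linalg.solve(M, G.T) + Q
    return float(np.linalg.norm(resid) / max(1.0, np.linalg.norm(P)))


def _dare_sda(A, C, Q, R, S, tol: float = 1e-12, max_iter: int = 100):
    """Structure-preserving doubling solution of the filtering DARE.

    Quadratically convergent and much faster than the QZ route for the small
    state dimensions used here. Returns the steady-state covariance ``P``.
    """
    m = A.shape[0]
    Ri = np.linalg.inv(R)
    SRi = S @ Ri
    Abar = A - SRi @ C
    Qbar = Q - SRi @ S.T
    Ak = Abar.T.copy()
    Gk = C.T @ Ri @ C
    Hk = Qbar.copy()
    eye = np.eye(m)
    for _ in range(max_iter):
        Wi = np.linalg.inv(eye + Gk @ Hk)
        WA = Wi @ Ak
        A_next = Ak @ WA
        G_next = Gk + Ak @ Wi @ Gk @ Ak.T
        H_next = Hk + Ak.T @ Hk @ WA
        H_next = 0.5 * (H_next + H_next.T)
        delta = np.max(np.abs(H_next - Hk)) / max(1.0, np.max(np.abs(H_next)))
        Ak, Gk, Hk = A_next, 0.5 * (G_next + G_next.T), H_next
        if delta < tol:
            return Hk
    raise FactorizationError("doubling iteration did not converge")


def _solve_dare(A, C, Q, R, S, tol: float = 1e-10, max_iter: int = 10_000):
    """Steady-state filtering Riccati solution for observation subset.

    Solves ``P = A P A' - (A P C' + S)(C P C' + R)^{-1}(A P C' + S)' + Q``.
    Tries the doubling algorithm, then the scipy QZ solver, then fixed-point
    iteration. Returns ``(K, Sigma)`` — the gain and innovations covariance.
    """
    A = np.atleast_2d(A)
    C = np.atleast_2d(C)
    try:
        P = _dare_sda(A, C, Q, R, S)
        if _dare_residual(A, C, Q, R, S, P) <= 1e-8:
            M = C @ P @ C.T + R
            Kg = np.linalg.solve(M.T, (A @ P @ C.T + S).T).T
            return Kg, 0.5 * (M + M.T)
    except (FactorizationError, np.linalg.LinAlgError):
        pass
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            P = sla.solve_discrete_are(A.T, C.T, Q, R, s=S)
        M = C @ P @ C.T + R
        Kg = np.linalg.solve(M.T, (A @ P @ C.T + S).T).T
        resid = A @ P @ A.T - P - Kg @ M @ Kg.T + Q
        if np.linalg.norm(resid) <= 1e-6 * max(1.0, np.linalg.norm(P)):
            return Kg, 0.5 * (M + M.T)
    except Exception:
        pass
    # fixed-point iteration on the Riccati recursion
    P = Q.copy()
    for it in range(max_iter):
        M = C @ P @ C.T + R
        G = A @ P @ C.T + S
        Kg = np.linalg.solve(M.T, G.T).T
        P_next = A @ P @ A.T - Kg @ G.T + Q
        P_next = 0.5 * (P_next + P_next.T)
        if np.max(np.abs(P_next - P)) < tol:
            M = C @ P_next @ C.T + R
            Kg = np.linalg.solve(M.T, (A @ P_next @ C.T + S).T).T
            return Kg, 0.5 * (M + M.T)
        P = P_next
    raise FactorizationError(
        f"DARE iteration did not converge within {max_iter} steps "
        f"(residual {np.max(np.abs(P_next - P)):.3g})"
    )


def reduced_model(model: StateSpaceModel, keep: np.ndarray) -> StateSpaceModel:
    """Innovations form of the subprocess observing only channels ``keep``.

    The state equation is unchanged; the new gain and innovations covariance
    come from the DARE for the subsystem observation.
    """
    keep = np.asarray(keep)
    C_r = model.C[keep]
    Q = model.K @ model.Sigma @ model.K.T
    R = model.Sigma[np.ix_(keep, keep)]
    S = model.K @ model.Sigma[:, keep]
    K_r, Sig_r = _solve_dare(model.A, C_r, Q, R, S)
    return StateSpaceModel(model.A, C_r, K_r, Sig_r, model.fs,
                           [model.labels[i] for i in keep])


# ---------------------------------------------------------------------------
# Spectral conditional Granger causality
# ---------------------------------------------------------------------------

def spectral_cgc(
    model: StateSpaceModel,
    freqs=None,
    neg_tol: float = -1e-8,
) -> CGCSpectrum:
    """Geweke spectral conditional GC for all ordered channel pairs.

    For source ``j``, the reduced model omitting ``j`` is solved via the
    DARE; with ``G(f) = H_R(f)^{-1} H_{full,R}(f)`` mapping full-model
    innovations to reduced-model innovations, the causality onto target ``a``
    is ``ln( S^u_aa / (S^u_aa - |G_aj|^2 sigma^2_{j|rest}) )`` where
    ``S^u = G Sigma G*`` and ``sigma^2_{j|rest}`` is the innovations variance
    of the source partialled on all other channels.
    """
    if freqs is None:
        freqs = default_freqs(min(50.0, model.fs / 2))
    freqs = np.asarray(freqs, dtype=float)
    c = model.n_channels
    if c < 2:
        raise ValueError("spectral CGC needs >= 2 channels")
    # cache the eigendecomposition of A: full and reduced models share it
    z = np.exp(2j * np.pi * freqs / model.fs)
    eig_cache = None
    try:
        d, V = np.linalg.eig(model.A)
        if np.isfinite(np.linalg.cond(V)) and np.linalg.cond(V) < 1e10:
            rz = 1.0 / (z[:, None] - d[None, :])  # (F, m)
            eig_cache = (V, rz)
    except np.linalg.LinAlgError:
        pass

    def _H(C_, K_):
        if eig_cache is None:
            return transfer_function(model.A, C_, K_, model.fs, freqs)
        V, rz = eig_cache
        CV = C_ @ V
        VK = np.linalg.solve(V, K_)
        H = np.einsum("ck,fk,kl->fcl", CV, rz, VK)
        return H + np.eye(C_.shape[0])[None, :, :]

    H_full = _H(model.C, model.K)
    Sigma = model.Sigma
    out = np.full((c, c, len(freqs)), np.nan)

    for j in range(c):
        keep = np.array([i for i in range(c) if i != j])
        red = reduced_model(model, keep)
        H_r = _H(red.C, red.K)
        # G(f): reduced innovations expressed in full innovations
        Hfr = H_full[:, keep, :]  # rows of kept targets, all sources
        G = np.linalg.solve(H_r, Hfr)  # (F, c-1, c)
        Su = np.einsum("fik,kl,fjl->fij", G, Sigma, G.conj())
        rest = keep  # all channels except the source
        Srr = Sigma[np.ix_(rest, rest)]
        sj = Sigma[j, rest]
        sig_cond = Sigma[j, j] - sj @ np.linalg.solve(Srr, sj)
        num = np.maximum(np.real(np.einsum("fii->fi", Su)), 1e-300)
        sub = (np.abs(G[:, :, j]) ** 2) * sig_cond
        den = num - sub
        f_ji = np.log(num / np.maximum(den, 1e-300 + 1e-14 * num))
        bad = f_ji < neg_tol
        if np.any(bad):
            raise FactorizationError(
                f"negative GC beyond tolerance for source {model.labels[j]!r} "
                f"(min {f_ji.min():.3g})"
            )
        f_ji = np.clip(f_ji, 0.0, None)
        for a_pos, a in enumerate(keep):
            out[j, a, :] = f_ji[:, a_pos]
    return CGCSpectrum(out, freqs, list(model.labels))


def time_domain_cgc(model: StateSpaceModel) -> np.ndarray:
    """Time-domain conditional GC matrix: ``F[j, i] = ln(Sigma^R_ii / Sigma_ii)``
    with the reduced model omitting source ``j``; diagonal NaN."""
    c = model.n_channels
    out = np.full((c, c), np.nan)
    for j in range(c):
        keep = np.array([i for i in range(c) if i != j])
        red = reduced_model(model, keep)
        for a_pos, a in enumerate(keep):
            out[j, a] = np.log(red.Sigma[a_pos, a_pos] / model.Sigma[a, a])
    return out


def band_cgc(spec: CGCSpectrum, bands: BandSet = CGC_BANDS) -> pd.DataFrame:
    """Unweighted in-band mean of the GC spectrum per ordered pair.

    Returns a tidy frame with columns ``source, target, band, value``.
    """
    masks = bands.mask(spec.freqs)
    rows = []
    c = len(spec.labels)
    for name, m in masks.items():
        if not m.any():
            raise ValueError(f"band {name!r} has no frequency bins in the grid")
        for j in range(c):
            for i in range(c):
                if i == j:
                    continue
                rows.append(
                    dict(source=spec.labels[j], target=spec.labels[i],
                         band=name, value=float(spec.values[j, i, m].mean()))
                )
    return pd.DataFrame(rows)


def band_matrix(band_df: pd.DataFrame, band: str, labels: list[str]) -> np.ndarray:
    """Square ``source x target`` weight matrix for one band (diagonal 0)."""
    sub = band_df[band_df["band"] == band]
    n = len(labels)
    M = np.zeros((n, n))
    idx = {l: i for i, l in enumerate(labels)}
    for r in sub.itertuples(index=False):
        M[idx[r.source], idx[r.target]] = r.value
    return M


# ---------------------------------------------------------------------------
# Subspace identification
# ---------------------------------------------------------------------------

def _hankel_blocks(y: np.ndarray, horizon: int):
    """Past/future stacked vectors for one trial; columns are time points.

    Past ``p_t = (y_{t-1}, ..., y_{t-horizon})``, future
    ``f_t = (y_t, ..., y_{t+horizon-1})`` for ``t`` in
    ``[horizon, T - horizon]``. No cross-trial wraparound.
    """
    c, T = y.shape
    n_col = T - 2 * horizon + 1
    if n_col < 1:
        raise ValueError("trial too short for the chosen horizon")
    win = sliding_window_view(y, horizon, axis=1)  # (c, T-h+1, h)
    # past: windows ending at t-1 -> start index t-horizon in [0, n_col)
    past = win[:, :n_col, ::-1]  # reversed so most recent lag first
    past = past.transpose(2, 0, 1).reshape(horizon * c, n_col)
    fut = win[:, horizon : horizon + n_col, :]
    fut = fut.transpose(2, 0, 1).reshape(horizon * c, n_col)
    return past, fut


class EnsembleMoments:
    """Per-trial second-moment blocks for subspace identification.

    For each trial, the stacked vector ``u_t = (p_t, p_{t+1}, f_t, y_t)`` —
    past, one-step-shifted past, future and current output — is formed over
    the admissible columns and its Gram matrix accumulated. Identification
    of any subset of trials then needs only the *sum* of the per-trial Gram
    matrices, which makes trial-label permutation loops cheap.
    """

    def __init__(self, data: np.ndarray, horizon: int):
        n_trials, c, T = data.shape
        self.c = c
        self.horizon = horizon
        self.ph = c * horizon
        D = 3 * self.ph + c
        self.gram = np.empty((n_trials, D, D))
        self.n_cols = np.empty(n_trials, dtype=int)
        for k, tr in enumerate(data):
            P, F = _hankel_blocks(tr, horizon)
            n_col = P.shape[1]
            if n_col < 2:
                raise ValueError("trial too short for the chosen horizon")
            U = np.concatenate(
                [P[:, :-1], P[:, 1:], F[:, :-1],
                 tr[:, horizon : horizon + n_col - 1]],
                axis=0,
            )
            self.gram[k] = U @ U.T
            self.n_cols[k] = n_col - 1

    def sums(self, idx=None) -> tuple[np.ndarray, int]:
        if idx is None:
            return self.gram.sum(axis=0), int(self.n_cols.sum())
        idx = np.asarray(idx)
        return self.gram[idx].sum(axis=0), int(self.n_cols[idx].sum())

    def batched_sums(self, weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Gram sums for many trial subsets at once.

        ``weights`` is a (k, n_trials) 0/1 matrix; returns the (k, D, D)
        summed Gram stack and the (k,) column counts via one matrix product,
        which is far cheaper than per-subset fancy indexing.
        """
        k = weights.shape[0]
        D = self.gram.shape[1]
        flat = self.gram.reshape(self.gram.shape[0], -1)
        out = (weights @ flat).reshape(k, D, D)
        return out, weights @ self.n_cols

    def canonical_correlations(self, gsum=None, N=None,
                               ridge: float = 1e-10) -> np.ndarray:
        if gsum is None:
            gsum, N = self.sums()
        ph = self.ph
        Rpp = gsum[:ph, :ph] / N
        Rff = gsum[2 * ph : 3 * ph, 2 * ph : 3 * ph] / N
        Rfp = gsum[2 * ph : 3 * ph, :ph] / N
        eps = ridge * max(np.trace(Rpp), np.trace(Rff)) / ph
        Lp = np.linalg.cholesky(Rpp + eps * np.eye(ph))
        Lf = np.linalg.cholesky(Rff + eps * np.eye(ph))
        M = np.linalg.solve(Lf, np.linalg.solve(Lp, Rfp.T).T)
        s = np.linalg.svd(M, compute_uv=False)
        return s

    def fit(self, order: int, fs: float, labels: list[str],
            idx=None, ridge: float = 1e-10,
            gsum: np.ndarray | None = None, N: int | None = None
            ) -> StateSpaceModel:
        """Identify an innovations-form model from (a subset of) the trials.

        A precomputed Gram sum (from :meth:`batched_sums`) may be passed to
        skip the per-subset accumulation.
        """
        if gsum is None:
            gsum, N = self.sums(idx)
        ph, c = self.ph, self.c
        sl_p = slice(0, ph)
        sl_1 = slice(ph, 2 * ph)
        sl_f = slice(2 * ph, 3 * ph)
        sl_y = slice(3 * ph, 3 * ph + c)
        Rpp = gsum[sl_p, sl_p] / N
        Rff = gsum[sl_f, sl_f] / N
        Rfp = gsum[sl_f, sl_p] / N
        eps = ridge * max(np.trace(Rpp), np.trace(Rff)) / ph
        Lp = np.linalg.cholesky(Rpp + eps * np.eye(ph))
        Lf = np.linalg.cholesky(Rff + eps * np.eye(ph))
        M = np.linalg.solve(Lf, np.linalg.solve(Lp, Rfp.T).T)
        _, s, Vt = np.linalg.svd(M, full_matrices=False)
        order = min(order, len(s))
        B = np.sqrt(s[:order])[:, None] * Vt[:order]
        J = np.linalg.solve(Lp.T, B.T).T  # x_t = J p_t

        R11 = gsum[sl_1, sl_1] / N
        R10 = gsum[sl_1, sl_p] / N
        Ryp = gsum[sl_y, sl_p] / N
        Ry1 = gsum[sl_y, sl_1] / N
        Ryy = gsum[sl_y, sl_y] / N
        S00 = J @ Rpp @ J.T  # Xn Xn'
        S11 = J @ R11 @ J.T  # Xp Xp'
        S10 = J @ R10 @ J.T  # Xp Xn'
        Syp = Ryp @ J.T      # Yn Xn'
        Sy1 = Ry1 @ J.T      # Yn Xp'
        try:
            S00i = np.linalg.inv(S00 + 1e-12 * np.trace(S00) / order
                                 * np.eye(order))
            A = S10 @ S00i
            C = Syp @ S00i
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"rank-deficient state covariance (order {order}): {err}"
            ) from err

        rho = float(np.max(np.abs(np.linalg.eigvals(A)))) if order else 0.0
        if rho >= 1.0:
            warnings.warn(
                f"identified A unstable (rho={rho:.4f}); shrinking onto the "
                "stability region",
                RuntimeWarning,
                stacklevel=2,
            )
            A = A * (0.995 / rho)

        Q = S11 - A @ S10.T - S10 @ A.T + A @ S00 @ A.T
        Rv = Ryy - C @ Syp.T - Syp @ C.T + C @ S00 @ C.T
        S = Sy1.T - S10 @ C.T - A @ Syp.T + A @ S00 @ C.T
        Q = 0.5 * (Q + Q.T)
        Rv = 0.5 * (Rv + Rv.T)
        K, Sigma = _solve_dare(A, C, Q, Rv, S)
        return StateSpaceModel(A, C, K, Sigma, fs, list(labels))


def principal_angles(ep: Epochs, horizon: int = 20) -> np.ndarray:
    """Principal angles (radians) between past and future data subspaces.

    Angles are ``arccos`` of the canonical correlations of the whitened past
    and future ensembles; angles well below pi/2 indicate predictable
    dynamics.
    """
    horizon = _cap_horizon(ep, horizon)
    s = EnsembleMoments(ep.data, horizon).canonical_correlations()
    return np.arccos(np.clip(s, 0.0, 1.0))


def select_order(
    ep: Epochs,
    max_order: int = 20,
    horizon: int | None = None,
    alpha: float = 0.05,
    n_surr: int = 20,
    seed: int | None = 0,
) -> int:
    """Choose the state order as the number of principal angles significantly
    below pi/2.

    The null for "no dependence between past and future" is built by
    recomputing the largest canonical correlation after randomly permuting
    the future columns relative to the past (which destroys their temporal
    alignment); the observed canonical correlations are compared with the
    ``1 - alpha`` quantile of the null maxima.
    """
    horizon = horizon or max(20, 2 * max_order)
    horizon = _cap_horizon(ep, horizon)
    pasts, futs = [], []
    for tr in ep.data:
        p, f = _hankel_blocks(tr, horizon)
        pasts.append(p)
        futs.append(f)
    P = np.concatenate(pasts, axis=1)
    F = np.concatenate(futs, axis=1)
    N = P.shape[1]
    eps = 1e-10
    Lp = np.linalg.cholesky(P @ P.T / N + eps * np.eye(P.shape[0]))
    Lf = np.linalg.cholesky(F @ F.T / N + eps * np.eye(F.shape[0]))
    Pw = np.linalg.solve(Lp, P)
    Fw = np.linalg.solve(Lf, F)
    s_obs = np.linalg.svd(Fw @ Pw.T / N, compute_uv=False)
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_surr)
    for k in range(n_surr):
        perm = rng.permutation(N)
        null_max[k] = np.linalg.svd(Fw[:, perm] @ Pw.T / N,
                                    compute_uv=False)[0]
    thr = np.quantile(null_max, 1 - alpha)
    m = int(np.sum(s_obs > thr))
    if m == 0:
        logger.info("no significant principal angles: degenerate order 0")
    return min(m, max_order)


def _cap_horizon(ep: Epochs, horizon: int) -> int:
    max_h = (ep.n_times - 1) // 2
    if horizon > max_h:
        logger.info("horizon capped at %d by trial length", max_h)
        horizon = max_h
    if horizon < 1:
        raise ValueError("trials are too short for subspace identification")
    return horizon


def subspace_identify(
    ep: Epochs,
    order: int,
    horizon: int | None = None,
) -> StateSpaceModel:
    """Identify an innovations-form state-space model from trial ensembles.

    Canonical-variate-weighted subspace identification: Hankel past/future
    blocks are built per trial (no cross-trial wraparound), the CVA state
    sequence is estimated from the whitened past, and (A, C) follow from
    least squares on consecutive states. The steady-state Kalman gain and
    innovations covariance come from the filtering DARE on the state/output
    residual covariances. An unstable ``A`` is shrunk onto the stability
    region with a warning.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    horizon = horizon or max(20, 2 * order)
    horizon = _cap_horizon(ep, horizon)
    moments = EnsembleMoments(ep.data, horizon)
    model = moments.fit(order, ep.fs, list(ep.labels))
    mp = model.minphase_radius()
    if mp >= 1.0:
        warnings.warn(
            f"identified model is not minimum phase (rho(A-KC)={mp:.4f})",
            RuntimeWarning,
            stacklevel=2,
        )
    return model


# ---------------------------------------------------------------------------
# Model/Results front end
# ---------------------------------------------------------------------------

class StateSpaceCGC:
    """State-space spectral conditional Granger causality model.

    Parameters
    ----------
    epochs : Epochs
        ROI-level, ensemble-normalised trial data.
    order : int or "auto"
        State order; ``"auto"`` selects it by the principal-angle rule.
    max_order : int
        Cap for automatic order selection.
    freqs : array-like, optional
        Spectral grid in Hz (default 0-50 Hz at 0.5 Hz, capped at Nyquist).
    bands : BandSet
        Bands for aggregate reporting.
    """

    def __init__(self, epochs: Epochs, order: int | str = "auto",
                 max_order: int = 20, freqs=None,
                 bands: BandSet = CGC_BANDS, horizon: int | None = None):
        self.epochs = epochs
        self.order = order
        self.max_order = max_order
        self.freqs = (np.asarray(freqs, dtype=float) if freqs is not None
                      else default_freqs(min(50.0, epochs.fs / 2)))
        self.bands = bands
        self.horizon = horizon

    def fit(self, seed: int | None = 0) -> "CGCResults":
        if self.order == "auto":
            m = select_order(self.epochs, self.max_order,
                             horizon=self.horizon, seed=seed)
            m = max(m, 1)
        else:
            m = int(self.order)
        model = subspace_identify(self.epochs, m, horizon=self.horizon)
        gc = spectral_cgc(model, self.freqs)
        bands_df = band_cgc(gc, self.bands)
        return CGCResults(self, model, gc, bands_df)


@dataclass
class CGCResults:
    """Fitted spectral CGC: identified model, GC spectra and band means."""

    model_spec: StateSpaceCGC
    model: StateSpaceModel
    gc: CGCSpectrum
    band_means: pd.DataFrame

    def band_matrix(self, band: str) -> np.ndarray:
        return band_matrix(self.band_means, band, self.gc.labels)

    def summary(self) -> str:
        lines = [
            "State-space spectral conditional Granger causality",
            f"  channels: {', '.join(self.gc.labels)}",
            f"  state order: {self.model.order}   fs: {self.model.fs:g} Hz",
            f"  spectral radius(A): {self.model.spectral_radius():.4f}   "
            f"rho(A-KC): {self.model.minphase_radius():.4f}",
            f"  grid: {self.gc.freqs[0]:g}-{self.gc.freqs[-1]:g} Hz "
            f"({len(self.gc.freqs)} bins)",
            "",
            "Band-mean CGC (nats), source -> target:",
        ]
        piv = self.band_means.pivot_table(
            index=["source", "target"], columns="band", values="value",
            sort=False,
        )
        lines.append(piv.to_string(float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("gc", data=self.gc.values)
            f.create_dataset("freqs", data=self.gc.freqs)
            f.create_dataset(
                "labels",
                data=np.array(self.gc.labels, dtype=h5py.string_dtype()),
            )
            g = f.create_group("model")
            for name in ("A", "C", "K", "Sigma"):
                g.create_dataset(name, data=getattr(self.model, name))
            g.attrs["fs"] = self.model.fs

    def to_json_summary(self, path=None):
        doc = dict(
            labels=self.gc.labels,
            order=self.model.order,
            fs=self.model.fs,
            band_means=self.band_means.to_dict(orient="records"),
        )
        if path is None:
            return json.dumps(doc, indent=1)
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
        return None
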