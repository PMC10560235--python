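"""State-space spectral conditional Granger causality.

The VAR-route reference in :mod:`ecognet.varref` (explicit truncated
Yule-Walker regressions on exact autocovariances) serves as the independent
oracle for the DARE-based state-space route.
"""

import numpy as np
import pytest

from ecognet.containers import Epochs
from ecognet.ssgc import (
    StateSpaceCGC,
    StateSpaceModel,
    band_cgc,
    default_freqs,
    principal_angles,
    reduced_model,
    select_order,
    spectral_cgc,
    spectral_matrices,
    subspace_identify,
    time_domain_cgc,
    transfer_function,
)
from ecognet.varref import var_autocov, var_spectral_cgc, var_time_domain_cgc

FS = 100.0
FREQS = default_freqs(50.0)


def simulate_ss(model: StateSpaceModel, n_trials, n_samples, seed,
                burn_in=200) -> Epochs:
    """Simulate trials from an innovations-form model (test helper)."""
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(model.Sigma)
    m, c = model.order, model.n_channels
    data = np.empty((n_trials, c, n_samples))
    for tr in range(n_trials):
        x = np.zeros(m)
        for t in range(burn_in + n_samples):
            e = L @ rng.normal(size=c)
            y = model.C @ x + e
            x = model.A @ x + model.K @ e
            if t >= burn_in:
                data[tr, :, t - burn_in] = y
    return Epochs(data, model.fs, 0.0, list(model.labels))


class TestSpectralMatrices:
    def test_memoryless_model_flat(self):
        Sigma = np.array([[2.0, 0.3], [0.3, 1.0]])
        m = StateSpaceModel(np.zeros((1, 1)), np.zeros((2, 1)),
                            np.zeros((1, 2)), Sigma, FS)
        sm = spectral_matrices(m, FREQS)
        assert np.allclose(sm.H, np.eye(2)[None])
        assert np.allclose(sm.S, Sigma[None])

    def test_ar1_textbook_spectrum(self):
        a, s2 = 0.7, 1.3
        m = StateSpaceModel.from_var(np.array([[[a]]]), [[s2]], FS)
        sm = spectral_matrices(m, FREQS)
        w = 2 * np.pi * FREQS / FS
        expected = s2 / np.abs(1 - a * np.exp(-1j * w)) ** 2
        np.testing.assert_allclose(sm.S[:, 0, 0].real, expected, rtol=1e-10)

    def test_parseval_autocovariance(self, chain_var):
        A, Sigma = chain_var
        m = StateSpaceModel.from_var(A, Sigma, FS)
        grid = np.linspace(0, FS / 2, 2001)
        S = spectral_matrices(m, grid).S
        gamma0 = var_autocov(A, Sigma, 0)[0]
        est = 2 * np.trapezoid(S.real, grid, axis=0) / FS
        np.testing.assert_allclose(np.diag(est), np.diag(gamma0), rtol=1e-3)

    def test_hermitian_psd(self, chain_var):
        A, Sigma = chain_var
        S = spectral_matrices(StateSpaceModel.from_var(A, Sigma, FS), FREQS).S
        assert np.allclose(S, np.conj(np.transpose(S, (0, 2, 1))))
        eigs = np.linalg.eigvalsh(S)
        assert eigs.min() > -1e-10


class TestSpectralCGC:
    def test_oracle_equivalence_bivariate(self):
        A = np.zeros((1, 2, 2))
        A[0] = [[0.5, 0.0], [0.5, 0.3]]
        Sigma = np.array([[1.0, 0.2], [0.2, 1.0]])
        gc = spectral_cgc(StateSpaceModel.from_var(A, Sigma, FS), FREQS).values
        oracle = var_spectral_cgc(A, Sigma, FS, FREQS)
        for j, i in [(0, 1), (1, 0)]:
            denom = max(np.linalg.norm(oracle[j, i]), 1e-12)
            assert np.linalg.norm(gc[j, i] - oracle[j, i]) / denom < 0.02

    def test_chain_conditional_vs_pairwise(self, chain_var):
        """Conditioning removes the indirect 0 -> 2 influence that a
        pairwise (unconditioned) analysis reports."""
        A, Sigma = chain_var
        full = StateSpaceModel.from_var(A, Sigma, FS)
        gc = spectral_cgc(full, FREQS).values
        assert np.nanmax(gc[0, 2]) < 1e-10  # no direct edge
        pairwise = reduced_model(full, np.array([0, 2]))
        gc_pair = spectral_cgc(pairwise, FREQS).values
        assert np.nanmax(gc_pair[0, 1]) > 0.01  # indirect influence visible

    def test_independent_channels_zero(self):
        A = np.zeros((1, 3, 3))
        A[0] = np.diag([0.5, -0.3, 0.7])
        gc = spectral_cgc(
            StateSpaceModel.from_var(A, np.eye(3), FS), FREQS
        ).values
        off = gc[~np.isnan(gc)]
        assert np.abs(off).max() < 1e-6

    def test_similarity_invariance(self, chain_var):
        A, Sigma = chain_var
        m = StateSpaceModel.from_var(A, Sigma, FS)
        rng = np.random.default_rng(0)
        T = rng.normal(size=(m.order, m.order)) + 3 * np.eye(m.order)
        Ti = np.linalg.inv(T)
        m2 = StateSpaceModel(T @ m.A @ Ti, m.C @ Ti, T @ m.K, m.Sigma, FS)
        H1 = transfer_function(m.A, m.C, m.K, FS, FREQS)
        H2 = transfer_function(m2.A, m2.C, m2.K, FS, FREQS)
        np.testing.assert_allclose(H1, H2, atol=1e-8)
        np.testing.assert_allclose(
            spectral_cgc(m, FREQS).values, spectral_cgc(m2, FREQS).values,
            atol=1e-8,
        )

    def test_nonnegative(self, chain_var):
        A, Sigma = chain_var
        gc = spectral_cgc(StateSpaceModel.from_var(A, Sigma, FS), FREQS).values
        assert np.nanmin(gc) >= 0.0

    def test_geweke_integral_identity(self, chain_var):
        A, Sigma = chain_var
        m = StateSpaceModel.from_var(A, Sigma, FS)
        grid = np.linspace(0, FS / 2, 4001)
        gc = spectral_cgc(m, grid).values
        F_spec = np.trapezoid(gc, grid, axis=2) / (FS / 2)
        F_time = time_domain_cgc(m)
        mask = ~np.isnan(F_time) & (F_time > 1e-6)
        assert np.all(
            np.abs(F_spec[mask] - F_time[mask]) / F_time[mask] < 0.05
        )
        oracle = var_time_domain_cgc(A, Sigma)
        np.testing.assert_allclose(F_time[mask], oracle[mask], rtol=1e-6)


class TestBandAggregation:
    def test_flat_spectrum(self, chain_var):
        from ecognet.ssgc import CGCSpectrum

        vals = np.full((2, 2, len(FREQS)), 0.7)
        vals[0, 0] = vals[1, 1] = np.nan
        df = band_cgc(CGCSpectrum(vals, FREQS, ["a", "b"]))
        assert np.allclose(df["value"], 0.7)

    def test_band_limited_coupling_lands_in_gamma(self, network_epochs):
        model = subspace_identify(network_epochs, 8, horizon=14)
        df = band_cgc(spectral_cgc(model, FREQS))
        piv = df[(df.source == "node1") & (df.target == "node0")]
        # node1 resonates at 40 Hz; any 1->0 estimate is noise, the true
        # edge 0->1 concentrates near the source resonance (10 Hz -> alpha)
        true_edge = df[(df.source == "node0") & (df.target == "node1")]
        assert true_edge["value"].max() > 10 * piv["value"].max()


@pytest.fixture(scope="module")
def true_model():
    A = np.zeros((2, 2, 2))
    A[0] = [[0.6, 0.0], [0.4, 0.2]]
    A[1] = [[-0.3, 0.0], [0.0, -0.2]]
    return StateSpaceModel.from_var(A, np.eye(2), FS)  # order 4


class TestIdentification:

    def test_transfer_recovery_within_5pct(self, true_model):
        ep = simulate_ss(true_model, 40, 500, seed=13)
        fit = subspace_identify(ep, 4)
        H_true = transfer_function(true_model.A, true_model.C, true_model.K,
                                   FS, FREQS)
        H_fit = transfer_function(fit.A, fit.C, fit.K, FS, FREQS)
        rel = np.linalg.norm(H_fit - H_true) / np.linalg.norm(H_true)
        assert rel < 0.05

    def test_white_noise_identity_transfer(self):
        rng = np.random.default_rng(14)
        ep = Epochs(rng.normal(size=(30, 2, 300)), FS, 0.0, ["a", "b"])
        fit = subspace_identify(ep, 2, horizon=10)
        H = transfer_function(fit.A, fit.C, fit.K, FS, FREQS)
        assert np.abs(H - np.eye(2)[None]).max() < 0.15
        S = spectral_matrices(fit, FREQS).S
        flat_dev = np.abs(S.real - S.real.mean(axis=0)).max()
        assert flat_dev < 0.2

    def test_innovations_covariance_on_heldout(self, true_model):
        ep = simulate_ss(true_model, 60, 400, seed=15)
        fit = subspace_identify(ep, 4)
        np.testing.assert_allclose(fit.Sigma, true_model.Sigma, atol=0.12)

    def test_stability_and_minimum_phase(self, network_epochs):
        fit = subspace_identify(network_epochs, 8)
        assert fit.spectral_radius() < 1.0
        assert fit.minphase_radius() < 1.0

    def test_order_15_accepted(self, network_epochs):
        fit = subspace_identify(network_epochs, 15)
        assert fit.order == 15


class TestOrderSelection:
    def test_white_noise_order_zero(self):
        rng = np.random.default_rng(16)
        ep = Epochs(rng.normal(size=(20, 2, 200)), FS, 0.0, ["a", "b"])
        assert select_order(ep, max_order=10, seed=0) == 0

    def test_recovers_true_order(self):
        A = np.zeros((2, 2, 2))
        A[0] = [[0.8, 0.0], [0.5, 0.3]]
        A[1] = [[-0.5, 0.0], [0.0, -0.4]]
        true = StateSpaceModel.from_var(A, np.eye(2), FS)
        hits = 0
        for s in range(5):
            ep = simulate_ss(true, 50, 400, seed=40 + s)
            if select_order(ep, max_order=10, seed=s) == 4:
                hits += 1
        assert hits >= 4

    def test_principal_angles_ordered(self, network_epochs):
        ang = principal_angles(network_epochs, horizon=14)
        assert np.all(np.diff(ang) >= -1e-12)
        assert np.all((ang >= 0) & (ang <= np.pi / 2 + 1e-12))


class TestModelResultsAPI:
    def test_fit_summary_and_bands(self, network_epochs):
        res = StateSpaceCGC(network_epochs, order=8, horizon=14).fit()
        assert res.model.order == 8
        s = res.summary()
        assert "state order: 8" in s
        M = res.band_matrix("alpha")
        assert M.shape == (3, 3)
        assert np.all(np.diag(M) == 0)

    def test_hdf5_round_trip(self, network_epochs, tmp_path):
        import h5py

        res = StateSpaceCGC(network_epochs, order=6, horizon=14).fit()
        p = tmp_path / "cgc.h5"
        res.to_hdf5(p)
        with h5py.File(p) as f:
            assert f["gc"].shape == res.gc.values.shape
            np.testing.assert_array_equal(f["freqs"][()], res.gc.freqs)

    def test_validate_rejects_bad_models(self):
        with pytest.raises(ValueError, match="unstable"):
            StateSpaceModel(np.eye(2) * 1.1, np.eye(2), np.zeros((2, 2)),
                            np.eye(2), FS).validate()
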