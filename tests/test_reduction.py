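import numpy as np
import pytest

from conftest import small_params
from sensmem.network import build_connectivity
from sensmem.reduction import (
    collect_manifold,
    drift_and_diffusion,
    jacobian_at,
    manifold_tangent,
    potential_and_indices,
    reduced_sde_spec,
    slow_mode,
)


@pytest.fixture(scope="module")
def small_manifold():
    """Noise-free manifold of a 60-neuron homogeneous coupled network."""
    return collect_manifold(small_params(), theta_grid=12, snapshot_s=1.0)


@pytest.fixture(scope="module")
def small_het_manifold():
    return collect_manifold(small_params(alpha=0.05), theta_grid=16, snapshot_s=1.0)


class TestManifold:
    def test_default_grid_is_50_orientations(self):
        # contract check without running the heavy default: grid generation only
        from sensmem.reduction import collect_manifold as cm
        import inspect
        assert inspect.signature(cm).parameters["theta_grid"].default == 50

    def test_homogeneous_states_are_index_rotations(self, small_manifold):
        ms = small_manifold
        p = ms.params
        # grid spacing 15 deg = 5 index steps for N=60
        shift = int(round(15.0 / (180.0 / p.Ns)))
        blocks = np.split(ms.sbar, [p.Ns, 2 * p.Ns, 2 * p.Ns + p.Nm])
        for blk in blocks:
            rolled = np.roll(blk[:, 0], shift)
            np.testing.assert_allclose(rolled, blk[:, 1], atol=1e-8 * blk.max())

    def test_residual_speed_small(self, small_manifold):
        assert np.all(small_manifold.residual_speed < 1e-3)

    def test_early_snapshot_rejected(self):
        with pytest.raises(ValueError):
            collect_manifold(small_params(), theta_grid=8, snapshot_s=0.2)


class TestTangent:
    def test_homogeneous_tangent_norm_constant(self, small_manifold):
        _, tnorm = manifold_tangent(small_manifold)
        assert np.ptp(tnorm) < 1e-6 * tnorm.mean()

    def test_periodic_closure(self, small_manifold):
        ds, _ = manifold_tangent(small_manifold)
        step = small_manifold.theta_grid[1] - small_manifold.theta_grid[0]
        closure = np.abs(ds.sum(axis=1) * step)
        assert closure.max() < 1e-6 * np.abs(small_manifold.sbar).max()

    def test_heterogeneous_tangent_larger_at_cardinal(self, small_het_manifold):
        _, tnorm = manifold_tangent(small_het_manifold)
        grid = small_het_manifold.theta_grid
        t0 = tnorm[np.argmin(np.abs(grid - 0.0))]
        t45 = tnorm[np.argmin(np.abs(grid - 45.0))]
        assert t0 > t45  # denser representation at the cardinal


class TestJacobian:
    def test_zero_state_subthreshold_is_minus_identity(self):
        # no background current: all operating points below threshold, G = 0
        p = small_params(Ic_m=0.0)
        K = jacobian_at(np.zeros(2 * p.Ns + 2 * p.Nm), p, mode="coupled")
        np.testing.assert_allclose(K, -np.eye(K.shape[0]), atol=1e-14)

    def test_matches_finite_difference_oracle(self, small_manifold):
        ms = small_manifold
        p = ms.params
        conn = build_connectivity(p, "coupled")
        s0 = ms.sbar[:, 3]
        K = jacobian_at(s0, p, conn, "coupled")

        from sensmem.reduction import _operating

        def rhs(s):
            flow, _, _, _ = _operating(p, conn, "coupled", s)
            return flow

        rng = np.random.default_rng(0)
        idx = rng.choice(s0.size, 25, replace=False)
        h = 1e-6
        for j in idx:
            e = np.zeros_like(s0)
            e[j] = h
            col = (rhs(s0 + e) - rhs(s0 - e)) / (2 * h)
            np.testing.assert_allclose(K[:, j], col, atol=1e-6)

    def test_neutral_mode_of_homogeneous_bump(self, small_manifold):
        ms = small_manifold
        K = jacobian_at(ms.sbar[:, 0], ms.params, mode="coupled")
        tangent, _ = manifold_tangent(ms)
        u, lam, gap = slow_mode(K, align_with=tangent[:, 0])
        assert abs(lam) < 1e-3  # continuous-attractor neutral rotation mode
        assert gap > 0.01
        # compare against a spectral (FFT) tangent: exact for the smooth
        # homogeneous manifold, unlike the coarse central difference
        n = ms.theta_grid.size
        freq = np.fft.fftfreq(n, d=1.0 / n)
        spectral = np.real(np.fft.ifft(1j * freq * np.fft.fft(ms.sbar, axis=1), axis=1))
        t0 = spectral[:, 0]
        cos = u @ t0 / np.linalg.norm(t0)
        assert cos > 0.999

    def test_condensed_slow_mode_matches_dense(self, small_manifold):
        ms = small_manifold
        conn = build_connectivity(ms.params, "coupled")
        from sensmem.reduction import _condensed_slow_mode, _operating

        tangent, _ = manifold_tangent(ms)
        _, _, slopes, _ = _operating(ms.params, conn, "coupled", ms.sbar[:, 2])
        u_c, lam_c, _ = _condensed_slow_mode(ms.params, conn, slopes, tangent[:, 2])
        K = jacobian_at(ms.sbar[:, 2], ms.params, conn, "coupled")
        u_d, lam_d, _ = slow_mode(K, align_with=tangent[:, 2])
        assert lam_c == pytest.approx(lam_d, abs=1e-10)
        np.testing.assert_allclose(u_c, u_d, atol=1e-8)

    def test_rank_one_analytic_eigenvector(self):
        # K = -I + a b^T has eigenvector a with eigenvalue -1 + b.a
        rng = np.random.default_rng(1)
        a = rng.normal(size=12)
        b = a + 0.1 * rng.normal(size=12)  # b.a > 0 so -1 + b.a is the top eigenvalue
        K = -np.eye(12) + np.outer(a, b)
        u, lam, _ = slow_mode(K, align_with=a)
        assert lam == pytest.approx(-1 + b @ a, rel=1e-10)
        np.testing.assert_allclose(u, a / np.linalg.norm(a), atol=1e-10)


class TestDriftDiffusion:
    def test_homogeneous_drift_negligible(self, small_manifold):
        rd = drift_and_diffusion(small_manifold)
        assert np.max(np.abs(rd.mu)) < 0.01  # deg/s

    def test_heterogeneous_drift_and_noise_pattern(self, small_het_manifold):
        rd = drift_and_diffusion(small_het_manifold)
        grid = rd.theta_grid
        i225 = np.argmin(np.abs(grid - 22.5))
        assert rd.mu[i225] > 0  # toward the oblique
        assert rd.dU > 0
        assert rd.noise_index > 0
        i45 = np.argmin(np.abs(grid - 45.0))
        assert rd.sigma[i45] == pytest.approx(rd.sigma.max(), rel=1e-6)

    def test_drift_antisymmetric_about_oblique(self, small_het_manifold):
        rd = drift_and_diffusion(small_het_manifold)
        # grid of 16: mu(22.5 + d) = -mu(67.5 - d) by the cos4psi symmetry
        mu = rd.mu
        np.testing.assert_allclose(mu, -np.roll(mu[::-1], 9), atol=1e-3 * np.abs(mu).max() + 1e-6)

    def test_roundtrip_drift_matches_full_network(self, small_het_manifold):
        # decoded drift rate of the noise-free network vs extracted mu
        from sensmem.experiments import estimate_pfs
        from sensmem.network import SimConfig, simulate
        from sensmem.readout import population_vector_decode

        ms = small_het_manifold
        p = ms.params
        pf, _ = estimate_pfs(p, mode="coupled", grid_n=24)
        cfg = SimConfig(t_stim=500, t_delay=2500, noise_model="none",
                        record_times=[2000, 3000])
        res = simulate(p, 22.5, cfg, mode="coupled")
        dec = population_vector_decode(res.r_m[:, 0, 0, :], pf.pf)
        v_net = (dec[1] - dec[0]) / 1.0  # deg/s between 1.5 s and 2.5 s of delay
        grid = np.append(ms.theta_grid, 180.0)
        mu = np.append(drift_and_diffusion(ms).mu, drift_and_diffusion(ms).mu[0])
        v_red = np.interp(dec.mean() % 180.0, grid, mu)
        assert v_net == pytest.approx(v_red, rel=0.25)


class TestPotentialAndIndices:
    def test_sin4_closed_form(self):
        grid = np.arange(72) / 72 * 180.0
        mu = np.sin(np.deg2rad(4 * grid))
        sigma = np.ones_like(mu)
        U, dU, ni = potential_and_indices(grid, mu, sigma)
        assert ni == 0.0
        assert dU > 0
        assert grid[np.argmin(U)] in (45.0, 135.0)

    def test_nonclosing_drift_flagged(self):
        grid = np.arange(36) / 36 * 180.0
        with pytest.warns(UserWarning, match="circulation"):
            potential_and_indices(grid, np.ones_like(grid), np.ones_like(grid))

    def test_reduced_sde_spec_interpolates(self, small_het_manifold):
        rd = drift_and_diffusion(small_het_manifold)
        spec = reduced_sde_spec(rd)
        spec.validate()
        i = 5
        assert spec.drift(rd.theta_grid[i]) == pytest.approx(
            rd.mu[i] - rd.mu.mean(), abs=1e-9
        )
        assert spec.noise_coef(rd.theta_grid[i]) == pytest.approx(rd.sigma[i], abs=1e-9)
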