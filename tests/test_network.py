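import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import small_params
from sensmem.network import (
    NetworkParams,
    SimConfig,
    TransferSpec,
    build_connectivity,
    build_intermodule_connectivity,
    build_memory_connectivity,
    build_sensory_connectivity,
    external_input,
    naka_rushton,
    simulate,
)

SENSORY_F = TransferSpec(100.0, 0.1, 2.0, 6.0)


class TestTransfer:
    def test_rectification_below_threshold(self):
        assert naka_rushton(0.1, SENSORY_F) == 0.0
        assert naka_rushton(-5.0, SENSORY_F) == 0.0

    def test_half_saturation_at_threshold_plus_w(self):
        assert naka_rushton(0.1 + 6.0, SENSORY_F) == pytest.approx(50.0)

    def test_sensory_spec_printed_value(self):
        assert naka_rushton(6.1, SENSORY_F) == pytest.approx(50.0)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(-2, 40), st.floats(-2, 40))
    def test_monotone_nondecreasing(self, a, b):
        lo, hi = sorted((a, b))
        assert naka_rushton(lo, SENSORY_F) <= naka_rushton(hi, SENSORY_F) + 1e-12

    def test_apply_matches_call(self):
        f = TransferSpec(100.0, 0.1, 1.5, 6.6)
        x = np.linspace(-1, 30, 997).reshape(1, -1)
        out = np.empty_like(x)
        scratch = np.empty_like(x)
        f.apply(x, out, scratch)
        np.testing.assert_allclose(out, f(x), rtol=1e-12)

    def test_derivative_matches_finite_difference(self):
        f = TransferSpec(100.0, 0.1, 1.5, 6.6)
        x = np.linspace(0.5, 30, 50)
        h = 1e-6
        fd = (f(x + h) - f(x - h)) / (2 * h)
        np.testing.assert_allclose(f.derivative(x), fd, rtol=1e-5)


class TestConnectivity:
    def test_combined_sensory_self_weights_printed_arithmetic(self):
        p = NetworkParams(alpha=0.04)
        Ws = build_sensory_connectivity(p)
        i45 = int(45 / 180 * p.Ns)
        # -JI + JE (1 - alpha cos 4psi) at zero distance
        assert p.Ns * Ws[i45, i45] == pytest.approx(-0.35 + 0.6 * 1.04)  # 0.274
        assert p.Ns * Ws[0, 0] == pytest.approx(-0.35 + 0.6 * 0.96)      # 0.226

    def test_memory_self_weight(self):
        p = NetworkParams()
        Wm = build_memory_connectivity(p)
        assert p.Nm * Wm[0, 0] == pytest.approx(1.0 - 0.17)

    def test_homogeneous_kernels_are_circulant(self):
        p = small_params()
        for W in (build_sensory_connectivity(p), build_memory_connectivity(p)):
            for row in (1, 17, 43):
                np.testing.assert_allclose(W[row], np.roll(W[0], row), atol=1e-14)

    def test_heterogeneous_memory_excitation_stronger_at_cardinal(self):
        p = NetworkParams(hetero_memory=True, alpha=5e-4, beta=2.4e-3)
        Wm = build_memory_connectivity(p)
        i45 = int(45 / 180 * p.Nm)
        # net self-weight reflects (1 + alpha) - JI(1 + beta) at psi=0
        exc0 = p.Nm * Wm[0, 0]
        exc45 = p.Nm * Wm[i45, i45]
        expected0 = 1.0 * (1 + 5e-4) - 0.17 * (1 + 2.4e-3)
        assert exc0 == pytest.approx(expected0)
        assert 1.0 * (1 + 5e-4) > 1.0 * (1 - 5e-4)  # modulation sign sanity
        assert exc0 != exc45

    def test_intermodule_peak_and_nonnegativity(self):
        p = NetworkParams()
        Wf, Wb = build_intermodule_connectivity(p)
        assert Wf.max() == pytest.approx(0.1 / 300)
        assert Wb.max() == pytest.approx(0.25 / 300)
        assert np.all(Wf >= 0) and np.all(Wb >= 0)

    def test_feedforward_feedback_kernel_symmetry(self):
        p = small_params()
        Wf, Wb = build_intermodule_connectivity(p)
        np.testing.assert_allclose(Wf / p.Jf * p.Ns, (Wb / p.Jb * p.Nm).T, atol=1e-14)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            NetworkParams(eps=0.6)
        with pytest.raises(ValueError):
            NetworkParams(alpha=-0.1)
        with pytest.raises(ValueError):
            TransferSpec(100.0, 0.1, 2.0, 0.0)


class TestExternalInput:
    def test_sensory_peak_and_tail(self):
        p = NetworkParams()
        vec = external_input(90.0, p, "sensory")
        i90 = int(90 / 180 * p.Ns)
        assert vec[i90] == pytest.approx(4.0)
        # far from the cue: baseline C (1 - 2 eps)
        assert vec[0] == pytest.approx(2.4, abs=0.02)

    def test_memory_isolated_peak(self):
        p = NetworkParams()
        vec = external_input(45.0, p, "memory_isolated")
        i45 = int(45 / 180 * p.Nm)
        assert vec[i45] == pytest.approx(1.0 + p.Ic_m)

    def test_memory_coupled_constant(self):
        p = NetworkParams()
        vec = external_input(10.0, p, "memory_coupled")
        assert np.all(vec == p.Ic_m)

    def test_unknown_target_rejected(self):
        with pytest.raises(ValueError):
            external_input(0.0, NetworkParams(), "cortex")


class TestSimulate:
    def test_memory_bump_persists_sensory_decays(self):
        p = NetworkParams()
        cfg = SimConfig(t_stim=500, t_delay=2000, noise_model="none",
                        record_times=[500, 2500])
        mem = simulate(p, 90.0, cfg, mode="memory_only").r_m[:, 0, 0, :]
        mod = mem.max(axis=1) - mem.min(axis=1)
        assert mod[1] > 0.5 * mod[0]
        sens = simulate(p, 90.0, cfg, mode="sensory_only").r_s[:, 0, 0, :]
        smod = sens.max(axis=1) - sens.min(axis=1)
        assert smod[1] < 0.05 * smod[0]

    def test_coupled_delay_rates_below_stimulus_rates(self):
        p = NetworkParams()
        cfg = SimConfig(t_stim=500, t_delay=2000, noise_model="none",
                        record_times=[500, 2500])
        res = simulate(p, 90.0, cfg, mode="coupled")
        assert res.r_s[1, 0, 0].max() < res.r_s[0, 0, 0].max()
        # memory module still carries a tuned bump in the delay
        rm = res.r_m[1, 0, 0]
        assert rm.max() - rm.min() > 10.0

    def test_rates_bounded_by_fmax(self):
        p = small_params()
        cfg = SimConfig(t_stim=300, t_delay=300, n_real=20, seed=0,
                        record_times=[150, 600])
        res = simulate(p, 45.0, cfg, mode="coupled")
        assert res.r_s.max() <= 100.0 and res.r_m.max() <= 100.0
        assert res.r_s.min() >= 0.0 and res.r_m.min() >= 0.0

    def test_rotation_equivariance_noise_free(self):
        # homogeneous network: shifting the cue by one index angle shifts
        # every profile by exactly one neuron
        p = small_params()
        step = 180.0 / p.Ns
        cfg = SimConfig(t_stim=300, t_delay=700, noise_model="none",
                        record_times=[1000])
        a = simulate(p, 60.0, cfg, mode="coupled")
        b = simulate(p, 60.0 + step, cfg, mode="coupled")
        np.testing.assert_allclose(np.roll(a.r_m[0, 0, 0], 1), b.r_m[0, 0, 0], atol=1e-10)
        np.testing.assert_allclose(np.roll(a.r_s[0, 0, 0], 1), b.r_s[0, 0, 0], atol=1e-10)

    def test_dt_convergence_noise_free(self):
        p = small_params()
        r1 = simulate(p, 30.0, SimConfig(t_stim=200, t_delay=300, noise_model="none",
                                         dt=1.0, record_times=[500]), mode="coupled")
        r2 = simulate(p, 30.0, SimConfig(t_stim=200, t_delay=300, noise_model="none",
                                         dt=0.5, record_times=[500]), mode="coupled")
        rel = np.linalg.norm(r1.r_m[0] - r2.r_m[0]) / np.linalg.norm(r2.r_m[0])
        assert rel < 2e-3

    def test_identical_seed_identical_result(self):
        p = small_params()
        cfg = SimConfig(t_stim=100, t_delay=100, n_real=10, seed=42, record_times=[200])
        a = simulate(p, 10.0, cfg, mode="coupled")
        b = simulate(p, 10.0, cfg, mode="coupled")
        np.testing.assert_array_equal(a.r_m, b.r_m)

    def test_frozen_transfer_one_step_noise_variance(self):
        # with rates pinned to r0, the first-step synaptic increment from s=0
        # has variance exactly r0 dt / tau^2
        r0 = 25.0

        class Frozen:
            def __call__(self, x):
                return np.full_like(x, r0)

        p = NetworkParams(Ns=64, Nm=64, fs=Frozen(), fm=Frozen())
        cfg = SimConfig(t_stim=1, t_delay=0, dt=1.0, n_real=20_000, seed=9,
                        record_times=[1], record_synaptic=True)
        res = simulate(p, 0.0, cfg, mode="memory_only")
        s1 = res.s["m"][0].astype(np.float64)  # (1, n_real, N)
        inc = s1 - r0 * cfg.dt / p.tau
        var = inc.var()
        assert var == pytest.approx(r0 * cfg.dt / p.tau**2, rel=0.03)

    def test_additive_gaussian_variance(self):
        r0 = 25.0

        class Frozen:
            def __call__(self, x):
                return np.full_like(x, r0)

        p = NetworkParams(Ns=64, Nm=64, fm=Frozen())
        cfg = SimConfig(t_stim=1, t_delay=0, dt=1.0, n_real=20_000, seed=10,
                        noise_model="additive_gaussian", gauss_sd=0.5,
                        record_times=[1], record_synaptic=True)
        res = simulate(p, 0.0, cfg, mode="memory_only")
        inc = res.s["m"][0].astype(np.float64) - r0 * cfg.dt / p.tau
        assert inc.var() == pytest.approx(0.5**2 * cfg.dt / p.tau**2, rel=0.03)

    def test_perturbation_gates_feedforward(self):
        p = small_params()
        base = SimConfig(t_stim=300, t_delay=700, noise_model="none", record_times=[1000])
        pert = SimConfig(t_stim=300, t_delay=700, noise_model="none", record_times=[1000],
                         perturb_t_on=0.0)
        a = simulate(p, 45.0, base, mode="coupled")
        b = simulate(p, 45.0, pert, mode="coupled")
        assert not np.allclose(a.r_m[0], b.r_m[0])

    def test_dt_too_large_rejected(self):
        with pytest.raises(ValueError, match="tau/5"):
            simulate(small_params(), 0.0, SimConfig(dt=5.0), mode="coupled")

    def test_bad_record_time_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            simulate(small_params(), 0.0,
                     SimConfig(t_stim=100, t_delay=100, record_times=[500]),
                     mode="coupled")

    def test_perturb_outside_delay_rejected(self):
        with pytest.raises(ValueError, match="delay"):
            SimConfig(t_stim=100, t_delay=100, perturb_t_on=200.0)
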