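"""Stochastic firing-rate networks with sensory and memory ring modules.

Each module is a ring of N rate units labelled by index angles
psi_i = (i-1)/N * 180 deg covering the orientation circle.  Rates follow
instantaneously from currents through a Naka-Rushton transfer function,
while synaptic activations low-pass filter the rates with time constant
tau and carry the noise:

    r = f(W s + I_ext)
    tau ds/dt = -s + r + xi,     <xi_i(t) xi_j(t')> = r_i(t) delta_ij delta(t-t')

The Poisson-like noise variance proportional to the presynaptic rate
approximates spiking variability.  In the coupled two-module network the
sensory rates drive both the recurrent (s_s) and feedforward (s_f)
synapses, and the memory rates drive the recurrent (s_m) and feedback
(s_b) synapses, each with an independent noise stream.

Because orientation is 180-degree periodic, the ring is laid out on the
angle-doubled circle: index angle psi_i = (i-1)/N * 180 deg maps to
phi_i = 2 psi_i in [0, 2 pi) radians, kernel distances are differences on
that full circle wrapped to (-pi, pi], and a stimulus theta enters at
phi = 2 theta.  All cos(4 psi) heterogeneity modulations equal cos(2 phi)
in this coordinate.  Heterogeneity enters as amplitude modulation of the
kernels: in the combined excitation/inhibition sensory kernel the
excitatory amplitude is scaled by (1 - alpha cos 4 psi_post) (strongest at
the obliques), while in the segregated kernels excitation and inhibition
are scaled by (1 + alpha cos 4 psi_post) and (1 + beta cos 4 psi_post)
(strongest at the cardinals).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._angles import wrap_index_angle

__all__ = [
    "TransferSpec",
    "NetworkParams",
    "ConnectivitySet",
    "SimConfig",
    "SimResult",
    "naka_rushton",
    "build_sensory_connectivity",
    "build_memory_connectivity",
    "build_intermodule_connectivity",
    "build_connectivity",
    "external_input",
    "simulate",
]


@dataclass(frozen=True)
class TransferSpec:
    """Naka-Rushton current-to-rate transfer f(x) = fmax (x-T)^q / (w^q + (x-T)^q)."""

    fmax: float
    T: float
    q: float
    w: float

    def __post_init__(self):
        if self.fmax <= 0 or self.w <= 0 or self.q <= 0:
            raise ValueError("fmax, w, q must be positive")

    def __call__(self, x):
        y = np.maximum(np.asarray(x) - self.T, 0.0)
        yq = y**self.q
        return self.fmax * yq / (self.w**self.q + yq)

    def apply(self, x, out, scratch):
        """Allocation-free evaluation into ``out`` using one scratch buffer."""
        np.subtract(x, self.T, out=scratch)
        np.maximum(scratch, 0.0, out=scratch)
        if self.q == 2.0:
            np.multiply(scratch, scratch, out=out)
        elif self.q == 1.5:
            np.sqrt(scratch, out=out)
            out *= scratch
        else:
            np.power(scratch, self.q, out=out)
        np.add(out, self.w**self.q, out=scratch)
        np.divide(out, scratch, out=out)
        out *= self.fmax
        return out

    def derivative(self, x):
        """df/dx; zero at and below threshold."""
        y = np.maximum(np.asarray(x, dtype=float) - self.T, 0.0)
        yq = y**self.q
        denom = (self.w**self.q + yq) ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            out = self.fmax * self.q * y ** (self.q - 1.0) * self.w**self.q / denom
        return np.where(y > 0, out, 0.0)


def naka_rushton(x, spec: TransferSpec):
    """Functional form of the transfer; see :class:`TransferSpec`."""
    return spec(x)


@dataclass(frozen=True)
class NetworkParams:
    """All structural parameters of the sensory-memory network.

    Defaults are the reference parameter set: synaptic amplitudes J (current
    per unit rate, scaled by 1/N_presynaptic), Gaussian kernel widths lam in
    radians of the [0, pi) index circle, stimulus contrast C with tuned
    fraction eps and width lam_ext_s, and per-module Naka-Rushton transfers.
    ``segregated_EI`` selects the segregated excitatory/inhibitory sensory
    kernel; ``hetero_memory`` makes the memory kernel heterogeneous (used
    for the one-module network).  Ic_m is the constant background current
    to the memory module; the default keeps the network quiescent without
    a stimulus while supporting a persistent bump after one.
    """

    Ns: int = 300
    Nm: int = 300
    tau: float = 10.0  # ms
    JE_s: float = 0.6
    JI_s: float = 0.35
    JE_m: float = 1.0
    JI_m: float = 0.17
    Jf: float = 0.1
    Jb: float = 0.25
    lamE_s: float = 0.36 * np.pi
    lamI_s: float = 1.1 * np.pi
    lamE_m: float = 0.2 * np.pi
    lamI_m: float = 0.6 * np.pi
    lamf: float = 0.17 * np.pi
    lamb: float = 0.17 * np.pi
    alpha: float = 0.0
    beta: float = 0.0
    C: float = 4.0
    eps: float = 0.2
    lam_ext_s: float = 0.3 * np.pi
    Ic_m: float = 0.7
    fs: TransferSpec = field(default_factory=lambda: TransferSpec(100.0, 0.1, 2.0, 6.0))
    fm: TransferSpec = field(default_factory=lambda: TransferSpec(100.0, 0.1, 1.5, 6.6))
    segregated_EI: bool = False
    hetero_memory: bool = False

    def __post_init__(self):
        if not (0.0 < self.eps <= 0.5):
            raise ValueError("eps must lie in (0, 0.5]")
        if self.Ns < 2 or self.Nm < 2:
            raise ValueError("population sizes must be >= 2")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("heterogeneity degrees must be nonnegative")
        for name in ("lamE_s", "lamI_s", "lamE_m", "lamI_m", "lamf", "lamb", "lam_ext_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def gamma(self) -> float:
        """Effective intermodule loop gain Jf * Jb."""
        return self.Jf * self.Jb

    def replace(self, **kw) -> "NetworkParams":
        return replace(self, **kw)


def _phi(n: int) -> np.ndarray:
    """Index angles on the doubled circle: phi_i = 2 psi_i in [0, 2 pi)."""
    return np.arange(n) / n * 2.0 * np.pi


@dataclass
class ConnectivitySet:
    Ws: np.ndarray | None
    Wm: np.ndarray | None
    Wf: np.ndarray | None
    Wb: np.ndarray | None
    psi_s: np.ndarray  # degrees
    psi_m: np.ndarray  # degrees


def _gauss_kernel(phi_post: np.ndarray, phi_pre: np.ndarray, lam: float) -> np.ndarray:
    d = wrap_index_angle(phi_post[:, None] - phi_pre[None, :], period=2.0 * np.pi)
    return np.exp(-(d**2) / lam**2)


def build_sensory_connectivity(params: NetworkParams) -> np.ndarray:
    """Recurrent sensory kernel Ws (signed, scaled by 1/Ns).

    Combined form: constant global inhibition -JI_s plus local excitation
    JE_s (1 - alpha cos 4 psi_post) with width lamE_s.  Segregated form:
    separate Gaussian inhibitory and excitatory kernels, amplitudes
    modulated by (1 + beta cos 4 psi_post) and (1 + alpha cos 4 psi_post).
    """
    phi = _phi(params.Ns)
    cos4 = np.cos(2.0 * phi)  # == cos(4 psi)
    kE = _gauss_kernel(phi, phi, params.lamE_s)
    if params.segregated_EI:
        kI = _gauss_kernel(phi, phi, params.lamI_s)
        J = (
            -params.JI_s * (1.0 + params.beta * cos4)[:, None] * kI
            + params.JE_s * (1.0 + params.alpha * cos4)[:, None] * kE
        )
    else:
        J = -params.JI_s + params.JE_s * (1.0 - params.alpha * cos4)[:, None] * kE
    return J / params.Ns


def build_memory_connectivity(params: NetworkParams) -> np.ndarray:
    """Recurrent memory kernel Wm: difference of Gaussians, scaled by 1/Nm.

    With ``hetero_memory`` the excitatory and inhibitory amplitudes carry
    cardinal-enhancing modulations (1 + alpha cos 4 psi_post) and
    (1 + beta cos 4 psi_post), as in the one-module network.
    """
    phi = _phi(params.Nm)
    kE = _gauss_kernel(phi, phi, params.lamE_m)
    kI = _gauss_kernel(phi, phi, params.lamI_m)
    if params.hetero_memory:
        cos4 = np.cos(2.0 * phi)
        J = (
            -params.JI_m * (1.0 + params.beta * cos4)[:, None] * kI
            + params.JE_m * (1.0 + params.alpha * cos4)[:, None] * kE
        )
    else:
        J = -params.JI_m * kI + params.JE_m * kE
    return J / params.Nm


def build_intermodule_connectivity(params: NetworkParams) -> tuple[np.ndarray, np.ndarray]:
    """Nonnegative Gaussian feedforward (Wf: sensory->memory) and feedback kernels."""
    phi_s = _phi(params.Ns)
    phi_m = _phi(params.Nm)
    Wf = params.Jf * _gauss_kernel(phi_m, phi_s, params.lamf) / params.Ns
    Wb = params.Jb * _gauss_kernel(phi_s, phi_m, params.lamb) / params.Nm
    return Wf, Wb


def build_connectivity(params: NetworkParams, mode: str = "coupled") -> ConnectivitySet:
    psi_s = np.arange(params.Ns) / params.Ns * 180.0
    psi_m = np.arange(params.Nm) / params.Nm * 180.0
    Ws = Wm = Wf = Wb = None
    if mode in ("coupled", "sensory_only"):
        Ws = build_sensory_connectivity(params)
    if mode in ("coupled", "memory_only"):
        Wm = build_memory_connectivity(params)
    if mode == "coupled":
        Wf, Wb = build_intermodule_connectivity(params)
    return ConnectivitySet(Ws=Ws, Wm=Wm, Wf=Wf, Wb=Wb, psi_s=psi_s, psi_m=psi_m)


def external_input(theta_deg, params: NetworkParams, target: str) -> np.ndarray:
    """Stimulus-epoch external currents for orientation(s) theta (deg).

    sensory: C (1 - 2 eps + 2 eps exp(-d(psi, theta)^2 / lam_ext_s^2));
    memory_isolated: (cos(2 (psi - theta)) + 1)/2 + Ic_m;
    memory_coupled: constant Ic_m.
    Returns shape (N,) for scalar theta, else (N, n_theta).
    """
    theta = 2.0 * np.deg2rad(np.asarray(theta_deg, dtype=float))  # doubled circle
    scalar = theta.ndim == 0
    theta = np.atleast_1d(theta)
    if target == "sensory":
        phi = _phi(params.Ns)
        d = wrap_index_angle(phi[:, None] - theta[None, :], period=2.0 * np.pi)
        out = params.C * (
            1.0 - 2.0 * params.eps + 2.0 * params.eps * np.exp(-(d**2) / params.lam_ext_s**2)
        )
    elif target == "memory_isolated":
        phi = _phi(params.Nm)
        d = wrap_index_angle(phi[:, None] - theta[None, :], period=2.0 * np.pi)
        out = 0.5 * (np.cos(d) + 1.0) + params.Ic_m  # cos(2(psi-theta)) == cos(dphi)
    elif target == "memory_coupled":
        out = np.full((params.Nm, theta.size), params.Ic_m)
    else:
        raise ValueError(f"unknown input target {target!r}")
    return out[:, 0] if scalar else out


@dataclass
class SimConfig:
    """Integration and protocol settings.

    Times are in ms.  The stimulus is on for t < t_stim and the delay lasts
    t_delay after stimulus offset.  ``record_times`` are absolute times
    (ms from stimulus onset) at which rates (and, optionally, synaptic
    states) are stored; by default only the final state is kept.
    ``perturb_t_on``, if set, gates the feedforward current to zero from
    that many ms into the delay (a model of TMS interrupting the
    feedforward pathway; the feedforward synapses keep integrating).
    """

    dt: float = 1.0
    t_stim: float = 500.0
    t_delay: float = 1000.0
    n_real: int = 1
    noise_model: str = "poisson_like"  # or "additive_gaussian", "none"
    gauss_sd: float = 0.5
    seed: int = 0
    record_times: Sequence[float] | None = None
    record_synaptic: bool = False
    perturb_t_on: float | None = None  # ms into the delay
    dtype: type | None = None

    def __post_init__(self):
        if self.dt <= 0 or self.t_stim < 0 or self.t_delay < 0:
            raise ValueError("dt must be positive; epochs nonnegative")
        if self.noise_model not in ("poisson_like", "additive_gaussian", "none"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.perturb_t_on is not None and not (
            0.0 <= self.perturb_t_on <= self.t_delay
        ):
            raise ValueError("perturb_t_on must lie inside the delay window")

    @property
    def t_total(self) -> float:
        return self.t_stim + self.t_delay


@dataclass
class SimResult:
    """Recorded ensemble state.

    Rate arrays have shape (n_record, n_theta, n_real, N); synaptic blocks
    (if recorded) are stored per name in ``s`` with the same layout.
    """

    times: np.ndarray
    thetas: np.ndarray
    r_s: np.ndarray | None
    r_m: np.ndarray | None
    s: dict | None
    mode: str
    params: NetworkParams
    config: SimConfig

    def at_time(self, t_ms: float, module: str = "m") -> np.ndarray:
        i = np.nonzero(np.isclose(self.times, t_ms))[0]
        if i.size == 0:
            raise KeyError(f"time {t_ms} ms was not recorded")
        arr = self.r_m if module == "m" else self.r_s
        if arr is None:
            raise KeyError(f"module {module!r} not present in this simulation")
        return arr[i[0]]

    def delay_time(self, seconds: float) -> float:
        """Absolute record time (ms) for a time point ``seconds`` into the delay."""
        return self.config.t_stim + 1000.0 * seconds


def simulate(
    params: NetworkParams,
    theta,
    config: SimConfig,
    mode: str = "coupled",
    conn: ConnectivitySet | None = None,
) -> SimResult:
    """Euler integration of the stochastic rate dynamics.

    All orientations in ``theta`` and all ``config.n_real`` realizations are
    advanced as one batch.  Per synaptic population the update is

        s <- s + (dt/tau) (r - s) + (1/tau) sqrt(r dt) eta,

    with independent standard-normal eta per neuron, step and population
    (poisson_like noise); rates are recomputed instantaneously from the
    currents each step.  The same seed yields an identical ensemble.
    """
    if mode not in ("coupled", "sensory_only", "memory_only"):
        raise ValueError(f"unknown mode {mode!r}")
    if config.dt > params.tau / 5.0:
        raise ValueError("dt must be at most tau/5 for a stable Euler step")
    conn = conn or build_connectivity(params, mode)
    thetas = np.atleast_1d(np.asarray(theta, dtype=float))
    n_theta, n_real = thetas.size, config.n_real
    B = n_theta * n_real
    dtype = config.dtype or (np.float64 if config.noise_model == "none" else np.float32)

    dt, tau = config.dt, params.tau
    n_steps = int(round(config.t_total / dt))
    record_times = (
        np.asarray(config.record_times, dtype=float)
        if config.record_times is not None
        else np.asarray([config.t_total])
    )
    record_steps = {}
    for i, t in enumerate(record_times):
        st = int(round(t / dt))
        if not (0 <= st <= n_steps):
            raise ValueError(f"record time {t} ms outside the simulated window")
        record_steps.setdefault(st, []).append(i)
    stim_steps = int(round(config.t_stim / dt))
    perturb_step = (
        stim_steps + int(round(config.perturb_t_on / dt))
        if config.perturb_t_on is not None
        else None
    )

    rng = np.random.default_rng(config.seed)

    def _tile(vec_or_mat):
        # (N,) or (N, n_theta) -> (N, B) with realization-major tiling
        arr = np.asarray(vec_or_mat, dtype=dtype)
        if arr.ndim == 1:
            arr = arr[:, None]
        return np.repeat(arr, n_real, axis=1) if arr.shape[1] == n_theta else arr

    has_s = mode in ("coupled", "sensory_only")
    has_m = mode in ("coupled", "memory_only")
    Ws = conn.Ws.astype(dtype) if has_s else None
    Wm = conn.Wm.astype(dtype) if has_m else None
    Wf = conn.Wf.astype(dtype) if mode == "coupled" else None
    Wb = conn.Wb.astype(dtype) if mode == "coupled" else None

    if has_s:
        I_s_stim = _tile(external_input(thetas, params, "sensory"))
        I_s_delay = np.zeros_like(I_s_stim)
    if mode == "memory_only":
        I_m_stim = _tile(external_input(thetas, params, "memory_isolated"))
        I_m_delay = np.full_like(I_m_stim, params.Ic_m)
    elif mode == "coupled":
        I_m_stim = I_m_delay = np.full((params.Nm, B), params.Ic_m, dtype=dtype)

    state_names = {
        "coupled": ("s", "f", "m", "b"),
        "sensory_only": ("s",),
        "memory_only": ("m",),
    }[mode]
    sizes = {"s": params.Ns, "f": params.Ns, "m": params.Nm, "b": params.Nm}
    if mode == "coupled":
        # states grouped by the current they feed, so each module's input is
        # one stacked GEMM: x_s = [Ws | Wb] [s_s; s_b], x_m = [Wm | Wf] [s_m; s_f]
        cat_sb = np.zeros((params.Ns + params.Nm, B), dtype=dtype)
        cat_mf = np.zeros((params.Nm + params.Ns, B), dtype=dtype)
        states = {
            "s": cat_sb[: params.Ns],
            "b": cat_sb[params.Ns :],
            "m": cat_mf[: params.Nm],
            "f": cat_mf[params.Nm :],
        }
        W_sens = np.ascontiguousarray(np.hstack([Ws, Wb]))
        W_mem = np.ascontiguousarray(np.hstack([Wm, Wf]))
    else:
        states = {k: np.zeros((sizes[k], B), dtype=dtype) for k in state_names}

    n_rec = record_times.size
    r_s_rec = np.empty((n_rec, params.Ns, B), dtype=dtype) if has_s else None
    r_m_rec = np.empty((n_rec, params.Nm, B), dtype=dtype) if has_m else None
    s_rec = (
        {k: np.empty((n_rec, sizes[k], B), dtype=dtype) for k in state_names}
        if config.record_synaptic
        else None
    )

    noisy = config.noise_model != "none"
    add_gauss = config.noise_model == "additive_gaussian"
    dt_over_tau = dtype(dt / tau)
    decay = dtype(1.0 - dt / tau)
    noise_scale = dtype(np.sqrt(dt) / tau)
    gauss_step_sd = dtype(config.gauss_sd) * noise_scale

    # preallocated work buffers (the loop below performs no allocations)
    buf = {
        "x_s": np.empty((params.Ns, B), dtype=dtype),
        "x_m": np.empty((params.Nm, B), dtype=dtype),
    }
    scratch_s = np.empty((params.Ns, B), dtype=dtype) if has_s else None
    scratch_m = np.empty((params.Nm, B), dtype=dtype) if has_m else None
    r_s = np.empty((params.Ns, B), dtype=dtype) if has_s else None
    r_m = np.empty((params.Nm, B), dtype=dtype) if has_m else None
    eta = np.empty((len(state_names), max(params.Ns, params.Nm), B), dtype=dtype) if noisy else None
    fs_apply = getattr(params.fs, "apply", None)
    fm_apply = getattr(params.fm, "apply", None)

    def _check_finite(step):
        arr = r_s if has_s else r_m
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError(f"non-finite state at t = {step * dt:.1f} ms")

    for step in range(n_steps + 1):
        stim_on = step < stim_steps
        ff_on = perturb_step is None or step < perturb_step
        if has_s:
            x_s = buf["x_s"]
            if mode == "coupled":
                np.matmul(W_sens, cat_sb, out=x_s)
            else:
                np.matmul(Ws, states["s"], out=x_s)
            x_s += I_s_stim if stim_on else I_s_delay
            if fs_apply is not None:
                fs_apply(x_s, r_s, scratch_s)
            else:
                r_s = np.asarray(params.fs(x_s), dtype=dtype)
        if has_m:
            x_m = buf["x_m"]
            if mode == "coupled" and ff_on:
                np.matmul(W_mem, cat_mf, out=x_m)
            else:
                np.matmul(Wm, states["m"], out=x_m)
            if mode != "sensory_only":
                x_m += I_m_stim if stim_on else I_m_delay
            if fm_apply is not None:
                fm_apply(x_m, r_m, scratch_m)
            else:
                r_m = np.asarray(params.fm(x_m), dtype=dtype)

        if step in record_steps:
            _check_finite(step)
            for i in record_steps[step]:
                if has_s:
                    r_s_rec[i] = r_s
                if has_m:
                    r_m_rec[i] = r_m
                if s_rec is not None:
                    for k in state_names:
                        s_rec[k][i] = states[k]
        if step == n_steps:
            _check_finite(step)
            break

        if noisy:
            rng.standard_normal(out=eta.reshape(-1), dtype=dtype)
        # per-module buffers shared by the two synaptic populations a rate
        # drives: the Euler drive term (dt/tau) r and the noise std sqrt(r dt)/tau
        if has_s:
            np.multiply(r_s, dt_over_tau, out=buf["x_s"])
            if noisy and not add_gauss:
                np.sqrt(r_s, out=scratch_s)
                scratch_s *= noise_scale
        if has_m:
            np.multiply(r_m, dt_over_tau, out=buf["x_m"])
            if noisy and not add_gauss:
                np.sqrt(r_m, out=scratch_m)
                scratch_m *= noise_scale
        for j, k in enumerate(state_names):
            sensory_driven = k in ("s", "f")
            s = states[k]
            s *= decay
            s += buf["x_s" if sensory_driven else "x_m"]
            if noisy:
                e = eta[j, : sizes[k], :]
                if add_gauss:
                    e *= gauss_step_sd
                else:
                    e *= scratch_s if sensory_driven else scratch_m
                s += e
        if step % 64 == 0:
            # quiescent states decay exponentially toward zero; flush them
            # before they reach the subnormal range (severe FPU slowdown)
            for k in state_names:
                s = states[k]
                np.copyto(s, 0.0, where=np.abs(s) < 1e-25)

    def _reshape(arr):
        if arr is None:
            return None
        return np.moveaxis(
            arr.reshape(arr.shape[0], arr.shape[1], n_theta, n_real), 1, -1
        )

    return SimResult(
        times=record_times,
        thetas=thetas,
        r_s=_reshape(r_s_rec),
        r_m=_reshape(r_m_rec),
        s={k: _reshape(v) for k, v in s_rec.items()} if s_rec is not None else None,
        mode=mode,
        params=params,
        config=config,
    )
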