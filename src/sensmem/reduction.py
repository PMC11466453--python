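"""Drift-diffusion reduction of the network dynamics along the memory manifold.

During the delay the noise-free network relaxes quickly onto a
one-dimensional trajectory of synaptic states s_bar(theta) parameterized
by the cue orientation.  Writing the synaptic dynamics in the compact form

    tau ds/dt = -s + phi(W s + h) + xi,

linearizing around s_bar gives tau d(ds)/dt = K ds with
K = -I + G W (G the diagonal of transfer-function slopes at the operating
currents).  The slow direction u is the right eigenvector of K with the
largest real eigenvalue (the near-neutral rotation mode of the ring).
Projecting the noise-free flow onto u and normalizing by the manifold
speed ||s_bar'(theta)|| yields the drift velocity

    mu(theta) = uT [ -s_bar + phi(W s_bar + h) ] / (tau ||s_bar'||),

and projecting the Poisson-like noise covariance (variance = rate) yields
the diffusion coefficient

    2 D(theta) = sum_i u_i^2 phi_i(W s_bar + h) / (tau ||s_bar'||)^2,

with noise coefficient sigma = sqrt(2 D).  Integrating -mu gives the
equivalent energy potential U(theta); the potential difference
U(0) - U(45) and the noise-coefficient index
(sigma(45) - sigma(0)) / (sigma(45) + sigma(0)) summarize how strongly
drift and diffusion distinguish cardinal from oblique orientations.

In the coupled network the linearization has a two-block structure: the
sensory rate drives both s_s and s_f, and the memory rate drives both
s_m and s_b, so every eigenmode of K with eigenvalue != -1 has equal
sensory-recurrent/feedforward and memory-recurrent/feedback components.
The slow mode is therefore computed from the condensed 2N x 2N matrix
[[Gs Ws, Gs Wb], [Gm Wf, Gm Wm]] - I and expanded back to 4N.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from .attractor import DriftDiffusionSpec
from .network import ConnectivitySet, NetworkParams, SimConfig, build_connectivity, simulate

__all__ = [
    "ManifoldSample",
    "ReducedDynamics",
    "collect_manifold",
    "manifold_tangent",
    "jacobian_at",
    "slow_mode",
    "drift_and_diffusion",
    "potential_and_indices",
    "reduced_sde_spec",
]

_BLOCKS = ("s", "f", "m", "b")


@dataclass
class ManifoldSample:
    """Noise-free synaptic states along the memory manifold.

    sbar has shape (dim, n_grid): dim = Ns + Ns + Nm + Nm (blocks s, f, m, b)
    for the coupled network, Nm for the one-module memory network.
    """

    sbar: np.ndarray
    theta_grid: np.ndarray        # deg
    snapshot_s: float             # s into the delay
    mode: str
    params: NetworkParams
    residual_speed: np.ndarray    # tau * ||ds/dt|| / ||s|| per grid point


@dataclass
class ReducedDynamics:
    """Reduced 1-D drift-diffusion description of the memory dynamics."""

    theta_grid: np.ndarray     # deg
    mu: np.ndarray             # deg / s
    D: np.ndarray              # deg^2 / s
    sigma: np.ndarray          # deg / sqrt(s)
    U: np.ndarray              # potential, deg^2 / s, zero mean
    dU: float                  # U(0 deg) - U(45 deg)
    noise_index: float         # (sigma(45) - sigma(0)) / (sigma(45) + sigma(0))
    tangent_norm: np.ndarray   # ||s_bar'(theta)|| per degree
    eigenvalue: np.ndarray     # slow eigenvalue per grid point (units of 1/tau)
    spectral_gap: np.ndarray   # Re(lambda_1) - Re(lambda_2) per grid point


def _operating(params: NetworkParams, conn: ConnectivitySet, mode: str, sbar: np.ndarray):
    """Currents, rates and slopes at a manifold state (single grid point)."""
    if mode == "coupled":
        Ns, Nm = params.Ns, params.Nm
        s_s, s_f, s_m, s_b = np.split(sbar, [Ns, 2 * Ns, 2 * Ns + Nm])
        x_s = conn.Ws @ s_s + conn.Wb @ s_b  # delay epoch: no external sensory drive
        x_m = conn.Wm @ s_m + conn.Wf @ s_f + params.Ic_m
        r_s, r_m = params.fs(x_s), params.fm(x_m)
        g_s, g_m = params.fs.derivative(x_s), params.fm.derivative(x_m)
        rates = np.concatenate([r_s, r_s, r_m, r_m])
        flow = -sbar + np.concatenate([r_s, r_s, r_m, r_m])
        return flow, rates, (g_s, g_m), (x_s, x_m)
    if mode == "memory_only":
        x_m = conn.Wm @ sbar + params.Ic_m
        r_m = params.fm(x_m)
        g_m = params.fm.derivative(x_m)
        return -sbar + r_m, r_m, (g_m,), (x_m,)
    raise ValueError(f"unsupported mode {mode!r}")


def collect_manifold(
    params: NetworkParams,
    theta_grid: np.ndarray | int = 50,
    snapshot_s: float = 1.0,
    mode: str = "coupled",
    t_stim: float = 500.0,
    residual_threshold: float = 1e-3,
) -> ManifoldSample:
    """One noise-free simulation per cue orientation; state at the snapshot.

    The snapshot (default 1 s into the delay) must leave enough time for
    the fast stimulus-offset transient to decay; the residual speed
    tau ||ds/dt|| / ||s|| is measured at the snapshot and a warning is
    emitted where it exceeds ``residual_threshold``.
    """
    if np.isscalar(theta_grid):
        theta_grid = np.arange(int(theta_grid)) / int(theta_grid) * 180.0
    theta_grid = np.asarray(theta_grid, dtype=float)
    if snapshot_s < 0.5:
        raise ValueError("snapshot must be at least 0.5 s into the delay")
    conn = build_connectivity(params, mode)
    t_rec = t_stim + 1000.0 * snapshot_s
    cfg = SimConfig(
        t_stim=t_stim,
        t_delay=1000.0 * snapshot_s,
        noise_model="none",
        record_times=[t_rec],
        record_synaptic=True,
    )
    res = simulate(params, theta_grid, cfg, mode=mode, conn=conn)
    if mode == "coupled":
        sbar = np.concatenate([res.s[k][0, :, 0, :] for k in _BLOCKS], axis=1).T
    else:
        sbar = res.s["m"][0, :, 0, :].T
    residual = np.empty(theta_grid.size)
    for k in range(theta_grid.size):
        flow, _, _, _ = _operating(params, conn, mode, sbar[:, k])
        residual[k] = np.linalg.norm(flow) / max(np.linalg.norm(sbar[:, k]), 1e-300)
    if np.any(residual > residual_threshold):
        warnings.warn(
            f"manifold residual speed up to {residual.max():.2e} exceeds "
            f"{residual_threshold:.1e}; transients may not have decayed",
            stacklevel=2,
        )
    return ManifoldSample(
        sbar=sbar,
        theta_grid=theta_grid,
        snapshot_s=snapshot_s,
        mode=mode,
        params=params,
        residual_speed=residual,
    )


def manifold_tangent(ms: ManifoldSample) -> tuple[np.ndarray, np.ndarray]:
    """Periodic central-difference tangent s_bar'(theta) and its norm (per deg)."""
    if ms.theta_grid.size < 8:
        raise ValueError("need at least 8 grid orientations")
    step = ms.theta_grid[1] - ms.theta_grid[0]
    ds = (np.roll(ms.sbar, -1, axis=1) - np.roll(ms.sbar, 1, axis=1)) / (2.0 * step)
    return ds, np.linalg.norm(ds, axis=0)


def jacobian_at(
    sbar_k: np.ndarray,
    params: NetworkParams,
    conn: ConnectivitySet | None = None,
    mode: str = "coupled",
) -> np.ndarray:
    """Full linearization K = -I + G W_big at one manifold state.

    For the coupled network W_big is the 4N x 4N block matrix routing the
    recurrent, feedforward and feedback currents, and G the diagonal of
    transfer slopes at the operating currents.  Operating points within
    1e-9 of the rectification threshold are flagged (the slope is not
    defined there).
    """
    conn = conn or build_connectivity(params, mode)
    _, _, slopes, currents = _operating(params, conn, mode, sbar_k)
    transfers = (params.fs, params.fm) if mode == "coupled" else (params.fm,)
    for x, f in zip(currents, transfers):
        if np.any(np.abs(x - f.T) < 1e-9):
            warnings.warn("operating point at the rectification threshold", stacklevel=2)
    if mode == "coupled":
        g_s, g_m = slopes
        Ns, Nm = params.Ns, params.Nm
        dim = 2 * Ns + 2 * Nm
        K = np.zeros((dim, dim))
        GsWs = g_s[:, None] * conn.Ws
        GsWb = g_s[:, None] * conn.Wb
        GmWf = g_m[:, None] * conn.Wf
        GmWm = g_m[:, None] * conn.Wm
        for row in (0, 1):  # s_s and s_f rows share the sensory current
            K[row * Ns : (row + 1) * Ns, :Ns] = GsWs
            K[row * Ns : (row + 1) * Ns, 2 * Ns + Nm :] = GsWb
        for row in (0, 1):  # s_m and s_b rows share the memory current
            lo = 2 * Ns + row * Nm
            K[lo : lo + Nm, Ns : 2 * Ns] = GmWf
            K[lo : lo + Nm, 2 * Ns : 2 * Ns + Nm] = GmWm
    else:
        (g_m,) = slopes
        K = g_m[:, None] * conn.Wm
    K[np.diag_indices_from(K)] -= 1.0
    return K


def _condensed_slow_mode(params, conn, slopes, align_with):
    """Slow mode of the coupled network via the 2N x 2N condensed matrix."""
    g_s, g_m = slopes
    Ns, Nm = params.Ns, params.Nm
    Kc = np.block(
        [
            [g_s[:, None] * conn.Ws, g_s[:, None] * conn.Wb],
            [g_m[:, None] * conn.Wf, g_m[:, None] * conn.Wm],
        ]
    )
    Kc[np.diag_indices_from(Kc)] -= 1.0
    lam, vec = sla.eig(Kc)
    order = np.argsort(-lam.real)
    lam1, lam2 = lam[order[0]], lam[order[1]]
    v = vec[:, order[0]]
    if np.max(np.abs(v.imag)) > 1e-6 * np.linalg.norm(v):
        raise ValueError(
            f"slow mode is complex (eigenvalues {lam1:.4g}, {np.conj(lam1):.4g})"
        )
    v = v.real
    u = np.concatenate([v[:Ns], v[:Ns], v[Ns:], v[Ns:]])
    u /= np.linalg.norm(u)
    if align_with is not None and u @ align_with < 0:
        u = -u
    return u, lam1.real, lam1.real - lam2.real


def slow_mode(K: np.ndarray, align_with: np.ndarray | None = None):
    """Normalized right eigenvector of K with the largest real eigenvalue.

    Returns (u, eigenvalue, spectral_gap).  The eigenvector is realified
    (raising if its imaginary part is significant) and sign-aligned with
    ``align_with`` (typically the manifold tangent) when given.
    """
    lam, vec = sla.eig(K)
    order = np.argsort(-lam.real)
    v = vec[:, order[0]]
    if np.max(np.abs(v.imag)) > 1e-6 * np.linalg.norm(v):
        raise ValueError(
            f"slow mode is complex (eigenvalue pair {lam[order[0]]:.4g})"
        )
    u = v.real / np.linalg.norm(v.real)
    if align_with is not None and u @ align_with < 0:
        u = -u
    return u, lam[order[0]].real, (lam[order[0]] - lam[order[1]]).real


def drift_and_diffusion(
    ms: ManifoldSample,
    use_condensed: bool = True,
) -> ReducedDynamics:
    """Extract mu(theta), D(theta), sigma(theta) and derived indices.

    tau converts from per-ms network time to per-second reporting units;
    the manifold derivative is taken per degree of orientation, so mu is
    in deg/s and sigma in deg/sqrt(s).
    """
    params, conn = ms.params, build_connectivity(ms.params, ms.mode)
    tangent, tnorm = manifold_tangent(ms)
    if np.any(tnorm < 1e-12):
        raise ValueError("collapsed manifold: tangent norm below floor")
    n = ms.theta_grid.size
    mu = np.empty(n)
    D = np.empty(n)
    lam1 = np.empty(n)
    gap = np.empty(n)
    tau_ms = params.tau
    for k in range(n):
        flow, rates, slopes, _ = _operating(params, conn, ms.mode, ms.sbar[:, k])
        if ms.mode == "coupled" and use_condensed:
            u, l1, g = _condensed_slow_mode(params, conn, slopes, tangent[:, k])
        else:
            K = jacobian_at(ms.sbar[:, k], params, conn, ms.mode)
            u, l1, g = slow_mode(K, align_with=tangent[:, k])
        denom = tau_ms * tnorm[k]
        mu[k] = (u @ flow) / denom * 1000.0                 # deg/ms -> deg/s
        D[k] = 0.5 * (u**2 @ rates) / denom**2 * 1000.0     # deg^2/ms -> deg^2/s
        lam1[k] = l1
        gap[k] = g
    sigma = np.sqrt(2.0 * D)
    U, dU, noise_index = potential_and_indices(ms.theta_grid, mu, sigma)
    return ReducedDynamics(
        theta_grid=ms.theta_grid,
        mu=mu,
        D=D,
        sigma=sigma,
        U=U,
        dU=dU,
        noise_index=noise_index,
        tangent_norm=tnorm,
        eigenvalue=lam1,
        spectral_gap=gap,
    )


def potential_and_indices(theta_grid, mu, sigma, closure_tol: float = 0.05):
    """Potential U (zero mean), dU = U(0) - U(45), and the noise index.

    U is the cumulative trapezoidal integral of -mu over the uniform grid.
    A nonzero circulation of mu over the period means the potential does
    not close; it is flagged with the residual rather than hidden.
    """
    theta_grid = np.asarray(theta_grid, dtype=float)
    mu = np.asarray(mu, dtype=float)
    step = theta_grid[1] - theta_grid[0]
    circ = np.sum(mu) * step
    scale = max(np.max(np.abs(mu)) * 180.0, 1e-300)
    if abs(circ) > closure_tol * scale:
        warnings.warn(
            f"drift circulation {circ:.3g} deg^2/s does not close the potential",
            stacklevel=2,
        )
    from scipy.integrate import cumulative_trapezoid

    U = -cumulative_trapezoid(mu, theta_grid, initial=0.0)
    U -= U.mean()
    from .readout import _value_at

    dU = _value_at(theta_grid, U, 0.0) - _value_at(theta_grid, U, 45.0)
    s45 = _value_at(theta_grid, sigma, 45.0)
    s0 = _value_at(theta_grid, sigma, 0.0)
    noise_index = (s45 - s0) / (s45 + s0)
    return U, float(dU), float(noise_index)


def reduced_sde_spec(rd: ReducedDynamics) -> DriftDiffusionSpec:
    """Package the extracted mu and sigma as a 1-D SDE (periodic splines).

    Time unit of the returned SDE is seconds.  The drift is recentred to
    zero circulation (numerical quadrature residue) so the potential is
    single-valued.
    """
    from scipy.interpolate import CubicSpline

    grid = np.append(rd.theta_grid, rd.theta_grid[0] + 180.0)
    mu = rd.mu - rd.mu.mean()
    mu_spl = CubicSpline(grid, np.append(mu, mu[0]), bc_type="periodic")
    sig_spl = CubicSpline(grid, np.append(rd.sigma, rd.sigma[0]), bc_type="periodic")
    return DriftDiffusionSpec(
        drift=lambda th: mu_spl(np.mod(th, 180.0)),
        noise_coef=lambda th: np.maximum(sig_spl(np.mod(th, 180.0)), 0.0),
        name="reduced",
    )
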