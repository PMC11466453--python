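"""One-dimensional drift-diffusion attractor models of orientation memory.

The remembered orientation theta_t is modelled by the Ito SDE

    d theta = mu(theta) dt + sigma(theta) dW_t,

on the 180-degree orientation circle, where mu is the drift velocity
(deg / unit time) and sigma the noise coefficient (deg / sqrt(unit time)),
with sigma = sqrt(2 D) for diffusion coefficient D.  Three canonical
presets contrast continuous attractors (flat potential, uniform noise)
with discrete attractors at the obliques, with either constant or
oblique-peaking noise.  The potential U obeys dU/dtheta = -mu.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

from ._angles import signed_circ_diff, wrap_orientation

__all__ = [
    "DriftDiffusionSpec",
    "TrajectoryEnsemble",
    "ErrorProfile",
    "attractor_presets",
    "simulate_drift_diffusion",
    "error_profile",
    "potential_from_drift",
]


@dataclass(frozen=True)
class DriftDiffusionSpec:
    """Drift and noise-coefficient functions of a 1-D orientation SDE.

    drift(theta_deg) -> deg per unit time; noise_coef(theta_deg) -> deg per
    sqrt(unit time).  Both must be periodic with ``period`` and the drift
    must integrate to zero over one period for a single-valued potential.
    """

    drift: Callable
    noise_coef: Callable
    period: float = 180.0
    name: str = ""

    def validate(self, n_check: int = 720, tol: float = 1e-8) -> None:
        grid = np.linspace(0.0, self.period, n_check, endpoint=False)
        sig = np.asarray(self.noise_coef(grid), dtype=float)
        if np.any(sig < -tol):
            raise ValueError("noise_coef must be nonnegative everywhere")
        mu = np.asarray(self.drift(grid), dtype=float)
        mu_shift = np.asarray(self.drift(grid + self.period), dtype=float)
        if np.max(np.abs(mu - mu_shift)) > 1e-6 * (1.0 + np.max(np.abs(mu))):
            raise ValueError("drift is not periodic with the declared period")


@dataclass
class TrajectoryEnsemble:
    """Orientation trajectories, shape (n_real, n_times, n_theta0), degrees."""

    theta: np.ndarray
    times: np.ndarray
    theta0: np.ndarray
    dt: float
    seed: int
    period: float = 180.0


@dataclass
class ErrorProfile:
    """Bias and SD of signed circular errors, shape (n_theta0, n_times)."""

    bias: np.ndarray
    sd: np.ndarray
    theta0: np.ndarray
    times: np.ndarray


def attractor_presets() -> dict:
    """The three canonical 1-D attractor models.

    - ``continuous``: mu = 0, sigma = 2 deg (flat ring, uniform noise).
    - ``discrete_constant``: mu(theta) = sin(4 theta), sigma = 2 deg
      (oblique attractors from the potential U ~ cos(4 theta)/4).
    - ``discrete_nonuniform``: same drift, sigma(theta) = 2 (1 - cos 4 theta)
      deg (noise maximal at the obliques, vanishing at the cardinals).
    """

    def _sin4(theta):
        return np.sin(np.deg2rad(4.0 * np.asarray(theta, dtype=float)))

    def _const(value):
        return lambda theta: np.full_like(np.asarray(theta, dtype=float), value)

    def _nonuniform(theta):
        return 2.0 * (1.0 - np.cos(np.deg2rad(4.0 * np.asarray(theta, dtype=float))))

    return {
        "continuous": DriftDiffusionSpec(
            drift=_const(0.0), noise_coef=_const(2.0), name="continuous"
        ),
        "discrete_constant": DriftDiffusionSpec(
            drift=_sin4, noise_coef=_const(2.0), name="discrete_constant"
        ),
        "discrete_nonuniform": DriftDiffusionSpec(
            drift=_sin4, noise_coef=_nonuniform, name="discrete_nonuniform"
        ),
    }


def simulate_drift_diffusion(
    spec: DriftDiffusionSpec,
    theta0: Sequence[float],
    T: float,
    dt: float = 0.01,
    n_real: int = 1000,
    seed: int = 0,
    record_times: Sequence[float] | None = None,
) -> TrajectoryEnsemble:
    """Euler-Maruyama integration of the orientation SDE.

    theta <- theta + mu(theta) dt + sigma(theta) sqrt(dt) eta, eta ~ N(0,1),
    wrapped into [0, period).  sigma is evaluated at the pre-step state
    (Ito convention).  All realizations and initial orientations are
    advanced as one vectorized batch from a single seeded generator.
    """
    if dt <= 0 or T < dt:
        raise ValueError("require dt > 0 and T >= dt")
    if n_real < 1:
        raise ValueError("n_real must be >= 1")
    theta0 = np.atleast_1d(np.asarray(theta0, dtype=float))
    n_steps = int(round(T / dt))
    if record_times is None:
        record_times = [T]
    record_steps = {int(round(t / dt)): i for i, t in enumerate(record_times)}

    rng = np.random.default_rng(seed)
    theta = np.broadcast_to(theta0, (n_real, theta0.size)).copy()
    out = np.empty((n_real, len(record_times), theta0.size))
    if 0 in record_steps:
        out[:, record_steps[0], :] = theta
    sqdt = np.sqrt(dt)
    for step in range(1, n_steps + 1):
        mu = np.asarray(spec.drift(theta), dtype=float)
        sig = np.asarray(spec.noise_coef(theta), dtype=float)
        if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(sig))):
            bad = theta[~(np.isfinite(mu) & np.isfinite(sig))]
            raise FloatingPointError(
                f"non-finite drift/noise at theta={bad.ravel()[:3]} (step {step})"
            )
        theta = theta + mu * dt + sig * sqdt * rng.standard_normal(theta.shape)
        theta = wrap_orientation(theta, spec.period)
        if step in record_steps:
            out[:, record_steps[step], :] = theta
    return TrajectoryEnsemble(
        theta=out,
        times=np.asarray(record_times, dtype=float),
        theta0=theta0,
        dt=dt,
        seed=seed,
        period=spec.period,
    )


def error_profile(ens: TrajectoryEnsemble, eval_times: Sequence[float] | None = None) -> ErrorProfile:
    """Bias and SD of errors theta(t) - theta0, wrapped to (-period/2, period/2].

    Bias is the mean signed circular error; SD is the linear standard
    deviation of the wrapped errors (errors are small relative to the
    period in all regimes of interest).
    """
    if ens.theta.shape[0] == 0:
        raise ValueError("empty ensemble")
    if eval_times is None:
        eval_times = ens.times
    idx = []
    for t in eval_times:
        matches = np.nonzero(np.isclose(ens.times, t))[0]
        if matches.size == 0:
            raise ValueError(f"time {t} not recorded in the ensemble")
        idx.append(matches[0])
    err = signed_circ_diff(ens.theta[:, idx, :], ens.theta0[None, None, :], ens.period)
    bias = err.mean(axis=0).T
    sd = err.std(axis=0, ddof=0).T
    return ErrorProfile(bias=bias, sd=sd, theta0=ens.theta0, times=np.asarray(eval_times, dtype=float))


def potential_from_drift(spec: DriftDiffusionSpec, grid: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Energy potential U on a uniform grid covering one period, dU/dtheta = -mu.

    U is the zero-mean cumulative trapezoidal integral of -mu.  A drift with
    nonzero mean over the period has no single-valued potential on the
    circle and is rejected.
    """
    grid = np.asarray(grid, dtype=float)
    mu = np.asarray(spec.drift(grid), dtype=float)
    dg = np.diff(grid)
    if grid.size < 8 or not np.allclose(dg, dg[0], rtol=1e-6):
        raise ValueError("grid must be uniform with >= 8 points")
    # closure over the full period, including the wrap segment
    grid_closed = np.append(grid, grid[0] + spec.period)
    mu_closed = np.append(mu, np.asarray(spec.drift(grid[:1]), dtype=float))
    total = np.trapezoid(mu_closed, grid_closed)
    scale = max(np.max(np.abs(mu)), 1.0) * spec.period
    if abs(total) > tol * scale:
        raise ValueError(
            f"drift has nonzero circulation ({total:.3g}); no single-valued potential"
        )
    u = -cumulative_trapezoid(mu, grid, initial=0.0)
    return u - u.mean()
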