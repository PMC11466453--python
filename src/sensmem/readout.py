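"""Tuning properties, population-vector decoding, and error statistics.

Tuning curves r_i(theta) are measured at the steady state of a long
stimulus epoch.  Each neuron's preferred feature (PF) is the argmax of a
periodic cubic-spline upsampling of its tuning curve, and its tuning
width the full width at half maximum (FWHM).  The width index

    WI = (FWHM(psi=45) - FWHM(psi=0)) / (FWHM(psi=45) + FWHM(psi=0))

contrasts oblique- and cardinal-indexed neurons; positive WI means
sharper tuning at the cardinals.  Orientation is decoded by the
population vector on the angle-doubled circle,

    theta_hat = 1/2 Arg sum_j r_j exp(2 i pf_j),

an approximation to Bayesian readout when PFs are estimated from the
heterogeneous steady-state responses.  Fisher information per neuron is
estimated from the empirical mean and variance of rates across
realizations under a Gaussian assumption,
FI_i(theta) = (dE[r_i]/dtheta)^2 / Var[r_i].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from ._angles import signed_circ_diff

__all__ = [
    "TuningCurveSet",
    "TuningProps",
    "ErrorSummary",
    "FisherProfile",
    "tuning_properties",
    "population_vector_decode",
    "error_summary",
    "fisher_information",
]


@dataclass
class TuningCurveSet:
    """Rates (neuron x stimulus grid, Hz) at a fixed time."""

    rates: np.ndarray
    theta_grid: np.ndarray  # deg, uniform over [0, 180)
    module: str = "m"
    time_ms: float | None = None


@dataclass
class TuningProps:
    pf: np.ndarray     # preferred feature per neuron, deg, NaN if flat
    fwhm: np.ndarray   # full width at half maximum, deg, NaN if flat
    wi: float          # width index

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.pf)


@dataclass
class ErrorSummary:
    """bias(theta, t) and sd(theta, t) of decoded errors, deg."""

    bias: np.ndarray          # (n_theta, n_times)
    sd: np.ndarray            # (n_theta, n_times)
    thetas: np.ndarray
    times: np.ndarray
    n_real: int

    def sd_index(self, time_index: int = -1) -> float:
        """(SD(45 deg) - SD(0 deg)) / (SD(45 deg) + SD(0 deg)).

        Uses exact grid matches when present, otherwise periodic linear
        interpolation over the stimulus grid.
        """
        sd45 = _value_at(self.thetas, self.sd[:, time_index], 45.0)
        sd0 = _value_at(self.thetas, self.sd[:, time_index], 0.0)
        return (sd45 - sd0) / (sd45 + sd0)

    def bias_at(self, theta: float, time_index: int = -1) -> float:
        return _value_at(self.thetas, self.bias[:, time_index], theta)


@dataclass
class FisherProfile:
    """Per-neuron and total Fisher information over the stimulus grid."""

    fi: np.ndarray        # (n_theta, n_neuron)
    fi_total: np.ndarray  # (n_theta,)
    theta_grid: np.ndarray
    n_excluded: int
    n_real: int


def _value_at(grid_deg: np.ndarray, values: np.ndarray, theta: float) -> float:
    """Value at an orientation, by exact match or periodic linear interpolation."""
    hit = np.nonzero(np.isclose(np.mod(grid_deg, 180.0), theta % 180.0))[0]
    if hit.size:
        return float(values[hit[0]])
    order = np.argsort(grid_deg)
    g = np.mod(grid_deg[order], 180.0)
    v = values[order]
    g_ext = np.concatenate([g, [g[0] + 180.0]])
    v_ext = np.concatenate([v, [v[0]]])
    return float(np.interp(theta % 180.0, g_ext, v_ext))


def _fwhm_circular(curve: np.ndarray, grid: np.ndarray, half_level: float, peak_idx: int) -> float:
    """Width (deg) of the contiguous above-half region containing the peak."""
    above = curve >= half_level
    n = above.size
    step = grid[1] - grid[0]
    if above.all():
        return 180.0
    # walk outward from the peak in both directions
    lo = peak_idx
    while above[(lo - 1) % n] and (peak_idx - lo) < n:
        lo -= 1
    hi = peak_idx
    while above[(hi + 1) % n] and (hi - peak_idx) < n:
        hi += 1
    return (hi - lo + 1) * step


def tuning_properties(
    tc: TuningCurveSet, n_upsample: int = 1000, half_from_baseline: bool = True
) -> TuningProps:
    """Preferred feature, FWHM, and width index from a tuning-curve set.

    Each neuron's curve is upsampled with a periodic cubic spline to
    ``n_upsample`` orientations.  The half level is min + (max - min)/2 by
    default (``half_from_baseline=False`` uses max/2).  Neurons with flat
    curves get NaN pf/fwhm rather than fabricated values.
    """
    rates = np.asarray(tc.rates, dtype=float)
    grid = np.asarray(tc.theta_grid, dtype=float)
    if grid.size < 8:
        raise ValueError("need at least 8 stimulus grid points")
    n_neuron = rates.shape[0]
    x = np.append(grid, grid[0] + 180.0)
    fine = np.linspace(0.0, 180.0, n_upsample, endpoint=False)
    pf = np.full(n_neuron, np.nan)
    fwhm = np.full(n_neuron, np.nan)
    for i in range(n_neuron):
        y = rates[i]
        if np.ptp(y) <= 1e-12 * max(1.0, np.abs(y).max()):
            continue  # flat tuning: undefined, flagged by NaN
        spl = CubicSpline(x, np.append(y, y[0]), bc_type="periodic")
        curve = spl(fine)
        peak = int(np.argmax(curve))
        # plateau-aware peak: circular mean of near-maximal points
        plateau = np.nonzero(curve >= curve[peak] - 1e-9 * max(1.0, abs(curve[peak])))[0]
        if plateau.size > 1:
            ang = fine[plateau] * np.pi / 90.0
            pf[i] = np.mod(np.angle(np.exp(1j * ang).mean()) * 90.0 / np.pi, 180.0)
        else:
            pf[i] = fine[peak]
        base = curve.min() if half_from_baseline else 0.0
        half = base + (curve.max() - base) / 2.0
        fwhm[i] = _fwhm_circular(curve, fine, half, peak)

    n_per_deg = n_neuron / 180.0
    i45 = int(round(45.0 * n_per_deg)) % n_neuron
    i0 = 0
    if np.isnan(fwhm[i45]) or np.isnan(fwhm[i0]):
        wi = np.nan
    else:
        wi = (fwhm[i45] - fwhm[i0]) / (fwhm[i45] + fwhm[i0])
    return TuningProps(pf=pf, fwhm=fwhm, wi=float(wi))


def population_vector_decode(rates: np.ndarray, pf_deg: np.ndarray) -> np.ndarray:
    """Population-vector estimate (deg) from rates and preferred features.

    theta_hat = 1/2 Arg sum_j r_j exp(2 i pf_j); rates index the last axis,
    so ensembles decode in one vectorized call.  Neurons with undefined
    (NaN) PF are ignored.  A zero resultant (e.g. perfectly uniform rates)
    has no defined estimate and raises.
    """
    rates = np.asarray(rates, dtype=float)
    pf = np.deg2rad(np.asarray(pf_deg, dtype=float)) * 2.0
    valid = np.isfinite(pf)
    if not valid.all():
        rates = rates[..., valid]
        pf = pf[valid]
    if np.any(rates < 0):
        raise ValueError("rates must be nonnegative")
    z = rates @ np.exp(1j * pf)
    scale = rates.sum(axis=-1)
    if np.any(np.abs(z) <= 1e-12 * np.maximum(scale, 1e-300)):
        raise ValueError("undefined decode: population vector has zero resultant")
    return np.mod(np.rad2deg(np.angle(z)) / 2.0, 180.0)


def error_summary(
    decoded: np.ndarray,
    true_thetas: np.ndarray,
    eval_times: np.ndarray,
) -> ErrorSummary:
    """Bias and SD of decoding errors.

    ``decoded`` has shape (n_times, n_theta, n_real), deg.  Errors are
    wrapped to (-90, 90]; bias is their mean and SD their linear standard
    deviation (errors are small against the period).
    """
    decoded = np.asarray(decoded, dtype=float)
    if decoded.shape[-1] < 2:
        raise ValueError("need at least 2 realizations")
    err = signed_circ_diff(decoded, np.asarray(true_thetas, dtype=float)[None, :, None])
    bias = err.mean(axis=-1).T
    sd = err.std(axis=-1, ddof=0).T
    return ErrorSummary(
        bias=bias,
        sd=sd,
        thetas=np.asarray(true_thetas, dtype=float),
        times=np.asarray(eval_times, dtype=float),
        n_real=decoded.shape[-1],
    )


def fisher_information(
    rates: np.ndarray,
    theta_grid: np.ndarray,
    var_floor: float = 1e-12,
) -> FisherProfile:
    """Fisher information from an ensemble of rates over a stimulus grid.

    ``rates`` has shape (n_theta, n_real, n_neuron) at one time point; the
    stimulus grid must be uniform over [0, 180).  The mean-rate derivative
    uses periodic central differences (per degree).  Neurons whose rate
    variance falls below ``var_floor`` at a grid point are excluded from
    the total there (their count is reported and a warning emitted).
    """
    rates = np.asarray(rates, dtype=float)
    grid = np.asarray(theta_grid, dtype=float)
    if grid.size < 3:
        raise ValueError("need at least 3 stimulus grid points")
    step = grid[1] - grid[0]
    if not np.allclose(np.diff(grid), step, rtol=1e-6):
        raise ValueError("stimulus grid must be uniform")
    if rates.shape[1] < 100:
        raise ValueError("need at least 100 realizations for stable FI estimates")
    mean = rates.mean(axis=1)
    var = rates.var(axis=1, ddof=1)
    dmean = (np.roll(mean, -1, axis=0) - np.roll(mean, 1, axis=0)) / (2.0 * step)
    ok = var > var_floor
    fi = np.zeros_like(mean)
    fi[ok] = dmean[ok] ** 2 / var[ok]
    n_excluded = int((~ok).sum())
    if n_excluded:
        warnings.warn(
            f"{n_excluded} neuron/orientation cells below variance floor excluded from FI",
            stacklevel=2,
        )
    return FisherProfile(
        fi=fi,
        fi_total=fi.sum(axis=1),
        theta_grid=grid,
        n_excluded=n_excluded,
        n_real=rates.shape[1],
    )
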