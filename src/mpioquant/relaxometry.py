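"""Voxelwise T2 mapping from multi-echo spin-echo series.

Two fitting routes are provided: a fast weighted log-linear fit, and a
mono-exponential nonlinear least-squares (NLLS) refinement initialised from
it. NLLS is the default because magnitude (Rician) noise biases log-linear
fits at low SNR. The NLLS solver is a damped Gauss-Newton iteration run
vectorised over all voxels; it falls back to the log-linear initialisation
for any voxel where iteration fails to reduce the residual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import MultiEchoSeries, Volume3D

__all__ = ["T2FitResult", "fit_t2_map", "estimate_background_sigma"]

logger = logging.getLogger(__name__)

_T2_MIN_MS = 1e-3
_T2_MAX_MS = 1e5


@dataclass
class T2FitResult:
    """Voxelwise mono-exponential fit of a multi-echo series.

    ``fit_mask`` marks voxels with a valid fit; ``t2_map``/``s0_map`` are
    undefined (zero) outside it.
    """

    t2_map: Volume3D
    s0_map: Volume3D
    fit_mask: np.ndarray
    method: str


def estimate_background_sigma(series: MultiEchoSeries, background_mask=None) -> float:
    """Estimate the noise level from background (air) voxels.

    Uses a user-supplied background mask, or the darkest 5% of first-echo
    voxels. For Rician noise the background magnitude is Rayleigh with mean
    sigma*sqrt(pi/2); the estimate inverts that relation.
    """
    first = series.echoes[0].data
    if background_mask is not None:
        vals = first[np.asarray(background_mask, dtype=bool)]
    else:
        flat = np.sort(first.ravel())
        vals = flat[: max(int(0.05 * flat.size), 1)]
    mean = float(np.mean(vals)) if vals.size else 0.0
    return mean / np.sqrt(np.pi / 2.0)


def _loglinear_fit(signals: np.ndarray, tes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted least squares on ln(signal) vs TE.

    Weights are the squared signals, compensating the noise amplification
    of the log transform. ``signals`` has shape (n_echo, n_voxel); returns
    (s0, t2) arrays of length n_voxel.
    """
    s = np.maximum(signals, 1e-300)
    y = np.log(s)
    w = s * s
    sw = w.sum(axis=0)
    t_mean = (w * tes[:, None]).sum(axis=0) / sw
    y_mean = (w * y).sum(axis=0) / sw
    dt = tes[:, None] - t_mean
    denom = (w * dt * dt).sum(axis=0)
    slope = (w * dt * (y - y_mean)).sum(axis=0) / np.maximum(denom, 1e-300)
    slope = np.minimum(slope, -1.0 / _T2_MAX_MS)  # enforce decay
    t2 = np.clip(-1.0 / slope, _T2_MIN_MS, _T2_MAX_MS)
    s0 = np.exp(y_mean + t_mean / t2)
    return s0, t2


def _ssr(signals: np.ndarray, tes: np.ndarray, s0: np.ndarray, t2: np.ndarray) -> np.ndarray:
    resid = signals - s0[None, :] * np.exp(-tes[:, None] / t2[None, :])
    return (resid * resid).sum(axis=0)


def _gauss_newton(
    signals: np.ndarray,
    tes: np.ndarray,
    s0: np.ndarray,
    t2: np.ndarray,
    max_iter: int = 60,
) -> tuple[np.ndarray, np.ndarray]:
    """Damped Gauss-Newton for s(te) = s0*exp(-te/t2), vectorised over voxels.

    Each iteration solves the 2x2 normal equations per voxel; steps that do
    not decrease the residual are halved (up to 8 times) and then rejected,
    so the result never has a larger SSR than its initialisation.
    """
    s0 = s0.copy()
    t2 = t2.copy()
    ssr = _ssr(signals, tes, s0, t2)
    for _ in range(max_iter):
        model = s0[None, :] * np.exp(-tes[:, None] / t2[None, :])
        resid = signals - model
        # Jacobian columns: d/ds0 = model/s0, d/dt2 = model * te / t2^2
        j1 = model / np.maximum(s0[None, :], 1e-300)
        j2 = model * tes[:, None] / (t2[None, :] ** 2)
        a11 = (j1 * j1).sum(axis=0)
        a12 = (j1 * j2).sum(axis=0)
        a22 = (j2 * j2).sum(axis=0)
        b1 = (j1 * resid).sum(axis=0)
        b2 = (j2 * resid).sum(axis=0)
        det = a11 * a22 - a12 * a12
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        ds0 = (a22 * b1 - a12 * b2) / det
        dt2 = (a11 * b2 - a12 * b1) / det

        step = np.ones_like(s0)
        improved = np.zeros_like(s0, dtype=bool)
        new_s0, new_t2 = s0.copy(), t2.copy()
        for _half in range(9):
            trial_s0 = s0 + step * ds0
            trial_t2 = np.clip(t2 + step * dt2, _T2_MIN_MS, _T2_MAX_MS)
            trial_s0 = np.maximum(trial_s0, 1e-300)
            trial_ssr = _ssr(signals, tes, trial_s0, trial_t2)
            better = (trial_ssr < ssr) & ~improved
            new_s0[better] = trial_s0[better]
            new_t2[better] = trial_t2[better]
            ssr = np.where(better, trial_ssr, ssr)
            improved |= better
            if improved.all():
                break
            step *= 0.5
        if not improved.any():
            break
        s0, t2 = new_s0, new_t2
    return s0, t2


def fit_t2_map(
    series: MultiEchoSeries,
    method: str = "nlls",
    signal_floor: float | None = None,
    background_mask=None,
) -> T2FitResult:
    """Fit a voxelwise mono-exponential T2 map.

    Parameters
    ----------
    series:
        Multi-echo series with at least 2 echoes.
    method:
        ``"loglinear"`` (weighted LS on log signal) or ``"nlls"``
        (Gauss-Newton refinement of the log-linear fit).
    signal_floor:
        Voxels with any echo at or below this level are excluded from the
        fit. Default: 3x the background noise estimate (from
        ``background_mask`` if given, else the darkest 5% of voxels).
    """
    if method not in ("loglinear", "nlls"):
        raise ValueError(f"method must be 'loglinear' or 'nlls', got {method!r}")
    if series.n_echoes < 2:
        raise ValueError(f"T2 fitting requires >= 2 echoes, got {series.n_echoes}")
    if signal_floor is None:
        signal_floor = 3.0 * estimate_background_sigma(series, background_mask)

    data = series.as_array()  # (n_echo, x, y, z)
    tes = np.asarray(series.echo_times_ms, dtype=float)
    shape = data.shape[1:]
    fit_mask = np.all(data > signal_floor, axis=0)
    if not fit_mask.any():
        logger.warning("fit_t2_map: no voxel has all echoes above floor %.3g", signal_floor)
        zero = Volume3D(np.zeros(shape), series.spacing)
        return T2FitResult(zero, zero, fit_mask, method)

    signals = data[:, fit_mask]  # (n_echo, n_voxel)
    s0, t2 = _loglinear_fit(signals, tes)
    if method == "nlls":
        s0, t2 = _gauss_newton(signals, tes, s0, t2)

    t2_full = np.zeros(shape)
    s0_full = np.zeros(shape)
    t2_full[fit_mask] = t2
    s0_full[fit_mask] = s0
    return T2FitResult(
        Volume3D(t2_full, series.spacing),
        Volume3D(s0_full, series.spacing),
        fit_mask,
        method,
    )
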