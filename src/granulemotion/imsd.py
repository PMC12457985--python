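"""Imaging-derived MSD from spatiotemporal image correlation.

The spatial cross-correlation of intensity fluctuations at increasing time
lags broadens as the imaged particles move; fitting each correlation map
with an isotropic Gaussian gives a width series sigma^2(tau) — the iMSD —
which is then fit with the anomalous-diffusion law

    sigma^2(tau) = sigma0^2 + 4 D_m tau^alpha

where alpha < 1 indicates sub-diffusion, ~1 Brownian motion and > 1
super-diffusion, D_m is the short-scale diffusivity, and the offset
sigma0^2 (the correlation waist at zero lag) is a squared apparent-size
metric growing with particle dimension at fixed PSF.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.optimize import curve_fit

from .models import CorrelationStack, iMSDCurve

logger = logging.getLogger(__name__)

__all__ = ["compute_correlation", "fit_width", "extract_curve", "fit_imsd", "analyze_stack"]


def compute_correlation(
    stack: np.ndarray,
    dt: float,
    pixel_size: float,
    max_lag_frames: int = 100,
    detrend: str = "none",
) -> CorrelationStack:
    """Spatiotemporal correlation G(xi, eta, tau) of an image stack.

    For each lag tau, G is the spatial (circular, FFT-based) cross-
    correlation of the intensity fluctuations delta-I between all frame
    pairs separated by tau, normalized by the product of the two frames'
    mean intensities and averaged over pairs. ``detrend`` selects the
    fluctuation definition: ``"none"`` subtracts each frame's own mean,
    ``"subtract_mean_image"`` subtracts the pixelwise temporal mean image
    (suppressing the immobile population).

    Returns maps with the zero spatial lag shifted to the center.
    """
    stack = np.asarray(stack, dtype=np.float64)
    n_frames, ny, nx = stack.shape
    if max_lag_frames < 1:
        raise ValueError("max_lag_frames must be >= 1")
    if n_frames < 2 * max_lag_frames:
        raise ValueError(
            f"stack has {n_frames} frames; need at least 2*max_lag = {2 * max_lag_frames}"
        )
    frame_means = stack.mean(axis=(1, 2))
    if np.any(frame_means <= 0) or np.allclose(stack.std(axis=(1, 2)), 0):
        raise ValueError("constant or empty stack: zero-variance correlation")

    if detrend == "none":
        delta = stack - frame_means[:, None, None]
    elif detrend == "subtract_mean_image":
        delta = stack - stack.mean(axis=0)[None]
    else:
        raise ValueError(f"unknown detrend mode {detrend!r}")
    # dividing each frame's fluctuation by its mean makes the per-pair
    # product carry the <I_t><I_{t+tau}> normalization automatically
    J = delta / frame_means[:, None, None]

    F = np.fft.fft2(J)
    npix = ny * nx
    lags = np.arange(1, max_lag_frames + 1)
    G = np.empty((len(lags), ny, nx))
    for li, lag in enumerate(lags):
        cross = np.conj(F[:-lag]) * F[lag:]
        G[li] = np.fft.fftshift(np.fft.ifft2(cross.mean(axis=0)).real) / npix
    return CorrelationStack(lags=lags * dt, G=G, pixel_size=pixel_size, dt=dt)


def _gauss2d(coords, A, sigma2, offset):
    xi, eta = coords
    return A * np.exp(-(xi**2 + eta**2) / sigma2) + offset


def fit_width(
    G_map: np.ndarray,
    pixel_size: float,
    window_px: int = 8,
) -> tuple[float, float, float]:
    """Fit an isotropic Gaussian to the central correlation peak.

    Fits ``A exp(-(xi^2+eta^2)/sigma^2) + c`` over a +-``window_px`` px
    region around the map center (physical coordinates in um); returns
    ``(sigma2_um2, amplitude, offset)``. Raises on non-convergence or a
    non-positive width so the caller can drop the lag.
    """
    ny, nx = G_map.shape
    cy, cx = ny // 2, nx // 2
    w = min(window_px, cy, cx)
    patch = G_map[cy - w : cy + w + 1, cx - w : cx + w + 1]
    yy, xx = np.mgrid[-w : w + 1, -w : w + 1]
    xi = xx.ravel() * pixel_size
    eta = yy.ravel() * pixel_size
    z = patch.ravel()

    A0 = float(patch[w, w] - np.median(patch))
    if A0 <= 0:
        raise RuntimeError("no central correlation peak to fit")
    s0 = (2.0 * pixel_size) ** 2
    popt, _ = curve_fit(
        _gauss2d,
        (xi, eta),
        z,
        p0=(A0, s0, float(np.median(patch))),
        bounds=([0.0, 1e-8, -np.inf], [np.inf, np.inf, np.inf]),
        maxfev=10_000,
    )
    A, sigma2, offset = popt
    if not np.isfinite(sigma2) or sigma2 <= 0:
        raise RuntimeError("degenerate width fit")
    return float(sigma2), float(A), float(offset)


def extract_curve(corr: CorrelationStack, window_px: int = 8) -> iMSDCurve:
    """Fit every lag's map; lags whose fit fails are dropped (logged)."""
    taus, sig2 = [], []
    for tau, g in zip(corr.lags, corr.G):
        try:
            s2, _, _ = fit_width(g, corr.pixel_size, window_px)
        except (RuntimeError, ValueError) as exc:
            logger.warning("iMSD width fit failed at tau=%.3f s: %s", tau, exc)
            continue
        taus.append(tau)
        sig2.append(s2)
    return iMSDCurve(tau=np.asarray(taus), sigma2=np.asarray(sig2))


def _anomalous(tau, offset, Dm, alpha):
    return offset + 4.0 * Dm * tau**alpha


def fit_imsd(curve: iMSDCurve) -> iMSDCurve:
    """Fit sigma^2(tau) = sigma0^2 + 4 D_m tau^alpha in place.

    Bounds: sigma0^2 > 0, D_m >= 0, 0.1 <= alpha <= 2. Initialization
    comes from a log-log linear fit of sigma^2(tau) - sigma^2(tau_1).
    """
    tau, sig2 = curve.tau, curve.sigma2
    if len(tau) < 5:
        raise ValueError("need at least 5 valid (tau, sigma^2) points")
    y = sig2 - sig2[0]
    pos = y > 0
    pos[0] = False
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(np.log(tau[pos]), np.log(y[pos]), 1)
        alpha0 = float(np.clip(slope, 0.1, 2.0))
        Dm0 = float(np.exp(intercept) / 4.0)
    else:
        alpha0, Dm0 = 1.0, max((sig2[-1] - sig2[0]) / (4.0 * tau[-1]), 0.0)
    off0 = max(sig2[0] - 4.0 * Dm0 * tau[0] ** alpha0, 0.5 * sig2[0])

    try:
        popt, pcov = curve_fit(
            _anomalous,
            tau,
            sig2,
            p0=(off0, Dm0, alpha0),
            bounds=([1e-12, 0.0, 0.1], [np.inf, np.inf, 2.0]),
            maxfev=20_000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"iMSD fit did not converge (init offset={off0:.3g}, Dm={Dm0:.3g}, "
            f"alpha={alpha0:.3g})"
        ) from exc
    curve.fit_offset, curve.fit_Dm, curve.fit_alpha = map(float, popt)
    curve.fit_cov = pcov
    return curve


def analyze_stack(
    stack: np.ndarray,
    dt: float,
    pixel_size: float,
    max_lag_frames: int = 100,
    detrend: str = "none",
    window_px: int = 8,
) -> iMSDCurve:
    """Stack -> correlation -> width series -> anomalous-diffusion fit."""
    corr = compute_correlation(stack, dt, pixel_size, max_lag_frames, detrend)
    curve = extract_curve(corr, window_px)
    return fit_imsd(curve)
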