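"""Traction force microscopy: registration, iterative PIV, and FTTC.

The measurement chain mirrors standard bead-based TFM practice:
(1) rigid positional correction of the stressed image onto the relaxed
reference by subpixel phase correlation; (2) multi-pass window
cross-correlation PIV with window shifting, 3-point Gaussian subpixel
peak fits and normalized-median outlier replacement; (3) inversion of
the interpolated displacement field to tractions with regularized
Fourier-transform traction cytometry (see :mod:`retmech.elastic`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import fft2, ifft2
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import gaussian_filter, map_coordinates, median_filter, shift as nd_shift
from skimage.registration import phase_cross_correlation

from .elastic import FttcConfig, fttc
from .grids import ImageGrid
from .model import DisplacementField, TractionField

__all__ = [
    "PivConfig",
    "FttcConfig",
    "register_images",
    "piv_displacement",
    "fttc",
    "traction_magnitude",
]


class RegistrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class PivConfig:
    """Multi-pass PIV parameters.

    window_sizes: descending interrogation-window edge lengths (px),
    each >= 8; overlap_fraction in [0, 1); subpixel_method one of
    gaussian_peak / parabolic; outlier_threshold in normalized-median
    units (Westerweel-Scarano test); smooth_sigma_px is a Gaussian
    smoothing (full-grid px, 0 disables) applied to the interpolated
    displacement field — traction inversion amplifies high-frequency
    vector noise, so a low-pass matched to the node spacing stabilizes
    it without touching the regularization of the inversion itself.
    """

    window_sizes: tuple[int, ...] = (64, 32, 16)
    overlap_fraction: float = 0.75
    subpixel_method: str = "gaussian_peak"
    outlier_threshold: float = 2.0
    smooth_sigma_px: float = 4.0

    def __post_init__(self) -> None:
        if any(w < 8 for w in self.window_sizes):
            raise ValueError("PIV windows must be >= 8 px")
        if any(b >= a for a, b in zip(self.window_sizes, self.window_sizes[1:])):
            pass  # descending enforced below
        if list(self.window_sizes) != sorted(self.window_sizes, reverse=True):
            raise ValueError("PIV windows must be descending")
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.subpixel_method not in ("gaussian_peak", "parabolic"):
            raise ValueError("unknown subpixel method")


def register_images(
    reference: np.ndarray, moving: np.ndarray, upsample_factor: int = 50
) -> tuple[np.ndarray, tuple[float, float]]:
    """Estimate and remove a rigid stage drift between two images.

    Subpixel phase correlation gives the (dx, dy) drift of ``moving``
    relative to ``reference``; the moving image is resampled back onto
    the reference frame. Returns (shifted image, drift (dx, dy) px).
    """
    reference = np.asarray(reference, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if reference.shape != moving.shape:
        raise ValueError("images must share a grid")
    if np.ptp(reference) == 0 or np.ptp(moving) == 0:
        raise RegistrationError("flat image: registration is undefined")
    shift_yx, _, _ = phase_cross_correlation(
        reference, moving, upsample_factor=upsample_factor, normalization=None
    )
    corrected = nd_shift(moving, shift_yx, order=3, mode="nearest")
    # shift_yx is (dy, dx) needed to align moving onto reference; the
    # drift of the moving image is the negative of that.
    return corrected, (float(-shift_yx[1]), float(-shift_yx[0]))


def _subpixel_offset(corr: np.ndarray, iy: int, ix: int, method: str) -> tuple[float, float]:
    """3-point peak interpolation around (iy, ix) in a correlation map."""

    def axis_offset(cm: float, c0: float, cp: float) -> float:
        if not (np.isfinite(cm) and np.isfinite(c0) and np.isfinite(cp)):
            return 0.0
        if method == "gaussian_peak" and min(cm, c0, cp) > 0:
            lm, l0, lp = np.log(cm), np.log(c0), np.log(cp)
            den = lm + lp - 2 * l0
            if den < 0:
                return float(0.5 * (lm - lp) / den)
        den = cm + cp - 2 * c0
        if den < 0:
            return float(0.5 * (cm - cp) / den)
        return 0.0

    h, w = corr.shape
    dy = dx = 0.0
    if 0 < iy < h - 1:
        dy = axis_offset(corr[iy - 1, ix], corr[iy, ix], corr[iy + 1, ix])
    if 0 < ix < w - 1:
        dx = axis_offset(corr[iy, ix - 1], corr[iy, ix], corr[iy, ix + 1])
    return dy, dx


def _window_correlate(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Batch linear cross-correlation of zero-mean windows (n, w, w).

    Windows are zero-padded to 2w (so the correlation is linear, not
    circular) and normalized by the per-lag overlap area, which removes
    the systematic peak bias toward zero lag of plain finite-window
    correlation. The returned maps are cropped back to (w, w) with zero
    lag at (w//2, w//2); peak position gives the shift of ``a``
    relative to ``b``.
    """
    n, w, _ = a.shape
    a = a - a.mean(axis=(1, 2), keepdims=True)
    b = b - b.mean(axis=(1, 2), keepdims=True)
    ap = np.zeros((n, 2 * w, 2 * w))
    bp = np.zeros((n, 2 * w, 2 * w))
    ap[:, :w, :w] = a
    bp[:, :w, :w] = b
    c = np.fft.fftshift(ifft2(fft2(ap) * np.conj(fft2(bp))).real, axes=(1, 2))
    lag = np.arange(2 * w) - w
    overlap = np.maximum(w - np.abs(lag), 1).astype(float)
    weight = np.outer(overlap, overlap)
    # clamp so sparse far-lag overlaps cannot blow up into false peaks
    c /= np.maximum(weight, (0.75 * w) ** 2)
    half = w // 2
    return c[:, w - half : w + w - half, w - half : w + w - half]


def _extract_windows(
    img: np.ndarray, cy: np.ndarray, cx: np.ndarray, win: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract win x win windows centered at integer (cy, cx), edge-clamped.

    Returns (windows, y0, x0) — the actual top-left corners, which can
    differ from cy - win//2 at the image border; callers must use them
    to compute the offset that was really applied.
    """
    h, w = img.shape
    half = win // 2
    y0 = np.clip(cy - half, 0, h - win)
    x0 = np.clip(cx - half, 0, w - win)
    out = np.empty((len(cy), win, win))
    for i, (yy, xx) in enumerate(zip(y0, x0)):
        out[i] = img[yy : yy + win, xx : xx + win]
    return out, y0, x0


def _median_replace_outliers(
    u: np.ndarray, v: np.ndarray, threshold: float, eps: float = 0.1
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized-median outlier test on a vector grid; replace with local median."""
    flags = np.zeros(u.shape, dtype=bool)
    for comp in (u, v):
        med = median_filter(comp, size=3, mode="nearest")
        resid = np.abs(comp - med)
        rmed = median_filter(resid, size=3, mode="nearest")
        flags |= resid / (rmed + eps) > threshold
    um = median_filter(u, size=3, mode="nearest")
    vm = median_filter(v, size=3, mode="nearest")
    u = np.where(flags, um, u)
    v = np.where(flags, vm, v)
    return u, v, flags


def piv_displacement(
    stressed: np.ndarray,
    relaxed: np.ndarray,
    grid: ImageGrid,
    config: PivConfig | None = None,
) -> DisplacementField:
    """Multi-pass window-shifted PIV displacement (stressed relative to relaxed).

    Each pass correlates relaxed-frame windows against stressed-frame
    windows offset by the current estimate, so large displacements are
    captured by the coarse pass and refined by smaller windows. The
    final vector grid is median-validated and bilinearly interpolated
    to the full pixel grid, in µm.
    """
    if config is None:
        config = PivConfig()
    stressed = np.asarray(stressed, dtype=float)
    relaxed = np.asarray(relaxed, dtype=float)
    if stressed.shape != relaxed.shape or stressed.shape != grid.shape:
        raise ValueError("images and grid must agree")
    h, w = grid.shape
    yy_full, xx_full = np.mgrid[0:h, 0:w]

    nodes_y = nodes_x = None
    u = v = None  # displacement estimate (px) on the node grid
    for ip, win in enumerate(config.window_sizes):
        step = max(int(round(win * (1 - config.overlap_fraction))), 1)
        ys = np.arange(win // 2, h - win // 2 + 1, step)
        xs = np.arange(win // 2, w - win // 2 + 1, step)
        if len(ys) < 2 or len(xs) < 2:
            continue
        XX, YY = np.meshgrid(xs, ys)
        if u is None:
            u_pred = np.zeros(XX.shape)
            v_pred = np.zeros(XX.shape)
            warped = stressed
        else:
            interp_u = RegularGridInterpolator(
                (nodes_y, nodes_x), u, bounds_error=False, fill_value=None
            )
            interp_v = RegularGridInterpolator(
                (nodes_y, nodes_x), v, bounds_error=False, fill_value=None
            )
            # clamp queries to the previous node hull: nearest-edge
            # prediction, never linear extrapolation
            yq = np.clip(YY, nodes_y[0], nodes_y[-1]).ravel()
            xq = np.clip(XX, nodes_x[0], nodes_x[-1]).ravel()
            pts = np.stack([yq, xq], axis=1)
            u_pred = interp_u(pts).reshape(XX.shape)
            v_pred = interp_v(pts).reshape(XX.shape)
            # deform the stressed image by the full-field prediction so
            # the residual shift is subpixel and gradient-free to first
            # order inside every window
            yg = np.clip(yy_full, nodes_y[0], nodes_y[-1]).ravel()
            xg = np.clip(xx_full, nodes_x[0], nodes_x[-1]).ravel()
            gpts = np.stack([yg, xg], axis=1)
            U = interp_u(gpts).reshape(h, w)
            V = interp_v(gpts).reshape(h, w)
            warped = map_coordinates(
                stressed, [yy_full + V, xx_full + U], order=3, mode="nearest"
            )

        ref_w, _, _ = _extract_windows(
            relaxed, YY.ravel().astype(int), XX.ravel().astype(int), win
        )
        mov_w, _, _ = _extract_windows(
            warped, YY.ravel().astype(int), XX.ravel().astype(int), win
        )
        corr = _window_correlate(mov_w, ref_w)
        n = corr.shape[0]
        center = win // 2
        # after deformation the residual is small: search peaks only
        # within a limited radius to reject spurious far-lag maxima
        radius = max(win // 4, 2) if ip == 0 else max(win // 8, 2)
        lag = np.arange(win) - center
        far = (np.abs(lag)[:, None] > radius) | (np.abs(lag)[None, :] > radius)
        corr = np.where(far[None], -np.inf, corr)
        flat = corr.reshape(n, -1)
        peaks = flat.argmax(axis=1)
        py, px = np.unravel_index(peaks, corr.shape[1:])
        du = np.empty(n)
        dv = np.empty(n)
        for i in range(n):
            sy, sx = _subpixel_offset(corr[i], py[i], px[i], config.subpixel_method)
            dv[i] = py[i] - center + sy
            du[i] = px[i] - center + sx
        lim = win / 2 - 1
        du = np.clip(du, -lim, lim)
        dv = np.clip(dv, -lim, lim)
        u = u_pred + du.reshape(XX.shape)
        v = v_pred + dv.reshape(XX.shape)
        u, v, _ = _median_replace_outliers(u, v, config.outlier_threshold)
        nodes_y, nodes_x = ys, xs

    if u is None:
        raise ValueError("image too small for the configured PIV windows")

    interp_u = RegularGridInterpolator(
        (nodes_y, nodes_x), u, bounds_error=False, fill_value=None
    )
    interp_v = RegularGridInterpolator(
        (nodes_y, nodes_x), v, bounds_error=False, fill_value=None
    )
    yy, xx = np.mgrid[0:h, 0:w]
    # clamp to the node hull: nearest-edge extrapolation outside
    yq = np.clip(yy, nodes_y[0], nodes_y[-1]).ravel()
    xq = np.clip(xx, nodes_x[0], nodes_x[-1]).ravel()
    pts = np.stack([yq, xq], axis=1)
    ux = interp_u(pts).reshape(h, w) * grid.pixel_size
    uy = interp_v(pts).reshape(h, w) * grid.pixel_size
    if config.smooth_sigma_px > 0:
        ux = gaussian_filter(ux, config.smooth_sigma_px)
        uy = gaussian_filter(uy, config.smooth_sigma_px)
    return DisplacementField(u_x=ux, u_y=uy, grid=grid)


def traction_magnitude(traction: TractionField) -> np.ndarray:
    """Per-pixel traction magnitude sqrt(t_x² + t_y²), Pa."""
    return traction.magnitude()
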