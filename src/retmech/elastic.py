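"""Elastic half-space (Boussinesq) displacement-traction relation in Fourier space.

The substrate is treated as a semi-infinite, homogeneous, isotropic
linear-elastic half-space. For a tangential traction field t(x) applied
on the free surface, the surface displacement is the convolution of t
with the Boussinesq point-force response; in Fourier space this is a
per-wavevector 2x2 multiplication

    u(k) = G(k) t(k),
    G(k) = 2 (1 + nu) / (E k^3) * [[(1-nu) k^2 + nu ky^2,  -nu kx ky],
                                   [-nu kx ky,             (1-nu) k^2 + nu kx^2]]

with E the Young's modulus (Pa), nu the Poisson ratio and k in rad/µm,
so tractions in Pa map to displacements in µm. The k = 0 mode (rigid
translation / net force) is undefined for a half-space and is set to
zero; fields are computed on a zero-padded grid (>= 2x linear size) to
suppress periodic wrap-around.

The traction recovery (Fourier-transform traction cytometry, FTTC)
inverts the same operator per wavevector with Tikhonov regularization:

    t(k) = (G^T G + lam_eff^2 I)^(-1) G^T u(k)

where lam_eff = lam * ||G||_max, i.e. the user-facing ``regularization``
is dimensionless on the unit-normalized Green's operator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import fft2, fftfreq, ifft2, next_fast_len

from .model import DisplacementField, SubstrateModel, TractionField

__all__ = ["FttcConfig", "greens_tensor", "forward_displacement", "fttc"]


@dataclass(frozen=True)
class FttcConfig:
    """FTTC inversion parameters.

    regularization: dimensionless Tikhonov parameter on the
    unit-normalized Green's operator (0 = plain inverse).
    padding_factor: linear zero-padding factor (>= 2) for the FFT.
    zero_mean: subtract the mean displacement before inversion (the
    k = 0 mode carries no traction information for a half-space).
    """

    regularization: float = 5e-4
    padding_factor: float = 2.0
    zero_mean: bool = True

    def __post_init__(self) -> None:
        if self.regularization < 0:
            raise ValueError("regularization must be >= 0")
        if self.padding_factor < 2:
            raise ValueError("padding_factor must be >= 2")


def _padded_shape(shape: tuple[int, int], factor: float) -> tuple[int, int]:
    return (
        next_fast_len(int(np.ceil(shape[0] * factor))),
        next_fast_len(int(np.ceil(shape[1] * factor))),
    )


def greens_tensor(
    kx: np.ndarray, ky: np.ndarray, substrate: SubstrateModel
) -> np.ndarray:
    """Half-space Green's tensor G(k), shape kx.shape + (2, 2), in µm/Pa.

    The k = 0 entry is set to zero (the operator is singular there).
    """
    E = substrate.youngs_modulus
    nu = substrate.poisson_ratio
    k2 = kx**2 + ky**2
    k = np.sqrt(k2)
    with np.errstate(divide="ignore", invalid="ignore"):
        pref = 2.0 * (1.0 + nu) / (E * k2 * k)
    pref = np.where(k > 0, pref, 0.0)
    g = np.empty(kx.shape + (2, 2), dtype=float)
    g[..., 0, 0] = pref * ((1.0 - nu) * k2 + nu * ky**2)
    g[..., 1, 1] = pref * ((1.0 - nu) * k2 + nu * kx**2)
    g[..., 0, 1] = g[..., 1, 0] = pref * (-nu * kx * ky)
    return g


def _wavevectors(shape: tuple[int, int], pixel_size: float):
    ky = 2 * np.pi * fftfreq(shape[0], d=pixel_size)
    kx = 2 * np.pi * fftfreq(shape[1], d=pixel_size)
    KX, KY = np.meshgrid(kx, ky)
    return KX, KY


def forward_displacement(
    traction: TractionField,
    substrate: SubstrateModel,
    padding_factor: float = 2.0,
) -> DisplacementField:
    """Surface displacement (µm) produced by a balanced traction field (Pa).

    Warns if the net force is not approximately balanced: the periodic
    FFT convolution only represents a half-space correctly for balanced
    loads (the k = 0 response is discarded).
    """
    grid = traction.grid
    fx, fy = traction.net_force()
    scale = float(np.abs(traction.magnitude()).sum() * grid.pixel_area * 1e-6)
    if scale > 0 and np.hypot(fx, fy) > 0.05 * scale:
        import warnings

        warnings.warn(
            "traction field is not force-balanced; half-space forward model "
            "discards the net-force component",
            stacklevel=2,
        )
    pshape = _padded_shape(grid.shape, padding_factor)
    tx = np.zeros(pshape)
    ty = np.zeros(pshape)
    tx[: grid.height, : grid.width] = traction.t_x
    ty[: grid.height, : grid.width] = traction.t_y
    KX, KY = _wavevectors(pshape, grid.pixel_size)
    G = greens_tensor(KX, KY, substrate)
    tkx = fft2(tx)
    tky = fft2(ty)
    ukx = G[..., 0, 0] * tkx + G[..., 0, 1] * tky
    uky = G[..., 1, 0] * tkx + G[..., 1, 1] * tky
    ux = ifft2(ukx).real[: grid.height, : grid.width]
    uy = ifft2(uky).real[: grid.height, : grid.width]
    return DisplacementField(u_x=ux, u_y=uy, grid=grid)


def fttc(
    displacement: DisplacementField,
    substrate: SubstrateModel,
    config: FttcConfig | None = None,
) -> TractionField:
    """Recover the traction field (Pa) from a displacement field (µm).

    Per-wavevector Tikhonov-regularized inversion of the half-space
    Green's operator; the zero-frequency traction is set to zero, so the
    recovered field is force-balanced on the padded grid.
    """
    if config is None:
        config = FttcConfig()
    grid = displacement.grid
    ux = displacement.u_x
    uy = displacement.u_y
    if config.zero_mean:
        ux = ux - ux.mean()
        uy = uy - uy.mean()
    pshape = _padded_shape(grid.shape, config.padding_factor)
    upx = np.zeros(pshape)
    upy = np.zeros(pshape)
    upx[: grid.height, : grid.width] = ux
    upy[: grid.height, : grid.width] = uy
    KX, KY = _wavevectors(pshape, grid.pixel_size)
    G = greens_tensor(KX, KY, substrate)

    # G is symmetric, so G^T G = G G; normalize lambda by the largest
    # spectral norm of G over the grid (attained at the smallest |k|).
    eig_hi = np.abs(G[..., 0, 0] + G[..., 1, 1]) / 2 + np.sqrt(
        ((G[..., 0, 0] - G[..., 1, 1]) / 2) ** 2 + G[..., 0, 1] ** 2
    )
    gmax = float(eig_hi.max())
    lam2 = (config.regularization * gmax) ** 2

    ukx = fft2(upx)
    uky = fft2(upy)
    # A = G^T G + lam^2 I (2x2 symmetric, real); b = G^T u(k)
    a00 = G[..., 0, 0] ** 2 + G[..., 0, 1] ** 2 + lam2
    a11 = G[..., 1, 1] ** 2 + G[..., 0, 1] ** 2 + lam2
    a01 = G[..., 0, 1] * (G[..., 0, 0] + G[..., 1, 1])
    b0 = G[..., 0, 0] * ukx + G[..., 0, 1] * uky
    b1 = G[..., 0, 1] * ukx + G[..., 1, 1] * uky
    det = a00 * a11 - a01**2
    with np.errstate(divide="ignore", invalid="ignore"):
        tkx = (a11 * b0 - a01 * b1) / det
        tky = (a00 * b1 - a01 * b0) / det
    zero = det == 0
    tkx[zero] = 0.0
    tky[zero] = 0.0
    tkx[0, 0] = 0.0
    tky[0, 0] = 0.0
    tx = ifft2(tkx).real[: grid.height, : grid.width]
    ty = ifft2(tky).real[: grid.height, : grid.width]
    return TractionField(t_x=tx, t_y=ty, grid=grid)
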