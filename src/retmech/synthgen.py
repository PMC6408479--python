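"""Synthetic contractile-cell generator and forward imaging models.

One ground-truth fiber-tension model drives every simulated observable:

* intracellular plane stress from the stress fibers, turned into an
  optical retardation image through the linear stress-optic law;
* focal-adhesion point forces at fiber endpoints, turned into substrate
  tractions, surface displacements (elastic half-space) and fiducial
  bead image pairs;
* fluorescence channels (actin / alpha-SMA tied to the fibers; tubulin /
  vimentin independent of them).

Because retardation and traction both derive from the same fiber
tensions, the generated population carries the monotone coupling
between contractility and retardation that the measurement pipeline is
meant to recover. All randomness is seeded and every generator is a
pure function of (inputs, seed).
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .elastic import forward_displacement
from .grids import ImageGrid
from .model import (
    BeadImagePair,
    CellModel,
    DisplacementField,
    PhotoelasticModel,
    RetardationImage,
    ScenarioSpec,
    StressFiber,
    StressField2D,
    SubstrateModel,
    TractionField,
)

__all__ = [
    "generate_cell_model",
    "intracellular_stress",
    "forward_retardation",
    "add_background",
    "focal_adhesion_tractions",
    "forward_displacement",
    "render_bead_images",
    "render_fluorescence",
    "simulate_timecourse",
    "scale_cell_model",
    "TimepointBundle",
    "PHENOTYPE_DEFAULTS",
]

# Phenotype presets: contractile cells (low passage) carry more and
# stronger stress fibers than synthetic (dedifferentiated) cells.
PHENOTYPE_DEFAULTS = {
    "contractile": {"n_fibers_mean": 13, "n_fibers_min": 4, "tension_scale": 12.0},
    "synthetic": {"n_fibers_mean": 5, "n_fibers_min": 2, "tension_scale": 5.0},
}

_MIN_CELL_GRID = 48  # px; below this a realistically shaped cell cannot fit


def _wobbly_ellipse_mask(
    grid: ImageGrid,
    center: tuple[float, float],
    a_px: float,
    b_px: float,
    angle_deg: float,
    rng: np.random.Generator,
    wobble: float = 0.10,
) -> np.ndarray:
    """Elliptical mask with a smooth low-order boundary perturbation."""
    x, y = grid.pixel_coords()
    th = np.deg2rad(angle_deg)
    dx = x - center[0]
    dy = y - center[1]
    xp = dx * np.cos(th) + dy * np.sin(th)
    yp = -dx * np.sin(th) + dy * np.cos(th)
    rho = np.sqrt((xp / a_px) ** 2 + (yp / b_px) ** 2)
    phi = np.arctan2(yp / b_px, xp / a_px)
    bound = np.ones_like(rho)
    for m in (2, 3, 4):
        amp = wobble * rng.uniform(0.2, 1.0) / m
        bound += amp * np.cos(m * phi + rng.uniform(0, 2 * np.pi))
    return rho <= bound


def generate_cell_model(
    grid: ImageGrid,
    phenotype: str = "contractile",
    n_fibers: int | None = None,
    tension_scale: float | None = None,
    seed: int = 0,
    thickness: float = 3.0,
    size_fraction: float = 0.35,
) -> CellModel:
    """Draw a random cell mask and a set of stress fibers spanning it.

    The mask is an elongated, slightly wobbly ellipse filling most of
    the field of view; fibers run roughly along the long axis with
    transverse and angular jitter, and endpoints are pulled inside the
    mask. Contractile-phenotype defaults draw more fibers at higher
    tension than synthetic-phenotype defaults. ``size_fraction`` sets
    the mean semi-major axis as a fraction of the shorter grid side;
    keep it <= ~0.2 on traction-microscopy grids so the substrate
    displacement decays within the field of view.
    """
    if phenotype not in PHENOTYPE_DEFAULTS:
        raise ValueError(f"unknown phenotype {phenotype!r}")
    if min(grid.height, grid.width) < _MIN_CELL_GRID:
        raise ValueError("grid too small to contain a cell")
    if n_fibers is not None and n_fibers < 0:
        raise ValueError("n_fibers must be >= 0")
    if tension_scale is not None and tension_scale < 0:
        raise ValueError("tension_scale must be >= 0")
    preset = PHENOTYPE_DEFAULTS[phenotype]
    rng = np.random.default_rng(seed)

    h, w = grid.shape
    center = (
        w / 2 + rng.uniform(-0.03, 0.03) * w,
        h / 2 + rng.uniform(-0.03, 0.03) * h,
    )
    a_px = rng.uniform(0.86, 1.14) * size_fraction * min(h, w)
    b_px = a_px * rng.uniform(0.30, 0.50)
    angle = rng.uniform(0.0, 180.0)
    mask = _wobbly_ellipse_mask(grid, center, a_px, b_px, angle, rng)

    if n_fibers is None:
        n_fibers = int(preset["n_fibers_min"] + rng.poisson(preset["n_fibers_mean"]))
    if tension_scale is None:
        tension_scale = float(preset["tension_scale"])

    th = np.deg2rad(angle)
    e_major = np.array([np.cos(th), np.sin(th)])
    e_minor = np.array([-np.sin(th), np.cos(th)])
    c = np.array(center)

    def _inside(p: np.ndarray) -> bool:
        xi, yi = int(round(p[0])), int(round(p[1]))
        return 0 <= xi < w and 0 <= yi < h and bool(mask[yi, xi])

    fibers: list[StressFiber] = []
    # Lognormal tensions with mean == tension_scale.
    sig = 0.35
    mu = np.log(tension_scale) - 0.5 * sig**2 if tension_scale > 0 else -np.inf
    for _ in range(n_fibers):
        off = rng.uniform(-0.65, 0.65) * b_px
        off2 = off + rng.uniform(-0.15, 0.15) * b_px
        ua = rng.uniform(0.35, 0.92)
        ub = rng.uniform(0.35, 0.92)
        pa = c - ua * a_px * e_major + off * e_minor
        pb = c + ub * a_px * e_major + off2 * e_minor
        # Pull endpoints toward the centroid until they land inside the mask.
        for p in (pa, pb):
            for _ in range(40):
                if _inside(p):
                    break
                p += 0.05 * (c - p)
        tension = float(np.exp(rng.normal(mu, sig))) if tension_scale > 0 else 0.0
        width = float(rng.uniform(1.0, 2.0))
        fibers.append(
            StressFiber(
                endpoint_a=(float(pa[0]), float(pa[1])),
                endpoint_b=(float(pb[0]), float(pb[1])),
                tension=tension,
                width=width,
            )
        )
    return CellModel(
        grid=grid,
        mask=mask,
        fibers=fibers,
        thickness=thickness,
        phenotype_label=phenotype,
    )


def _segment_distance(
    x: np.ndarray, y: np.ndarray, pa: tuple[float, float], pb: tuple[float, float]
) -> np.ndarray:
    """Distance (px) from each (x, y) to the segment pa-pb."""
    ax, ay = pa
    bx, by = pb
    abx, aby = bx - ax, by - ay
    ab2 = abx**2 + aby**2
    if ab2 == 0:
        return np.hypot(x - ax, y - ay)
    t = ((x - ax) * abx + (y - ay) * aby) / ab2
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(x - (ax + t * abx), y - (ay + t * aby))


def _fiber_bbox(
    fiber: StressFiber, grid: ImageGrid, margin_px: float
) -> tuple[slice, slice]:
    xs = (fiber.endpoint_a[0], fiber.endpoint_b[0])
    ys = (fiber.endpoint_a[1], fiber.endpoint_b[1])
    x0 = max(int(np.floor(min(xs) - margin_px)), 0)
    x1 = min(int(np.ceil(max(xs) + margin_px)) + 1, grid.width)
    y0 = max(int(np.floor(min(ys) - margin_px)), 0)
    y1 = min(int(np.ceil(max(ys) + margin_px)) + 1, grid.height)
    return slice(y0, y1), slice(x0, x1)


def rasterize_fibers(model: CellModel, weights: np.ndarray | None = None) -> np.ndarray:
    """Accumulate per-fiber weights over fiber footprints (round-capped strips)."""
    grid = model.grid
    out = np.zeros(grid.shape)
    if weights is None:
        weights = np.ones(len(model.fibers))
    for fiber, wgt in zip(model.fibers, weights):
        half = 0.5 * fiber.width / grid.pixel_size
        sy, sx = _fiber_bbox(fiber, grid, half + 1.5)
        yy, xx = np.mgrid[sy, sx]
        d = _segment_distance(xx.astype(float), yy.astype(float), fiber.endpoint_a, fiber.endpoint_b)
        out[sy, sx] += wgt * (d <= half)
    return out


def intracellular_stress(model: CellModel) -> StressField2D:
    """Plane-stress field (Pa) from uniaxial fiber stresses added tensorially.

    Each fiber carries axial stress tension / (width * thickness) within
    its footprint; tensors from overlapping fibers add component-wise.
    """
    grid = model.grid
    sxx = np.zeros(grid.shape)
    syy = np.zeros(grid.shape)
    sxy = np.zeros(grid.shape)
    for fiber in model.fibers:
        if fiber.tension == 0:
            continue
        half = 0.5 * fiber.width / grid.pixel_size
        sy, sx = _fiber_bbox(fiber, grid, half + 1.5)
        yy, xx = np.mgrid[sy, sx]
        d = _segment_distance(xx.astype(float), yy.astype(float), fiber.endpoint_a, fiber.endpoint_b)
        foot = d <= half
        dx, dy = fiber.direction
        # nN / µm² -> kPa -> Pa
        sigma = 1000.0 * fiber.tension / (fiber.width * model.thickness)
        sxx[sy, sx] += sigma * dx * dx * foot
        syy[sy, sx] += sigma * dy * dy * foot
        sxy[sy, sx] += sigma * dx * dy * foot
    return StressField2D(sigma_xx=sxx, sigma_yy=syy, sigma_xy=sxy, grid=grid)


def forward_retardation(
    stress: StressField2D, optics: PhotoelasticModel
) -> RetardationImage:
    """Stress-optic forward model: delta = C * t * (sigma1 - sigma2).

    The principal-stress difference is sqrt((sxx - syy)^2 + 4 sxy^2);
    the slow axis is the orientation of the larger principal stress,
    folded to [0, 180) degrees.
    """
    dxx = stress.sigma_xx - stress.sigma_yy
    diff = np.sqrt(dxx**2 + 4.0 * stress.sigma_xy**2)
    delta = optics.stress_optic_coefficient * optics.thickness * diff
    axis = np.degrees(0.5 * np.arctan2(2.0 * stress.sigma_xy, dxx))
    axis = np.mod(axis, 180.0)
    return RetardationImage(retardation=delta, grid=stress.grid, slow_axis=axis)


def _drift_field(shape: tuple[int, int], amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth nonnegative low-frequency drift with peak scale ~ amplitude."""
    if amplitude == 0:
        return np.zeros(shape)
    h, w = shape
    y, x = np.mgrid[0:h, 0:w]
    raw = np.zeros(shape)
    for _ in range(3):
        fy = rng.uniform(0.3, 1.5)
        fx = rng.uniform(0.3, 1.5)
        ph = rng.uniform(0, 2 * np.pi)
        raw += rng.uniform(0.3, 1.0) * np.cos(2 * np.pi * (fx * x / w + fy * y / h) + ph)
    raw -= raw.min()
    if raw.max() > 0:
        raw /= raw.max()
    return amplitude * raw


def add_background(
    image: RetardationImage, optics: PhotoelasticModel, seed: int = 0
) -> tuple[RetardationImage, RetardationImage]:
    """Superimpose gel/optics background onto a clean retardation image.

    Returns (observed, background). Both share one low-frequency drift
    realization (the drift varies slowly compared to the acquisition
    interval) but carry independent per-pixel noise, so subtracting the
    returned background emulates the imperfect correction of real acquisitions.
    """
    rng = np.random.default_rng(seed)
    drift = _drift_field(image.grid.shape, optics.background_drift_amplitude, rng)
    noise_obs = rng.normal(0.0, optics.noise_sd, image.grid.shape) if optics.noise_sd else 0.0
    noise_bg = rng.normal(0.0, optics.noise_sd, image.grid.shape) if optics.noise_sd else 0.0
    observed = np.clip(image.retardation + drift + noise_obs, 0.0, None)
    background = np.clip(drift + noise_bg, 0.0, None)
    return (
        RetardationImage(retardation=observed, grid=image.grid, slow_axis=image.slow_axis),
        RetardationImage(retardation=background, grid=image.grid),
    )


def focal_adhesion_tractions(
    model: CellModel,
    substrate: SubstrateModel | None = None,
    fa_sigma_um: float = 2.5,
) -> TractionField:
    """Traction field (Pa) from equal-and-opposite fiber endpoint forces.

    Each fiber pulls inward at both endpoints with force equal to its
    tension; point forces are splatted as Gaussian focal-adhesion
    patches. The residual imbalance from patches clipped at the image
    border is removed so the net force is exactly zero.
    """
    grid = model.grid
    fmap_x = np.zeros(grid.shape)  # nN / µm²
    fmap_y = np.zeros(grid.shape)
    sig_px = fa_sigma_um / grid.pixel_size
    r = int(np.ceil(4 * sig_px))
    for fiber in model.fibers:
        if fiber.tension == 0:
            continue
        dx, dy = fiber.direction
        for point, sgn in ((fiber.endpoint_a, +1.0), (fiber.endpoint_b, -1.0)):
            px, py = point
            x0 = max(int(np.floor(px - r)), 0)
            x1 = min(int(np.ceil(px + r)) + 1, grid.width)
            y0 = max(int(np.floor(py - r)), 0)
            y1 = min(int(np.ceil(py + r)) + 1, grid.height)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            k = np.exp(-((xx - px) ** 2 + (yy - py) ** 2) / (2 * sig_px**2))
            tot = k.sum()
            if tot == 0:
                continue
            k /= tot * grid.pixel_area  # density, integrates to 1 over µm²
            fmap_x[y0:y1, x0:x1] += sgn * fiber.tension * dx * k
            fmap_y[y0:y1, x0:x1] += sgn * fiber.tension * dy * k
    tx = 1000.0 * fmap_x  # nN/µm² -> Pa
    ty = 1000.0 * fmap_y
    tx -= tx.mean()
    ty -= ty.mean()
    return TractionField(t_x=tx, t_y=ty, grid=grid)


def render_bead_images(
    displacement: DisplacementField,
    density: float = 0.5,
    bead_sigma: float = 0.3,
    noise_sd: float = 0.02,
    seed: int = 0,
    stage_drift_px: tuple[float, float] = (0.0, 0.0),
    bead_diameter: float = 0.2,
) -> BeadImagePair:
    """Render the before/after fiducial-bead image pair for TFM.

    ``image_relaxed`` shows beads at rest (cell removed); in
    ``image_stressed`` each bead is shifted by the displacement field
    interpolated at its rest position, plus an optional rigid stage
    drift (px) for registration testing. Beads are Gaussian spots of
    sigma ``bead_sigma`` µm placed uniformly at ``density`` beads/µm².
    """
    if density <= 0:
        raise ValueError("bead density must be > 0")
    grid = displacement.grid
    rng = np.random.default_rng(seed)
    area = grid.extent_um[0] * grid.extent_um[1]
    n_beads = max(int(round(density * area)), 1)
    xs = rng.uniform(0, grid.width, n_beads)
    ys = rng.uniform(0, grid.height, n_beads)

    ux = map_coordinates(displacement.u_x, [ys, xs], order=1, mode="nearest")
    uy = map_coordinates(displacement.u_y, [ys, xs], order=1, mode="nearest")
    xs_s = xs + ux / grid.pixel_size + stage_drift_px[0]
    ys_s = ys + uy / grid.pixel_size + stage_drift_px[1]

    sig_px = bead_sigma / grid.pixel_size
    r = int(np.ceil(4 * sig_px))

    def _render(bx: np.ndarray, by: np.ndarray) -> np.ndarray:
        img = np.zeros(grid.shape)
        for px, py in zip(bx, by):
            x0 = max(int(np.floor(px - r)), 0)
            x1 = min(int(np.ceil(px + r)) + 1, grid.width)
            y0 = max(int(np.floor(py - r)), 0)
            y1 = min(int(np.ceil(py + r)) + 1, grid.height)
            if x0 >= x1 or y0 >= y1:
                continue
            yy, xx = np.mgrid[y0:y1, x0:x1]
            img[y0:y1, x0:x1] += np.exp(
                -((xx - px) ** 2 + (yy - py) ** 2) / (2 * sig_px**2)
            )
        return img

    relaxed = _render(xs, ys)
    stressed = _render(xs_s, ys_s)
    if noise_sd > 0:
        relaxed = relaxed + rng.normal(0, noise_sd, grid.shape)
        stressed = stressed + rng.normal(0, noise_sd, grid.shape)
    return BeadImagePair(
        image_stressed=np.clip(stressed, 0, None),
        image_relaxed=np.clip(relaxed, 0, None),
        grid=grid,
        bead_diameter=bead_diameter,
        bead_density=density,
    )


def render_fluorescence(
    model: CellModel, channel: str, seed: int = 0, background_level: float = 2.0
) -> np.ndarray:
    """Render one fluorescence channel as a nonnegative intensity map.

    actin: fiber footprints (overlaps add) over a cytoplasmic baseline.
    alpha_sma: footprints with intensity scaled by fiber tension (the
    contractile-marker readout). tubulin / vimentin: a diffuse
    filamentous texture inside the cell, statistically independent of
    fiber positions. Poisson shot noise throughout;
    ``background_level`` is the extracellular intensity.
    """
    rng = np.random.default_rng(seed)
    grid = model.grid
    baseline = np.where(model.mask, 30.0, background_level)
    if channel == "actin":
        signal = 90.0 * rasterize_fibers(model)
    elif channel == "alpha_sma":
        scale = PHENOTYPE_DEFAULTS["contractile"]["tension_scale"]
        weights = np.array([f.tension / scale for f in model.fibers])
        signal = 90.0 * rasterize_fibers(model, weights)
    elif channel in ("tubulin", "vimentin"):
        white = rng.normal(0, 1, grid.shape)
        texture = gaussian_filter(white, 1.0) - gaussian_filter(white, 3.0)
        sd = texture.std() or 1.0
        signal = 60.0 * np.clip(texture / sd, 0, None) * model.mask
    else:
        raise ValueError(f"unknown channel {channel!r}")
    return rng.poisson(baseline + signal).astype(float)


def scale_cell_model(
    model: CellModel, tension_multiplier: float, area_multiplier: float
) -> CellModel:
    """Rescale a cell about its centroid: area by ``area_multiplier``
    (nearest-neighbor mask resampling keeps it binary), all linear
    dimensions by sqrt of it, and every fiber tension by
    ``tension_multiplier``."""
    if area_multiplier <= 0:
        raise ValueError("area_multiplier must be > 0")
    grid = model.grid
    s = float(np.sqrt(area_multiplier))
    ys, xs = np.nonzero(model.mask)
    cy, cx = ys.mean(), xs.mean()
    if s != 1.0:
        y, x = np.mgrid[0 : grid.height, 0 : grid.width]
        mask = map_coordinates(
            model.mask.astype(np.uint8),
            [cy + (y - cy) / s, cx + (x - cx) / s],
            order=0,
            mode="constant",
            cval=0,
        ).astype(bool)
    else:
        mask = model.mask.copy()
    fibers = [
        StressFiber(
            endpoint_a=(cx + (f.endpoint_a[0] - cx) * s, cy + (f.endpoint_a[1] - cy) * s),
            endpoint_b=(cx + (f.endpoint_b[0] - cx) * s, cy + (f.endpoint_b[1] - cy) * s),
            tension=f.tension * tension_multiplier,
            width=f.width,
        )
        for f in model.fibers
    ]
    return CellModel(
        grid=grid,
        mask=mask,
        fibers=fibers,
        thickness=model.thickness,
        phenotype_label=model.phenotype_label,
    )


class TimepointBundle:
    """Forward-simulated observables for one cell at one timepoint."""

    def __init__(
        self,
        timepoint: float,
        observed: RetardationImage,
        background: RetardationImage,
        mask: np.ndarray,
        traction: TractionField,
        clean: RetardationImage,
        tension_multiplier: float,
        area_multiplier: float,
    ) -> None:
        self.timepoint = timepoint
        self.observed = observed
        self.background = background
        self.mask = mask
        self.traction = traction
        self.clean = clean
        self.tension_multiplier = tension_multiplier
        self.area_multiplier = area_multiplier


def simulate_timecourse(
    model: CellModel,
    scenario: ScenarioSpec,
    optics: PhotoelasticModel | None = None,
    substrate: SubstrateModel | None = None,
) -> list[TimepointBundle]:
    """Re-run every forward model at each scenario timepoint.

    Fiber tensions follow the scenario's tension curve and the mask is
    rescaled to follow its area curve; multiplicative jitter of
    ``scenario.jitter_sd`` (zero at t = 0) emulates spontaneous
    remodeling. Returns one observable bundle per timepoint.
    """
    if optics is None:
        optics = PhotoelasticModel(thickness=model.thickness)
    rng = np.random.default_rng(scenario.seed)
    bundles: list[TimepointBundle] = []
    for i, t in enumerate(scenario.timepoints):
        tmul = scenario.tension_curve[i]
        amul = scenario.area_curve[i]
        if i > 0 and scenario.jitter_sd > 0:
            tmul *= float(np.exp(rng.normal(0, scenario.jitter_sd)))
            amul *= float(np.exp(rng.normal(0, scenario.jitter_sd / 2)))
        scaled = scale_cell_model(model, tmul, amul)
        clean = forward_retardation(intracellular_stress(scaled), optics)
        bg_seed = int(rng.integers(0, 2**31 - 1))
        observed, background = add_background(clean, optics, seed=bg_seed)
        traction = focal_adhesion_tractions(scaled, substrate)
        bundles.append(
            TimepointBundle(
                timepoint=float(t),
                observed=observed,
                background=background,
                mask=scaled.mask,
                traction=traction,
                clean=clean,
                tension_multiplier=tmul,
                area_multiplier=amul,
            )
        )
    return bundles
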