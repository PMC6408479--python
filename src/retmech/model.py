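"""Domain containers shared across the simulation and measurement pipeline.

Units are fixed per field and never implicit: lengths µm, stresses and
tractions Pa, fiber tensions nN, forces µN, retardation nm, angles
degrees in [0, 180).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import ImageGrid

__all__ = [
    "StressFiber",
    "CellModel",
    "StressField2D",
    "PhotoelasticModel",
    "RetardationImage",
    "SubstrateModel",
    "TractionField",
    "DisplacementField",
    "BeadImagePair",
    "ScenarioSpec",
    "CellMask",
    "CellMetrics",
    "TimeCourse",
    "Ellipse",
    "CtfResult",
]


@dataclass(frozen=True)
class StressFiber:
    """A straight contractile actomyosin bundle.

    ``endpoint_a``/``endpoint_b`` are (x, y) pixel coordinates; ``tension``
    is the axial force in nN carried by the bundle; ``width`` is its
    transverse footprint in µm.
    """

    endpoint_a: tuple[float, float]
    endpoint_b: tuple[float, float]
    tension: float
    width: float

    def __post_init__(self) -> None:
        if self.tension < 0:
            raise ValueError("fiber tension must be >= 0")
        if self.width <= 0:
            raise ValueError("fiber width must be > 0")

    @property
    def length_px(self) -> float:
        ax, ay = self.endpoint_a
        bx, by = self.endpoint_b
        return float(np.hypot(bx - ax, by - ay))

    @property
    def direction(self) -> tuple[float, float]:
        """Unit vector from endpoint_a toward endpoint_b."""
        ax, ay = self.endpoint_a
        bx, by = self.endpoint_b
        n = self.length_px
        if n == 0:
            raise ValueError("degenerate fiber with coincident endpoints")
        return ((bx - ax) / n, (by - ay) / n)


@dataclass
class CellModel:
    """Ground-truth synthetic cell: mask, stress fibers, optical thickness."""

    grid: ImageGrid
    mask: np.ndarray
    fibers: list[StressFiber]
    thickness: float = 3.0  # µm, optical path through the cell body
    phenotype_label: str = "contractile"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        if self.thickness <= 0:
            raise ValueError("thickness must be > 0")
        if self.phenotype_label not in ("contractile", "synthetic"):
            raise ValueError("phenotype_label must be 'contractile' or 'synthetic'")

    @property
    def total_tension(self) -> float:
        """Sum of fiber tensions, nN."""
        return float(sum(f.tension for f in self.fibers))


@dataclass
class StressField2D:
    """Per-pixel plane stress tensor (Pa)."""

    sigma_xx: np.ndarray
    sigma_yy: np.ndarray
    sigma_xy: np.ndarray
    grid: ImageGrid

    def __post_init__(self) -> None:
        for name in ("sigma_xx", "sigma_yy", "sigma_xy"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.grid.shape:
                raise ValueError(f"{name} shape does not match grid")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, arr)


@dataclass(frozen=True)
class PhotoelasticModel:
    """Stress-optic law parameters and background-image statistics.

    ``stress_optic_coefficient`` C converts in-plane principal-stress
    difference times optical thickness into retardation:
    delta = C * t * (sigma1 - sigma2), with C in nm µm⁻¹ Pa⁻¹.
    The default is tuned so a typical contractile cell of the generator
    shows a mean cell retardation near 0.2 nm.
    """

    stress_optic_coefficient: float = 7.2e-6
    thickness: float = 3.0
    background_drift_amplitude: float = 0.08  # nm, low-frequency gel/optics drift
    noise_sd: float = 0.03  # nm, per-pixel readout noise

    def __post_init__(self) -> None:
        if self.stress_optic_coefficient <= 0:
            raise ValueError("stress-optic coefficient must be > 0")
        if self.thickness <= 0:
            raise ValueError("thickness must be > 0")
        if self.noise_sd < 0 or self.background_drift_amplitude < 0:
            raise ValueError("noise/drift amplitudes must be >= 0")


@dataclass
class RetardationImage:
    """Per-pixel optical retardation magnitude (nm), optional slow axis (deg)."""

    retardation: np.ndarray
    grid: ImageGrid
    slow_axis: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.retardation = np.asarray(self.retardation, dtype=float)
        if self.retardation.shape != self.grid.shape:
            raise ValueError("retardation shape does not match grid")
        if np.any(self.retardation < 0):
            raise ValueError("retardation is a magnitude and must be >= 0")
        if self.slow_axis is not None:
            self.slow_axis = np.asarray(self.slow_axis, dtype=float)
            if self.slow_axis.shape != self.grid.shape:
                raise ValueError("slow_axis shape does not match grid")


@dataclass(frozen=True)
class SubstrateModel:
    """Linear-elastic half-space substrate (polyacrylamide gel)."""

    youngs_modulus: float = 16e3  # Pa
    poisson_ratio: float = 0.5  # incompressible gel
    grid: ImageGrid | None = None

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise ValueError("Young's modulus must be > 0")
        if not (0.0 <= self.poisson_ratio <= 0.5):
            raise ValueError("Poisson ratio must be in [0, 0.5]")


@dataclass
class TractionField:
    """In-plane traction stress on the substrate surface, Pa per component."""

    t_x: np.ndarray
    t_y: np.ndarray
    grid: ImageGrid

    def __post_init__(self) -> None:
        self.t_x = np.asarray(self.t_x, dtype=float)
        self.t_y = np.asarray(self.t_y, dtype=float)
        if self.t_x.shape != self.grid.shape or self.t_y.shape != self.grid.shape:
            raise ValueError("traction component shape does not match grid")
        if not (np.all(np.isfinite(self.t_x)) and np.all(np.isfinite(self.t_y))):
            raise ValueError("traction field contains non-finite values")

    def net_force(self) -> tuple[float, float]:
        """Net in-plane force (µN components): sum(t) * pixel area * 1e-6."""
        a = self.grid.pixel_area * 1e-6  # Pa µm² = pN; to µN
        return (float(self.t_x.sum() * a), float(self.t_y.sum() * a))

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.t_x, self.t_y)


@dataclass
class DisplacementField:
    """In-plane substrate surface displacement, µm per component."""

    u_x: np.ndarray
    u_y: np.ndarray
    grid: ImageGrid

    def __post_init__(self) -> None:
        self.u_x = np.asarray(self.u_x, dtype=float)
        self.u_y = np.asarray(self.u_y, dtype=float)
        if self.u_x.shape != self.grid.shape or self.u_y.shape != self.grid.shape:
            raise ValueError("displacement component shape does not match grid")
        if not (np.all(np.isfinite(self.u_x)) and np.all(np.isfinite(self.u_y))):
            raise ValueError("displacement field contains non-finite values")

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u_x, self.u_y)


@dataclass
class BeadImagePair:
    """Fluorescent fiducial bead images with (stressed) and without (relaxed) the cell."""

    image_stressed: np.ndarray
    image_relaxed: np.ndarray
    grid: ImageGrid
    bead_diameter: float = 0.2  # µm
    bead_density: float = 0.5  # beads / µm²

    def __post_init__(self) -> None:
        self.image_stressed = np.asarray(self.image_stressed, dtype=float)
        self.image_relaxed = np.asarray(self.image_relaxed, dtype=float)
        if self.image_stressed.shape != self.grid.shape:
            raise ValueError("stressed image shape does not match grid")
        if self.image_relaxed.shape != self.grid.shape:
            raise ValueError("relaxed image shape does not match grid")
        if np.any(self.image_stressed < 0) or np.any(self.image_relaxed < 0):
            raise ValueError("bead images must be nonnegative")


@dataclass(frozen=True)
class ScenarioSpec:
    """A pharmacological time-course scenario.

    ``tension_curve`` and ``area_curve`` give the multiplier applied to
    all fiber tensions / to the cell area at each timepoint (both 1 at
    t = 0). ``jitter_sd`` adds seeded multiplicative noise around the
    curve, emulating spontaneous remodeling in untreated cells.
    """

    treatment: str
    timepoints: tuple[float, ...]
    tension_curve: tuple[float, ...]
    area_curve: tuple[float, ...]
    jitter_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.treatment not in ("control", "contraction", "relaxation"):
            raise ValueError("unknown treatment")
        if len(self.timepoints) != len(self.tension_curve) or len(
            self.timepoints
        ) != len(self.area_curve):
            raise ValueError("curves must align with timepoints")
        if self.timepoints[0] != 0:
            raise ValueError("timepoints must start at 0")
        if any(b <= a for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if self.tension_curve[0] != 1 or self.area_curve[0] != 1:
            raise ValueError("multipliers must equal 1 at t = 0")

    # -- canonical scenarios ------------------------------------------------
    # Endpoint anchors: actomyosin stimulation raises tension 1.6-fold by
    # 50 min while the projected area shrinks; ROCK inhibition halves
    # tension while the cell spreads. Intermediate points are linear.
    @staticmethod
    def default_timepoints() -> tuple[float, ...]:
        return (0.0, 10.0, 20.0, 30.0, 40.0, 50.0)

    @classmethod
    def control(cls, seed: int = 0, jitter_sd: float = 0.05) -> "ScenarioSpec":
        t = cls.default_timepoints()
        ones = tuple(1.0 for _ in t)
        return cls("control", t, ones, ones, jitter_sd=jitter_sd, seed=seed)

    @classmethod
    def contraction(
        cls,
        seed: int = 0,
        jitter_sd: float = 0.05,
        tension_at_end: float = 1.6,
        area_at_end: float = 0.85,
    ) -> "ScenarioSpec":
        t = cls.default_timepoints()
        frac = tuple(ti / t[-1] for ti in t)
        return cls(
            "contraction",
            t,
            tuple(1 + (tension_at_end - 1) * f for f in frac),
            tuple(1 + (area_at_end - 1) * f for f in frac),
            jitter_sd=jitter_sd,
            seed=seed,
        )

    @classmethod
    def relaxation(
        cls,
        seed: int = 0,
        jitter_sd: float = 0.05,
        tension_at_end: float = 0.5,
        area_at_end: float = 1.2,
    ) -> "ScenarioSpec":
        t = cls.default_timepoints()
        frac = tuple(ti / t[-1] for ti in t)
        return cls(
            "relaxation",
            t,
            tuple(1 + (tension_at_end - 1) * f for f in frac),
            tuple(1 + (area_at_end - 1) * f for f in frac),
            jitter_sd=jitter_sd,
            seed=seed,
        )


@dataclass
class CellMask:
    """Binary cell region with provenance (manual outline, threshold, or ground truth)."""

    mask: np.ndarray
    grid: ImageGrid
    provenance: str = "ground_truth"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        if not self.mask.any():
            raise ValueError("cell mask is empty")
        if self.provenance not in ("manual", "threshold", "ground_truth"):
            raise ValueError("unknown mask provenance")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class CellMetrics:
    """Single-cell, single-timepoint retardation summary.

    ret_cell: mean retardation within the mask (nm); a_cell: projected
    area (µm²); ret_cell_total = ret_cell * a_cell (nm µm²); i_cell:
    optional mean fluorescence intensity within the mask.
    """

    ret_cell: float
    a_cell: float
    i_cell: float | None = None
    timepoint: float | None = None

    def __post_init__(self) -> None:
        if self.ret_cell < 0:
            raise ValueError("ret_cell must be >= 0")
        if self.a_cell <= 0:
            raise ValueError("a_cell must be > 0")

    @property
    def ret_cell_total(self) -> float:
        return self.ret_cell * self.a_cell


@dataclass
class TimeCourse:
    """Ordered per-timepoint metrics for one cell; optionally 0-min normalized."""

    metrics: list[CellMetrics]
    normalized: bool = False

    def __post_init__(self) -> None:
        ts = [m.timepoint for m in self.metrics]
        if any(t is None for t in ts):
            raise ValueError("all metrics in a time course need a timepoint")
        if ts and ts[0] != 0:
            raise ValueError("time course must start at 0 min")
        if any(b <= a for a, b in zip(ts, ts[1:])):  # type: ignore[operator]
            raise ValueError("timepoints must be strictly increasing")

    @property
    def timepoints(self) -> list[float]:
        return [float(m.timepoint) for m in self.metrics]  # type: ignore[arg-type]


@dataclass(frozen=True)
class Ellipse:
    """Equal-second-moment ellipse of a region: centroid (µm), semi-axes (µm), orientation (deg)."""

    centroid: tuple[float, float]
    semi_major: float
    semi_minor: float
    orientation: float

    def __post_init__(self) -> None:
        if not (self.semi_major >= self.semi_minor > 0):
            raise ValueError("require semi_major >= semi_minor > 0")
        if not (0.0 <= self.orientation < 180.0):
            raise ValueError("orientation must lie in [0, 180)")

    @property
    def major_axis_vector(self) -> tuple[float, float]:
        th = np.deg2rad(self.orientation)
        return (float(np.cos(th)), float(np.sin(th)))

    @property
    def minor_axis_vector(self) -> tuple[float, float]:
        th = np.deg2rad(self.orientation + 90.0)
        return (float(np.cos(th)), float(np.sin(th)))


@dataclass
class CtfResult:
    """Axis-projected traction sums (µN) and their combined total."""

    s_major: float
    s_minor: float
    ctf_cell_total: float
    combiner: str
    band_mask: np.ndarray | None = None
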