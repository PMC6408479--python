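# Methods

`retmech` simulates contractile adherent cells (vascular smooth muscle
cells are the motivating system) and measures them twice, through two
physically distinct readouts that share one ground truth:

1. **Photoelastic retardation.** Stress fibers are birefringent; the
   optical retardation of a cell reports the in-plane principal-stress
   difference inside it.
2. **Traction force microscopy (TFM).** The same fibers pull on the
   substrate through focal adhesions; gel deformation reports the
   traction the cell exerts.

Because both observables are driven by the same fiber tensions, the
package can test quantitatively whether a retardation-based
contractility readout tracks the traction-based one — the question the
analysis scripts address.

## Ground-truth cell model

A cell is a wobbly-ellipse binary mask plus a set of straight stress
fibers, each with endpoints (inside the mask, roughly along the long
axis), a tension `T` (nN) and a width `w` (µm); the cell has an optical
thickness `t` (default 3 µm). Phenotype presets encode the biology:
*contractile* cells draw ~17 fibers at mean tension 12 nN, *synthetic*
(dedifferentiated) cells ~7 fibers at 5 nN. Tensions are lognormal
(shape 0.35) so cohorts overlap realistically. Per-fiber tensions of a
few to tens of nN match single-stress-fiber force estimates; the
initial draft used 25 nN with tightly focused adhesions, which produced
multi-micrometer gel displacements that no window-based PIV could
track and which are not representative of 16 kPa-gel experiments, so
the defaults were fixed at the current values when the forward model
was designed and not revisited.

Every generator is a pure function of its inputs and a seed.

## Forward models

**Stress and retardation.** Each fiber contributes uniaxial plane
stress `T/(w·t)` along its axis within its footprint; overlapping
fibers add tensorially. The stress-optic law gives the retardation

    δ = C · t · (σ₁ − σ₂),   σ₁−σ₂ = √((σxx−σyy)² + 4σxy²),

with the slow axis along the major principal direction, folded to
[0°, 180°). `C` (nm µm⁻¹ Pa⁻¹) is an *instrument-scale* constant, not a
fitted physical property: its default 7.2 × 10⁻⁶ is chosen once so a
default contractile cell shows a mean cell retardation Ret_Cell ≈ 0.2
nm, the scale observed for cultured vascular smooth muscle cells.
Background images (slow cosine drift ~0.08 nm plus 0.03 nm pixel
noise) model gel/optics birefringence; the observed image and the
returned background share one drift realization but carry independent
noise, so background subtraction is realistically imperfect.

**Tractions and displacements.** Each fiber deposits equal-and-opposite
inward point forces of magnitude `T` at its endpoints, splatted as
Gaussian focal-adhesion patches (σ = 2.5 µm); the residual border
imbalance is removed so the net force is exactly zero. The substrate is
a semi-infinite, isotropic, incompressible (ν = 0.5 by default,
configurable; E = 16 kPa) elastic half-space: displacement follows from
the Boussinesq Green's tensor applied per wavevector,

    u(k) = G(k) t(k),
    G(k) = 2(1+ν)/(E k³) [[(1−ν)k² + ν k_y², −ν k_x k_y],
                          [−ν k_x k_y, (1−ν)k² + ν k_x²]],

on a ≥2× zero-padded grid with the singular k = 0 mode set to zero.
The real gel in such experiments is ~30 µm thick; the finite-thickness
correction is a documented, deliberate omission (it stiffens the
apparent response for cell-sized load patches).

**Bead images.** Fiducial beads (0.2 µm nominal, rendered as Gaussian
spots of σ = 0.3 µm ≈ 1.5 px) are placed uniformly at 1.0 beads/µm²;
the "stressed" frame shifts each bead by the displacement interpolated
at its rest position, optionally plus a rigid stage drift, and both
frames receive Gaussian readout noise.

**Fluorescence.** Actin and α-SMA channels render the fiber footprints
(α-SMA scaled by tension — the contractile-phenotype marker); tubulin
and vimentin render a band-passed random texture inside the mask,
independent of the fibers by construction. All channels carry Poisson
shot noise over a cytoplasmic baseline.

**Time courses.** A scenario multiplies all fiber tensions and the cell
area along piecewise-linear curves over 0–50 min: contraction ramps
tension to 1.6× with area ×0.85; relaxation ramps tension to 0.5× with
area ×1.2; control stays at 1 with multiplicative jitter (σ = 0.05)
emulating spontaneous remodeling. Masks are rescaled about their
centroid with nearest-neighbor sampling to stay binary.

## Measurement pipeline

**Retardation metrics.** Background subtraction is pixelwise with
clipping at zero (retardation is a magnitude; how negative residuals
were handled in practice is generally unstated, and clipping is the
conservative reading). Ret_Cell is the unweighted mean over the mask,
A_Cell the pixel count times pixel area, Ret_CellTotal their exact
product; time courses are normalized metric-wise by the 0-min value.
Segmentation is Otsu on a log-compressed, Gaussian-smoothed image with
largest-component selection and hole filling; log compression stops
Otsu from splitting cytoplasm off bright fibers instead of cell off
background. Measurement-grade masks in the experiments come from the
ground truth, mirroring manual outlining practice; threshold
segmentation needs a channel with cytoplasmic signal (a fiber-only
retardation image of a sparse cell under-covers the mask).

**Registration and PIV.** Stage drift is removed by subpixel phase
correlation. Displacement is then estimated by multipass
image-deformation PIV: windows of 64→32→16 px with 75% overlap; after
each pass the stressed image is warped by the interpolated estimate, so
the residual within every window is subpixel and gradient-free to
first order. Window correlation is zero-padded *linear* correlation
normalized by per-lag overlap — plain circular correlation of finite
windows biases peaks toward zero lag by ~1/window, which this removes —
with a 3-point Gaussian subpixel fit and a restricted peak-search
radius. Vectors failing a 3×3 normalized-median test (threshold 2.0)
are replaced by the local median. The node field is bilinearly
interpolated to the pixel grid (nearest-edge beyond the node hull) and
smoothed with a Gaussian of σ = 4 px: traction inversion amplifies
high-wavenumber vector noise by ~E·k, and a low-pass matched to the
final node spacing stabilizes the inversion far more gracefully than
raising the Tikhonov parameter. The 75% overlap and the smoothing step
were chosen during pipeline design because 50% overlap without
smoothing leaves ~20–23% traction error versus 15–17% with them.

**FTTC.** Tractions solve `t(k) = (GᵀG + λ_eff²I)⁻¹ Gᵀ u(k)` per
wavevector with λ_eff = λ·‖G‖_max, i.e. the user-facing λ (default
5 × 10⁻⁴) is dimensionless on the unit-normalized operator; λ = 0 is
the plain inverse. Zero-frequency traction is set to zero and fields
are mean-subtracted and ≥2× padded. No L-curve automation is provided.

**CTF aggregation.** The equal-second-moment ellipse of the mask
defines major/minor axes (orientation 0 as tie-break for isotropic
masks; the pixel self-moment px²/12 is included so thin masks stay
non-singular). Within the cell-plus-10 µm band (disk dilation via
distance transform; an annulus-only mode exists because "near the cell
area" could exclude the subcellular region), traction vectors are
projected onto each axis and only positive projections are summed,
times pixel area — for a force-balanced field the axis-sign ambiguity
is immaterial. The two axis forces combine as root mean square by
default (the literal reading of the procedure this mirrors), with a
Euclidean option since the wording is ambiguous. Units: Pa·µm² = pN,
reported in µN.

**Regions.** The mask's projected extent along the major axis is cut
into five equal intervals (half-open, last closed — no ties); outer two
slabs are "edge", middle three "central". The extent is the mask's own,
not the ellipse's vertices (the unstated alternative).

**Statistics.** Mann-Whitney U uses the exact enumeration null for
n₁+n₂ ≤ 20 without ties, and the tie-corrected normal approximation
otherwise (scipy backs both branches; tests check the exact branch
against full enumeration). Steel's many-to-one procedure is implemented
as a permutation test: each treatment's pairwise rank-sum against the
shared control is standardized by its exact finite-population moments
(equal to the classical tie-corrected formula), and the family-wise
adjusted p-value is the tail probability of the maximum standardized
statistic over ≥10⁴ seeded relabelings of the pooled sample — a
published-table-free approximation of the classical procedure that
handles unequal group sizes. Its empirical family-wise error at nominal
0.05 measures ~0.04–0.05 over 1000 null simulations. Pearson r is
reported with r² and the t-based two-sided p. Significance is read at
α = 0.05 throughout, with no multiplicity control beyond Steel's own.

## Problem sizes and what the simulations do (not) show

TFM experiments run on 256² px grids at 0.2 µm/px with the cell's
semi-major axis ≈ 20 µm (size_fraction 0.20): the periodic, cropped
Fourier treatment of the half-space needs the displacement field to
decay within the field of view, and a cell filling the frame degrades
even the noise-free round trip catastrophically. Retardation-only
cohorts use 128² grids. Simulated cells are therefore somewhat smaller
than the 50–150 µm of real VSMC cultures, and per-cell CTF_CellTotal
comes out ~0.1–0.3 µN — inside the sub-µN range reported for such
cells, though below typical means. Cohort sizes (10–30 cells per arm,
20 per phenotype) match the desk-scale study designs the experiments
emulate.

The generator omits, deliberately: optical diffraction and the
polarization microscope's PSF; 3-D cell geometry (thickness is a single
scalar); gel finite thickness; fiber curvature, turnover and
remodeling dynamics; and any real coupling constant between fiber
tension and birefringence — the linear stress-optic law with constant
`C` is this package's modeling choice, not an established property of
stress fibers. Passing tests therefore demonstrate that the *pipeline*
is correct and self-consistent (forward models match independent
oracles; the inverse chain recovers known ground truth; the statistics
are calibrated), and that the qualitative orderings hold under the
stated noise model. They do not validate the stress-optic constant, nor
transfer error bars to real microscope data.

## Numerical details worth knowing

- k = 0 of the Green's tensor is undefined (rigid translation); both
  forward and inverse transforms zero it, so absolute mean displacement
  carries no information.
- FTTC recovers a force-balanced field on the padded grid; after
  cropping, the residual net force is small but nonzero (<5% of total
  absolute traction in the acceptance checks).
- `subtract_background` clips at zero; with zero-mean noise this biases
  Ret_Cell upward by O(noise_sd) in dim regions. The bias is identical
  across compared cohorts and cancels in normalized time courses at
  t = 0.
- Orientation angles live in [0°, 180°) with a guard against the float
  wrap of tiny negative angles to 180.0.
- The PIV search radius is win/4 on the first pass and win/8 after
  deformation; vectors are clamped to half-window magnitude. Windows at
  the image border are clamped inside the frame and the *actually
  applied* offset is used, not the requested one.
- Degenerate inputs raise: empty masks, flat images for registration or
  segmentation, zero-variance channels for correlation, masks thinner
  than five pixels along the major axis for partitioning, control
  groups with n < 2 for Steel's test.
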