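# retmech

Photoelastic retardation imaging and traction force microscopy (TFM) of
contractile cells, as one tested pipeline: a seeded forward simulator
of stress-fiber-driven cells (retardation maps, fluorescence channels,
TFM bead-image pairs — all from one ground-truth fiber-tension model)
and the full measurement chain that recovers contractility from those
images.

**Who it is for.** Mechanobiologists and image-analysis developers who
want a label-free contractility readout — optical retardation — and
need to know how well it tracks the standard traction-based readout.
Vascular smooth muscle cells are the motivating system: their
contractile (healthy) and synthetic (disease-associated) phenotypes
differ chiefly in contractile force, so a fast optical proxy for force
is a phenotype assay.

**The model at the core.** Stress fibers carrying tensions `T_i`
generate intracellular plane stress; photoelasticity links the
retardation δ to the principal-stress difference through the
stress-optic law

    δ = C · t · (σ₁ − σ₂),

while the same fibers pull the substrate through focal-adhesion forces,
deforming an elastic half-space (E = 16 kPa, ν = 0.5):
u(k) = G(k)·t(k) with the Boussinesq Green's tensor G. The measurement
chain inverts this: subpixel registration → multipass image-deformation
PIV → Tikhonov-regularized Fourier-transform traction cytometry →
CTF_CellTotal (positive traction projections onto the best-fit-ellipse
axes in a 10 µm peri-cell band, combined as RMS). Retardation metrics
(Ret_Cell, A_Cell, Ret_CellTotal = Ret_Cell × A_Cell) come from
background-subtracted retardation images. Steel's many-to-one
permutation test, Mann-Whitney U and Pearson r² provide the statistics.
See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Simulate a cell, measure it optically, and recover its traction:

```python
from retmech import synthgen, retard, tfm
from retmech.grids import ImageGrid
from retmech.model import CellMask, PhotoelasticModel, SubstrateModel
from retmech.elastic import forward_displacement, fttc
from retmech import ctf

grid = ImageGrid(256, 256, pixel_size=0.2)          # 51 µm field of view
optics, substrate = PhotoelasticModel(), SubstrateModel()

model = synthgen.generate_cell_model(grid, "contractile", seed=42,
                                     size_fraction=0.2)
clean = synthgen.forward_retardation(synthgen.intracellular_stress(model), optics)
observed, background = synthgen.add_background(clean, optics, seed=43)
corrected = retard.subtract_background(observed, background)
mask = CellMask(model.mask, grid)
m = retard.measure_cell(corrected, mask)

traction = synthgen.focal_adhesion_tractions(model, substrate)
beads = synthgen.render_bead_images(forward_displacement(traction, substrate), seed=44)
disp = tfm.piv_displacement(beads.image_stressed, beads.image_relaxed, grid)
recovered = fttc(disp, substrate)
res = ctf.aggregate_ctf(recovered, mask)
print(f"Ret_Cell={m.ret_cell:.3f} nm  A_Cell={m.a_cell:.1f} µm²  "
      f"Ret_CellTotal={m.ret_cell_total:.1f} nm·µm²  CTF={res.ctf_cell_total:.3f} µN")
```

prints (seeds as above):

```
Ret_Cell=0.165 nm  A_Cell=175.7 µm²  Ret_CellTotal=29.0 nm·µm²  CTF=0.194 µN
```

Ret_Cell ≈ 0.17 nm is the sub-nanometer retardation scale of cultured
contractile cells; CTF ≈ 0.2 µN is the recovered single-cell traction
force, which for this noise model lands within ~4% of the ground-truth
aggregate (0.187 µN).

The numbered scripts under `analysis/` run the four cohort-level
analyses (pharmacological time courses, traction-retardation
correlation, phenotype discrimination, central-vs-edge regional
retardation) plus colocalization, writing tables under `results/`:

```bash
python analysis/04_traction_correlation.py
# n = 30 cells: r² = 0.962 (p = 1.93e-21)
# CTF_CellTotal = 0.204 ± 0.076 µN (mean ± SD, recovered)
```

The same experiments are scriptable via the `retmech` CLI
(`retmech experiment correlation --seed 3 --out-dir out/`), and
each stage is independently runnable (`retmech synth generate-tfm-pair`,
`retmech tfm run`, `retmech ctf aggregate`, `retmech stats steel`, ...).

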