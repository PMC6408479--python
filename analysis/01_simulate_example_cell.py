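#!/usr/bin/env python
"""Simulate one contractile cell and write every forward-model observable.

Produces the raw material the later analyses consume in bulk: the cell
mask and fiber table, the clean / observed / background retardation
images, fluorescence channels, and the TFM bead pair with ground-truth
traction. Outputs land in results/example_cell/.
"""

from pathlib import Path

import pandas as pd

from retmech import io as rio
from retmech import retard, synthgen
from retmech.elastic import forward_displacement
from retmech.grids import ImageGrid
from retmech.model import CellMask, PhotoelasticModel, SubstrateModel

OUT = Path(__file__).resolve().parent.parent / "results" / "example_cell"
SEED = 42


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    grid = ImageGrid(256, 256, 0.2)
    optics = PhotoelasticModel()
    substrate = SubstrateModel()

    model = synthgen.generate_cell_model(grid, "contractile", seed=SEED, size_fraction=0.2)
    clean = synthgen.forward_retardation(synthgen.intracellular_stress(model), optics)
    observed, background = synthgen.add_background(clean, optics, seed=SEED + 1)
    corrected = retard.subtract_background(observed, background)
    mask = CellMask(model.mask, grid, provenance="ground_truth")
    metrics = retard.measure_cell(corrected, mask)

    traction = synthgen.focal_adhesion_tractions(model, substrate)
    disp = forward_displacement(traction, substrate)
    beads = synthgen.render_bead_images(disp, seed=SEED + 2)

    rio.write_mask(OUT / "mask.tif", mask)
    rio.write_retardation(OUT / "retardation_clean.tif", clean)
    rio.write_retardation(OUT / "retardation_observed.tif", observed)
    rio.write_retardation(OUT / "retardation_background.tif", background)
    for ch in ("actin", "alpha_sma", "tubulin", "vimentin"):
        rio.write_tiff(
            OUT / f"fluor_{ch}.tif",
            synthgen.render_fluorescence(model, ch, seed=SEED + 3),
            grid.pixel_size,
        )
    rio.write_vector_field(OUT / "traction_x.tif", OUT / "traction_y.tif", traction)
    rio.write_tiff(OUT / "beads_stressed.tif", beads.image_stressed, grid.pixel_size)
    rio.write_tiff(OUT / "beads_relaxed.tif", beads.image_relaxed, grid.pixel_size)
    fibers = pd.DataFrame(
        [
            {
                "ax_px": f.endpoint_a[0],
                "ay_px": f.endpoint_a[1],
                "bx_px": f.endpoint_b[0],
                "by_px": f.endpoint_b[1],
                "tension_nN": f.tension,
                "width_um": f.width,
            }
            for f in model.fibers
        ]
    )
    rio.write_csv(OUT / "fibers.csv", fibers)

    print(f"cell with {len(model.fibers)} fibers, total tension {model.total_tension:.1f} nN")
    print(
        f"Ret_Cell = {metrics.ret_cell:.3f} nm, A_Cell = {metrics.a_cell:.1f} µm², "
        f"Ret_CellTotal = {metrics.ret_cell_total:.1f} nm µm²"
    )
    print(f"peak |u| = {disp.magnitude().max():.2f} µm, peak |t| = {traction.magnitude().max():.0f} Pa")
    print(f"wrote observables to {OUT}")


if __name__ == "__main__":
    main()
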