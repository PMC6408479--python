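"""End-to-end experiment orchestration.

Four reproducible experiment kinds tie the generator to the
measurement pipeline, mirroring the study design the package emulates:

* ``timecourse`` — control / contraction / relaxation cohorts;
  0-min-normalized Ret_Cell, A_Cell, Ret_CellTotal curves and Steel's
  many-to-one test of each arm against control per timepoint.
* ``correlation`` — a heterogeneous-tension population run through
  the full bead-image TFM chain and the retardation chain;
  CTF_CellTotal vs Ret_CellTotal with Pearson r².
* ``phenotype`` — contractile vs synthetic cohorts; Ret_Cell and
  I_Cell (alpha-SMA) with Mann-Whitney U.
* ``regions`` — central vs edge mean retardation per cell with
  Mann-Whitney U.

Every run derives all randomness from one seed and can emit its result
tables, resolved configuration and a manifest to an output directory.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ctf as ctf_mod
from . import regions as regions_mod
from . import retard, synthgen, tfm
from .elastic import FttcConfig, forward_displacement, fttc
from .grids import ImageGrid
from .model import (
    CellMask,
    CellMetrics,
    PhotoelasticModel,
    ScenarioSpec,
    SubstrateModel,
    TimeCourse,
)
from .stats import GroupSample, mann_whitney_u, pearson_correlation, steel_test
from .tfm import PivConfig

__all__ = ["ExperimentConfig", "RunManifest", "run_experiment", "recover_cell_tfm"]

EXPERIMENTS = ("timecourse", "correlation", "phenotype", "regions")


@dataclass(frozen=True)
class ExperimentConfig:
    """Resolved parameters for one experiment run (fully serializable)."""

    seed: int = 0
    # grids: a compact one for pure-retardation cohorts, a larger one for TFM
    grid_small: tuple[int, int, float] = (128, 128, 0.2)
    grid_tfm: tuple[int, int, float] = (256, 256, 0.2)
    cell_fraction_tfm: float = 0.20
    optics: PhotoelasticModel = field(default_factory=PhotoelasticModel)
    substrate: SubstrateModel = field(default_factory=SubstrateModel)
    piv: PivConfig = field(default_factory=PivConfig)
    fttc: FttcConfig = field(default_factory=FttcConfig)
    band_width: float = 10.0  # µm
    combiner: str = "rms"
    band_mode: str = "cell_plus_annulus"
    bead_density: float = 1.0  # beads / µm²
    bead_sigma: float = 0.3  # µm
    bead_noise_sd: float = 0.02
    stage_drift_px: tuple[float, float] = (1.25, -0.75)
    tension_heterogeneity: tuple[float, float] = (0.5, 2.0)
    n_cells_timecourse: int = 10
    n_cells_correlation: int = 30
    n_cells_phenotype: int = 20
    n_cells_regions: int = 20
    steel_permutations: int = 10_000

    def small_grid(self) -> ImageGrid:
        h, w, p = self.grid_small
        return ImageGrid(int(h), int(w), float(p))

    def tfm_grid(self) -> ImageGrid:
        h, w, p = self.grid_tfm
        return ImageGrid(int(h), int(w), float(p))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["piv"] = asdict(self.piv)
        d["fttc"] = asdict(self.fttc)
        d["optics"] = asdict(self.optics)
        d["substrate"] = {
            "youngs_modulus": self.substrate.youngs_modulus,
            "poisson_ratio": self.substrate.poisson_ratio,
        }
        return d


@dataclass
class RunManifest:
    experiment: str
    config_hash: str
    files: list[str]
    stages: list[dict]

    def to_dict(self) -> dict:
        return asdict(self)


def _child_seeds(seed: int, n: int, tag: int = 0) -> list[int]:
    rng = np.random.default_rng([seed, tag])
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def recover_cell_tfm(
    model,
    config: ExperimentConfig,
    seed: int,
):
    """Full TFM measurement of one synthetic cell.

    Ground-truth tractions drive the forward half-space model; bead
    pairs are rendered with stage drift and noise, registered, run
    through multi-pass PIV and regularized FTTC, and aggregated into
    CTF_CellTotal using the ground-truth mask. Returns (truth traction,
    recovered traction, CtfResult recovered, CtfResult truth).
    """
    grid = model.grid
    truth = synthgen.focal_adhesion_tractions(model, config.substrate)
    disp = forward_displacement(truth, config.substrate, config.fttc.padding_factor)
    beads = synthgen.render_bead_images(
        disp,
        density=config.bead_density,
        bead_sigma=config.bead_sigma,
        noise_sd=config.bead_noise_sd,
        seed=seed,
        stage_drift_px=config.stage_drift_px,
    )
    stressed, _drift = tfm.register_images(beads.image_relaxed, beads.image_stressed)
    recovered_disp = tfm.piv_displacement(stressed, beads.image_relaxed, grid, config.piv)
    recovered = fttc(recovered_disp, config.substrate, config.fttc)
    mask = CellMask(mask=model.mask, grid=grid, provenance="ground_truth")
    res = ctf_mod.aggregate_ctf(
        recovered, mask, config.band_width, config.combiner, config.band_mode
    )
    res_truth = ctf_mod.aggregate_ctf(
        truth, mask, config.band_width, config.combiner, config.band_mode
    )
    return truth, recovered, res, res_truth


def _measured_metrics(bundle, grid, timepoint=None) -> CellMetrics:
    """Background-subtract the observed image and measure the cell."""
    corrected = retard.subtract_background(bundle.observed, bundle.background)
    mask = CellMask(mask=bundle.mask, grid=grid, provenance="ground_truth")
    return retard.measure_cell(corrected, mask, timepoint=timepoint)


# --------------------------------------------------------------------------
# experiment bodies


def _run_timecourse(config: ExperimentConfig) -> dict[str, pd.DataFrame]:
    grid = config.small_grid()
    arms = {
        "control": ScenarioSpec.control,
        "contraction": ScenarioSpec.contraction,
        "relaxation": ScenarioSpec.relaxation,
    }
    rows = []
    n = config.n_cells_timecourse
    for ai, (arm, factory) in enumerate(arms.items()):
        seeds = _child_seeds(config.seed, n, tag=100 + ai)
        for ci, s in enumerate(seeds):
            model = synthgen.generate_cell_model(grid, "contractile", seed=s)
            scenario = factory(seed=s + 1)
            bundles = synthgen.simulate_timecourse(
                model, scenario, config.optics, config.substrate
            )
            tc = TimeCourse(
                metrics=[_measured_metrics(b, grid, b.timepoint) for b in bundles]
            )
            norm = retard.normalize_timecourse(tc)
            for m in norm.metrics:
                rows.append(
                    {
                        "arm": arm,
                        "cell_id": ci,
                        "timepoint_min": m.timepoint,
                        "ret_cell_norm": m.ret_cell,
                        "a_cell_norm": m.a_cell,
                        "ret_cell_total_norm": m.ret_cell_total,
                    }
                )
    curves = pd.DataFrame(rows)

    test_rows = []
    for metric in ("ret_cell_norm", "a_cell_norm", "ret_cell_total_norm"):
        for t in sorted(curves["timepoint_min"].unique()):
            if t == 0:
                continue
            sub = curves[curves["timepoint_min"] == t]
            control = GroupSample(
                "control", tuple(sub[sub["arm"] == "control"][metric])
            )
            treats = [
                GroupSample(arm, tuple(sub[sub["arm"] == arm][metric]))
                for arm in ("contraction", "relaxation")
            ]
            results = steel_test(
                control,
                treats,
                n_permutations=config.steel_permutations,
                seed=config.seed + int(t),
            )
            for arm, res in zip(("contraction", "relaxation"), results):
                test_rows.append(
                    {
                        "metric": metric,
                        "timepoint_min": t,
                        "arm": arm,
                        "z": res.statistic,
                        "p_adjusted": res.p_value,
                        "significant": res.significant,
                    }
                )
    return {"timecourse_curves": curves, "timecourse_steel": pd.DataFrame(test_rows)}


def _run_correlation(config: ExperimentConfig) -> dict[str, pd.DataFrame]:
    grid = config.tfm_grid()
    n = config.n_cells_correlation
    seeds = _child_seeds(config.seed, n, tag=300)
    lo, hi = config.tension_heterogeneity
    rng = np.random.default_rng([config.seed, 301])
    rows = []
    for ci, s in enumerate(seeds):
        scale = float(
            synthgen.PHENOTYPE_DEFAULTS["contractile"]["tension_scale"]
            * rng.uniform(lo, hi)
        )
        model = synthgen.generate_cell_model(
            grid,
            "contractile",
            tension_scale=scale,
            seed=s,
            size_fraction=config.cell_fraction_tfm,
        )
        # retardation chain (with background) on the same ground truth
        clean = synthgen.forward_retardation(
            synthgen.intracellular_stress(model), config.optics
        )
        observed, background = synthgen.add_background(clean, config.optics, seed=s + 1)
        corrected = retard.subtract_background(observed, background)
        mask = CellMask(mask=model.mask, grid=grid, provenance="ground_truth")
        metrics = retard.measure_cell(corrected, mask)
        _, _, res, res_truth = recover_cell_tfm(model, config, seed=s + 2)
        rows.append(
            {
                "cell_id": ci,
                "tension_scale_nN": scale,
                "total_tension_nN": model.total_tension,
                "ret_cell_nm": metrics.ret_cell,
                "a_cell_um2": metrics.a_cell,
                "ret_cell_total_nm_um2": metrics.ret_cell_total,
                "ctf_recovered_uN": res.ctf_cell_total,
                "ctf_truth_uN": res_truth.ctf_cell_total,
            }
        )
    table = pd.DataFrame(rows)
    r, r2, p = pearson_correlation(
        table["ctf_recovered_uN"], table["ret_cell_total_nm_um2"]
    )
    summary = pd.DataFrame(
        [
            {
                "x": "ctf_recovered_uN",
                "y": "ret_cell_total_nm_um2",
                "pearson_r": r,
                "r_squared": r2,
                "p_value": p,
                "n_cells": len(table),
                "mean_ctf_uN": table["ctf_recovered_uN"].mean(),
                "sd_ctf_uN": table["ctf_recovered_uN"].std(ddof=1),
            }
        ]
    )
    return {"correlation_cells": table, "correlation_summary": summary}


def _run_phenotype(config: ExperimentConfig) -> dict[str, pd.DataFrame]:
    grid = config.small_grid()
    n = config.n_cells_phenotype
    rows = []
    for pi, phenotype in enumerate(("contractile", "synthetic")):
        seeds = _child_seeds(config.seed, n, tag=400 + pi)
        for ci, s in enumerate(seeds):
            model = synthgen.generate_cell_model(grid, phenotype, seed=s)
            clean = synthgen.forward_retardation(
                synthgen.intracellular_stress(model), config.optics
            )
            observed, background = synthgen.add_background(
                clean, config.optics, seed=s + 1
            )
            corrected = retard.subtract_background(observed, background)
            mask = CellMask(mask=model.mask, grid=grid, provenance="ground_truth")
            fluor = synthgen.render_fluorescence(model, "alpha_sma", seed=s + 2)
            metrics = retard.measure_cell(corrected, mask, fluor=fluor)
            rows.append(
                {
                    "phenotype": phenotype,
                    "cell_id": ci,
                    "ret_cell_nm": metrics.ret_cell,
                    "a_cell_um2": metrics.a_cell,
                    "i_cell": metrics.i_cell,
                }
            )
    cells = pd.DataFrame(rows)
    tests = []
    for metric in ("ret_cell_nm", "i_cell"):
        a = GroupSample(
            "contractile", tuple(cells[cells["phenotype"] == "contractile"][metric])
        )
        b = GroupSample(
            "synthetic", tuple(cells[cells["phenotype"] == "synthetic"][metric])
        )
        res = mann_whitney_u(a, b)
        tests.append(
            {
                "metric": metric,
                "U": res.statistic,
                "p_value": res.p_value,
                "significant": res.significant,
                "mean_contractile": a.array.mean(),
                "mean_synthetic": b.array.mean(),
            }
        )
    return {"phenotype_cells": cells, "phenotype_tests": pd.DataFrame(tests)}


def _run_regions(config: ExperimentConfig) -> dict[str, pd.DataFrame]:
    grid = config.small_grid()
    seeds = _child_seeds(config.seed, config.n_cells_regions, tag=500)
    rows = []
    for ci, s in enumerate(seeds):
        model = synthgen.generate_cell_model(grid, "contractile", seed=s)
        clean = synthgen.forward_retardation(
            synthgen.intracellular_stress(model), config.optics
        )
        observed, background = synthgen.add_background(clean, config.optics, seed=s + 1)
        corrected = retard.subtract_background(observed, background)
        mask = CellMask(mask=model.mask, grid=grid, provenance="ground_truth")
        ellipse = ctf_mod.best_fit_ellipse(mask)
        labels = regions_mod.partition_cell(mask, ellipse)
        central, edge = regions_mod.regional_retardation(corrected, labels)
        rows.append(
            {"cell_id": ci, "central_mean_nm": central, "edge_mean_nm": edge}
        )
    cells = pd.DataFrame(rows)
    res = mann_whitney_u(
        GroupSample("central", tuple(cells["central_mean_nm"])),
        GroupSample("edge", tuple(cells["edge_mean_nm"])),
    )
    summary = pd.DataFrame(
        [
            {
                "central_mean_nm": cells["central_mean_nm"].mean(),
                "central_sd_nm": cells["central_mean_nm"].std(ddof=1),
                "edge_mean_nm": cells["edge_mean_nm"].mean(),
                "edge_sd_nm": cells["edge_mean_nm"].std(ddof=1),
                "mwu_p": res.p_value,
                "significant": res.significant,
                "n_cells": len(cells),
            }
        ]
    )
    return {"regions_cells": cells, "regions_summary": summary}


_BODIES = {
    "timecourse": _run_timecourse,
    "correlation": _run_correlation,
    "phenotype": _run_phenotype,
    "regions": _run_regions,
}


def run_experiment(
    config: ExperimentConfig,
    experiment: str,
    out_dir: str | Path | None = None,
) -> tuple[RunManifest, dict[str, pd.DataFrame]]:
    """Run one experiment; optionally persist tables, config and manifest."""
    if experiment not in _BODIES:
        raise ValueError(f"unknown experiment {experiment!r}; one of {EXPERIMENTS}")
    cfg_yaml = yaml.safe_dump(config.to_dict(), sort_keys=True)
    cfg_hash = hashlib.sha256(cfg_yaml.encode()).hexdigest()[:16]
    t0 = time.perf_counter()
    tables = _BODIES[experiment](config)
    elapsed = time.perf_counter() - t0
    files: list[str] = []
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.yaml").write_text(cfg_yaml)
        files.append("config.yaml")
        for name, df in tables.items():
            fname = f"{name}.csv"
            df.to_csv(out / fname, index=False)
            files.append(fname)
    manifest = RunManifest(
        experiment=experiment,
        config_hash=cfg_hash,
        files=files,
        stages=[{"stage": experiment, "wall_time_s": round(elapsed, 3)}],
    )
    if out_dir is not None:
        (Path(out_dir) / "manifest.json").write_text(
            json.dumps(manifest.to_dict(), indent=2)
        )
    return manifest, tables
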