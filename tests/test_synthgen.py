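"""Generator and forward-model tests: every expected value is either a
hand computation, an independent per-pixel oracle, or a construction
property of the generator itself."""

import numpy as np
import pytest
from scipy import stats as sps

from retmech import synthgen
from retmech.elastic import forward_displacement
from retmech.grids import ImageGrid
from retmech.model import (
    CellModel,
    PhotoelasticModel,
    RetardationImage,
    ScenarioSpec,
    StressFiber,
    StressField2D,
    SubstrateModel,
    TractionField,
)


class TestGenerateCellModel:
    def test_zero_fibers_yields_valid_mask_and_empty_list(self, grid128):
        m = synthgen.generate_cell_model(grid128, "contractile", n_fibers=0, seed=1)
        assert m.fibers == []
        assert m.mask.any()
        # one connected component
        from scipy.ndimage import label

        _, n = label(m.mask)
        assert n == 1

    def test_seeded_determinism_is_bitwise(self, grid128):
        a = synthgen.generate_cell_model(grid128, seed=7)
        b = synthgen.generate_cell_model(grid128, seed=7)
        assert np.array_equal(a.mask, b.mask)
        assert a.fibers == b.fibers

    def test_fibers_lie_inside_mask(self, grid128):
        for seed in range(5):
            m = synthgen.generate_cell_model(grid128, seed=seed)
            for f in m.fibers:
                for px, py in (f.endpoint_a, f.endpoint_b):
                    assert m.mask[int(round(py)), int(round(px))]

    def test_contractile_population_carries_more_tension(self, grid128):
        # oracle: direct summation of generated fiber tensions
        tot = {
            ph: np.mean(
                [
                    synthgen.generate_cell_model(grid128, ph, seed=s).total_tension
                    for s in range(50)
                ]
            )
            for ph in ("contractile", "synthetic")
        }
        assert tot["contractile"] > tot["synthetic"]

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            synthgen.generate_cell_model(ImageGrid(32, 32, 0.2), seed=0)


class TestIntracellularStress:
    def test_empty_fiber_list_gives_zero_field(self, grid128):
        m = synthgen.generate_cell_model(grid128, n_fibers=0, seed=2)
        s = synthgen.intracellular_stress(m)
        assert not s.sigma_xx.any() and not s.sigma_yy.any() and not s.sigma_xy.any()

    def test_horizontal_fiber_hand_value(self, grid128):
        # T/(w*t) = 10 nN / (1 µm * 2 µm) = 5 nN/µm² = 5000 Pa
        fiber = StressFiber((30.0, 64.0), (90.0, 64.0), tension=10.0, width=1.0)
        mask = np.zeros(grid128.shape, dtype=bool)
        mask[50:80, 20:100] = True
        m = CellModel(grid=grid128, mask=mask, fibers=[fiber], thickness=2.0)
        s = synthgen.intracellular_stress(m)
        assert s.sigma_xx[64, 60] == pytest.approx(5000.0)
        assert s.sigma_yy[64, 60] == 0.0
        assert s.sigma_xy[64, 60] == 0.0

    def test_orthogonal_crossing_is_isotropic_at_center(self, grid128):
        mask = np.ones(grid128.shape, dtype=bool)
        fx = StressFiber((34.0, 64.0), (94.0, 64.0), tension=8.0, width=1.0)
        fy = StressFiber((64.0, 34.0), (64.0, 94.0), tension=8.0, width=1.0)
        m = CellModel(grid=grid128, mask=mask, fibers=[fx, fy], thickness=2.0)
        s = synthgen.intracellular_stress(m)
        assert s.sigma_xx[64, 64] == pytest.approx(s.sigma_yy[64, 64])
        assert s.sigma_xy[64, 64] == pytest.approx(0.0)


class TestForwardRetardation:
    def test_matches_eigendecomposition_oracle(self, grid128):
        rng = np.random.default_rng(0)
        sxx, syy, sxy = rng.normal(0, 1000, (3, 256, 256))
        grid = ImageGrid(256, 256, 0.2)
        stress = StressField2D(sxx, syy, sxy, grid)
        optics = PhotoelasticModel(stress_optic_coefficient=1e-4, thickness=1.0)
        img = synthgen.forward_retardation(stress, optics)
        # oracle: per-pixel 2x2 symmetric eigendecomposition
        tensors = np.empty((256, 256, 2, 2))
        tensors[..., 0, 0] = sxx
        tensors[..., 1, 1] = syy
        tensors[..., 0, 1] = tensors[..., 1, 0] = sxy
        eig = np.linalg.eigvalsh(tensors)
        expected = 1e-4 * 1.0 * (eig[..., 1] - eig[..., 0])
        np.testing.assert_allclose(img.retardation, expected, rtol=1e-10)

    def test_hydrostatic_stress_has_zero_retardation(self, grid128, optics):
        s = StressField2D(
            np.full(grid128.shape, 1000.0),
            np.full(grid128.shape, 1000.0),
            np.zeros(grid128.shape),
            grid128,
        )
        assert synthgen.forward_retardation(s, optics).retardation.max() == 0.0

    def test_pure_shear_closed_form(self, grid128):
        # sigma1 - sigma2 = 2s; with C*t = 1 nm/kPa and s = 100 Pa -> 0.2 nm
        optics = PhotoelasticModel(stress_optic_coefficient=1e-3, thickness=1.0)
        s = StressField2D(
            np.zeros(grid128.shape),
            np.zeros(grid128.shape),
            np.full(grid128.shape, 100.0),
            grid128,
        )
        img = synthgen.forward_retardation(s, optics)
        np.testing.assert_allclose(img.retardation, 0.2, rtol=1e-12)
        np.testing.assert_allclose(img.slow_axis, 45.0)

    def test_rotation_invariance_of_magnitude(self, grid128, optics):
        rng = np.random.default_rng(1)
        sxx, syy, sxy = rng.normal(0, 500, (3,) + grid128.shape)
        base = synthgen.forward_retardation(
            StressField2D(sxx, syy, sxy, grid128), optics
        )
        th = np.deg2rad(30.0)
        c, s = np.cos(th), np.sin(th)
        # pointwise tensor rotation R sigma R^T with R = [[c, -s], [s, c]]
        rxx = c * c * sxx - 2 * c * s * sxy + s * s * syy
        ryy = s * s * sxx + 2 * c * s * sxy + c * c * syy
        rxy = c * s * (sxx - syy) + (c * c - s * s) * sxy
        rot = synthgen.forward_retardation(
            StressField2D(rxx, ryy, rxy, grid128), optics
        )
        np.testing.assert_allclose(rot.retardation, base.retardation, rtol=1e-9)
        shift = np.mod(rot.slow_axis - base.slow_axis, 180.0)
        mask = base.retardation > 1e-6
        np.testing.assert_allclose(shift[mask], 30.0, atol=1e-6)


class TestAddBackground:
    def test_zero_drift_zero_noise_is_identity(self, clean_retardation):
        optics = PhotoelasticModel(background_drift_amplitude=0.0, noise_sd=0.0)
        obs, bg = synthgen.add_background(clean_retardation, optics, seed=4)
        np.testing.assert_array_equal(obs.retardation, clean_retardation.retardation)
        assert not bg.retardation.any()

    def test_seeded_determinism(self, clean_retardation, optics):
        a = synthgen.add_background(clean_retardation, optics, seed=9)
        b = synthgen.add_background(clean_retardation, optics, seed=9)
        np.testing.assert_array_equal(a[0].retardation, b[0].retardation)
        np.testing.assert_array_equal(a[1].retardation, b[1].retardation)

    def test_noise_sd_matches_sample_sd_oracle(self):
        grid = ImageGrid(128, 128, 0.2)
        optics = PhotoelasticModel(background_drift_amplitude=0.0, noise_sd=0.05)
        zero = RetardationImage(np.zeros(grid.shape), grid)
        obs, _ = synthgen.add_background(zero, optics, seed=5)
        # observed = clip(noise, 0): recover sd from the positive half
        pos = obs.retardation[obs.retardation > 0]
        half_sd = np.sqrt(np.mean(pos**2))  # E[N^2 | N>0] = sd^2
        assert half_sd == pytest.approx(0.05, rel=0.10)


class TestFocalAdhesionTractions:
    def test_zero_fiber_model_gives_zero_field(self, grid128):
        m = synthgen.generate_cell_model(grid128, n_fibers=0, seed=2)
        t = synthgen.focal_adhesion_tractions(m)
        assert not t.t_x.any() and not t.t_y.any()

    def test_net_force_is_zero_to_machine_precision(self, contractile_model):
        t = synthgen.focal_adhesion_tractions(contractile_model)
        fx, fy = t.net_force()
        scale = t.magnitude().sum() * t.grid.pixel_area * 1e-6
        assert abs(fx) < 1e-12 * scale and abs(fy) < 1e-12 * scale

    def test_endpoint_patch_integrates_to_fiber_tension(self):
        grid = ImageGrid(192, 192, 0.2)
        mask = np.ones(grid.shape, dtype=bool)
        fiber = StressFiber((48.0, 96.0), (144.0, 96.0), tension=20.0, width=1.5)
        m = CellModel(grid=grid, mask=mask, fibers=[fiber])
        t = synthgen.focal_adhesion_tractions(m, fa_sigma_um=1.0)
        # oracle: quadrature over the left half-plane around endpoint_a
        left = np.zeros(grid.shape, dtype=bool)
        left[:, :96] = True
        fx = t.t_x[left].sum() * grid.pixel_area * 1e-3  # Pa µm² -> nN
        fy = t.t_y[left].sum() * grid.pixel_area * 1e-3
        assert fx == pytest.approx(20.0, rel=0.01)  # pulls inward (+x)
        assert fy == pytest.approx(0.0, abs=0.2)

    def test_net_torque_is_negligible(self, contractile_model):
        t = synthgen.focal_adhesion_tractions(contractile_model)
        y, x = np.mgrid[0 : t.grid.height, 0 : t.grid.width]
        x = x * t.grid.pixel_size
        y = y * t.grid.pixel_size
        cx, cy = x.mean(), y.mean()
        torque = ((x - cx) * t.t_y - (y - cy) * t.t_x).sum() * t.grid.pixel_area
        scale = (np.hypot(x - cx, y - cy) * t.magnitude()).sum() * t.grid.pixel_area
        assert abs(torque) < 0.01 * scale


class TestForwardDisplacement:
    def test_zero_traction_zero_displacement(self, grid128, substrate):
        t = TractionField(np.zeros(grid128.shape), np.zeros(grid128.shape), grid128)
        d = forward_displacement(t, substrate)
        assert not d.u_x.any() and not d.u_y.any()

    def test_linearity_in_traction(self, contractile_model, substrate):
        t = synthgen.focal_adhesion_tractions(contractile_model)
        d1 = forward_displacement(t, substrate)
        t2 = TractionField(2.0 * t.t_x, 2.0 * t.t_y, t.grid)
        d2 = forward_displacement(t2, substrate)
        np.testing.assert_allclose(d2.u_x, 2.0 * d1.u_x, rtol=1e-10, atol=1e-14)

    def test_matches_realspace_boussinesq_quadrature(self, substrate):
        """FFT result vs direct summation of the surface point-force
        response u_i(r) = (1+nu)/(pi E r) [(1-nu) d_ij + nu r_i r_j/r²] F_j
        over all traction pixels, inside the central third of the grid."""
        grid = ImageGrid(64, 64, 0.5)
        y, x = np.mgrid[0:64, 0:64]
        # smooth compact force dipole along x
        sig = 3.0
        blob_p = np.exp(-((x - 38) ** 2 + (y - 32) ** 2) / (2 * sig**2))
        blob_m = np.exp(-((x - 26) ** 2 + (y - 32) ** 2) / (2 * sig**2))
        tx = 100.0 * (blob_p - blob_m)
        tx -= tx.mean()
        t = TractionField(tx, np.zeros_like(tx), grid)
        d = forward_displacement(t, substrate, padding_factor=4.0)

        E = substrate.youngs_modulus
        nu = substrate.poisson_ratio
        h = grid.pixel_size
        pref = (1 + nu) / (np.pi * E)
        targets = [(yi, xi) for yi in range(26, 39, 4) for xi in range(26, 39, 4)]

        def kernel_sum(rx, ry, f):
            r = np.hypot(rx, ry)
            ux = np.sum(f / r * ((1 - nu) + nu * rx**2 / r**2))
            uy = np.sum(f / r * (nu * rx * ry / r**2))
            return pref * ux, pref * uy

        # near-source pixels are subdivided so the 1/r quadrature converges
        sub = 8
        off = (np.arange(sub) + 0.5) / sub - 0.5
        ox, oy = np.meshgrid(off, off)
        for yi, xi in targets:
            rx = (xi - x).astype(float) * h
            ry = (yi - y).astype(float) * h
            near = np.hypot(rx, ry) <= 3 * h
            ux, uy = kernel_sum(
                rx[~near], ry[~near], tx[~near] * grid.pixel_area
            )
            for ny, nx in zip(*np.nonzero(near)):
                srx = (xi - nx - ox.ravel()) * h
                sry = (yi - ny - oy.ravel()) * h
                dux, duy = kernel_sum(
                    srx, sry, np.full(sub * sub, tx[ny, nx] * grid.pixel_area / sub**2)
                )
                ux += dux
                uy += duy
            err = np.hypot(d.u_x[yi, xi] - ux, d.u_y[yi, xi] - uy)
            assert err < 0.05 * np.abs(d.magnitude()).max()


class TestRenderBeadImages:
    def test_zero_displacement_pair_identical(self, grid128):
        d = synthgen.DisplacementField(
            np.zeros(grid128.shape), np.zeros(grid128.shape), grid128
        )
        pair = synthgen.render_bead_images(d, density=0.3, noise_sd=0.0, seed=3)
        np.testing.assert_array_equal(pair.image_stressed, pair.image_relaxed)

    def test_seeded_determinism(self, grid128):
        d = synthgen.DisplacementField(
            np.zeros(grid128.shape), np.zeros(grid128.shape), grid128
        )
        a = synthgen.render_bead_images(d, density=0.3, seed=3)
        b = synthgen.render_bead_images(d, density=0.3, seed=3)
        np.testing.assert_array_equal(a.image_stressed, b.image_stressed)

    def test_uniform_shift_bead_centroids(self, grid128):
        """Center of mass of isolated beads shifts by 1.0 µm / pixel_size px."""
        d = synthgen.DisplacementField(
            np.full(grid128.shape, 1.0), np.zeros(grid128.shape), grid128
        )
        pair = synthgen.render_bead_images(d, density=0.02, noise_sd=0.0, seed=6)
        # rest positions drawn exactly as in the renderer
        rng = np.random.default_rng(6)
        area = grid128.extent_um[0] * grid128.extent_um[1]
        n = max(int(round(0.02 * area)), 1)
        xs = rng.uniform(0, grid128.width, n)
        ys = rng.uniform(0, grid128.height, n)
        shift_px = 1.0 / grid128.pixel_size
        checked = 0
        for bx, by in zip(xs, ys):
            if not (15 < bx < 100 and 15 < by < 112):
                continue
            dmin = np.min(
                [np.hypot(bx - ox, by - oy) or np.inf for ox, oy in zip(xs, ys)]
            )
            if dmin < 14:
                continue

            def com(img, cx, cy):
                x0, y0 = int(round(cx)) - 6, int(round(cy)) - 6
                win = img[y0 : y0 + 13, x0 : x0 + 13]
                yy, xx = np.mgrid[y0 : y0 + 13, x0 : x0 + 13]
                return (xx * win).sum() / win.sum(), (yy * win).sum() / win.sum()

            rx, _ = com(pair.image_relaxed, bx, by)
            sx, _ = com(pair.image_stressed, bx + shift_px, by)
            assert sx - rx == pytest.approx(shift_px, abs=0.05)
            checked += 1
        assert checked >= 3


class TestRenderFluorescence:
    def test_zero_fiber_actin_is_background_only(self, grid128):
        m = synthgen.generate_cell_model(grid128, n_fibers=0, seed=2)
        img = synthgen.render_fluorescence(m, "actin", seed=1)
        # Poisson around the 30/2 baseline, nothing brighter than shot noise
        assert img[m.mask].mean() == pytest.approx(30.0, rel=0.1)
        assert img.max() < 80

    def test_unknown_channel_rejected(self, contractile_model):
        with pytest.raises(ValueError, match="channel"):
            synthgen.render_fluorescence(contractile_model, "desmin", seed=0)


class TestTimecourse:
    def test_scenario_default_endpoints(self):
        assert ScenarioSpec.contraction().tension_curve[-1] == pytest.approx(1.6)
        assert ScenarioSpec.relaxation().tension_curve[-1] == pytest.approx(0.5)
        assert ScenarioSpec.contraction().timepoints[-1] == 50.0

    def test_zero_jitter_control_is_static(self, contractile_model, optics):
        scen = ScenarioSpec.control(seed=1, jitter_sd=0.0)
        bundles = synthgen.simulate_timecourse(contractile_model, scen, optics)
        for b in bundles[1:]:
            np.testing.assert_array_equal(b.mask, bundles[0].mask)
            np.testing.assert_array_equal(
                b.clean.retardation, bundles[0].clean.retardation
            )

    def test_scale_model_area_and_tension(self, contractile_model):
        scaled = synthgen.scale_cell_model(contractile_model, 1.6, 0.85)
        assert scaled.total_tension == pytest.approx(
            1.6 * contractile_model.total_tension
        )
        ratio = scaled.mask.sum() / contractile_model.mask.sum()
        assert ratio == pytest.approx(0.85, rel=0.05)

    def test_invalid_scenarios_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec("contraction", (0.0, 10.0), (1.0, 1.2), (1.0,))
        with pytest.raises(ValueError):
            ScenarioSpec("control", (5.0, 10.0), (1.0, 1.0), (1.0, 1.0))
        with pytest.raises(ValueError):
            ScenarioSpec("control", (0.0, 10.0), (1.1, 1.0), (1.0, 1.0))


class TestPopulationCoupling:
    def test_tension_retardation_traction_monotone(self, optics, substrate):
        """Across a zero-noise population, total tension, total
        retardation and total traction rank identically (Spearman > 0.9)."""
        grid = ImageGrid(128, 128, 0.2)
        tensions, rets, tracs = [], [], []
        rng = np.random.default_rng(11)
        for s in range(30):
            scale = 12.0 * rng.uniform(0.5, 2.0)
            m = synthgen.generate_cell_model(grid, tension_scale=scale, seed=s)
            tensions.append(m.total_tension)
            ret = synthgen.forward_retardation(
                synthgen.intracellular_stress(m), optics
            )
            rets.append(ret.retardation.sum() * grid.pixel_area)
            t = synthgen.focal_adhesion_tractions(m, substrate)
            tracs.append(t.magnitude().sum() * grid.pixel_area)
        for a, b in [(tensions, rets), (tensions, tracs), (rets, tracs)]:
            rho = sps.spearmanr(a, b).statistic
            assert rho > 0.9
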