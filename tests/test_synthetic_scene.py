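"""Synthetic scene generator: spectra, particle fields, rendering, tables."""

import numpy as np
import pandas as pd
import pytest

from pomscan import preprocess as pp
from pomscan import synthetic_scene as ss
from pomscan.profile_stats import pearson


def continuum_depth(lib, name, wl, shoulders=(2150.0, 2320.0)):
    """Absorption depth below the straight-line continuum between shoulders."""
    grid = lib.grid.centers
    spectrum = lib.spectrum(name)
    lo, hi = (np.interp(s, grid, spectrum) for s in shoulders)
    continuum = lo + (hi - lo) * (wl - shoulders[0]) / (shoulders[1] - shoulders[0])
    return continuum - np.interp(wl, grid, spectrum)


class TestMakeEndmembers:
    def test_mineral_has_phyllosilicate_feature(self, asd_library):
        # the 2206 nm Al-OH dip dominates over the 2276 nm region
        assert (continuum_depth(asd_library, "MinRest", 2204.0)
                > continuum_depth(asd_library, "MinRest", 2276.0))

    def test_organic_darker_in_visible(self, asd_library):
        grid = asd_library.grid.centers
        vis = (grid >= 410) & (grid <= 990)
        assert (asd_library.spectrum("oPOM")[vis].mean()
                < asd_library.spectrum("MinRest")[vis].mean())

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_every_seed_satisfies_feature_constraints(self, seed):
        from pomscan import unmix as ux
        from pomscan.formats_io import resample_library

        lib = ss.make_endmembers(ss.asd_grid(), seed)
        assert lib.spectra.min() >= 0.02 and lib.spectra.max() <= 0.9
        grid = lib.grid.centers
        vis = (grid >= 410) & (grid <= 990)
        assert (lib.spectrum("oPOM")[vis].mean()
                < lib.spectrum("MinRest")[vis].mean())
        assert (continuum_depth(lib, "MinRest", 2204.0)
                > continuum_depth(lib, "MinRest", 2276.0))
        cam = resample_library(lib, ss.swir_camera_grid())
        em = ux.build_endmember_matrix(cam, ux.select_bands(cam.grid))
        assert em.condition_number < 100

    def test_seeds_produce_distinct_spectra(self):
        a = ss.make_endmembers(ss.asd_grid(), 0)
        b = ss.make_endmembers(ss.asd_grid(), 1)
        assert not np.array_equal(a.spectra, b.spectra)

    def test_grid_must_cover_diagnostic_range(self):
        from pomscan.formats_io import WavelengthGrid
        with pytest.raises(ValueError, match="span"):
            ss.make_endmembers(WavelengthGrid(np.arange(410.0, 2200.0)), 0)


class TestPlaceParticles:
    def test_zero_density_gives_empty_scene(self):
        cfg = ss.SceneConfig(lines=40, samples=30, particle_count_surface=0.0)
        truth = ss.place_particles(cfg)
        assert not truth.abundance.any()
        assert not truth.particle_labels.any()
        assert truth.n_particles == 0
        assert (truth.block_abundance["abundance"] == 0).all()

    def test_fixed_seed_is_deterministic(self):
        cfg = ss.SceneConfig(lines=80, samples=50, seed=4)
        a = ss.place_particles(cfg)
        b = ss.place_particles(cfg)
        assert np.array_equal(a.abundance, b.abundance)
        assert np.array_equal(a.particle_labels, b.particle_labels)
        pd.testing.assert_frame_equal(a.block_abundance, b.block_abundance)

    def test_interior_sizes_respect_area_range(self):
        cfg = ss.SceneConfig(lines=150, samples=100,
                             particle_count_surface=0.8,
                             particle_area_range=(8, 40), seed=21)
        truth = ss.place_particles(cfg)
        assert truth.n_particles > 0
        for lab in range(1, truth.n_particles + 1):
            interior = ((truth.particle_labels == lab)
                        & (truth.abundance == 1.0)).sum()
            assert interior <= 40
        # with no overlaps every interior meets the minimum too
        sizes = [((truth.particle_labels == lab)
                  & (truth.abundance == 1.0)).sum()
                 for lab in range(1, truth.n_particles + 1)]
        if sum(sizes) == (truth.abundance == 1.0).sum():
            assert min(sizes) >= 8

    def test_rim_is_half_cover(self):
        cfg = ss.SceneConfig(lines=80, samples=50, seed=4)
        truth = ss.place_particles(cfg)
        values = set(np.unique(truth.abundance).tolist())
        assert values <= {0.0, 0.5, 1.0}
        assert 0.5 in values

    def test_block_abundance_equals_blockwise_mean(self):
        cfg = ss.SceneConfig(lines=100, samples=60, seed=6)
        truth = ss.place_particles(cfg)
        for _, rec in truth.block_abundance.iterrows():
            b = next(blk for blk in truth.roi.blocks
                     if blk.row == rec.row and blk.col == rec.col)
            block = truth.abundance[b.line_start:b.line_stop,
                                    b.sample_start:b.sample_stop]
            assert rec.abundance == pytest.approx(block.mean(), abs=1e-15)

    def test_oversized_particles_rejected(self):
        with pytest.raises(ValueError, match="area"):
            ss.SceneConfig(lines=10, samples=10,
                           particle_area_range=(8, 200))

    def test_realized_coverage_matches_expectation(self):
        # density tuned for 5% expected interior coverage; the realized
        # mean over seeds matches 1 - exp(-0.05) (Poisson overlap) within
        # three standard errors
        target = 0.05
        mean_area = (8 + 40) / 2
        base = ss.SceneConfig(lines=100, samples=100, depth_decay=1e6,
                              particle_count_surface=1.0)
        scale = target * base.lines * base.samples / (
            mean_area * ss.expected_particle_count(base))
        covers = []
        for seed in range(100):
            cfg = ss.SceneConfig(lines=100, samples=100, depth_decay=1e6,
                                 particle_count_surface=scale, seed=seed)
            truth = ss.place_particles(cfg)
            covers.append((truth.abundance == 1.0).mean())
        covers = np.asarray(covers)
        expected = 1.0 - np.exp(-target)
        sem = covers.std(ddof=1) / np.sqrt(covers.size)
        assert abs(covers.mean() - expected) <= 3 * sem

    def test_density_decays_with_depth(self):
        cfg = ss.SceneConfig(lines=400, samples=100, depth_decay=3.0,
                             particle_count_surface=6.0, seed=2)
        truth = ss.place_particles(cfg)
        top = (truth.abundance[:100] == 1.0).mean()
        bottom = (truth.abundance[300:] == 1.0).mean()
        assert top > 3 * bottom


class TestRenderScene:
    def test_noiseless_render_calibrates_back_exactly(self, clean_cfg):
        truth, lib, cube, panel = ss.simulate_scene(clean_cfg)
        calib = pp.calibrate(cube, pp.ReferencePanel(panel, ss.PANEL_RHO))
        mixed = (truth.abundance[:, :, None] * lib.spectrum("oPOM")
                 + (1 - truth.abundance)[:, :, None] * lib.spectrum("MinRest"))
        assert np.abs(calib.data - mixed).max() <= 1e-6

    def test_pure_organic_pixel_yields_opom_spectrum(self, clean_cfg):
        truth, lib, cube, panel = ss.simulate_scene(clean_cfg)
        calib = pp.calibrate(cube, pp.ReferencePanel(panel, ss.PANEL_RHO))
        ys, xs = np.nonzero(truth.abundance == 1.0)
        assert ys.size > 0
        np.testing.assert_allclose(calib.data[ys[0], xs[0]],
                                   lib.spectrum("oPOM"), atol=1e-9)

    def test_line_gain_gradient_removed_by_calibration(self):
        cfg = ss.SceneConfig(lines=100, samples=40, noise_sigma=0.0,
                             illumination_amplitude=0.2,
                             particle_count_surface=0.0, seed=1)
        truth, lib, cube, panel = ss.simulate_scene(cfg)
        # raw radiance varies along track; calibrated reflectance does not
        raw_line_means = cube.data.mean(axis=(1, 2))
        assert raw_line_means.std() / raw_line_means.mean() > 0.05
        calib = pp.calibrate(cube, pp.ReferencePanel(panel, ss.PANEL_RHO))
        line_means = calib.data.mean(axis=(1, 2))
        assert line_means.std() / line_means.mean() < 0.01

    def test_missing_endmember_rejected(self, clean_cfg):
        truth = ss.place_particles(clean_cfg)
        lib = ss.make_endmembers(ss.asd_grid(), 0)
        from pomscan.formats_io import EndmemberLibrary, resample_library
        cam = resample_library(lib, clean_cfg.grid)
        renamed = EndmemberLibrary(["MinRest", "organic"], cam.spectra,
                                   cam.grid)
        with pytest.raises(KeyError, match="oPOM"):
            ss.render_scene(truth, renamed, clean_cfg)


class TestMakeFractionTable:
    def _blocks(self, abundances):
        depths = [(0, 6), (6, 12), (12, 18), (18, 24), (24, 30)]
        n = len(abundances)
        return pd.DataFrame({
            "row": np.repeat(np.arange(n // 2), 2)[:n],
            "col": np.tile([0, 1], n // 2 + 1)[:n],
            "depth_cm": [depths[r % 5] for r in np.repeat(
                np.arange(n // 2), 2)[:n]],
            "abundance": abundances,
        })

    def test_zero_noise_gives_perfect_correlation(self):
        rng = np.random.default_rng(5)
        blocks = self._blocks(rng.uniform(0.02, 0.3, 10))
        ft = ss.make_fraction_table(blocks, alpha=50.0, sigma=0.0)
        pom = ft["fPOM"] + ft["oPOM"] + ft["soPOM"]
        assert pearson(pom, ft["abundance"]) == pytest.approx(1.0, abs=1e-12)

    def test_split_proportions_and_bulk_sum(self):
        blocks = self._blocks([0.1, 0.2, 0.3, 0.4])
        ft = ss.make_fraction_table(blocks, alpha=50.0, sigma=0.0)
        np.testing.assert_allclose(ft["fPOM"], 0.55 * 50.0 * blocks["abundance"])
        np.testing.assert_allclose(ft["oPOM"], 0.25 * 50.0 * blocks["abundance"])
        np.testing.assert_allclose(ft["soPOM"], 0.20 * 50.0 * blocks["abundance"])
        np.testing.assert_allclose(
            ft["bulk"], ft[["fPOM", "oPOM", "soPOM", "MinRest"]].sum(axis=1))

    def test_all_zero_abundance_flags_undefined_correlation(self):
        blocks = self._blocks([0.0] * 10)
        ft = ss.make_fraction_table(blocks, alpha=50.0, sigma=0.5, seed=3)
        assert (ft[["fPOM", "oPOM", "soPOM"]] >= 0).all().all()
        pom = ft["fPOM"] + ft["oPOM"] + ft["soPOM"]
        assert np.isnan(pearson(pom, ft["abundance"]))

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            ss.make_fraction_table(self._blocks([0.1, 0.2, 0.3, 0.4]),
                                   alpha=50.0, sigma=-1.0)

    def test_closed_form_coupling_recovered(self):
        # sigma from r = alpha*s_a/sqrt(alpha^2 s_a^2 + sigma^2) at r=0.8
        alpha, mu_a, s_a, target = 50.0, 0.10, 0.012, 0.8
        sigma = alpha * s_a * np.sqrt(1 / target**2 - 1)
        rs = []
        for seed in range(100):
            rng = np.random.default_rng([seed, 17])
            blocks = self._blocks(np.clip(rng.normal(mu_a, s_a, 40),
                                          1e-4, None))
            ft = ss.make_fraction_table(blocks, alpha, sigma, seed=seed)
            pom = ft["fPOM"] + ft["oPOM"] + ft["soPOM"]
            rs.append(pearson(pom, ft["abundance"]))
        assert abs(np.mean(rs) - target) <= 0.05
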