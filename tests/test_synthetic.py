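"""Synthetic scene generator: endmembers, scenes, experiments, DN frames."""

import numpy as np
import pytest

from ricespec import (
    CLASS_CODES,
    ExperimentDesign,
    SceneConfig,
    calibrate_reflectance,
    compute_vi,
    generate_dn_frames,
    generate_endmembers,
    generate_experiment,
    generate_scene,
)
from ricespec.synthetic import STAGE_PHASES, stage_defaults


class TestEndmembers:
    def test_reflectance_bounds_and_grid(self, library, wavelengths):
        for role, spec in library.spectra.items():
            assert spec.shape == wavelengths.shape
            assert np.all(spec >= 0) and np.all(spec <= 1), role

    def test_leaf_nir_exceeds_water(self, library, wavelengths):
        nir = (wavelengths >= 760) & (wavelengths <= 900)
        assert library.spectra["sunlit_leaf"][nir].mean() > library.water()[nir].mean()

    def test_panicle_pri_below_classifier_cutoff(self, library, wavelengths):
        for shaded in (False, True):
            pri = compute_vi("PRI", library.panicle(shaded), wavelengths)
            assert pri <= -0.058

    def test_panicle_pri_below_leaf_pri(self, library, wavelengths):
        leaf_pri = compute_vi("PRI", library.leaf(0.5), wavelengths)
        pan_pri = compute_vi("PRI", library.panicle(), wavelengths)
        assert pan_pri < leaf_pri

    def test_zero_chlorophyll_has_no_absorption_features(self, library):
        """At chl proxy 0 the leaf spectrum equals its pigment-free baseline."""
        p = library.params
        wl = library.wavelengths
        base = (p["leaf_vis"]
                + (p["leaf_nir"] - p["leaf_vis"])
                * (1 / (1 + np.exp(-(wl - p["edge_center"]) / p["edge_width"])))
                + p["green_bump"] * np.exp(-0.5 * ((wl - 550.0) / 35.0) ** 2))
        np.testing.assert_allclose(library.leaf(0.0), np.clip(base, 0, 1), atol=1e-12)

    def test_seed_determinism(self, wavelengths):
        a = generate_endmembers(wavelengths, seed=42)
        b = generate_endmembers(wavelengths, seed=42)
        for role in a.ROLES:
            np.testing.assert_array_equal(a.spectrum(role), b.spectrum(role))

    def test_grid_must_cover_visible_to_nir(self):
        with pytest.raises(ValueError, match="400-900"):
            generate_endmembers(np.arange(500.0, 900.0, 2.0))

    def test_red_edge_shifts_with_chlorophyll(self, library, wavelengths):
        """More chlorophyll moves the red edge to longer wavelengths, the
        mechanism behind red-edge VI sensitivity to nitrogen."""
        lo = compute_vi("MTCI", library.leaf(0.2), wavelengths)
        hi = compute_vi("MTCI", library.leaf(0.9), wavelengths)
        assert hi > lo + 0.5


class TestSceneGeneration:
    def test_noiseless_vegetation_equals_endmember(self, noiseless_scene, library):
        cfg, cube, labels = noiseless_scene
        flat = cube.data.reshape(-1, cube.n_bands)
        for code, role in [(CLASS_CODES["sunlit_leaf"], "sunlit_leaf"),
                           (CLASS_CODES["shaded_leaf"], "shaded_leaf")]:
            mask = labels.ravel() == code
            expected = library.spectrum(role, chl=cfg.chl,
                                        nir_scale=cfg.canopy_nir_scale)
            np.testing.assert_array_equal(flat[mask], np.tile(expected, (mask.sum(), 1)))

    def test_green_fraction_within_tolerance(self, library):
        for stage in ("ET", "LT", "JT", "LB"):
            d = stage_defaults(stage)
            cfg = SceneConfig(stage=stage, green_fraction=d["green_fraction"],
                              lnc=d["lnc"], shade_fraction=d["shade_fraction"],
                              seed=2)
            _, labels = generate_scene(cfg, library)
            gf = np.mean(labels != CLASS_CODES["background"])
            assert abs(gf - d["green_fraction"]) <= 0.02

    def test_heading_panicle_share(self, heading_scene):
        cfg, _, labels = heading_scene
        veg = labels[labels != CLASS_CODES["background"]]
        pan = np.isin(veg, [CLASS_CODES["sunlit_panicle"], CLASS_CODES["shaded_panicle"]])
        assert abs(pan.mean() - 0.2) <= 0.03

    def test_spatial_clumping_not_salt_and_pepper(self, noiseless_scene):
        """Vegetation pixels neighbour other vegetation pixels far more often
        than chance under an i.i.d. layout."""
        _, _, labels = noiseless_scene
        veg = labels != CLASS_CODES["background"]
        gf = veg.mean()
        same = (veg[:, 1:] == veg[:, :-1]).mean()
        iid_same = gf ** 2 + (1 - gf) ** 2
        assert same > iid_same + 0.2

    def test_seed_determinism(self, library):
        cfg = SceneConfig(stage="JT", green_fraction=0.6, lnc=2.9, seed=9)
        a_cube, a_lab = generate_scene(cfg, library)
        b_cube, b_lab = generate_scene(cfg, library)
        np.testing.assert_array_equal(a_cube.data, b_cube.data)
        np.testing.assert_array_equal(a_lab, b_lab)

    def test_vegetative_stage_rejects_panicles(self):
        with pytest.raises(ValueError, match="panicle"):
            SceneConfig(stage="ET", green_fraction=0.15, lnc=4.0, panicle_fraction=0.1)

    def test_lnc_bounds_enforced(self):
        with pytest.raises(ValueError, match="LNC"):
            SceneConfig(stage="ET", green_fraction=0.15, lnc=6.0)


class TestExperiment:
    def test_design_arithmetic(self):
        design = ExperimentDesign()
        assert design.n_plots == 36
        assert len(design.treatments) == 12
        assert design.n_scenes == 432

    def test_scene_counts_from_metadata(self):
        design = ExperimentDesign()
        records = list(generate_experiment(design, seed=0, render=False))
        assert len(records) == 432
        per_date = [r for r in records if r["year"] == 2014 and r["date_index"] == 0]
        assert len(per_date) == 36

    def test_nitrogen_rate_orders_lnc_in_expectation(self):
        """N3 plots carry more leaf nitrogen than N0 plots at the same stage,
        averaged over seeds."""
        diffs = []
        for seed in range(20):
            recs = list(generate_experiment(ExperimentDesign(years=(2014,)),
                                            seed=seed, render=False))
            for stage in ("ET", "JT", "LF"):
                sub = [r for r in recs if r["stage"] == stage]
                n3 = np.mean([r["lnc"] for r in sub if r["n_rate"] == "N3"])
                n0 = np.mean([r["lnc"] for r in sub if r["n_rate"] == "N0"])
                diffs.append(n3 - n0)
        assert np.mean(diffs) > 0
        assert np.mean(np.array(diffs) > 0) > 0.9

    def test_lnc_trajectory_declines_across_stages(self):
        recs = list(generate_experiment(ExperimentDesign(years=(2014,)),
                                        seed=3, render=False))
        by_phase = {}
        for r in recs:
            by_phase.setdefault(STAGE_PHASES[r["stage"]], []).append(r["lnc"])
        means = [np.mean(by_phase[k]) for k in sorted(by_phase)]
        assert all(a > b for a, b in zip(means, means[1:]))
        assert means[0] > 3.5 and means[-1] < 2.0

    def test_rendered_record_has_truth(self):
        rec = next(generate_experiment(ExperimentDesign(years=(2014,)), seed=1,
                                       scene_kwargs={"rows": 32, "cols": 32}))
        assert rec["cube"] is not None and rec["class_map"] is not None
        assert rec["cube"].shape[:2] == (32, 32)


class TestDNRoundTrip:
    def test_zero_noise_round_trip_machine_precision(self, noiseless_scene):
        _, cube, _ = noiseless_scene
        frames = generate_dn_frames(cube, panel_reflectance=0.99)
        back = calibrate_reflectance(frames)
        np.testing.assert_allclose(back.data, cube.data, atol=1e-12)

    def test_zero_reflectance_maps_to_dark_level(self, wavelengths):
        from ricespec import SpectralCube
        cube = SpectralCube(np.zeros((2, 2, wavelengths.size)), wavelengths)
        frames = generate_dn_frames(cube, dark_level=123.0)
        np.testing.assert_allclose(frames.dn_target, 123.0)

    def test_panel_pixel_recovers_panel_reflectance(self, wavelengths):
        from ricespec import SpectralCube
        cube = SpectralCube(np.full((2, 2, wavelengths.size), 0.99), wavelengths)
        back = calibrate_reflectance(generate_dn_frames(cube, panel_reflectance=0.99))
        np.testing.assert_allclose(back.data, 0.99, atol=1e-12)

    def test_invalid_panel_reflectance(self, noiseless_scene):
        _, cube, _ = noiseless_scene
        with pytest.raises(ValueError, match="panel"):
            generate_dn_frames(cube, panel_reflectance=0.0)
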