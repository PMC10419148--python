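"""Generator geometry, determinism and population-structure unit tests."""

import dataclasses

import numpy as np
import pytest

from holocyte import synthgen as sg
from holocyte.exceptions import ConfigurationError, GeometryOverflowError


def _rng(seed=0):
    return np.random.default_rng(seed)


def _noiseless():
    return sg.ImagingConfig(background_phase_sd=0.0, background_residual_sd=0.0)


class TestNormalImage:
    def test_plain_disc_profile(self):
        shape = sg.CellShapeParams("normal_like", radius_um=3.5, elongation=1.0,
                                   dimple_depth=0.0, peak_phase_rad=1.2)
        img = sg.make_normal_phase_image(shape, _noiseless(), _rng())
        assert np.all(np.isfinite(img.phase))
        # max phase equals the peak up to the half-pixel offset of the grid centre
        assert img.phase.max() == pytest.approx(1.2, abs=0.01)
        assert img.phase.max() <= 1.2
        # mask is a disc: second moments are isotropic
        ys, xs = np.nonzero(img.mask)
        mu20 = np.var(xs)
        mu02 = np.var(ys)
        assert mu20 == pytest.approx(mu02, rel=0.02)

    def test_elongation_matches_moment_oracle(self):
        shape = sg.CellShapeParams("normal_like", radius_um=3.0, elongation=2.0,
                                   dimple_depth=0.0, peak_phase_rad=1.2)
        img = sg.make_normal_phase_image(shape, _noiseless(), _rng())
        ys, xs = np.nonzero(img.mask)
        # axis ratio of the mask from second central moments
        cov = np.cov(np.vstack([xs, ys]))
        ev = np.sort(np.linalg.eigvalsh(cov))
        ratio = np.sqrt(ev[1] / ev[0])
        assert ratio == pytest.approx(2.0, abs=0.08)

    def test_dimple_reduces_centre(self):
        base = dict(radius_um=3.5, elongation=1.0, peak_phase_rad=1.2)
        flat = sg.make_normal_phase_image(
            sg.CellShapeParams("normal_like", dimple_depth=0.0, **base), _noiseless(), _rng())
        dimpled = sg.make_normal_phase_image(
            sg.CellShapeParams("normal_like", dimple_depth=0.8, **base), _noiseless(), _rng())
        c = flat.phase.shape[0] // 2
        assert dimpled.phase[c, c] < flat.phase[c, c]

    def test_deterministic_under_fixed_seed(self):
        shape = sg.CellShapeParams("normal_like", radius_um=3.5)
        im = sg.ImagingConfig()
        a = sg.make_normal_phase_image(shape, im, _rng(42))
        b = sg.make_normal_phase_image(shape, im, _rng(42))
        assert np.array_equal(a.phase, b.phase)
        assert np.array_equal(a.mask, b.mask)

    def test_footprint_overflow_raises(self):
        shape = sg.CellShapeParams("normal_like", radius_um=9.0)
        with pytest.raises(GeometryOverflowError):
            sg.make_normal_phase_image(shape, sg.ImagingConfig(), _rng())

    def test_rejects_sickled_subtype(self):
        shape = sg.CellShapeParams("critically_sickled", radius_um=2.5)
        with pytest.raises(ConfigurationError):
            sg.make_normal_phase_image(shape, sg.ImagingConfig(), _rng())


class TestSickledImage:
    def test_zero_curvature_reduces_to_elongated_disc(self):
        im = _noiseless()
        crescent = sg.make_sickled_phase_image(
            sg.CellShapeParams("critically_sickled", radius_um=2.8, elongation=2.5,
                               curvature=0.0, peak_phase_rad=1.8, dimple_depth=0.0),
            im, _rng(0))
        disc = sg.make_normal_phase_image(
            sg.CellShapeParams("normal_like", radius_um=2.8, elongation=2.5,
                               curvature=0.0, peak_phase_rad=1.8, dimple_depth=0.0),
            im, _rng(0))
        assert np.array_equal(crescent.phase, disc.phase)

    def test_elongation_recovered_by_moment_oracle(self):
        img = sg.make_sickled_phase_image(
            sg.CellShapeParams("critically_sickled", radius_um=2.4, elongation=3.0,
                               curvature=0.0, peak_phase_rad=1.8, dimple_depth=0.0),
            _noiseless(), _rng(0))
        ys, xs = np.nonzero(img.mask)
        cov = np.cov(np.vstack([xs, ys]))
        ev = np.sort(np.linalg.eigvalsh(cov))
        assert np.sqrt(ev[1] / ev[0]) == pytest.approx(3.0, abs=0.12)

    def test_curvature_bends_centreline(self):
        base = dict(radius_um=2.8, elongation=2.5, peak_phase_rad=1.8, dimple_depth=0.0)
        straight = sg.make_sickled_phase_image(
            sg.CellShapeParams("critically_sickled", curvature=0.0, **base), _noiseless(), _rng())
        bent = sg.make_sickled_phase_image(
            sg.CellShapeParams("critically_sickled", curvature=0.8, **base), _noiseless(), _rng())
        assert not np.array_equal(straight.mask, bent.mask)
        # a bent crescent is less solid (convex deficiency grows)
        from holocyte.morphometry import compute_features
        assert compute_features(bent)["solidity"] < compute_features(straight)["solidity"]


class TestSampleGeneration:
    def test_pure_population(self):
        pop = sg.SamplePopulation("p", "NOR", 100, (1.0, 0.0, 0.0), seed=3)
        _, records = sg.generate_sample(pop, sg.ImagingConfig())
        assert len(records) == 100
        assert all(r.subtype == "normal_like" for r in records)

    def test_multinomial_counts_within_binomial_bound(self):
        pop = sg.SamplePopulation("p", "SCD", 10000, (0.5, 0.35, 0.15), seed=11)
        _, records = sg.generate_sample(pop, sg.ImagingConfig())
        n_crit = sum(r.subtype == "critically_sickled" for r in records)
        sd = np.sqrt(10000 * 0.15 * 0.85)
        assert abs(n_crit - 1500) < 4 * sd

    def test_identical_seeds_identical_tables(self):
        im = sg.ImagingConfig()
        p1 = sg.SamplePopulation("a", "SCD", 50, sg.SCD_FRACTIONS, seed=9)
        p2 = sg.SamplePopulation("a", "SCD", 50, sg.SCD_FRACTIONS, seed=9)
        im1, r1 = sg.generate_sample(p1, im)
        im2, r2 = sg.generate_sample(p2, im)
        assert [r.as_dict() for r in r1] == [r.as_dict() for r in r2]
        assert all(np.array_equal(a.phase, b.phase) for a, b in zip(im1, im2))

    def test_streaming_matches_batch(self):
        im = sg.ImagingConfig()
        pop = sg.SamplePopulation("a", "SCD", 30, sg.SCD_FRACTIONS, seed=5)
        batch_imgs, batch_recs = sg.generate_sample(pop, im)
        for (img, rec), bimg, brec in zip(sg.iter_sample_cells(pop, im), batch_imgs, batch_recs):
            assert np.array_equal(img.phase, bimg.phase)
            assert rec.as_dict() == brec.as_dict()

    def test_nor_population_rejects_critical_fraction(self):
        with pytest.raises(ConfigurationError):
            sg.SamplePopulation("p", "NOR", 10, (0.8, 0.1, 0.1), seed=0)

    def test_invalid_simplex_rejected(self):
        with pytest.raises(ConfigurationError):
            sg.SamplePopulation("p", "SCD", 10, (0.5, 0.5, 0.5), seed=0)


class TestMaskScaling:
    def test_mask_area_scales_with_radius_squared(self):
        im = _noiseless()
        for r_um in (2.0, 3.0, 4.0, 5.0):
            shape = sg.CellShapeParams("normal_like", radius_um=r_um, elongation=1.0,
                                       dimple_depth=0.3, peak_phase_rad=1.2)
            img = sg.make_normal_phase_image(shape, im, _rng())
            area_px = img.mask.sum()
            expected = np.pi * (r_um / im.pixel_pitch_um) ** 2
            assert area_px == pytest.approx(expected, rel=0.10)


class TestStudyIO:
    @pytest.fixture
    def tiny_config(self):
        mk = sg.SamplePopulation
        return sg.StudyConfig(
            imaging=sg.ImagingConfig(),
            train_scd=(mk("s1", "SCD", 20, sg.SCD_FRACTIONS, seed=1),),
            train_nor=(mk("n1", "NOR", 20, sg.NOR_FRACTIONS, seed=2),),
            test_samples=(mk("t1", "SCD", 15, (0.45, 0.29, 0.26), seed=3),),
        )

    def test_manifest_lists_every_sample(self, tiny_config, tmp_path):
        manifest = sg.generate_study(tiny_config, tmp_path)
        assert len(manifest["samples"]) == 3
        for entry in manifest["samples"]:
            assert (tmp_path / entry["tiff"]).exists()
            assert (tmp_path / entry["csv"]).exists()
            assert entry["n_cells"] in (15, 20)

    def test_regeneration_is_byte_identical(self, tiny_config, tmp_path):
        sg.generate_study(tiny_config, tmp_path / "a")
        sg.generate_study(tiny_config, tmp_path / "b")
        for name in ("s1.csv", "n1.csv", "t1.csv", "manifest.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_requested_fraction_recorded(self, tiny_config, tmp_path):
        manifest = sg.generate_study(tiny_config, tmp_path)
        t1 = next(e for e in manifest["samples"] if e["sample_id"] == "t1")
        assert t1["requested_fractions"][2] == 0.26


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"wavelength_nm": -1.0},
            {"pixel_pitch_um": 0.0},
            {"image_side": 16},
            {"background_phase_sd": -0.1},
        ],
    )
    def test_imaging_invariants(self, kwargs):
        with pytest.raises(ConfigurationError):
            sg.ImagingConfig(**kwargs)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"elongation": 0.5},
            {"dimple_depth": 1.5},
            {"curvature": -0.1},
            {"peak_phase_rad": 0.0},
        ],
    )
    def test_shape_invariants(self, kwargs):
        base = dict(subtype="normal_like", radius_um=3.0)
        with pytest.raises(ConfigurationError):
            sg.CellShapeParams(**{**base, **kwargs})
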