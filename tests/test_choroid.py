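import numpy as np
import pytest

from myovis.choroid import (
    BinarizationParams,
    BoundarySet,
    BScan,
    INNER_SUBFIELD,
    OUTER_SUBFIELD,
    Subfield,
    agreement_stats,
    choroid_mask_from_boundaries,
    choroid_metrics,
    linearize,
    niblack_binarize,
    sublayer_thickness,
)
from myovis.synthetic import ChoroidPhantomSpec, gen_choroid_phantom


def _scan(pixels, lateral=10.0, axial=10.0, fovea=None):
    px = np.asarray(pixels, dtype=float)
    return BScan(pixels=px, lateral_scale=lateral, axial_scale=axial,
                 fovea_column=px.shape[1] // 2 if fovea is None else fovea)


FULL_WIDTH = Subfield("full", 0.0, 1.79)  # whole analyzed phantom width


@pytest.fixture(scope="module")
def phantom():
    spec = ChoroidPhantomSpec(seed=3)
    scan, boundaries, labels = gen_choroid_phantom(spec)
    flat, fb, valid = linearize(scan, boundaries)
    return spec, scan, flat, fb, labels


class TestBoundarySet:
    def test_crossing_boundaries_rejected(self):
        with pytest.raises(ValueError, match="choroid-sclera"):
            BoundarySet({"rpe_bruch": np.array([10.0, 10.0]),
                         "choroid_sclera": np.array([8.0, 12.0])})

    def test_unordered_intraretinal_rejected(self):
        with pytest.raises(ValueError, match="crosses"):
            BoundarySet({"elm": np.array([20.0]), "is_os": np.array([18.0])})


class TestLinearize:
    def test_flat_boundary_is_noop(self):
        img = np.arange(40.0).reshape(8, 5) * 1.0
        b = BoundarySet({"rpe_bruch": np.full(5, 4.0), "choroid_sclera": np.full(5, 6.0)})
        flat, fb, valid = linearize(_scan(img), b)
        np.testing.assert_array_equal(flat.pixels, img)
        assert valid.all()

    def test_sloped_boundary_flattened(self):
        w = 30
        img = np.zeros((80, w))
        rpe = 10.0 + np.arange(w)  # slope 1 px/column
        b = BoundarySet({"rpe_bruch": rpe, "choroid_sclera": rpe + 10})
        _, fb, _ = linearize(_scan(img), b)
        assert np.var(fb["rpe_bruch"]) == 0.0

    def test_smooth_boundary_residual_below_half_pixel(self):
        rng = np.random.default_rng(1)
        w = 200
        x = np.arange(w)
        rpe = 40 + 8 * np.sin(2 * np.pi * x / w) + rng.normal(0, 0.2, w)
        b = BoundarySet({"rpe_bruch": rpe, "choroid_sclera": rpe + 20})
        _, fb, _ = linearize(_scan(np.zeros((120, w))), b)
        assert np.std(fb["rpe_bruch"]) < 0.5

    def test_missing_boundary_rejected(self):
        b = BoundarySet({"choroid_sclera": np.full(5, 6.0)})
        with pytest.raises(ValueError, match="rpe_bruch"):
            linearize(_scan(np.zeros((10, 5))), b)


class TestNiblack:
    def test_uniform_region_has_empty_lumen(self):
        scan = _scan(np.full((60, 60), 100.0))
        mask = np.ones((60, 60), dtype=bool)
        lumen = niblack_binarize(scan, mask, BinarizationParams(window=11, k=-0.2))
        assert not lumen.any()

    def test_dark_blocks_classified_lumen(self):
        # central 20-px dark block; the 39-px window around every dark pixel
        # spans both levels, so the local threshold falls between them
        img = np.full((40, 80), 220.0)
        dark = np.zeros(80, dtype=bool)
        dark[30:50] = True
        img[:, dark] = 20.0
        scan = _scan(img)
        mask = np.ones_like(img, dtype=bool)
        lumen = niblack_binarize(scan, mask, BinarizationParams(window=39, k=-0.2))
        assert lumen[:, dark].all()
        assert not lumen[:, ~dark].any()

    def test_window_larger_than_image_rejected(self):
        scan = _scan(np.zeros((20, 20)))
        with pytest.raises(ValueError, match="window"):
            niblack_binarize(scan, np.ones((20, 20), bool), BinarizationParams(window=51))

    def test_cvi_invariant_to_affine_intensity_rescaling(self, phantom):
        _, _, flat, fb, _ = phantom
        choroid = choroid_mask_from_boundaries(flat, fb)
        params = BinarizationParams()
        lumen_a = niblack_binarize(flat, choroid, params)
        rescaled = BScan(pixels=2.5 * flat.pixels + 40.0, lateral_scale=flat.lateral_scale,
                         axial_scale=flat.axial_scale, fovea_column=flat.fovea_column)
        lumen_b = niblack_binarize(rescaled, choroid, params)
        np.testing.assert_array_equal(lumen_a, lumen_b)


class TestChoroidMetrics:
    def test_arithmetic_example(self):
        # 20 columns x 50 rows of choroid = 1000 px, 650 of them lumen
        h, w = 60, 20
        img = np.zeros((h, w))
        b = BoundarySet({"rpe_bruch": np.full(w, 5.0), "choroid_sclera": np.full(w, 55.0)})
        scan = _scan(img, lateral=10.0, axial=10.0, fovea=10)
        lumen = np.zeros((h, w), dtype=bool)
        lumen[5:38, :] = True  # 33 rows x 20 cols = 660 -> trim to 650
        lumen[5, :10] = False
        sub = Subfield("all", 0.0, 0.2)  # covers every column around the fovea
        q = choroid_metrics(scan, b, lumen, sub)
        assert q.TCA == pytest.approx(0.1)
        assert q.LA == pytest.approx(0.065)
        assert q.SA == pytest.approx(0.035)
        assert q.CVI == pytest.approx(0.65)
        assert q.CT == pytest.approx(500.0)

    def test_empty_lumen_gives_zero_cvi(self):
        w = 20
        b = BoundarySet({"rpe_bruch": np.full(w, 5.0), "choroid_sclera": np.full(w, 35.0)})
        scan = _scan(np.zeros((40, w)), fovea=10)
        q = choroid_metrics(scan, b, np.zeros((40, w), bool), Subfield("all", 0.0, 0.2))
        assert q.CVI == 0.0
        assert q.SA == q.TCA > 0

    def test_constant_separation_ct(self):
        w = 40
        b = BoundarySet({"rpe_bruch": np.full(w, 10.0), "choroid_sclera": np.full(w, 40.0)})
        scan = _scan(np.zeros((60, w)), axial=10.0, fovea=20)
        q = choroid_metrics(scan, b, np.zeros((60, w), bool), Subfield("all", 0.0, 0.2))
        assert q.CT == pytest.approx(300.0)

    def test_area_conservation_on_phantom(self, phantom):
        _, _, flat, fb, _ = phantom
        choroid = choroid_mask_from_boundaries(flat, fb)
        lumen = niblack_binarize(flat, choroid, BinarizationParams())
        for sub in (INNER_SUBFIELD, OUTER_SUBFIELD, FULL_WIDTH):
            q = choroid_metrics(flat, fb, lumen, sub)
            assert q.LA + q.SA == q.TCA  # pixel-count conservation, exact

    def test_lumen_fraction_recovery_improves_with_contrast(self):
        errs = []
        for stroma in (100.0, 140.0, 180.0):
            spec = ChoroidPhantomSpec(seed=0, stroma_mean=stroma)
            scan, b, labels = gen_choroid_phantom(spec)
            flat, fb, _ = linearize(scan, b)
            choroid = choroid_mask_from_boundaries(flat, fb)
            lumen = niblack_binarize(flat, choroid, BinarizationParams())
            q = choroid_metrics(flat, fb, lumen, FULL_WIDTH)
            true_frac = (labels == 2).sum() / (labels > 0).sum()
            errs.append(abs(q.CVI - true_frac))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 0.05


class TestSublayerThickness:
    def _boundaries(self, w, sep):
        names = ["inl_opl", "opl_hfl", "elm", "is_os", "os_iz", "rpe_bruch"]
        depth = 10.0
        b = {}
        for i, n in enumerate(names):
            b[n] = np.full(w, depth) + i * np.asarray(sep, dtype=float)
        b["choroid_sclera"] = b["rpe_bruch"] + 30
        return BoundarySet(b)

    def test_parallel_boundaries(self):
        b = self._boundaries(40, 5.0)
        out = sublayer_thickness(b, Subfield("all", 0.0, 0.2), axial_scale=4.0,
                                 fovea_column=20, lateral_scale=10.0)
        assert out == pytest.approx({k: 20.0 for k in out})

    def test_identical_boundaries_zero_thickness(self):
        w = 40
        b = BoundarySet({"elm": np.full(w, 12.0), "is_os": np.full(w, 12.0),
                         "rpe_bruch": np.full(w, 30.0), "choroid_sclera": np.full(w, 60.0)})
        out = sublayer_thickness(b, Subfield("all", 0.0, 0.2), axial_scale=4.0,
                                 fovea_column=20, lateral_scale=10.0)
        assert out["IS"] == 0.0

    def test_linear_ramp_mean(self):
        # separation ramps 2 -> 6 px over the analyzed columns: mean 4 px = 16 um
        w = 41
        ramp = np.linspace(2.0, 6.0, w)
        b = BoundarySet({"elm": np.full(w, 10.0), "is_os": 10.0 + ramp,
                         "rpe_bruch": np.full(w, 40.0), "choroid_sclera": np.full(w, 80.0)})
        out = sublayer_thickness(b, Subfield("all", 0.0, 0.3), axial_scale=4.0,
                                 fovea_column=20, lateral_scale=10.0)
        assert out["IS"] == pytest.approx(16.0, rel=0.01)

    def test_matches_brute_force_oracle(self, phantom):
        _, scan, _, fb, _ = phantom
        sub = INNER_SUBFIELD
        out = sublayer_thickness(fb, sub, scan.axial_scale, scan.fovea_column,
                                 scan.lateral_scale)
        # brute force: per-column subtraction, explicit loop
        lo = sub.lower_mm * 1000 / scan.lateral_scale
        hi = sub.upper_mm * 1000 / scan.lateral_scale
        cols = [j for j in range(fb.n_columns)
                if lo <= abs(j - scan.fovea_column) < hi]
        diffs = [fb["is_os"][j] - fb["elm"][j] for j in cols]
        assert out["IS"] == pytest.approx(np.mean(diffs) * scan.axial_scale, abs=1e-12)


class TestAgreementStats:
    def test_identical_series(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        out = agreement_stats(x, x)
        assert out["cor"] == 0.0
        assert out["icc"] == pytest.approx(1.0)

    def test_cor_is_1p96_sd_of_differences(self):
        rng = np.random.default_rng(2)
        a = rng.normal(10, 3, 50)
        d = rng.normal(0, 2.0, 50)
        out = agreement_stats(a, a + d)
        assert out["cor"] == pytest.approx(1.96 * np.std(d, ddof=1))

    def test_independent_series_icc_near_zero(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 200)
        b = rng.normal(0, 1, 200)
        out = agreement_stats(a, b)
        assert abs(out["icc"]) < 0.1

    def test_zero_variance_flagged(self):
        out = agreement_stats(np.full(5, 3.0), np.full(5, 3.0))
        assert out["flag"] == 1.0 and np.isnan(out["icc"])

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            agreement_stats(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
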