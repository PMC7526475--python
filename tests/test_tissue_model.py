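"""LGE normalization, CV bands, ionic remodeling, fibrotic segmentation,
and conductivity calibration."""

import numpy as np
import pytest

from valab import tissue_model as tm
from valab.tissue_model import LGEMap
from valab import monodomain_sim as ms
from valab import io as vio


def _lge(values, bp_mean=100.0, bp_sd=10.0):
    return LGEMap(intensity=np.asarray(values, dtype=float),
                  bp_mean=bp_mean, bp_sd=bp_sd)


class TestNormalizeLge:
    def test_linear_map(self):
        assert np.allclose(tm.normalize_lge(_lge([2, 4, 6])), [0, 0.5, 1])

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            tm.normalize_lge(_lge([5, 5, 5]))

    def test_affine_rescale_invariance(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            x = rng.uniform(0, 200, 50)
            a, b = rng.uniform(0.2, 5.0), rng.uniform(-10, 50)
            n1 = tm.normalize_lge(_lge(x))
            n2 = tm.normalize_lge(_lge(a * x + b))
            assert np.allclose(n1, n2, atol=1e-12)


class TestCvBands:
    @pytest.mark.parametrize("value,band", [
        (0.50, 100), (0.62, 60), (1.0, 40),
        (0.0, 100), (0.56, 80), (0.60, 60), (0.64, 40), (0.639, 60),
    ])
    def test_band_assignment(self, value, band):
        assert tm.assign_cv_bands(np.array([value]))[0] == band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tm.assign_cv_bands(np.array([1.2]))

    def test_partition_covers_unit_interval(self):
        x = np.linspace(0, 1, 1001)
        bands = tm.assign_cv_bands(x)
        assert set(np.unique(bands)) == {100, 80, 60, 40}


class TestZScore:
    def test_values(self):
        lge = _lge([100.0, 130.0, 125.0])
        assert np.allclose(tm.lge_z_score(lge), [0.0, 3.0, 2.5])

    def test_bad_sd_rejected(self):
        with pytest.raises(ValueError):
            _lge([1.0], bp_sd=0.0)


class TestIonicRemodeling:
    def test_af_body_ical(self):
        m = tm.apply_ionic_remodeling(np.zeros(1), np.zeros(1, dtype=int), True)
        assert np.isclose(m["gCaL"][0], 0.3)

    def test_pv_gkr_compounds(self):
        m = tm.apply_ionic_remodeling(np.zeros(1), np.full(1, 2), False)
        assert np.isclose(m["gKr"][0], 1.6 * 1.5)

    def test_fibrotic_gna_compounds(self):
        m = tm.apply_ionic_remodeling(np.array([4.0]), np.zeros(1, dtype=int), False)
        assert np.isclose(m["gNa"][0], 2.0 * 0.6)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            tm.apply_ionic_remodeling(np.zeros(1), np.array([7]))

    def test_layer_order_irrelevant(self):
        z = np.array([0.0, 4.0, 2.0])
        lab = np.array([0, 2, 1])
        a = tm.apply_ionic_remodeling(z, lab, True)
        # rebuild by composing the layers in a different order by hand
        b = {ch: np.ones(3) for ch in tm.CHANNELS}
        layers = [(np.ones(3, bool), tm.AF_REMODELING_MODIFIERS),
                  (z > 3, tm.FIBROTIC_MODIFIERS),
                  (lab == 1, tm.LAA_MODIFIERS),
                  (np.isin(lab, tm.PV_REGIONS), tm.PV_MODIFIERS),
                  (np.ones(3, bool), tm.LA_BASELINE_MODIFIERS)]
        for mask, table in layers:
            for ch, mval in table.items():
                b[ch][mask] *= mval
        for ch in tm.CHANNELS:
            assert np.allclose(a[ch], b[ch])


class TestFibroticRegions:
    def test_empty_when_below_threshold(self, surface):
        z = np.zeros(len(surface.vertices))
        assert len(tm.identify_fibrotic_regions(z, surface)) == 0

    def test_planted_patches_recovered(self, surface):
        rng = np.random.default_rng(1)
        z = np.zeros(len(surface.vertices))
        centers = [100, 900]
        planted = []
        for c in centers:
            d = surface.geodesic_distance([c])
            mask = d < 6.0
            z[mask] = 5.0
            planted.append(mask)
        regions = tm.identify_fibrotic_regions(z, surface)
        assert len(regions) == 2
        va = surface.vertex_areas()
        got = sorted(a for a in regions.areas_cm2)
        want = sorted(float(va[m].sum()) / 100.0 for m in planted)
        assert np.allclose(got, want)

    def test_total_area_is_partition_sum(self, surface):
        rng = np.random.default_rng(2)
        z = rng.normal(2.5, 0.8, len(surface.vertices))
        regions = tm.identify_fibrotic_regions(z, surface)
        va = surface.vertex_areas()
        assert np.isclose(regions.total_area_cm2,
                          float(va[z > 3].sum()) / 100.0)

    def test_matches_brute_force_flood_fill(self, surface):
        """Segmentation equals an independent recursive flood fill."""
        rng = np.random.default_rng(3)
        z = rng.normal(2.8, 0.5, len(surface.vertices))
        regions = tm.identify_fibrotic_regions(z, surface)
        # brute force: python-set flood fill over mesh edges
        mask = z > 3
        edges = surface.edges()
        neigh = {}
        for a, b in edges:
            if mask[a] and mask[b]:
                neigh.setdefault(a, set()).add(b)
                neigh.setdefault(b, set()).add(a)
        seen = set()
        brute = []
        for v in np.where(mask)[0]:
            if v in seen:
                continue
            stack, comp = [v], set()
            while stack:
                x = stack.pop()
                if x in comp:
                    continue
                comp.add(x)
                stack.extend(neigh.get(x, ()))
            seen |= comp
            brute.append(frozenset(int(i) for i in comp))
        got = {frozenset(int(i) for i in r) for r in regions.regions}
        assert got == set(brute)


class TestCalibration:
    def test_full_speed_scale_is_unity(self, band_scales):
        assert band_scales[100] == 1.0

    def test_scales_monotone_in_band(self, band_scales):
        assert band_scales[40] < band_scales[60] < band_scales[80] < band_scales[100]

    def test_forty_percent_band(self, band_scales):
        """s*sigma strip gives CV ratio 0.40 +- 0.02; the continuum limit
        (CV proportional to sqrt sigma) predicts s near 0.16."""
        cv0 = ms.strip_cv(1.0)
        ratio = ms.strip_cv(band_scales[40]) / cv0
        assert abs(ratio - 0.40) <= 0.02
        assert 0.1 < band_scales[40] < 0.45

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            tm.calibrate_conductivity(0.0)


def test_build_tissue_properties_worst_vertex_band(surface, patient):
    tissue = tm.build_tissue_properties(patient.surface, patient.lge)
    bands = tissue.cv_band
    tris = patient.surface.triangles
    elem_band = np.min(bands[tris], axis=1)
    slow = elem_band < 100
    assert (tissue.sigma_long[slow] < tm.SIGMA_LONG_BASELINE - 1e-12).all()
    assert (tissue.sigma_long > 0).all()


def test_scalar_map_export_roundtrip(tmp_path, patient):
    norm = tm.normalize_lge(patient.lge)
    path = tmp_path / "norm.dat"
    vio.write_dat(path, norm)
    back = vio.read_dat(path)
    assert np.allclose(back, norm, atol=1e-6)


class TestBandPartitionProperties:
    """Property-based checks of the normalization/banding contracts."""

    from hypothesis import given, settings, strategies as st

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_every_value_gets_exactly_one_band(self, values):
        bands = tm.assign_cv_bands(np.asarray(values))
        assert set(np.unique(bands)) <= {100, 80, 60, 40}
        t1, t2, t3 = tm.CV_BAND_THRESHOLDS
        for x, b in zip(values, bands):
            expect = 100 if x < t1 else 80 if x < t2 else 60 if x < t3 else 40
            assert b == expect

    @given(st.lists(st.floats(0.0, 500.0), min_size=3, max_size=40,
                    unique=True),
           st.floats(0.1, 10.0), st.floats(-50.0, 50.0))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_normalization_affine_invariant(self, values, a, b):
        x = np.asarray(values)
        n1 = tm.normalize_lge(_lge(x))
        n2 = tm.normalize_lge(_lge(a * x + b))
        assert np.allclose(n1, n2, atol=1e-9)
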