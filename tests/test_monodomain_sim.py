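"""Solver correctness: operator structure, resting stability, CV scaling,
spiral initiation, and termination detection."""

import numpy as np
import pytest

from valab import monodomain_sim as ms
from valab import phase_mapping as pm
from valab import tissue_model as tm
from valab.monodomain_sim import IonicModelParams


def _flat_patch(n=12, h=1.0):
    surf = ms.make_strip(length=n * h, width=n * h, edge_length=h)
    return surf


class TestDiffusionOperator:
    def test_zero_row_sums_and_symmetry(self, strip):
        tissue = ms.strip_tissue(strip)
        stiff, mass = ms.build_diffusion_operator(strip, tissue)
        assert np.max(np.abs(stiff.sum(axis=1))) < 1e-10
        assert abs(stiff - stiff.T).max() < 1e-12
        assert np.isclose(mass.sum(), strip.triangle_areas().sum())

    def test_constant_field_maps_to_zero(self, strip):
        tissue = ms.strip_tissue(strip)
        stiff, _ = ms.build_diffusion_operator(strip, tissue)
        assert np.max(np.abs(stiff @ np.ones(len(strip.vertices)))) < 1e-10

    def test_quadratic_field_converges_to_laplacian(self):
        """Isotropic operator action on x^2+y^2 approaches -div(D grad u) =
        -4D in the interior under refinement."""
        errs = []
        for h in (2.0, 1.0, 0.5):
            patch = _flat_patch(n=int(12 / h), h=h)
            ne = len(patch.triangles)
            nv = len(patch.vertices)
            tissue = tm.TissueProperties(
                sigma_long=np.full(ne, 1.0 / ms.DIFFUSIVITY_PER_SM),
                sigma_trans=np.full(ne, 1.0 / ms.DIFFUSIVITY_PER_SM),
                cv_band=np.full(nv, 100),
                ionic_multipliers=None)
            stiff, mass = ms.build_diffusion_operator(patch, tissue)
            x, y = patch.vertices[:, 0], patch.vertices[:, 1]
            u = x ** 2 + y ** 2
            lap = (stiff @ u) / mass   # = -div(grad u) weakly, interior
            interior = ((x > 3) & (x < x.max() - 3) & (y > 3) & (y < y.max() - 3))
            errs.append(np.abs(lap[interior] + (-4.0) * -1.0).max())
        assert errs[-1] < 0.1
        assert errs[-1] <= errs[0]

    def test_zero_conductivity_band_blocks_wave(self):
        strip = ms.make_strip(length=20, width=4, edge_length=1.0)
        ne = len(strip.triangles)
        tissue = ms.strip_tissue(strip)
        bary_x = strip.vertices[strip.triangles].mean(axis=1)[:, 0]
        band = (bary_x > 9) & (bary_x < 12)
        tissue.sigma_long[band] = 0.0
        tissue.sigma_trans[band] = 0.0
        ionic = IonicModelParams.uniform(len(strip.vertices))
        init = {"u": np.where(strip.vertices[:, 0] < 1.5, 1.0, 0.0)}
        res = ms.run_simulation(strip, tissue, ionic, init, duration=150.0)
        past = strip.vertices[:, 0] > 13
        assert (res.activation_times[past] < 0).all()

    def test_degenerate_triangle_rejected(self, strip):
        bad = ms.make_strip(edge_length=2.0)
        bad.vertices[bad.triangles[5]] = bad.vertices[bad.triangles[5][0]]
        tissue = ms.strip_tissue(bad)
        with pytest.raises(ValueError, match="degenerate"):
            ms.build_diffusion_operator(bad, tissue)


class TestRestingStability:
    def test_no_stimulus_stays_at_rest(self, strip):
        tissue = ms.strip_tissue(strip)
        ionic = IonicModelParams.uniform(len(strip.vertices))
        res = ms.run_simulation(strip, tissue, ionic, {}, duration=200.0)
        assert np.max(np.abs(res.voltage - ionic.v_rest)) < 0.1


class TestConductionVelocity:
    def test_cv_matches_calibration_target(self, band_scales):
        cv0 = ms.strip_cv(1.0)
        for band in (80, 60, 40):
            ratio = ms.strip_cv(band_scales[band]) / cv0
            assert abs(ratio - band / 100.0) <= 0.02

    def test_cv_scales_as_sqrt_sigma(self):
        """Linear regression of CV on sqrt(scale) across a 4-point sweep
        explains >99% of variance."""
        scales = np.array([0.25, 0.5, 0.75, 1.0])
        cvs = np.array([ms.strip_cv(s) for s in scales])
        x = np.sqrt(scales)
        coef = np.polyfit(x, cvs, 1)
        pred = np.polyval(coef, x)
        ss_res = ((cvs - pred) ** 2).sum()
        ss_tot = ((cvs - cvs.mean()) ** 2).sum()
        assert 1 - ss_res / ss_tot > 0.99

    def test_transverse_longitudinal_ratio(self):
        """CV across fibers over CV along fibers approximates
        sqrt(0.1/0.4) = 0.5 within 10%."""
        cv_l = ms.strip_cv(1.0, edge_length=0.25)
        cv_t = ms.strip_cv(1.0, edge_length=0.25, transverse=True)
        assert abs(cv_t / cv_l - 0.5) < 0.05

    def test_doubling_probe_distance_same_cv(self):
        strip = ms.make_strip(edge_length=0.5)
        tissue = ms.strip_tissue(strip)
        ionic = IonicModelParams.uniform(len(strip.vertices))
        init = {"u": np.where(strip.vertices[:, 0] < 1.5, 1.0, 0.0)}
        res = ms.run_simulation(strip, tissue, ionic, init, duration=150.0)
        a = ms._strip_probe(strip, 0.25)
        b = ms._strip_probe(strip, 0.50)
        c = ms._strip_probe(strip, 0.75)
        cv_ab = ms.measure_cv(res, a, b)
        cv_ac = ms.measure_cv(res, a, c)
        assert abs(cv_ab - cv_ac) / cv_ac < 0.01

    def test_unactivated_probe_rejected(self, strip):
        tissue = ms.strip_tissue(strip)
        ionic = IonicModelParams.uniform(len(strip.vertices))
        res = ms.run_simulation(strip, tissue, ionic, {}, duration=50.0)
        with pytest.raises(RuntimeError, match="not activated"):
            ms.measure_cv(res, 0, 1)

    def test_temporal_convergence(self):
        """Halving dt changes strip activation times by less than 1 ms."""
        strip = ms.make_strip(edge_length=1.0)
        tissue = ms.strip_tissue(strip)
        ionic = IonicModelParams.uniform(len(strip.vertices))
        init = {"u": np.where(strip.vertices[:, 0] < 1.5, 1.0, 0.0)}
        r1 = ms.run_simulation(strip, tissue, ionic, init, duration=120.0, dt=0.1)
        r2 = ms.run_simulation(strip, tissue, ionic, init, duration=120.0, dt=0.05)
        both = (r1.activation_times > 0) & (r2.activation_times > 0)
        assert both.mean() > 0.95
        assert np.abs(r1.activation_times[both] - r2.activation_times[both]).max() < 1.0


class TestSpiralInit:
    def test_exactly_four_singularities(self, surface):
        phi = ms.spiral_phase_field(surface)
        hits = pm.detect_ps(phi, surface)
        charges = [q for _, q in hits]
        assert len(hits) == 4
        assert sorted(charges) == [-1, -1, 1, 1]

    def test_adjacent_spirals_opposite_chirality(self, surface):
        """The two anterior spirals (and the two posterior ones) carry
        opposite topological charge."""
        phi = ms.spiral_phase_field(surface)
        hits = pm.detect_ps(phi, surface)
        bary = surface.surf_coord[surface.triangles].mean(axis=1)
        anterior = [q for e, q in hits if bary[e][1] < 0.5]
        posterior = [q for e, q in hits if bary[e][1] >= 0.5]
        assert sorted(anterior) == [-1, 1]
        assert sorted(posterior) == [-1, 1]

    def test_activation_times_within_cycle(self, patient, band_scales):
        tissue = tm.build_tissue_properties(patient.surface, patient.lge,
                                            band_scales=band_scales)
        ionic = IonicModelParams.from_tissue(tissue, seed=1,
                                             surface=patient.surface)
        init = ms.init_spiral_field(patient.surface, ionic, cycle_length=200.0)
        assert init["t_act"].min() >= 0.0
        assert init["t_act"].max() < 200.0
        assert init["u"].shape == (len(patient.surface.vertices),)

    def test_too_short_cycle_rejected(self, patient, band_scales):
        tissue = tm.build_tissue_properties(patient.surface, patient.lge,
                                            band_scales=band_scales)
        ionic = IonicModelParams.from_tissue(tissue, seed=1,
                                             surface=patient.surface)
        with pytest.raises(ValueError, match="shorter"):
            ms.init_spiral_field(patient.surface, ionic, cycle_length=60.0)


class TestTermination:
    def _result(self, voltage, dt_output=5.0):
        strip = ms.make_strip(length=4, width=2, edge_length=2.0)
        nv = len(strip.vertices)
        v = np.broadcast_to(np.asarray(voltage)[:, None], (len(voltage), nv))
        return ms.SimulationResult(
            voltage=np.array(v, dtype=np.float32), dt_output=dt_output,
            duration=(len(voltage) - 1) * dt_output, surface=strip,
            activation_times=np.full(nv, -1.0), final_state=None,
            clamped=np.zeros(nv, dtype=bool))

    def test_all_rest_terminates_at_zero(self):
        res = self._result([-81.0] * 200)
        assert ms.detect_termination(res) == 0.0

    def test_sustained_movie_returns_none(self):
        res = self._result([0.0 if i % 2 else -81.0 for i in range(200)])
        assert ms.detect_termination(res) is None

    def test_planted_quiescence_time_recovered(self):
        trace = [0.0] * 240 + [-81.0] * 160   # active until 1200 ms
        res = self._result(trace)
        t = ms.detect_termination(res)
        assert t is not None and abs(t - 1200.0) <= 5.0


def test_full_backend_not_available(patient, band_scales):
    tissue = tm.build_tissue_properties(patient.surface, patient.lge,
                                        band_scales=band_scales)
    ionic = IonicModelParams.from_tissue(tissue)
    ionic.model_kind = "atrial_full"
    with pytest.raises(NotImplementedError):
        ms.run_simulation(patient.surface, tissue, ionic, {}, duration=1.0)


def test_simulation_determinism(band_scales):
    strip = ms.make_strip(length=10, width=4, edge_length=1.0)
    tissue = ms.strip_tissue(strip)
    ionic = IonicModelParams.uniform(len(strip.vertices))
    init = {"u": np.where(strip.vertices[:, 0] < 1.5, 1.0, 0.0)}
    r1 = ms.run_simulation(strip, tissue, ionic, init, duration=80.0)
    r2 = ms.run_simulation(strip, tissue, ionic, init, duration=80.0)
    assert np.array_equal(r1.voltage, r2.voltage)


def test_af_episode_outlasts_ablation_time(cohort_cases):
    """Induced AF persists beyond the ablation-application time in every
    default-preset patient, and the cohort mean episode length covers a
    substantial fraction of the analysis window (window-scaled analogue of
    the source cohort's AF-duration spread)."""
    durations = []
    for cases in cohort_cases.values():
        for case in cases:
            t = ms.detect_termination(case.pre, quiescence_window=0.1)
            durations.append(case.pre.duration if t is None else t)
    durations = np.asarray(durations)
    window = cohort_cases[1][0].pre.duration
    assert (durations >= 150.0).all()
    assert durations.mean() >= 0.15 * window
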