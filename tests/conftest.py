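"""Shared fixtures: calibrated band scales, a reference surface/patient, and
cohort evaluations reused across structural and ordering tests."""

from __future__ import annotations

import numpy as np
import pytest

from valab import synthetic_cohort as sc
from valab import tissue_model as tm
from valab import monodomain_sim as ms
from valab import phase_mapping as pm
from valab import ablation_planner as ap
from valab import outcome_metrics as om


@pytest.fixture(scope="session")
def band_scales():
    """CV-band conductivity scales calibrated once per test session."""
    return tm.band_conductivity_scales()


@pytest.fixture(scope="session")
def surface():
    return sc.generate_surface(3)


@pytest.fixture(scope="session")
def patient():
    return sc.make_patient(7, "persistent")


@pytest.fixture(scope="session")
def strip():
    return ms.make_strip(edge_length=1.0)


class CohortCase:
    """Pre-ablation simulation plus lesion planning for one patient.

    Post-ablation simulations are run only for the strategies the structural
    and ordering checks need (PVI and all-hotspots).
    """

    def __init__(self, patient, band_scales, pre_ms=2000.0, post_ms=1500.0,
                 branch_ms=150.0):
        self.patient = patient
        surface = patient.surface
        self.tissue = tm.build_tissue_properties(surface, patient.lge,
                                                 band_scales=band_scales)
        self.ionic = ms.IonicModelParams.from_tissue(
            self.tissue, seed=patient.rng_seed, surface=surface)
        init = ms.init_spiral_field(surface, self.ionic)
        self.init_phase = init["phase"]
        pre_a = ms.run_simulation(surface, self.tissue, self.ionic, init,
                                  duration=branch_ms)
        branch = pre_a.final_state
        ub, vb, wb = branch
        pre_b = ms.run_simulation(surface, self.tissue, self.ionic,
                                  {"u": ub, "v": vb, "w": wb},
                                  duration=pre_ms - branch_ms)
        self.pre = ms.SimulationResult(
            voltage=np.vstack([pre_a.voltage, pre_b.voltage[1:]]),
            dt_output=pre_a.dt_output,
            duration=pre_a.duration + pre_b.duration, surface=surface,
            activation_times=pre_a.activation_times,
            final_state=pre_b.final_state, clamped=pre_a.clamped)
        self.branch_state = branch
        self.hotspots = pm.hotspot_map_from_result(self.pre)
        z = tm.lge_z_score(patient.lge)
        self.fibrotic = tm.identify_fibrotic_regions(z, surface)
        self.lge_norm = tm.normalize_lge(patient.lge)
        self.lesions, self.partitions, self.metrics = {}, {}, {}
        for strat in ap.STRATEGIES:
            les = ap.plan_strategy(surface, strat,
                                   fibrotic_regions=self.fibrotic,
                                   hotspots=self.hotspots)
            self.lesions[strat] = les
            self.partitions[strat] = ap.partition_post_ablation(surface, les)
            self.metrics[strat] = om.compute_lesion_metrics(
                surface, les, self.partitions[strat], self.lge_norm,
                self.hotspots)
        self.outcomes = {}
        u0, v0, w0 = self.branch_state
        for strat in ("pvi", "all_hotspots"):
            tis = ap.apply_lesions(self.tissue, self.lesions[strat])
            post = ms.run_simulation(surface, tis, self.ionic,
                                     {"u": u0, "v": v0, "w": w0},
                                     duration=post_ms)
            self.outcomes[strat] = om.classify_outcome(post)


@pytest.fixture(scope="session")
def cohort_cases(band_scales):
    """Evaluated 10-patient cohorts for three seeds (structural zeros and
    qualitative orderings are checked on these)."""
    out = {}
    for seed in (1, 2, 3):
        cohort = sc.generate_cohort(4, 6, seed)
        out[seed] = [CohortCase(p, band_scales) for p in cohort]
    return out


@pytest.fixture(scope="session")
def planted_tables():
    """Feature tables with a planted deterministic responder rule.

    Non-responder iff remaining_hotspot_area exceeds a known cutoff; all
    other features are uninformative noise.
    """
    rng = np.random.default_rng(11)
    rows = []
    for a in range(50):
        base = {
            "la_body_area": rng.normal(105, 15),
            "pv_area": rng.normal(28, 5),
            "fibrosis_area": rng.normal(25, 6),
            "mean_df": rng.normal(5.0, 0.3),
            "hotspot_area": rng.normal(25, 8),
        }
        for strat in ap.STRATEGIES:
            rha = float(rng.uniform(0, 30))
            rows.append({
                "anatomy_id": f"a{a:03d}", "strategy": strat, **base,
                "remaining_hotspot_area": rha,
                "remaining_la_area": rng.normal(85, 15),
                "remaining_fibrosis_area": rng.normal(28, 10),
                "roof_width": max(0.0, rng.normal(2.5, 1.0)),
                "min_channel_height": max(0.0, rng.normal(1.8, 0.7)),
                "responder": rha <= 15.0,
            })
    from valab import response_classifier as rc
    table = rc.build_feature_table(rows)
    train, test = rc.grouped_split(table, seed=0)
    return table, train, test


@pytest.fixture(scope="session")
def planted_rf(planted_tables):
    """Grid-searched forest trained on the planted-rule table."""
    from valab import response_classifier as rc
    _, train, test = planted_tables
    report, model, cols = rc.train_and_evaluate(
        train, test, "imaging+electrical+lesion", seed=0)
    return report, model, cols, train, test
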