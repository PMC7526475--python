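"""End-to-end virtual ablation trial.

cohort -> tissue heterogeneity -> pre-ablation AF -> PS hotspots ->
six lesion sets -> post-ablation outcomes -> feature table -> classifiers.

Desk-scale defaults (10 patients, 2 s pre-ablation and 1.5 s post-ablation
windows, surrogate kinetics, ~2 mm edge length) keep a full trial within
minutes on one CPU; all sizes are configurable.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, asdict, field
from typing import Optional

import numpy as np
import pandas as pd

from . import synthetic_cohort as sc
from . import tissue_model as tm
from . import monodomain_sim as ms
from . import phase_mapping as pm
from . import ablation_planner as ap
from . import outcome_metrics as om
from . import response_classifier as rc


@dataclass
class TrialConfig:
    n_paroxysmal: int = 4
    n_persistent: int = 6
    seed: int = 1
    subdivisions: int = 4
    pre_duration_ms: float = 2000.0
    post_duration_ms: float = 1500.0
    ablate_at_ms: float = 150.0
    cycle_length_ms: float = 200.0
    spiral_wavelength_mm: float = 45.0
    dt_ms: float = 0.1
    dt_output_ms: float = 5.0
    df_threshold_hz: float = om.DF_THRESHOLD_HZ
    pvi_distance_mm: float = ap.DEFAULT_PVI_DISTANCE_MM
    lesion_width_mm: float = ap.DEFAULT_LESION_WIDTH_MM
    smoothing_radius_mm: float = 5.0
    hotspot_k_sd: float = 1.0
    repol_het_sd: float = 0.5
    repol_het_corr_mm: float = 13.0
    calibration_edge_mm: float = 0.5
    train_fraction: float = 0.7
    classifier_seed: int = 0
    cache_dir: Optional[str] = None

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "cache_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class PatientEvaluation:
    patient_id: str
    af_class: str
    features: dict                      # imaging + electrical
    strategy_outcomes: dict             # strategy -> OutcomeLabel
    strategy_metrics: dict              # strategy -> LesionMetrics
    strategy_ablated_cm2: dict
    strategy_largest_cm2: dict
    optimal_strategy: Optional[str]
    pre_sustained_ms: float


def evaluate_patient(patient: sc.VirtualPatient, config: TrialConfig,
                     band_scales: dict) -> PatientEvaluation:
    """Run the full per-patient pipeline: AF induction, hotspot mapping, six
    ablations, outcome classification, and lesion metrics."""
    surface = patient.surface
    tissue = tm.build_tissue_properties(surface, patient.lge,
                                        band_scales=band_scales)
    ionic = ms.IonicModelParams.from_tissue(
        tissue, seed=patient.rng_seed, surface=surface,
        repol_het_sd=config.repol_het_sd,
        repol_het_corr_mm=config.repol_het_corr_mm)
    init = ms.init_spiral_field(surface, ionic, config.cycle_length_ms,
                                config.spiral_wavelength_mm, dt=config.dt_ms)
    # ablation branches from the early AF state, before self-termination can
    # dominate the cohort; the full pre-ablation window feeds the PS analysis
    t_branch = min(config.ablate_at_ms, config.pre_duration_ms)
    pre_a = ms.run_simulation(surface, tissue, ionic, init,
                              duration=t_branch, dt=config.dt_ms,
                              dt_output=config.dt_output_ms)
    branch_state = pre_a.final_state
    ua, va, wa = branch_state
    pre_b = ms.run_simulation(surface, tissue, ionic,
                              {"u": ua, "v": va, "w": wa},
                              duration=config.pre_duration_ms - t_branch,
                              dt=config.dt_ms, dt_output=config.dt_output_ms)
    pre = ms.SimulationResult(
        voltage=np.vstack([pre_a.voltage, pre_b.voltage[1:]]),
        dt_output=config.dt_output_ms,
        duration=pre_a.duration + pre_b.duration,
        surface=surface,
        activation_times=pre_a.activation_times,
        final_state=pre_b.final_state,
        clamped=pre_a.clamped)
    hotspots = pm.hotspot_map_from_result(
        pre, smoothing_radius=config.smoothing_radius_mm,
        k_sd=config.hotspot_k_sd)
    z = tm.lge_z_score(patient.lge)
    fibrotic = tm.identify_fibrotic_regions(z, surface)
    lge_norm = tm.normalize_lge(patient.lge)
    features = om.imaging_electrical_features(patient, pre, hotspots)

    terminated = ms.detect_termination(pre)
    pre_sustained = pre.duration if terminated is None else terminated

    outcomes, metrics, ablated, largest = {}, {}, {}, {}
    u0, v0, w0 = branch_state
    for strategy in ap.STRATEGIES:
        lesions = ap.plan_strategy(surface, strategy,
                                   fibrotic_regions=fibrotic, hotspots=hotspots,
                                   pvi_distance=config.pvi_distance_mm,
                                   width=config.lesion_width_mm)
        partition = ap.partition_post_ablation(surface, lesions)
        tissue_abl = ap.apply_lesions(tissue, lesions)
        post = ms.run_simulation(surface, tissue_abl, ionic,
                                 {"u": u0, "v": v0, "w": w0},
                                 duration=config.post_duration_ms,
                                 dt=config.dt_ms,
                                 dt_output=config.dt_output_ms)
        outcomes[strategy] = om.classify_outcome(post, config.df_threshold_hz)
        metrics[strategy] = om.compute_lesion_metrics(
            surface, lesions, partition, lge_norm, hotspots)
        ablated[strategy] = partition.ablated_area_cm2
        largest[strategy] = float(partition.areas_cm2[0])
    partitions = {s: type("P", (), {"ablated_area_cm2": ablated[s]})()
                  for s in ap.STRATEGIES}
    optimal = om.select_optimal_strategy(outcomes, partitions)
    return PatientEvaluation(
        patient_id=patient.id, af_class=patient.af_class, features=features,
        strategy_outcomes=outcomes, strategy_metrics=metrics,
        strategy_ablated_cm2=ablated, strategy_largest_cm2=largest,
        optimal_strategy=optimal, pre_sustained_ms=pre_sustained)


def _evaluation_to_rows(ev: PatientEvaluation) -> list:
    rows = []
    for s in ap.STRATEGIES:
        row = {"anatomy_id": ev.patient_id, "af_class": ev.af_class,
               "strategy": s, **ev.features,
               **ev.strategy_metrics[s].as_dict(),
               "ablated_area": ev.strategy_ablated_cm2[s],
               "outcome": ev.strategy_outcomes[s].category,
               "post_mean_df": ev.strategy_outcomes[s].mean_df,
               "responder": ev.strategy_outcomes[s].responder}
        rows.append(row)
    return rows


@dataclass
class TrialResults:
    config: TrialConfig
    table: pd.DataFrame                 # one row per (anatomy, strategy)
    outcome_tally: pd.DataFrame         # strategy x category counts
    optimal_distribution: dict          # strategy (or "none") -> fraction
    lesion_metric_summary: pd.DataFrame # mean +- SD per strategy
    classifier_reports: dict = field(default_factory=dict)
    runtime_s: float = 0.0

    def save(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        self.table.to_csv(os.path.join(out_dir, "cases.csv"), index=False)
        self.outcome_tally.to_csv(os.path.join(out_dir, "outcome_tally.csv"))
        self.lesion_metric_summary.to_csv(
            os.path.join(out_dir, "lesion_metrics.csv"))
        manifest = {"config": asdict(self.config),
                    "config_hash": self.config.config_hash(),
                    "optimal_distribution": self.optimal_distribution,
                    "runtime_s": self.runtime_s,
                    "classifiers": {k: {"accuracy": r.accuracy,
                                        "precision": r.precision,
                                        "recall": r.recall,
                                        "params": r.chosen_params}
                                    for k, r in self.classifier_reports.items()}}
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)


def run_trial(config: TrialConfig = TrialConfig(),
              train_classifiers: bool = True) -> TrialResults:
    """Execute the whole virtual trial; idempotent given the config seeds."""
    t0 = time.time()
    band_scales = tm.band_conductivity_scales(config.calibration_edge_mm)
    cohort = sc.generate_cohort(config.n_paroxysmal, config.n_persistent,
                                config.seed, subdivisions=config.subdivisions)
    evaluations, failures = [], []
    for patient in cohort:
        cached = _cache_load(patient, config)
        if cached is not None:
            evaluations.append(cached)
            continue
        try:
            ev = evaluate_patient(patient, config, band_scales)
        except Exception as exc:  # pragma: no cover - defensive
            failures.append((patient.id, repr(exc)))
            continue
        _cache_store(ev, config)
        evaluations.append(ev)
    if failures:
        print(f"excluded {len(failures)} patients: {failures}")
    if not evaluations:
        raise RuntimeError(f"every patient failed: {failures}")
    rows = [r for ev in evaluations for r in _evaluation_to_rows(ev)]
    table = rc.build_feature_table(rows)
    keep = [c for c in table.columns if c != "label"]
    table = table[keep + ["label"]]

    largest_mean = table.groupby("strategy")["remaining_la_area"].mean()
    order = sorted(ap.STRATEGIES, key=lambda s: -largest_mean[s])
    tally = (table.groupby(["strategy", "outcome"]).size().unstack(fill_value=0)
             .reindex(order))
    opt_counts = {s: 0 for s in ap.STRATEGIES}
    none_count = 0
    for ev in evaluations:
        if ev.optimal_strategy is None:
            none_count += 1
        else:
            opt_counts[ev.optimal_strategy] += 1
    n = max(len(evaluations), 1)
    optimal = {**{k: v / n for k, v in opt_counts.items()}, "none": none_count / n}

    metric_cols = rc.LESION_FEATURES
    summary = table.groupby("strategy")[metric_cols].agg(["mean", "std"]).reindex(order)

    reports = {}
    if train_classifiers and table["anatomy_id"].nunique() >= 4 \
            and table["label"].nunique() == 2:
        train, test = rc.grouped_split(table, config.train_fraction,
                                       config.classifier_seed)
        if train["label"].nunique() == 2:
            for fs in rc.FEATURE_SETS:
                try:
                    rep, _, _ = rc.train_and_evaluate(
                        train, test, fs, seed=config.classifier_seed)
                    reports[fs] = rep
                except ValueError:
                    pass
    return TrialResults(config=config, table=table, outcome_tally=tally,
                        optimal_distribution=optimal,
                        lesion_metric_summary=summary,
                        classifier_reports=reports,
                        runtime_s=time.time() - t0)


# ---------------------------------------------------------------------------
# per-patient cache (keyed by config hash and patient id)
# ---------------------------------------------------------------------------

def _cache_path(patient_id: str, config: TrialConfig) -> Optional[str]:
    if not config.cache_dir:
        return None
    return os.path.join(config.cache_dir,
                        f"{config.config_hash()}_{patient_id}.json")


def _cache_store(ev: PatientEvaluation, config: TrialConfig) -> None:
    path = _cache_path(ev.patient_id, config)
    if path is None:
        return
    os.makedirs(os.path.dirname(path), exist_ok=True)
    payload = {
        "patient_id": ev.patient_id, "af_class": ev.af_class,
        "features": ev.features,
        "outcomes": {s: {"category": o.category, "mean_df": o.mean_df}
                     for s, o in ev.strategy_outcomes.items()},
        "metrics": {s: m.as_dict() for s, m in ev.strategy_metrics.items()},
        "ablated": ev.strategy_ablated_cm2,
        "largest": ev.strategy_largest_cm2,
        "optimal": ev.optimal_strategy,
        "pre_sustained_ms": ev.pre_sustained_ms,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def _cache_load(patient: sc.VirtualPatient,
                config: TrialConfig) -> Optional[PatientEvaluation]:
    path = _cache_path(patient.id, config)
    if path is None or not os.path.exists(path):
        return None
    with open(path) as fh:
        d = json.load(fh)
    outcomes = {s: om.OutcomeLabel(o["category"], o["mean_df"],
                                   config.df_threshold_hz)
                for s, o in d["outcomes"].items()}
    metrics = {s: om.LesionMetrics(**{
        "remaining_la_area": m["remaining_la_area"],
        "remaining_fibrosis_area": m["remaining_fibrosis_area"],
        "remaining_hotspot_area": m["remaining_hotspot_area"],
        "roof_width": m["roof_width"],
        "min_channel_height": m["min_channel_height"]})
        for s, m in d["metrics"].items()}
    return PatientEvaluation(
        patient_id=d["patient_id"], af_class=d["af_class"],
        features=d["features"], strategy_outcomes=outcomes,
        strategy_metrics=metrics, strategy_ablated_cm2=d["ablated"],
        strategy_largest_cm2=d["largest"], optimal_strategy=d["optimal"],
        pre_sustained_ms=d["pre_sustained_ms"])
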