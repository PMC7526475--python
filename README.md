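# valab — a virtual atrial-fibrillation ablation laboratory

`valab` rebuilds, at desk scale and from fully synthetic data, the pipeline
of an in-silico trial of atrial-fibrillation (AF) ablation strategies:

1. **Synthetic cohort** — seeded virtual left atria: a five-holed shell
   (mitral valve + four pulmonary veins) with region labels, an analytic
   two-coordinate surface chart, a smooth random fiber field, and a
   late-gadolinium-enhancement (LGE) style intensity map with blood-pool
   reference statistics, calibrated to clinical cohort statistics
   (paroxysmal LA body ≈ 102 cm², persistent ≈ 120 cm²; fibrotic area
   ≈ 23 / 26 cm²).
2. **Tissue model** — normalized LGE maps to conduction-velocity bands
   (100/80/60/40 % of baseline at 0.56/0.60/0.64 thresholds) with
   conductivity scales calibrated by bisection against planar-wave CV on a
   strip (baseline σ_l = 0.4, σ_t = 0.1 S/m); blood-pool z > 3 defines
   fibrotic regions and rescales ionic conductances (gK1×0.5, gNa×0.6,
   gCaL×0.5) on top of regional and AF-remodeling modifiers.
3. **Monodomain simulation** — P1 finite elements with per-element
   anisotropic tensors, operator-split time stepping, and a three-variable
   phenomenological ionic surrogate; AF is initiated as four Archimedean
   spiral re-entries of alternating chirality (exactly four phase
   singularities by construction).
4. **Phase mapping** — Hilbert-transform phase, topological-charge
   phase-singularity (PS) detection, PS-density maps, and driver hotspots
   (connected regions above mean + 1 SD of density).
5. **Ablation planning** — six automated strategies: PVI, posterior-wall
   box, largest/all fibrotic regions, largest/all PS hotspots; every
   non-PVI lesion is joined to the closest boundary or lesion so no
   ablated island floats freely.
6. **Outcomes and prediction** — termination / AT / AF classification with
   a 4.7 Hz dominant-frequency threshold, five lesion metrics, per-patient
   optimal-strategy selection, and a grid-searched random-forest
   acute-responder classifier with grouped 70:30 splitting and exact
   additive feature attribution.

The scientific scope, the model's assumptions, and the deliberate
desk-scale deviations are documented in [`docs/methods.md`](docs/methods.md).

## Worked example

```python
from valab import generate_cohort, lge_z_score

cohort = generate_cohort(n_paroxysmal=2, n_persistent=3, seed=11)
p = cohort[0]
print(p.id, p.af_class)
print("LA body area  %.1f cm^2" % p.surface.region_area_cm2(0))
va = p.surface.vertex_areas()
print("fibrotic area %.1f cm^2" % (va[lge_z_score(p.lge) > 3].sum() / 100))
print("boundary loops:", len(p.surface.boundary_loops))
```

prints

```
par-000 paroxysmal
LA body area  87.3 cm^2
fibrotic area 17.6 cm^2
boundary loops: 5
```

— one seeded paroxysmal patient with its calibrated body area, its
fibrotic burden (intensity more than 3 SD above the blood-pool mean), and
the five anatomical openings. A full trial (cohort → AF simulation →
hotspot mapping → six ablations → outcome table → classifiers) runs with

```bash
valab run --out trial_out            # desk defaults: 10 patients
valab evaluate --patient-seed 7 --af-class persistent --strategy box
```

`trial_out/cases.csv` holds one row per (anatomy, strategy) with imaging,
electrical, and lesion features plus the outcome label;
`outcome_tally.csv` is the per-strategy outcome count ordered by mean
remaining LA area; `manifest.json` records the full configuration.

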