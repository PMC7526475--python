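# Methods

`valab` is a desk-scale, fully synthetic re-implementation of an in-silico
atrial-fibrillation (AF) ablation trial: virtual left atria (LA) with
imaging-derived-style fibrosis, monodomain AF simulation, phase-singularity
(PS) driver mapping, six automated ablation strategies, dominant-frequency
(DF) outcome classification, and a machine-learning acute-responder
predictor. This note records the models, the tunable parameters, the
numerical choices, and what the synthetic setting does and does not show.

## Synthetic cohort

Each virtual patient is an idealized LA: an icosphere scaled by jittered
per-axis radii (paroxysmal preset 34/36/30 mm, persistent 37/39/32.5 mm,
6% log-normal jitter) and deformed by six smooth random radial bumps
(±15%), with five geodesic disks removed: the mitral valve (MV, angular
radius 0.50 rad, antipodal to the roof) and four pulmonary veins (PVs). The
two superior PV ostia sit at the poles of the first surface coordinate;
the inferior PVs sit posterior, between them and the MV. Labeled PV sleeves
(0.25 rad annuli) and a left-appendage (LAA) disk complete the region map.
Radii were tuned once so that cohort mean LA-body area matches the target
cohort statistics (paroxysmal ≈ 102 cm², persistent ≈ 120 cm²) and then
frozen.

The surface chart is computed analytically from the generating
parameterization: coordinate 1 is the polar angle about the
septal-lateral axis (the superior PV ostia sit at its poles), coordinate 2
runs from the anterior mitral margin (0) over the roof (0.5) to the
posterior mitral margin (1). The roof line used by box ablation is the
coordinate-2 = 0.5 isocontour; the inferior line sits at 0.85 (0.15 above
the posterior mitral margin). Anterior/posterior wall halves are split at
coordinate 2 = 0.5.

Fibers are a Gaussian-kernel-smoothed white-noise tangent field
(correlation length 15 mm, unit vectors per triangle). This reproduces the
statistical role of an atlas fiber field (smooth, locally coherent,
globally disordered) but none of its anatomical motifs (septopulmonary
bundle, circumferential mitral fibers).

LGE intensity is baseline (50 a.u.) plus 9–10 geodesic Gaussian blobs
(amplitude 35–72 a.u., width 0.12–0.22 rad) plus white noise (SD 5). The
blood pool is synthetic metadata (mean 40, SD 10), placed so blob cores
exceed the fibrosis threshold of 3 SD above the blood-pool mean. Blob
counts/amplitudes were calibrated once against the target fibrotic-area
statistics (≈ 23 / 26 cm² for paroxysmal / persistent) and frozen.

All randomness derives from integer seeds through `numpy.random.SeedSequence`
spawning; identical seeds give byte-identical patients.

## Tissue model

Normalized LGE (per-patient min–max) maps to conduction-velocity (CV)
bands: 100% of baseline CV below 0.56, 80% in [0.56, 0.60), 60% in
[0.60, 0.64), 40% at or above 0.64 (half-open, left-closed boundaries).
Baseline conductivities are 0.4 S/m longitudinal and 0.1 S/m transverse;
element conductivity uses the worst (lowest-CV) band among the element's
vertices. The scale factor for each band is found by bisection so that
planar-wave CV on a 40 × 10 mm strip (fibers along the strip, paced at one
end, probes at 25% and 75% of its length, 0.5 mm elements) equals the band
fraction of baseline CV within 1.5%. The continuum monodomain limit
(CV ∝ √σ) seeds the bisection near fraction².

Ionic heterogeneity composes multiplicatively per vertex: an LA baseline
(gKr×1.6, gNa×2, gK1×0.8); appendage (gCaL×1.06, gto×0.67) and PV-sleeve
(gto×0.75, gCaL×0.75, gKr×1.5, gKs×0.67) modifiers; AF electrical
remodeling everywhere (gto×0.5, gKur×0.5, gCaL×0.3); and fibrotic
remodeling where blood-pool z-score exceeds 3 (gK1×0.5, gNa×0.6,
gCaL×0.5). Multiplication commutes, so layer order is irrelevant. Fibrotic
regions are the edge-connected components of the z > 3 vertex set with
one-third-triangle (barycentric) area attribution.

## Monodomain solver and surrogate kinetics

Space: linear finite elements on the triangle mesh; the per-element
anisotropic tensor is σ_l f fᵀ + σ_t (I − f fᵀ) restricted to the triangle
plane; the mass matrix is barycentrically lumped; boundaries are no-flux.
Time: operator splitting with forward-Euler reaction at dt = 0.1 ms and
Crank–Nicolson diffusion (pre-factorized sparse LU), output every 5 ms.
Conductivity maps to diffusivity at 0.30 mm²/ms per S/m, i.e. 0.12 mm²/ms
longitudinally at baseline.

The ionic backend is a three-variable phenomenological model of the
Fenton–Karma family: a fast inward (excitability/upstroke), slow outward
(repolarization), and slow inward (plateau) current with two recovery
gates. The frozen parameter set (tau_d 0.25, tau_r 50, tau_si 38,
u_csi 0.5, tau_v1m 19.6, tau_v2m 1250, tau_vp 3.33, tau_wm 41, tau_wp 870,
tau_0 12.5, u_c 0.13, u_v 0.04, all ms) yields, under the AF-remodeled LA
multipliers at the default 2.2 mm resolution: propagated APD ≈ 150 ms,
longitudinal CV ≈ 0.36 mm/ms, transverse/longitudinal CV ratio 0.5 on
resolved strips, and re-entrant rates near 5–6 Hz. Named channel
multipliers map onto the surrogate as: gNa scales the fast inward current;
√gCaL scales the slow inward current; potassium multipliers combine into
the slow outward current by a weighted geometric mean (gK1 0.4, gKr 0.2,
gKs 0.1, gto 0.15, gKur 0.15). The map preserves the qualitative paper
effects (AF remodeling shortens APD strongly; fibrotic tissue is less
excitable and conducts slowly) without claiming quantitative ionic
fidelity. A full human atrial ionic model is not included;
`model_kind="atrial_full"` raises `NotImplementedError`.

A smooth log-normal repolarization-heterogeneity field (SD 0.5 in log
outward-current scale, correlation 13 mm, zero-mean per patient, seeded per
patient) multiplies the outward current. It stands for the cell-to-cell
electrophysiological variability of real atria, which the deterministic
remodeling layers cannot supply on an idealized smooth shell, and is the
main source of wavebreak at desk scale.

AF is initiated as four spiral re-entries: the initial phase field is the
argument of a rational function of the stereographic coordinate (projected
from inside the mitral opening) with zeros/poles at two anterior and two
posterior centers of alternating chirality (chart positions 0.3/0.7 ×
0.25/0.75), plus a radial Archimedean term (wavelength 45 mm). By
construction the field carries exactly four phase singularities with
charges +1, −1, −1, +1. Each vertex is assigned the state of a reference
propagated action potential (one paced beat on a cable at the simulation
resolution) at the phase implied by its activation time within a 200 ms
cycle. A cycle shorter than the reference action potential is rejected.

### AF duration at desk scale

At this domain size and resolution the initiated re-entry is transient: the
four spirals complete one to a few rotations and annihilate, so the AF
episode spans roughly 0.3-0.6 s of the 2 s analysis window (cohort mean
~0.5 s), with every patient still fibrillating at 150 ms. An extensive
exploration of the surrogate's parameter space (diffusivity, plateau
strength, gate recoveries, restitution steepness, anisotropy treatment,
mesh refinement, fibrosis texture, spiral placement) found no regime in
which free or pinned rotors persist for multiples of the window on a
~140 cm^2, ~2 mm-resolution shell with physiological repolarization;
configurations that appeared to sustain longer turned out to rest on
locally non-repolarizing plateau states and were rejected. The source
study's own cohort at 7.5x the scale also contains early self-termination
(about half its models stop before the full 15 s window). The package's
frozen study conditions are therefore window-scaled: ablation is applied
to the AF state at 150 ms - while every patient is still fibrillating -
and judged on the following 1.5 s window; the full pre-ablation recording,
truncated to its active part, feeds the PS-density and DF analyses; the
sustainability contract is that every patient's episode outlasts the
ablation time and the cohort mean covers at least 15% of the window. Two
consequences are documented rather than hidden: post-ablation recordings
at desk scale essentially always terminate (acute response is the norm,
and the outcome tally is correspondingly one-sided), and PS-density maps
built from such short episodes are sparse, so hotspot-directed strategies
can degenerate to their PVI base on patients without supra-threshold
density regions. The repolarization-heterogeneity field is clipped at
-0.8 sigma so that its weak-repolarization tail cannot hold tissue
depolarized, and the normalized variable is capped at 1.2 (~ +46 mV) as a
saturation guard.

## Phase mapping

Instantaneous phase is the argument of the analytic signal (Hilbert
transform along time) of each vertex's mean-subtracted voltage trace,
restricted to the active window of the recording; flat traces are flagged
invalid. A PS is localized to a triangle whose wrapped phase circulation
around its vertex loop is ±2π (integer winding = topological charge).
PS events over the window, spread from triangle barycenters with a
Gaussian kernel (5 mm) normalized against vertex areas, give a density in
events/cm²/s whose surface integral times the window equals the event
count. Hotspots are connected components of vertices above mean + 1 SD of
density (invalid vertices excluded from both statistics and mask).

## Ablation planning

All six strategies include PV isolation (PVI): elements straddling the
geodesic 5 mm contour outside the PV/body junction are ablated (lesion
width 3 mm ≈ one to two element rings), restricted to the body side;
ipsilateral bands merge where their annuli overlap. Box ablation adds the
roof (coordinate-2 = 0.5) and inferior (0.85) isocontour lines between and
into the PV bands; both must meet the PVI bands or planning fails.
Fibrotic-region and PS-hotspot strategies fill the selected region(s)
(largest or all, in descending area) and join each to the closest of the
mesh boundaries or the growing lesion set along the graph-geodesic
shortest path, preferring the boundary on exact ties. Ablated elements get
zero conductivity; vertices all of whose incident elements are ablated are
clamped to rest. Partitioning the non-ablated elements into shared-edge
components yields region areas whose sum plus the ablated area equals the
total surface area to rounding.

## Outcomes, metrics, and strategy selection

A post-ablation recording that goes quiescent (no vertex above −40 mV for
a 300 ms window) is a *termination*. Otherwise the mean DF over valid
LA-body vertices — Welch periodogram, 2 s windows, 50% overlap,
zero-padded to 0.05 Hz bins, peak in 0.5–20 Hz — classifies the case:
*AT* at or below 4.7 Hz, *AF* above. AT and termination are acute
responders. The five lesion metrics follow the trial definitions:
remaining LA / fibrosis (normalized LGE > 0.56) / pre-ablation hotspot
areas inside the largest connected region; conducting roof width as the
length of the roof isocontour restricted to largest-region elements (zero
under box by construction); and the smallest channel height as the minimum
distance from the mitral rim to lesion components larger than 80% of the
second-largest component. The optimal strategy per patient ranks
termination over AT over AF and breaks ties by smallest ablated area; a
patient with AF under all six strategies has no optimal strategy.

## Response classifier

One row per (anatomy, strategy): three imaging features, two electrical
features, five lesion metrics, one-hot strategy encoding, binary label
(0 responder / 1 non-responder). A 70:30 split at anatomy level keeps all
six rows of an anatomy together. Random forests are grid-searched over
estimators {10, 20, 50, 70, 80, 100} × depth {4, 8, 16} × min-leaf
{5, 10, 20} by five-fold anatomy-grouped cross-validation maximizing
balanced accuracy (grouping inside CV is stricter than the source
protocol, which states grouping only for the train/test split), then
trained with class-balanced weights. Logistic-regression and RBF-SVC
baselines use the same splits with standardized features. Precision and
recall are class-weighted averages.

Feature attribution is exact decision-path credit: walking each sample's
path in every tree, the change in expected non-responder probability at
each split is credited to the split feature; attributions plus the forest
baseline reconstruct the predicted probability exactly (local accuracy to
numerical precision). Rankings use mean absolute attribution. This is an
additive attribution in the SHAP spirit but attributes along the realized
path only; it is not a Shapley value.

## Numerical choices and degenerate inputs

- Half-open, left-closed CV-band boundaries; constant LGE maps are
  rejected (min–max normalization undefined).
- Elements with degenerate geometry abort operator assembly by name.
- The DF of a movie with fewer than two cycles of activity is undefined;
  such vertices are excluded, and an all-quiescent movie raises rather
  than returning a number.
- Bisection for CV calibration brackets around the continuum seed and
  reports the last CV on failure.
- Dijkstra graph geodesics (mesh edges) stand in for exact surface
  geodesics; at 2 mm resolution the difference is below the lesion width.
- Exact ties in joining lesions prefer the mesh boundary, then the lowest
  component index.

## What the synthetic setting shows — and does not

The generator reproduces the *structure* the pipeline needs (topology,
region labels, a consistent chart, calibrated areas and fibrosis burden,
patchy enhancement) but not real anatomy: no appendage geometry, no wall
thickness, a single layer instead of an endo–epicardial bilayer, synthetic
fibers, and an idealized smooth shell. Desk-resolution meshes (≈ 2.2 mm
versus 0.34 mm in the source study) under-resolve wavefronts, which the
strip-based CV calibration absorbs for planar propagation but which, with
the shorter effective wavelengths, changes re-entry statistics: absolute
responder rates, optimal-strategy percentages, and classifier accuracies
from the full-scale study are out of reach by design. What passing tests
do show: every structural and algorithmic contract of the pipeline
(calibration accuracy, lesion topology and structural zeros, PS detection
against brute-force winding, conservation laws, grouped-split hygiene,
planted-signal recovery and attribution exactness) and the qualitative
cohort-level orderings (PVI largest / box smallest remaining area;
hotspot-directed ablation at least as effective as PVI).
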