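"""LGE-driven tissue heterogeneity: conduction-velocity bands, ionic remodeling,
and fibrotic-region segmentation.

Normalized LGE intensity (min-max within a patient map) partitions the surface
into four conduction-velocity bands: 100% of baseline CV below 0.56, 80% in
[0.56, 0.60), 60% in [0.60, 0.64), and 40% at or above 0.64. Band boundaries
are half-open, left-closed. Conductivity scale factors for each band are found
by bisection against planar-wave CV measured on a calibration strip.

Blood-pool z-scored LGE above 3 SD marks fibrotic tissue: ionic conductances
are rescaled there (gK1 x0.5, gNa x0.6, gCaL x0.5) on top of regional and
AF-remodeling modifiers, all composed multiplicatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph

from .synthetic_cohort import AtrialSurface, LAA, LSPV, LIPV, RSPV, RIPV, PV_REGIONS

SIGMA_LONG_BASELINE = 0.4   # S/m
SIGMA_TRANS_BASELINE = 0.1  # S/m
CV_BAND_THRESHOLDS = (0.56, 0.60, 0.64)
CV_BANDS = (100, 80, 60, 40)
FIBROSIS_Z_THRESHOLD = 3.0

CHANNELS = ("gNa", "gCaL", "gK1", "gKr", "gKs", "gto", "gKur")

# multiplicative conductance modifiers, composed per vertex
LA_BASELINE_MODIFIERS = {"gKr": 1.6, "gNa": 2.0, "gK1": 0.8}
LAA_MODIFIERS = {"gCaL": 1.06, "gto": 0.67}
PV_MODIFIERS = {"gto": 0.75, "gCaL": 0.75, "gKr": 1.5, "gKs": 0.67}
AF_REMODELING_MODIFIERS = {"gto": 0.5, "gKur": 0.5, "gCaL": 0.3}
FIBROTIC_MODIFIERS = {"gK1": 0.5, "gNa": 0.6, "gCaL": 0.5}


@dataclass
class LGEMap:
    """Per-vertex LGE intensity with blood-pool reference statistics."""

    intensity: np.ndarray
    bp_mean: float
    bp_sd: float

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("LGE intensities must be finite")
        if self.bp_sd <= 0:
            raise ValueError("blood-pool SD must be positive")


@dataclass
class TissueProperties:
    sigma_long: np.ndarray        # (nt,) S/m per element
    sigma_trans: np.ndarray       # (nt,) S/m per element
    cv_band: np.ndarray           # (nv,) in {100, 80, 60, 40}
    ionic_multipliers: dict       # channel -> (nv,) array
    band_thresholds: tuple = CV_BAND_THRESHOLDS
    fibrosis_z_threshold: float = FIBROSIS_Z_THRESHOLD
    ablated_elements: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))


@dataclass
class FibroticRegionSet:
    regions: list                 # list of vertex-index arrays, descending area
    areas_cm2: np.ndarray         # matching areas

    @property
    def total_area_cm2(self) -> float:
        return float(self.areas_cm2.sum())

    def __len__(self):
        return len(self.regions)


# ---------------------------------------------------------------------------
# scalar maps
# ---------------------------------------------------------------------------

def normalize_lge(lge: LGEMap) -> np.ndarray:
    """Min-max normalize intensity to [0, 1] within the patient map."""
    lo, hi = float(lge.intensity.min()), float(lge.intensity.max())
    if hi <= lo:
        raise ValueError("constant LGE map: min-max normalization undefined")
    return (lge.intensity - lo) / (hi - lo)


def assign_cv_bands(norm_lge: np.ndarray) -> np.ndarray:
    """Map normalized LGE to CV bands (% of baseline), left-closed boundaries."""
    norm_lge = np.asarray(norm_lge, dtype=float)
    if norm_lge.min() < 0 or norm_lge.max() > 1:
        raise ValueError("normalized LGE values must lie in [0, 1]")
    t1, t2, t3 = CV_BAND_THRESHOLDS
    return np.select(
        [norm_lge < t1, norm_lge < t2, norm_lge < t3],
        [100, 80, 60], default=40).astype(int)


def lge_z_score(lge: LGEMap) -> np.ndarray:
    """Intensity re-expressed in SD units of the blood pool."""
    return (lge.intensity - lge.bp_mean) / lge.bp_sd


def apply_ionic_remodeling(z: np.ndarray, region_label: np.ndarray,
                           af_remodeling: bool = True) -> dict:
    """Per-vertex channel-conductance multipliers.

    Layers compose multiplicatively: LA baseline everywhere; appendage and PV
    regional modifiers; AF electrical remodeling when flagged; fibrotic
    modifiers where z exceeds 3 SD. Multiplication commutes, so layer order
    is irrelevant.
    """
    region_label = np.asarray(region_label)
    if region_label.min() < 0 or region_label.max() > 5:
        raise ValueError("unknown region label")
    nv = len(region_label)
    mult = {ch: np.ones(nv) for ch in CHANNELS}

    def apply(mask, table):
        for ch, m in table.items():
            mult[ch][mask] *= m

    apply(np.ones(nv, dtype=bool), LA_BASELINE_MODIFIERS)
    apply(region_label == LAA, LAA_MODIFIERS)
    apply(np.isin(region_label, PV_REGIONS), PV_MODIFIERS)
    if af_remodeling:
        apply(np.ones(nv, dtype=bool), AF_REMODELING_MODIFIERS)
    apply(np.asarray(z) > FIBROSIS_Z_THRESHOLD, FIBROTIC_MODIFIERS)
    return mult


# ---------------------------------------------------------------------------
# conductivity calibration
# ---------------------------------------------------------------------------

def calibrate_conductivity(target_cv_fraction: float, edge_length: float = 0.5,
                           rel_tol: float = 0.015, max_iter: int = 40,
                           _cache: dict = {}) -> float:
    """Conductivity scale s so that strip CV equals the target fraction of baseline.

    Planar waves are paced on a 40 x 10 mm strip with fibers along the strip;
    CV is measured between probes at 25% and 75% of strip length. In the
    continuous monodomain limit CV scales with the square root of conductivity,
    so the bisection is seeded near (fraction)^2; the simulated strip absorbs
    discretization effects.
    """
    from .monodomain_sim import strip_cv

    if not (0 < target_cv_fraction <= 100):
        raise ValueError("target CV fraction must lie in (0, 100]")
    key = (round(float(target_cv_fraction), 6), edge_length)
    if key in _cache:
        return _cache[key]
    frac = target_cv_fraction / 100.0
    cv0 = strip_cv(1.0, edge_length=edge_length)
    target = frac * cv0
    if abs(target_cv_fraction - 100.0) < 1e-9:
        _cache[key] = 1.0
        return 1.0
    lo, hi = 0.01, 1.5
    seed = frac ** 2
    # establish a bracket around the closed-form seed
    a, b = max(lo, 0.3 * seed), min(hi, 3.0 * seed + 0.05)
    fa = strip_cv(a, edge_length=edge_length) - target
    fb = strip_cv(b, edge_length=edge_length) - target
    it = 0
    while fa * fb > 0 and it < 8:
        a = max(lo, 0.5 * a)
        b = min(hi, 1.5 * b)
        fa = strip_cv(a, edge_length=edge_length) - target
        fb = strip_cv(b, edge_length=edge_length) - target
        it += 1
    if fa * fb > 0:
        raise RuntimeError(
            f"CV calibration failed to bracket target {target_cv_fraction}% "
            f"(cv({a})={fa + target:.3f}, cv({b})={fb + target:.3f}, "
            f"baseline {cv0:.3f} mm/ms)")
    for _ in range(max_iter):
        m = 0.5 * (a + b)
        cv = strip_cv(m, edge_length=edge_length)
        if abs(cv - target) <= rel_tol * target:
            _cache[key] = m
            return m
        if (cv - target) * fa < 0:
            b = m
        else:
            a, fa = m, cv - target
    raise RuntimeError(
        f"CV calibration did not converge for {target_cv_fraction}% "
        f"within {max_iter} bisection steps (last CV {cv:.4f}, target {target:.4f})")


def band_conductivity_scales(edge_length: float = 0.5) -> dict:
    """Calibrated conductivity scale for each CV band."""
    return {band: calibrate_conductivity(band, edge_length=edge_length)
            for band in CV_BANDS}


def build_tissue_properties(surface: AtrialSurface, lge: LGEMap,
                            af_remodeling: bool = True,
                            band_scales: dict | None = None) -> TissueProperties:
    """Assemble element conductivities and vertex ionic multipliers from an LGE map.

    Element conductivity uses the worst (lowest-CV) band among its vertices.
    """
    norm = normalize_lge(lge)
    bands = assign_cv_bands(norm)
    z = lge_z_score(lge)
    mult = apply_ionic_remodeling(z, surface.region_label, af_remodeling)
    if band_scales is None:
        band_scales = {100: 1.0, 80: 0.64, 60: 0.36, 40: 0.16}  # continuum-limit seeds
    scale_by_band = np.zeros(101)
    for b, s in band_scales.items():
        scale_by_band[b] = s
    elem_band = np.min(bands[surface.triangles], axis=1)
    s_el = scale_by_band[elem_band]
    return TissueProperties(
        sigma_long=SIGMA_LONG_BASELINE * s_el,
        sigma_trans=SIGMA_TRANS_BASELINE * s_el,
        cv_band=bands,
        ionic_multipliers=mult,
    )


# ---------------------------------------------------------------------------
# fibrotic-region segmentation
# ---------------------------------------------------------------------------

def connected_vertex_regions(mask: np.ndarray, surface: AtrialSurface) -> list:
    """Edge-connected components of a vertex mask, as vertex-index arrays."""
    idx = np.where(mask)[0]
    if len(idx) == 0:
        return []
    sub = surface.vertex_graph()[idx][:, idx]
    n, lab = csgraph.connected_components(sub, directed=False)
    return [idx[lab == k] for k in range(n)]


def identify_fibrotic_regions(z: np.ndarray, surface: AtrialSurface,
                              threshold: float = FIBROSIS_Z_THRESHOLD) -> FibroticRegionSet:
    """Supra-threshold connected components with one-ring area attribution,
    sorted by descending area."""
    mask = np.asarray(z) > threshold
    regions = connected_vertex_regions(mask, surface)
    va = surface.vertex_areas()
    areas = np.array([va[r].sum() / 100.0 for r in regions])
    order = np.argsort(-areas) if len(areas) else np.array([], dtype=int)
    return FibroticRegionSet(regions=[regions[i] for i in order],
                             areas_cm2=areas[order])
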